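"""Tests for gene-block decomposition and rearrangement classification."""
import numpy as np
import pytest

from mitokmer import (
    BlockDecomposition,
    GeneBlock,
    GenomePlan,
    VERTEBRATE_ORDER,
    architecture_string,
    classify_events,
    decompose,
    make_genome,
)
from mitokmer._seq import revcomp
from mitokmer.simulate import borchgrevinki_plan, georgianus_plan, gunnari_plan


def reference_genes(genome):
    """One sequence per gene label, in genome-forward orientation."""
    genes = {}
    for row in genome.annotation.itertuples():
        if row.gene not in genes:
            seq = genome.sequence[row.start - 1 : row.end]
            genes[row.gene] = seq if row.strand == "+" else revcomp(seq)
    return genes


def fake_decomposition(labels, strands=None, circular=True, step=500):
    strands = strands or ["+"] * len(labels)
    blocks = [
        GeneBlock(g, i * step, i * step + 100, s, 1.0, 80)
        for i, (g, s) in enumerate(zip(labels, strands))
    ]
    return BlockDecomposition(blocks, len(labels) * step, circular)


class TestDecompose:
    def test_identity_decomposition(self):
        genome = make_genome(GenomePlan(n_copies=1, seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        expected = list(genome.annotation.gene)
        assert decomp.labels == expected
        assert all(b.strand == "+" for b in decomp.blocks)
        assert all(b.query_coverage > 0.95 for b in decomp.blocks)
        assert classify_events(decomp) == []

    def test_triplicated_unit_interleaved(self):
        genome = make_genome(GenomePlan(n_copies=3, seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        for gene in ("ND6", "trnE", "trnP", "CR"):
            assert decomp.labels.count(gene) == 3
        tail = [g for g in decomp.labels if g in {"ND6", "trnE", "trnP", "CR"}]
        assert tail == ["ND6", "trnE", "trnP", "CR"] * 3

    def test_inverted_span_on_minus_strand(self):
        genome = make_genome(borchgrevinki_plan(seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        by_gene = {b.gene: b.strand for b in decomp.blocks}
        for gene in ("trnF", "12S", "trnV", "16S", "trnL1", "ND1", "trnI", "CR"):
            assert by_gene[gene] == "-"
        assert by_gene["CYTB"] == "+"

    def test_short_gene_raises(self):
        genome = make_genome(GenomePlan(n_copies=1, seed=11))
        with pytest.raises(ValueError, match="shorter than k"):
            decompose(genome.sequence, {"tiny": "ACGTACGT"}, k=19)

    def test_empty_decomposition_warns(self, rng):
        from mitokmer._seq import random_dna

        genome = make_genome(GenomePlan(n_copies=1, seed=11))
        with pytest.warns(UserWarning, match="decomposition empty"):
            decompose(random_dna(rng, 2000), {"ND6": reference_genes(genome)["ND6"]})


class TestClassify:
    def test_canonical_order_no_events(self):
        assert classify_events(fake_decomposition(VERTEBRATE_ORDER)) == []

    def test_tandem_triplication(self):
        labels = ["trnT"] + ["ND6", "trnE", "trnP", "CR"] * 3 + ["trnF"]
        events = classify_events(fake_decomposition(labels, circular=False))
        assert len(events) == 1
        assert events[0].type == "tandem_duplication"
        assert events[0].unit == ("ND6", "trnE", "trnP", "CR")
        assert events[0].n_copies == 3

    def test_remnant_suffix_detected(self):
        labels = ["trnT", "trnP", "CR"] + ["ND6", "trnE", "trnP", "CR"] * 2
        events = classify_events(fake_decomposition(labels, circular=False))
        types = {e.type: e for e in events}
        assert types["tandem_duplication"].unit == ("ND6", "trnE", "trnP", "CR")
        assert types["tandem_duplication"].n_copies == 2
        assert types["remnant_block"].unit == ("trnP", "CR")
        assert "ND6 trnE" in types["remnant_block"].evidence

    def test_single_minus_block_is_not_inversion(self):
        labels, strands = ["trnT", "ND6", "CYTB"], ["+", "-", "+"]
        events = classify_events(fake_decomposition(labels, strands, circular=False))
        assert events == []

    def test_rotation_invariance(self):
        genome = make_genome(georgianus_plan(seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        events = classify_events(decomp)
        L = decomp.target_length
        for shift in (4321, 12345):
            rotated = BlockDecomposition(
                sorted(
                    (GeneBlock(b.gene, (b.start + shift) % L,
                               (b.start + shift) % L + b.span, b.strand,
                               b.query_coverage, b.n_kmers)
                     for b in decomp.blocks),
                    key=lambda b: b.start,
                ),
                L, circular=True,
            )
            got = classify_events(rotated)
            assert [(e.type, e.unit, e.n_copies, e.span) for e in got] == \
                [(e.type, e.unit, e.n_copies, e.span) for e in events]


class TestEndToEndArchitectures:
    @pytest.mark.parametrize(
        "plan,n_copies",
        [(GenomePlan(n_copies=4, truncations=((1, 241, "G"),), seed=11), 4),
         (gunnari_plan(seed=11), 4),
         (GenomePlan(n_copies=3, seed=11), 3),
         (GenomePlan(n_copies=2, seed=11), 2)],
    )
    def test_duplication_recovered_from_sequence(self, plan, n_copies):
        genome = make_genome(plan)
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        events = classify_events(decomp)
        dups = [e for e in events if e.type == "tandem_duplication"]
        assert len(dups) == 1
        assert dups[0].unit == ("ND6", "trnE", "trnP", "CR")
        assert dups[0].n_copies == n_copies

    def test_remnant_architecture_recovered(self):
        genome = make_genome(georgianus_plan(seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        events = {e.type: e for e in classify_events(decomp)}
        assert events["tandem_duplication"].n_copies == 2
        assert events["remnant_block"].unit == ("trnP", "CR")

    def test_inversion_span_recovered(self):
        genome = make_genome(borchgrevinki_plan(seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        [event] = [e for e in classify_events(decomp) if e.type == "inversion"]
        assert set(event.unit) == {"CR", "trnF", "12S", "trnV", "16S", "trnL1",
                                   "ND1", "trnI"}
        assert abs(event.span - genome.inversion_span) <= 18

    def test_architecture_string_folds_duplication(self):
        genome = make_genome(GenomePlan(n_copies=3, seed=11))
        decomp = decompose(genome.sequence, reference_genes(genome), circular=True)
        text = architecture_string(decomp)
        assert "(ND6 trnE trnP CR)x3" in text
        assert text.startswith("trnF")
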
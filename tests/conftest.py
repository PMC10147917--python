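import numpy as np
import pytest

from mitokmer import (
    AnchorPair,
    build_kmer_index,
    call_copies,
    sample_reads,
    screen_mt_reads,
)
from mitokmer import io as mio
from mitokmer.simulate import esox_pool


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def esox_run():
    """Full end-to-end run on the heteroplasmic 4/3/1/5-copy pool.

    2000 CLR-like reads screened, anchor-matched and copy-called once per
    session; several tests share the result.
    """
    pool = esox_pool()
    reads, truth = sample_reads(pool, 2000, seed=42)
    reference = pool.variants[0]  # the dominant 4-copy variant
    genes = mio.gene_sequences(reference.sequence, reference.annotation)
    anchors = AnchorPair.from_genes(genes)
    results = screen_mt_reads(reads, reference.sequence, anchors=anchors)
    spanning = {r.read_id for r in results if r.spans_anchors}
    dup_side = {r.read_id for r in results if r.anchor_side == "duplicated"}
    index = build_kmer_index(genes["ND6"], 19)
    by_id = dict(reads)
    calls = {
        rid: call_copies(by_id[rid], index, read_id=rid) for rid in sorted(dup_side)
    }
    return {
        "pool": pool,
        "reads": reads,
        "truth": truth,
        "results": results,
        "spanning": spanning,
        "dup_side": dup_side,
        "calls": calls,
        "genes": genes,
    }
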
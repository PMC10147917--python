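"""File I/O: FASTA/FASTQ via Biopython, BED-like annotation TSVs, reports.

On-disk coordinates are 1-based inclusive (annotation TSV, report TSVs);
everything in memory is 0-based half-open.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .architecture import BlockDecomposition, RearrangementEvent
from .heteroplasmy import CopySpectrum, HeteroplasmyCall
from .kmer import CopyCall
from .repeats import TandemRepeat
from .screen import ScreenResult

ANNOTATION_COLUMNS = ["gene", "start", "end", "strand"]


def _fmt(path) -> str:
    suffix = Path(path).suffix.lower()
    return "fastq" if suffix in {".fastq", ".fq"} else "fasta"


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path) -> list[tuple[str, str]]:
    """Read a FASTA or FASTQ read file (qualities ignored)."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), _fmt(path))
    ]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path), "fasta",
    )


def write_fastq(records: Iterable[tuple[str, str]], path) -> None:
    recs = []
    for rid, seq in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_annotation(path) -> pd.DataFrame:
    """BED-like TSV (gene, start, end, strand; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (df.start < 1).any() or (df.end < df.start).any():
        raise ValueError("annotation coordinates must be 1-based inclusive")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def gene_sequences(reference: str, annotation: pd.DataFrame) -> dict[str, str]:
    """Extract one sequence per gene label (first copy wins).

    Strand is ignored on extraction: matching is strand-aware downstream.
    """
    out: dict[str, str] = {}
    for row in annotation.itertuples():
        if row.gene not in out:
            out[row.gene] = reference[int(row.start) - 1 : int(row.end)]
    return out


def _blocks_str(call: CopyCall) -> str:
    return ";".join(
        f"{b.read_start + 1}-{b.read_end}({b.strand})" for b in call.blocks
    )


def copy_calls_frame(calls: Sequence[CopyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "read_length": [c.read_length for c in calls],
            "n_blocks": [c.n_blocks for c in calls],
            "copy_count": [c.copy_count for c in calls],
            "blocks": [_blocks_str(c) for c in calls],
        }
    )


def screen_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in results],
            "read_length": [r.read_length for r in results],
            "mt_block_span": [r.mt_block_span for r in results],
            "is_mt": [r.is_mt for r in results],
            "spans_anchors": [r.spans_anchors for r in results],
            "anchor_orientation": [r.anchor_orientation for r in results],
            "anchor_side": [r.anchor_side for r in results],
        }
    )


def spectrum_frame(spectrum: CopySpectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "copy_number": list(spectrum.counts),
            "n_reads": list(spectrum.counts.values()),
        }
    )


def heteroplasmy_json(spectrum: CopySpectrum, call: HeteroplasmyCall) -> dict:
    return {
        "sample": spectrum.label,
        "n_spanning_reads": spectrum.n_spanning,
        "spectrum": {str(c): n for c, n in spectrum.counts.items()},
        "is_heteroplasmic": call.is_heteroplasmic,
        "min_support": call.min_support,
        "classes": [
            {"copy_number": c, "n_reads": n, "flag": flag}
            for c, n, flag in call.supported_classes
        ],
    }


def repeats_frame(repeats: Sequence[TandemRepeat], offset: int = 0) -> pd.DataFrame:
    """TandemRepeats -> TSV frame with 1-based inclusive intervals."""
    return pd.DataFrame(
        {
            "start": [r.start + offset + 1 for r in repeats],
            "end": [r.end + offset for r in repeats],
            "period": [r.period for r in repeats],
            "copies": [r.copies for r in repeats],
            "identity": [round(r.identity, 3) for r in repeats],
            "consensus": [r.consensus for r in repeats],
        }
    )


def decomposition_json(
    decomp: BlockDecomposition, events: Sequence[RearrangementEvent]
) -> dict:
    return {
        "target_length": decomp.target_length,
        "circular": decomp.circular,
        "blocks": [
            {
                "gene": b.gene,
                "start": b.start + 1,
                "end": b.end,
                "strand": b.strand,
                "query_coverage": round(b.query_coverage, 3),
                "n_kmers": b.n_kmers,
            }
            for b in decomp.blocks
        ],
        "events": [
            {
                "type": e.type,
                "unit": list(e.unit),
                "n_copies": e.n_copies,
                "span": e.span,
                "evidence": e.evidence,
            }
            for e in events
        ],
    }


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
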
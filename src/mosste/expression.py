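"""Sense-strand read assignment and normalized expression values.

Reads are assigned best-hit to the kept assemblies; only reads on the
assembly's sense strand count, so antisense transcription contributes
nothing. The per-condition value is reads / (assembly length in kb x total
trimmed reads in the condition) x 1e6 — an RPKM-like unit; the 1e6 factor
only rescales, every cross-condition comparison is invariant to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .align import seeded_local_align
from .io import SeqRecord

__all__ = [
    "AssignConfig",
    "ReadAssignment",
    "assign_reads",
    "count_sense_reads",
    "normalize_expression",
    "expression_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    assembly_id: str
    strand: str  # read strand relative to the assembly
    condition: str


@dataclass
class AssignConfig:
    """``min_score_frac``: a placement must score at least this fraction of
    the read length (match +1 / mismatch -2) or the read is dropped."""

    kmer: int = 11
    min_score_frac: float = 0.5


def assign_reads(
    reads_by_condition: Mapping[str, Sequence[SeqRecord]],
    assemblies: Sequence[SeqRecord],
    cfg: AssignConfig | None = None,
) -> list[ReadAssignment]:
    """Best-hit assignment of each read to the kept assemblies.

    Each read is aligned to every assembly on both strands; the single
    best-scoring placement is kept (ties go to the lexicographically
    smallest assembly id). Reads scoring below threshold everywhere are
    dropped and counted in a log message.
    """
    if not assemblies:
        raise ValueError("kept_assemblies must be non-empty")
    cfg = cfg or AssignConfig()
    assignments: list[ReadAssignment] = []
    dropped = 0
    for condition in sorted(reads_by_condition):
        for read in reads_by_condition[condition]:
            best = None
            for asm in sorted(assemblies, key=lambda a: a.id):
                hits = seeded_local_align(read, asm, kmer=cfg.kmer)
                if not hits:
                    continue
                h = hits[0]
                if best is None or h.score > best[0]:
                    best = (h.score, asm.id, h.subject_strand)
            if best is None or best[0] < cfg.min_score_frac * len(read):
                dropped += 1
                continue
            # read strand relative to assembly: the aligner reports the
            # subject strand matching the query, which is the same thing
            assignments.append(ReadAssignment(read.id, best[1], best[2], condition))
    if dropped:
        logger.info("assign_reads: %d unmappable read(s) dropped", dropped)
    return assignments


def count_sense_reads(
    assignments: Sequence[ReadAssignment],
) -> dict[tuple[str, str], int]:
    """Count assignments per (assembly, condition), sense strand only."""
    counts: dict[tuple[str, str], int] = {}
    for a in assignments:
        if a.strand != "+":
            continue
        key = (a.assembly_id, a.condition)
        counts[key] = counts.get(key, 0) + 1
    return counts


def normalize_expression(
    count: int, assembly_len_nt: int, total_trimmed_reads: int
) -> float:
    """count / (length_kb x total_reads) x 1e6 (reads/kb/million reads)."""
    if total_trimmed_reads == 0:
        raise ValueError("empty library: total_trimmed_reads is 0")
    if assembly_len_nt < 1 or total_trimmed_reads < 0:
        raise ValueError("assembly_len_nt and total_trimmed_reads must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / ((assembly_len_nt / 1000.0) * total_trimmed_reads) * 1e6


def expression_table(
    assignments: Sequence[ReadAssignment],
    assemblies: Sequence[SeqRecord],
    totals_by_condition: Mapping[str, int],
) -> pd.DataFrame:
    """Long-form expression table: one row per (assembly, condition) with
    sense read count and normalized value (zero rows included)."""
    counts = count_sense_reads(assignments)
    lengths = {a.id: len(a) for a in assemblies}
    rows = []
    for asm_id in sorted(lengths):
        for condition in sorted(totals_by_condition):
            c = counts.get((asm_id, condition), 0)
            total = totals_by_condition[condition]
            value = 0.0 if total == 0 else normalize_expression(c, lengths[asm_id], total)
            rows.append(
                {
                    "assembly_id": asm_id,
                    "condition": condition,
                    "sense_read_count": c,
                    "assembly_len_kb": lengths[asm_id] / 1000.0,
                    "total_trimmed_reads": total,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
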
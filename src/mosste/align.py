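"""Sequence alignment primitives used across the pipeline.

Three aligners live here:

* :func:`seeded_local_align` — a k-mer seeded, chained, gap-tolerant local
  DNA aligner reporting identity, coverage, strand and a Karlin–Altschul
  style e-value proxy. Seeding, diagonal chaining and maximal-scoring
  end-trimming are implemented here; the banded gapped extension within a
  chained window is delegated to edlib.
* :func:`global_align_ltrs` — Needleman–Wunsch global alignment of an LTR
  pair (match +1, mismatch -1, gap open -2, gap extend -1) for divergence
  counting; gap and N columns are excluded downstream.
* :func:`best_protein_hit` — BLOSUM62 local alignment of a translated frame
  against a protein domain consensus, for orientation calling.

The e-value proxy replaces tool-specific BLAST e-values with a fixed
formula: ``E = K_ka * m * n * exp(-lambda_ka * S)`` with lambda=1.28,
K=0.46, score S from match +1 / mismatch -2 / gap column -2, m the query
length and n the search-space length (total library length by default).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SeqRecord, revcomp

__all__ = [
    "AlignmentHit",
    "seeded_local_align",
    "evalue_proxy",
    "global_align_ltrs",
    "LTRAlignment",
    "best_protein_hit",
]

# Fixed Karlin-Altschul-style parameters for the e-value proxy.
LAMBDA_KA = 1.28
K_KA = 0.46
MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_SCORE = -2

# Diagonal band within which seed clusters are merged into one chain; also
# the extra width given to the edlib extension window.
_BAND = 32
_END_PAD = 24

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a query against a subject.

    ``identity`` is matches / alignment columns (gap columns included);
    ``query_cov`` is the aligned fraction of the query; coordinates are
    0-based half-open on the forward strand of each sequence.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    query_cov: float
    subject_strand: str  # strand of the subject relative to the query
    score: int
    evalue_proxy: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0


def evalue_proxy(score: int, query_len: int, search_space_len: int) -> float:
    """Karlin-Altschul style expected hit count for a local-alignment score."""
    if score <= 0:
        return float("inf")
    # exp underflows to 0.0 for large scores, which is the right limit here
    return K_KA * query_len * search_space_len * math.exp(-LAMBDA_KA * score)


@lru_cache(maxsize=64)
def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    # cached: read assignment aligns thousands of queries to few subjects
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _cluster_seeds(seeds: list[tuple[int, int]], k: int) -> list[tuple[int, int, int, int]]:
    """Group (q_pos, s_pos) seeds into chains of nearby diagonals.

    Returns (q_lo, q_hi, s_lo, s_hi) spans per chain. Two seeds join the
    same chain when their diagonals differ by at most the band width and
    their query positions are within a gap of 400 nt (tandem copies of the
    same subject region therefore form separate chains).
    """
    # sort by diagonal then query position
    seeds = sorted(seeds, key=lambda t: (t[1] - t[0], t[0]))
    raw: list[list[tuple[int, int]]] = []
    for q, s in seeds:
        d = s - q
        placed = False
        for chain in raw:
            cq, cs = chain[-1]
            if abs(d - (cs - cq)) <= _BAND and abs(q - cq) <= 400:
                chain.append((q, s))
                placed = True
                break
        if not placed:
            raw.append([(q, s)])
    # merge chains that overlap heavily on both axes (split diagonals)
    spans = []
    for chain in raw:
        qs = [q for q, _ in chain]
        ss = [s for _, s in chain]
        spans.append([min(qs), max(qs) + k, min(ss), max(ss) + k])
    spans.sort()
    merged: list[list[int]] = []
    for sp in spans:
        for m in merged:
            if (
                min(m[1], sp[1]) - max(m[0], sp[0]) > 0
                and min(m[3], sp[3]) - max(m[2], sp[2]) > -_BAND
            ):
                m[0], m[1] = min(m[0], sp[0]), max(m[1], sp[1])
                m[2], m[3] = min(m[2], sp[2]), max(m[3], sp[3])
                break
        else:
            merged.append(sp)
    return [tuple(m) for m in merged]


def _columns_from_cigar(cigar: str) -> list[str]:
    cols: list[str] = []
    for n, op in _CIGAR_RE.findall(cigar):
        cols.extend(op * int(n))
    return cols


def _trim_to_max_scoring(cols: list[str]) -> tuple[int, int]:
    """Kadane-style maximal-scoring contiguous run of alignment columns."""
    best, best_lo, best_hi = 0, 0, 0
    run, lo = 0, 0
    score_of = {"=": MATCH_SCORE, "X": MISMATCH_SCORE, "I": GAP_SCORE, "D": GAP_SCORE}
    for i, op in enumerate(cols):
        run += score_of[op]
        if run <= 0:
            run, lo = 0, i + 1
        elif run > best:
            best, best_lo, best_hi = run, lo, i + 1
    return best_lo, best_hi


def _extend_chain(
    q: str, subject: str, span: tuple[int, int, int, int]
) -> tuple[list[str], int, int, int, int] | None:
    """Gapped extension of a seed chain: align the padded query slice into a
    padded subject window (edlib infix mode), then trim ragged ends."""
    q_lo, q_hi, s_lo, s_hi = span
    q_lo = max(0, q_lo - _END_PAD)
    q_hi = min(len(q), q_hi + _END_PAD)
    s_lo = max(0, s_lo - _END_PAD - _BAND)
    s_hi = min(len(subject), s_hi + _END_PAD + _BAND)
    res = edlib.align(q[q_lo:q_hi], subject[s_lo:s_hi], mode="HW", task="path")
    if res["cigar"] is None:
        return None
    loc_s, loc_e = res["locations"][0]
    cols = _columns_from_cigar(res["cigar"])
    t_lo, t_hi = _trim_to_max_scoring(cols)
    if t_hi <= t_lo:
        return None
    # walk columns to convert trimmed column offsets into sequence offsets
    qa = 0
    sa = 0
    q_off = s_off = 0
    q_cols = s_cols = 0
    for i, op in enumerate(cols):
        if i == t_lo:
            q_off, s_off = qa, sa
        if t_lo <= i < t_hi:
            if op in ("=", "X", "I"):
                q_cols += 1
            if op in ("=", "X", "D"):
                s_cols += 1
        if op in ("=", "X", "I"):
            qa += 1
        if op in ("=", "X", "D"):
            sa += 1
    trimmed = cols[t_lo:t_hi]
    return (
        trimmed,
        q_lo + q_off,
        q_lo + q_off + q_cols,
        s_lo + loc_s + s_off,
        s_lo + loc_s + s_off + s_cols,
    )


def seeded_local_align(
    query: SeqRecord,
    subject: SeqRecord,
    kmer: int = 11,
    search_space_len: int | None = None,
) -> list[AlignmentHit]:
    """Local alignments of ``query`` against both strands of ``subject``.

    Returns hits sorted by score descending, ties broken by
    (subject_id, subject start). A query shorter than the seed length yields
    an empty list. ``subject_strand`` is '-' when the query matches the
    reverse complement of the subject.
    """
    if len(query) < kmer:
        return []
    n = search_space_len if search_space_len is not None else len(subject)
    index = _kmer_index(subject.sequence, kmer)
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        q = query.sequence if strand == "+" else revcomp(query.sequence)
        seeds: list[tuple[int, int]] = []
        for i in range(len(q) - kmer + 1):
            for s_pos in index.get(q[i : i + kmer], ()):
                seeds.append((i, s_pos))
        if not seeds:
            continue
        for span in _cluster_seeds(seeds, kmer):
            ext = _extend_chain(q, subject.sequence, span)
            if ext is None:
                continue
            cols, q_s, q_e, s_s, s_e = ext
            matches = cols.count("=")
            mismatches = cols.count("X")
            gaps = len(cols) - matches - mismatches
            score = MATCH_SCORE * matches + MISMATCH_SCORE * mismatches + GAP_SCORE * gaps
            if score <= 0 or len(cols) < kmer:
                continue
            if strand == "-":  # map back to forward-strand query coordinates
                q_s, q_e = len(query) - q_e, len(query) - q_s
            hits.append(
                AlignmentHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    identity=matches / len(cols),
                    aln_len=len(cols),
                    query_cov=(q_e - q_s) / len(query),
                    subject_strand=strand,
                    score=score,
                    evalue_proxy=evalue_proxy(score, len(query), n),
                    q_start=q_s,
                    q_end=q_e,
                    s_start=s_s,
                    s_end=s_e,
                )
            )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
    return hits


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose query and subject spans are mostly contained in a
    higher-scoring hit on the same strand."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if k.subject_strand != h.subject_strand:
                continue
            q_ov = min(k.q_end, h.q_end) - max(k.q_start, h.q_start)
            s_ov = min(k.s_end, h.s_end) - max(k.s_start, h.s_start)
            if q_ov > 0.7 * (h.q_end - h.q_start) and s_ov > 0.7 * (h.s_end - h.s_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Global LTR alignment


@dataclass(frozen=True)
class LTRAlignment:
    """A gapped global alignment of an LTR pair (equal-length gapped strings)."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("gapped sequences must have equal length")

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.seq1, self.seq2))


_ltr_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


def global_align_ltrs(ltr5: SeqRecord, ltr3: SeqRecord) -> LTRAlignment:
    """Needleman-Wunsch global alignment of the two LTRs of an element.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1 (the opening
    residue of a gap costs 2, each further residue 1). The first optimal
    traceback is returned; divergence counting excludes gap and N columns.
    """
    if len(ltr5.sequence) == 0 or len(ltr3.sequence) == 0:
        raise ValueError("empty LTR sequence")
    aln = _ltr_aligner.align(ltr5.sequence, ltr3.sequence)[0]
    # reconstruct gapped strings from indices (robust to renderer wrapping)
    idx = aln.indices
    s1 = "".join("-" if i < 0 else ltr5.sequence[i] for i in idx[0])
    s2 = "".join("-" if i < 0 else ltr3.sequence[i] for i in idx[1])
    return LTRAlignment(s1, s2)


# ---------------------------------------------------------------------------
# Protein local alignment (orientation calling)

_protein_aligner = Align.PairwiseAligner(
    mode="local",
    substitution_matrix=substitution_matrices.load("BLOSUM62"),
    open_gap_score=-11,
    extend_gap_score=-1,
)


def best_protein_hit(frame_aa: str, domain_aa: str) -> float:
    """Best local BLOSUM62 alignment score of a translated frame against a
    protein domain consensus. Stop codons ('*') break alignments; frames
    shorter than 10 aa score 0."""
    if len(frame_aa) < 10 or not domain_aa:
        return 0.0
    # PairwiseAligner rejects '*' with BLOSUM62; split on stops and take the best
    best = 0.0
    for segment in frame_aa.split("*"):
        if len(segment) < 10:
            continue
        seg = "".join(c if c in "ARNDCQEGHILKMFPSTWYVBZX" else "X" for c in segment)
        score = _protein_aligner.score(seg, domain_aa)
        best = max(best, float(score))
    return best
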
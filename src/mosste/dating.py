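"""LTR-retrotransposon insertion dating and expressed-copy identification.

An LTR element's two terminal repeats are identical at insertion time and
diverge independently afterwards, so the substitution-corrected distance K
between them, divided by twice the per-site per-year rate r, estimates the
insertion age: T = K / (2 r). K is the Kimura two-parameter distance,

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over the ungapped,
N-free columns of a global LTR-LTR alignment. The default rate is the moss
estimate r = 9e-9 substitutions/site/year.

Copies compatible with an expressed assembly are found either by the
stringent e-value rule (proxy exponent -90, best-hit mode) or by the 80/80
rule: >= 80% identity over >= 80% of the assembly length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import LTRAlignment, global_align_ltrs, seeded_local_align
from .io import GenomicFeature, SeqRecord

__all__ = [
    "DEFAULT_RATE",
    "LTRPairDivergence",
    "ExpressedCopyRule",
    "kimura2p",
    "estimate_age",
    "date_copy",
    "date_all_copies",
    "find_expressed_copies",
    "summarize_age_shift",
]

#: Default substitution rate, substitutions per site per year.
DEFAULT_RATE = 9e-9

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class LTRPairDivergence:
    copy_id: str
    aligned_cols: int
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # Kimura two-parameter distance
    T: float  # age in years
    r: float  # substitution rate used


@dataclass
class ExpressedCopyRule:
    """How genomic copies are matched to an expressed assembly.

    ``best_hit``: alignment e-value proxy must fall below
    10^best_hit_evalue_exponent. ``similarity_80_80``: identity >=
    ``min_identity`` over >= ``min_cov_of_assembly`` of the assembly length.
    """

    mode: str = "similarity_80_80"
    best_hit_evalue_exponent: int = -90
    min_identity: float = 0.80
    min_cov_of_assembly: float = 0.80

    def __post_init__(self) -> None:
        if self.mode not in ("best_hit", "similarity_80_80"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.min_identity <= 1 and 0 < self.min_cov_of_assembly <= 1):
            raise ValueError("thresholds must be in (0, 1]")


def kimura2p(aln: LTRAlignment, min_cols: int = 50) -> tuple[float, float, float]:
    """Transition/transversion proportions and K2P distance of an aligned
    pair. Columns with a gap or an N are excluded. Raises on fewer than
    ``min_cols`` usable columns or in the saturated-divergence domain where
    the logarithm is undefined."""
    transitions = transversions = cols = 0
    for a, b in aln.columns():
        if a not in _VALID or b not in _VALID:
            continue
        cols += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if cols < min_cols:
        raise ValueError(f"alignment too short: {cols} < {min_cols} usable columns")
    P = transitions / cols
    Q = transversions / cols
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("saturated divergence: K2P distance undefined")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, K


def estimate_age(K: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age in years, T = K / (2 r): both LTRs accumulate
    substitutions independently, so the pairwise distance is twice the
    per-lineage branch length."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("substitution rate must be > 0")
    return K / (2.0 * r)


def _ltr_records(
    genome: Sequence[SeqRecord], te_features: Sequence[GenomicFeature], copy_id: str
) -> tuple[SeqRecord, SeqRecord] | None:
    chroms = {rec.id: rec.sequence for rec in genome}
    five = three = None
    for f in te_features:
        if f.copy_id == copy_id and f.kind == "ltr5":
            five = f
        elif f.copy_id == copy_id and f.kind == "ltr3":
            three = f
    if five is None or three is None:
        return None
    return (
        SeqRecord(f"{copy_id}_ltr5", chroms[five.seq_id][five.start : five.end]),
        SeqRecord(f"{copy_id}_ltr3", chroms[three.seq_id][three.start : three.end]),
    )


def date_copy(
    genome: Sequence[SeqRecord],
    te_features: Sequence[GenomicFeature],
    copy_id: str,
    r: float = DEFAULT_RATE,
) -> LTRPairDivergence:
    """Date one complete copy from its annotated ltr5/ltr3 features."""
    pair = _ltr_records(genome, te_features, copy_id)
    if pair is None:
        raise ValueError(f"copy {copy_id!r} lacks ltr5/ltr3 annotation")
    aln = global_align_ltrs(*pair)
    P, Q, K = kimura2p(aln)
    cols = sum(
        1 for a, b in aln.columns() if a in _VALID and b in _VALID
    )
    return LTRPairDivergence(copy_id, cols, P, Q, K, estimate_age(K, r), r)


def date_all_copies(
    genome: Sequence[SeqRecord],
    te_features: Sequence[GenomicFeature],
    r: float = DEFAULT_RATE,
) -> pd.DataFrame:
    """Date every complete copy (one with both ltr5 and ltr3 features).

    Copies whose LTR pair is saturated or too short are skipped. Returns a
    table (copy_id, family, aligned_cols, P, Q, K, T_years).
    """
    family_of = {
        f.copy_id: f.family for f in te_features if f.kind == "te_copy"
    }
    with_5 = {f.copy_id for f in te_features if f.kind == "ltr5"}
    with_3 = {f.copy_id for f in te_features if f.kind == "ltr3"}
    rows = []
    for copy_id in sorted(with_5 & with_3):
        try:
            d = date_copy(genome, te_features, copy_id, r)
        except ValueError:
            continue
        rows.append(
            {
                "copy_id": d.copy_id,
                "family": family_of.get(copy_id, ""),
                "aligned_cols": d.aligned_cols,
                "P": d.P,
                "Q": d.Q,
                "K": d.K,
                "T_years": d.T,
            }
        )
    return pd.DataFrame(
        rows, columns=["copy_id", "family", "aligned_cols", "P", "Q", "K", "T_years"]
    )


def find_expressed_copies(
    assembly: SeqRecord,
    genome: Sequence[SeqRecord],
    te_features: Sequence[GenomicFeature],
    rule: ExpressedCopyRule | None = None,
    search_space_len: int | None = None,
) -> list[str]:
    """Genomic copies compatible with an expressed assembly.

    Each annotated te_copy is aligned to the assembly; copies pass by the
    configured rule. Output is sorted by identity descending (ties by
    copy_id). The e-value proxy search space defaults to the genome length.
    """
    rule = rule or ExpressedCopyRule()
    chroms = {rec.id: rec.sequence for rec in genome}
    if search_space_len is None:
        search_space_len = sum(len(s) for s in chroms.values())
    scored: list[tuple[float, str]] = []
    for f in te_features:
        if f.kind != "te_copy":
            continue
        subject = SeqRecord(f.copy_id, chroms[f.seq_id][f.start : f.end])
        hits = seeded_local_align(
            assembly, subject, search_space_len=search_space_len
        )
        if not hits:
            continue
        best = hits[0]
        if rule.mode == "best_hit":
            if best.evalue_proxy <= 10.0 ** rule.best_hit_evalue_exponent:
                scored.append((best.identity, f.copy_id))
        else:
            cov = sum(
                h.q_end - h.q_start
                for h in hits
                if h.subject_strand == best.subject_strand
                and h.identity >= rule.min_identity
            ) / len(assembly)
            if best.identity >= rule.min_identity and cov >= rule.min_cov_of_assembly:
                scored.append((best.identity, f.copy_id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [copy_id for _, copy_id in scored]


def summarize_age_shift(
    expressed: pd.DataFrame, all_copies: pd.DataFrame, bin_width: float = 0.01
) -> dict:
    """Compare K (and age) of the expressed subset against all complete
    copies: per-group medians, fixed-width K histograms and a one-sided
    rank-sum test for 'expressed younger than all'. Groups smaller than 3
    yield the statistic marked 'insufficient n'."""
    if expressed.empty or all_copies.empty:
        raise ValueError("both groups must be non-empty")
    k_exp = expressed["K"].to_numpy(dtype=float)
    k_all = all_copies["K"].to_numpy(dtype=float)
    hi = max(k_all.max(), k_exp.max())
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    summary = {
        "n_expressed": int(len(k_exp)),
        "n_all": int(len(k_all)),
        "median_K_expressed": float(np.median(k_exp)),
        "median_K_all": float(np.median(k_all)),
        "median_T_expressed": float(expressed["T_years"].median()),
        "median_T_all": float(all_copies["T_years"].median()),
        "bin_edges": edges.tolist(),
        "hist_expressed": np.histogram(k_exp, bins=edges)[0].tolist(),
        "hist_all": np.histogram(k_all, bins=edges)[0].tolist(),
    }
    if len(k_exp) < 3 or len(k_all) < 3:
        summary["shift_statistic"] = "insufficient n"
        summary["shift_pvalue"] = None
    else:
        res = stats.mannwhitneyu(k_exp, k_all, alternative="less")
        summary["shift_statistic"] = float(res.statistic)
        summary["shift_pvalue"] = float(res.pvalue)
    return summary
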
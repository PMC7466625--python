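"""Insertion-polymorphism filtering and gene-context classification.

Caller output is filtered to confident, non-reference insertions (zygosity
>= 0.7 by default — appropriate for a haploid-dominant species, where a
genuine insertion should be supported by most reads at the locus), then
each insertion point is binned by distance to the nearest annotated gene:
``inside`` (within a gene), ``near`` (closer than 1 kb) or ``far``. A
boundary distance of exactly 1 kb falls in ``far``. Distances are
point-to-interval and ignore gene strand, matching bedtools closest with
default flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicFeature, InsertionCall

__all__ = [
    "MobilityConfig",
    "BinnedInsertion",
    "UNBOUNDED",
    "filter_insertions",
    "nearest_gene_bin",
    "bin_insertions",
    "polymorphism_count_matrix",
    "near_gene_fraction",
]

#: Sentinel distance for insertions on a chromosome without any gene.
UNBOUNDED = -1


@dataclass
class MobilityConfig:
    min_zygosity: float = 0.7
    require_non_reference: bool = True
    near_gene_bp: int = 1000
    #: optional family-label aliasing applied at counting time, e.g. merging
    #: a truncated form with its full-length family
    family_aliases: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_zygosity <= 1.0):
            raise ValueError("min_zygosity must be in [0, 1]")
        if self.near_gene_bp <= 0:
            raise ValueError("near_gene_bp must be > 0")


@dataclass(frozen=True)
class BinnedInsertion:
    call: InsertionCall
    distance_bp: int  # 0 when inside a gene; UNBOUNDED when no gene on the chromosome
    bin: str  # inside / near / far

    def __post_init__(self) -> None:
        if self.bin not in ("inside", "near", "far"):
            raise ValueError(f"unknown bin {self.bin!r}")


def filter_insertions(
    calls: Sequence[InsertionCall], cfg: MobilityConfig | None = None
) -> list[InsertionCall]:
    """Keep confident calls: zygosity >= threshold (inclusive) and, when
    required, absent from the reference genome. Order is preserved and the
    operation is idempotent."""
    cfg = cfg or MobilityConfig()
    return [
        c
        for c in calls
        if c.zygosity >= cfg.min_zygosity
        and not (cfg.require_non_reference and c.in_reference)
    ]


def nearest_gene_bin(
    call: InsertionCall,
    genes: Sequence[GenomicFeature],
    cfg: MobilityConfig | None = None,
) -> BinnedInsertion:
    """Distance from the insertion point to the nearest gene on its
    chromosome, binned. A chromosome without genes yields the UNBOUNDED
    sentinel and the 'far' bin."""
    cfg = cfg or MobilityConfig()
    dist = UNBOUNDED
    for g in genes:
        if g.kind != "gene" or g.seq_id != call.seq_id:
            continue
        if g.start <= call.position < g.end:
            d = 0
        elif call.position < g.start:
            d = g.start - call.position
        else:
            d = call.position - (g.end - 1)
        if dist == UNBOUNDED or d < dist:
            dist = d
        if dist == 0:
            break
    if dist == 0:
        bin_ = "inside"
    elif dist != UNBOUNDED and dist < cfg.near_gene_bp:
        bin_ = "near"
    else:
        bin_ = "far"
    return BinnedInsertion(call, dist, bin_)


def bin_insertions(
    calls: Sequence[InsertionCall],
    genes: Sequence[GenomicFeature],
    cfg: MobilityConfig | None = None,
) -> list[BinnedInsertion]:
    cfg = cfg or MobilityConfig()
    return [nearest_gene_bin(c, genes, cfg) for c in calls]


def _family_of(call: InsertionCall, cfg: MobilityConfig) -> str:
    if cfg.family_aliases:
        return cfg.family_aliases.get(call.family, call.family)
    return call.family


def polymorphism_count_matrix(
    calls: Sequence[InsertionCall | BinnedInsertion],
    cfg: MobilityConfig | None = None,
) -> pd.DataFrame:
    """Accession x family insertion counts. Totals are never stored: use
    ``.sum(axis=1)`` / ``.sum(axis=0)`` / ``.to_numpy().sum()``, which this
    module's reports recompute on the fly. The grand total equals the input
    length."""
    cfg = cfg or MobilityConfig()
    plain = [c.call if isinstance(c, BinnedInsertion) else c for c in calls]
    if not plain:
        return pd.DataFrame(dtype=int)
    df = pd.DataFrame(
        {
            "accession": [c.accession for c in plain],
            "family": [_family_of(c, cfg) for c in plain],
        }
    )
    mat = pd.crosstab(df["accession"], df["family"])
    return mat.sort_index(axis=0).sort_index(axis=1)


def near_gene_fraction(binned: Sequence[BinnedInsertion]) -> float:
    """Percentage of insertions inside or < 1 kb from a gene, to one
    decimal place."""
    if not binned:
        raise ValueError("no calls: near-gene fraction undefined")
    hits = sum(1 for b in binned if b.bin in ("inside", "near"))
    return round(100.0 * hits / len(binned), 1)
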
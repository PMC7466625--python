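"""Classify transcript assemblies against a TE library and filter decoys.

The cascade mirrors the curation a transcript set needs before TE
expression can be trusted: assemblies without a credible library hit are
dropped; class-I (retrotransposon) assemblies whose best alignment is short
are fragments (often bare LTRs) rather than element mRNAs; assemblies whose
hits are confined to the exemplar's LTR regions are solo-LTR transcripts,
typically read-through from a neighbouring gene; assemblies split between
two families are chimeric read-through units; and assemblies oriented
antisense to the element's coding strand are regulatory by-products, not
productive TE transcripts. Only the survivors are quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import AlignmentHit, best_protein_hit, seeded_local_align
from .io import SeqRecord, TEFamily, revcomp

__all__ = [
    "ClassifierConfig",
    "ClassifiedAssembly",
    "classify_assembly",
    "detect_orientation",
    "filter_assemblies",
    "flag_readthrough",
    "verdicts_table",
]

DISCARD_REASONS = (
    "short_classI",
    "solo_ltr",
    "chimeric",
    "antisense",
    "no_hit",
    "poor_annotation",
)


@dataclass
class ClassifierConfig:
    """Thresholds of the filtering cascade.

    ``min_evalue_exponent`` applies the classification e-value cutoff
    (10^-5) to the aligner's e-value proxy; ``min_classI_len`` is the
    class-I minimum alignment length in nt (alignments must exceed it);
    ``chimera_min_secondary_cov`` is the query coverage each of two families
    must reach for the chimera rule. ``domain_library`` maps domain names
    (GAG/PR/RT/RH/INT/transposase consensus) to protein sequences; when
    empty it is derived from the TE library's family domain proteins.
    """

    min_hit_identity: float = 0.75
    min_evalue_exponent: int = -5
    min_classI_len: int = 1000
    kmer: int = 11
    chimera_min_secondary_cov: float = 0.3
    domain_library: Mapping[str, str] = field(default_factory=dict)
    domain_score_min: float = 100.0
    solo_ltr_min_ltr_frac: float = 0.9
    solo_ltr_max_internal_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_hit_identity <= 1):
            raise ValueError("min_hit_identity must be in (0, 1]")
        if not (0 < self.chimera_min_secondary_cov <= 1):
            raise ValueError("chimera_min_secondary_cov must be in (0, 1]")
        if self.min_classI_len < 0 or self.kmer < 4:
            raise ValueError("invalid min_classI_len or kmer")


@dataclass
class ClassifiedAssembly:
    assembly: SeqRecord
    best_family: str | None
    te_class: str  # "I", "II" or "none"
    hits: list[AlignmentHit]
    orientation: str  # sense / antisense / unknown
    verdict: str  # kept / discarded
    discard_reason: str | None

    def __post_init__(self) -> None:
        if self.verdict == "kept" and self.discard_reason is not None:
            raise ValueError("kept assemblies carry no discard reason")
        if self.discard_reason is not None and self.discard_reason not in DISCARD_REASONS:
            raise ValueError(f"unknown discard reason {self.discard_reason!r}")

    @property
    def top_hit(self) -> AlignmentHit | None:
        return self.hits[0] if self.hits else None


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_assembly(
    assembly: SeqRecord,
    te_library: Sequence[TEFamily],
    cfg: ClassifierConfig | None = None,
) -> ClassifiedAssembly:
    """Run the hit-based part of the cascade (everything but orientation).

    Verdict logic, in order: no passing hit -> no_hit; best family flagged
    poorly annotated -> poor_annotation; class I with no alignment longer
    than ``min_classI_len`` -> short_classI; hits confined to the exemplar's
    LTR regions with no internal coverage -> solo_ltr; two families each
    covering >= ``chimera_min_secondary_cov`` of the query -> chimeric;
    otherwise kept pending orientation. Degenerate inputs yield discard
    verdicts, never exceptions.
    """
    if not te_library:
        raise ValueError("TE library must be non-empty")
    cfg = cfg or ClassifierConfig()
    total_lib_len = sum(len(f.exemplar) for f in te_library)
    cutoff = 10.0 ** cfg.min_evalue_exponent

    by_family: dict[str, list[AlignmentHit]] = {}
    all_hits: list[AlignmentHit] = []
    for fam in te_library:
        hits = seeded_local_align(
            assembly, fam.exemplar, kmer=cfg.kmer, search_space_len=total_lib_len
        )
        passing = [
            h
            for h in hits
            if h.evalue_proxy <= cutoff and h.identity >= cfg.min_hit_identity
        ]
        if passing:
            by_family[fam.name] = passing
            all_hits.extend(passing)

    all_hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))

    def _done(verdict: str, reason: str | None, best: str | None, cls: str):
        return ClassifiedAssembly(
            assembly=assembly,
            best_family=best,
            te_class=cls,
            hits=all_hits,
            orientation="unknown",
            verdict=verdict,
            discard_reason=reason,
        )

    if not all_hits:
        return _done("discarded", "no_hit", None, "none")

    best_family = all_hits[0].subject_id
    fam = next(f for f in te_library if f.name == best_family)
    te_class = fam.te_class

    if fam.poorly_annotated:
        return _done("discarded", "poor_annotation", best_family, te_class)

    fam_hits = by_family[best_family]
    if te_class == "I" and max(h.aln_len for h in fam_hits) <= cfg.min_classI_len:
        return _done("discarded", "short_classI", best_family, te_class)

    if fam.ltr_regions:
        spans = [(h.s_start, h.s_end) for h in fam_hits]
        span_total = _union_len(spans)
        ltr_ov = sum(
            _overlap((s, e), region) for s, e in spans for region in fam.ltr_regions
        )
        internal_regions = _complement_regions(fam.ltr_regions, len(fam.exemplar))
        internal_ov = sum(
            _overlap((s, e), region) for s, e in spans for region in internal_regions
        )
        if (
            span_total > 0
            and ltr_ov >= cfg.solo_ltr_min_ltr_frac * span_total
            and internal_ov <= cfg.solo_ltr_max_internal_frac * span_total
        ):
            return _done("discarded", "solo_ltr", best_family, te_class)

    covs = {
        name: _union_len([(h.q_start, h.q_end) for h in hits]) / len(assembly)
        for name, hits in by_family.items()
    }
    heavy = [n for n, c in covs.items() if c >= cfg.chimera_min_secondary_cov]
    if len(heavy) >= 2:
        return _done("discarded", "chimeric", best_family, te_class)

    return _done("kept", None, best_family, te_class)


def _complement_regions(
    regions: Sequence[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for s, e in sorted(regions):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def _six_frames(seq: str) -> list[tuple[str, str]]:
    frames = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append((strand, str(Seq(sub).translate())))
    return frames


def detect_orientation(
    assembly: SeqRecord,
    domain_library: Mapping[str, str],
    score_min: float = 100.0,
) -> str:
    """Call sense/antisense from six-frame translations aligned against the
    protein domain consensus library; 'unknown' when no frame scores above
    ``score_min`` (set well above the shuffled-sequence null)."""
    if not domain_library:
        raise ValueError("domain library must be non-empty")
    best_score, best_strand = 0.0, "unknown"
    for strand, aa in _six_frames(assembly.sequence):
        for domain_aa in domain_library.values():
            score = best_protein_hit(aa, domain_aa)
            if score > best_score:
                best_score, best_strand = score, strand
    if best_score < score_min:
        return "unknown"
    return "sense" if best_strand == "+" else "antisense"


def filter_assemblies(
    assemblies: Sequence[SeqRecord],
    te_library: Sequence[TEFamily],
    cfg: ClassifierConfig | None = None,
) -> list[ClassifiedAssembly]:
    """Full cascade: classify, then orient the survivors and discard
    antisense transcripts. Returns a verdict for every input assembly."""
    cfg = cfg or ClassifierConfig()
    domains = dict(cfg.domain_library)
    if not domains:
        domains = {
            f.name: f.domain_protein for f in te_library if f.domain_protein
        }
    out: list[ClassifiedAssembly] = []
    for asm in assemblies:
        ca = classify_assembly(asm, te_library, cfg)
        if ca.verdict == "kept" and domains:
            ca.orientation = detect_orientation(asm, domains, cfg.domain_score_min)
            if ca.orientation == "antisense":
                ca.verdict = "discarded"
                ca.discard_reason = "antisense"
        out.append(ca)
    return out


def flag_readthrough(
    te_profile: Sequence[float],
    gene_profile: Sequence[float],
    distance_bp: int,
    same_strand: bool,
    r_min: float = 0.8,
    max_distance_bp: int = 1000,
) -> tuple[bool, float | None]:
    """Flag a TE expression profile as read-through from a neighbouring gene.

    Flagged when the Pearson correlation of the two per-condition profiles
    is >= ``r_min``, the TE lies within ``max_distance_bp`` of the gene and
    both are on the same strand. Zero-variance profiles yield (False, None)
    — the correlation is not computable.
    """
    te = np.asarray(te_profile, dtype=float)
    gene = np.asarray(gene_profile, dtype=float)
    if te.shape != gene.shape or te.size < 4:
        raise ValueError("profiles must share at least 4 conditions")
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    if te.std() == 0 or gene.std() == 0:
        return False, None
    r = float(np.corrcoef(te, gene)[0, 1])
    return bool(r >= r_min and distance_bp <= max_distance_bp and same_strand), r


def verdicts_table(classified: Sequence[ClassifiedAssembly]) -> list[dict]:
    """Rows for the verdicts TSV."""
    rows = []
    for ca in classified:
        top = ca.top_hit
        rows.append(
            {
                "assembly_id": ca.assembly.id,
                "best_family": ca.best_family or "",
                "te_class": ca.te_class,
                "orientation": ca.orientation,
                "verdict": ca.verdict,
                "discard_reason": ca.discard_reason or "",
                "top_hit_identity": round(top.identity, 4) if top else "",
                "top_hit_cov": round(top.query_cov, 4) if top else "",
            }
        )
    return rows
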
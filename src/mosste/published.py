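"""Published polymorphism counts for the *P. patens* accession panel.

Per-family counts of non-reference TE insertions (zygosity >= 0.7) detected
in three resequenced accessions relative to the Gransden reference
assembly, and their distances to the nearest annotated gene. These serve as
call-level input fixtures: :func:`expand_counts_to_calls` emits one
synthetic insertion call per counted polymorphism so the count-matrix and
gene-distance reports can be recomputed from call level.
"""

from __future__ import annotations

from .io import InsertionCall

__all__ = [
    "POLYMORPHISM_COUNTS",
    "GENE_DISTANCE_BINS",
    "expand_counts_to_calls",
    "expand_bins_to_binned",
]

#: accession -> family -> count of non-reference insertions.
POLYMORPHISM_COUNTS: dict[str, dict[str, int]] = {
    "Reute": {
        "RLG1": 18, "RLG2": 0, "RLG3": 4, "RLC4": 0, "tRLC5/RLC5": 5,
        "LINE-1": 0, "LINE-2": 0, "PpTc1": 0, "PpTc2": 0,
    },
    "Kaskaskia": {
        "RLG1": 147, "RLG2": 0, "RLG3": 15, "RLC4": 0, "tRLC5/RLC5": 17,
        "LINE-1": 0, "LINE-2": 0, "PpTc1": 0, "PpTc2": 0,
    },
    "Villersexel": {
        "RLG1": 229, "RLG2": 2, "RLG3": 48, "RLC4": 2, "tRLC5/RLC5": 21,
        "LINE-1": 0, "LINE-2": 0, "PpTc1": 1, "PpTc2": 0,
    },
}

#: accession -> counts of insertions inside genes, < 1 kb from the closest
#: gene, and > 1 kb away.
GENE_DISTANCE_BINS: dict[str, dict[str, int]] = {
    "Reute": {"inside": 4, "near": 4, "far": 19},
    "Kaskaskia": {"inside": 12, "near": 27, "far": 140},
    "Villersexel": {"inside": 22, "near": 34, "far": 247},
}


def expand_counts_to_calls() -> list[InsertionCall]:
    """One synthetic non-reference call (zygosity 1.0) per counted
    polymorphism; positions are synthetic placeholders."""
    calls: list[InsertionCall] = []
    pos = 0
    for accession in sorted(POLYMORPHISM_COUNTS):
        for family in sorted(POLYMORPHISM_COUNTS[accession]):
            for _ in range(POLYMORPHISM_COUNTS[accession][family]):
                pos += 1000
                calls.append(
                    InsertionCall(
                        accession=accession,
                        seq_id="Chr01",
                        position=pos,
                        family=family,
                        zygosity=1.0,
                        in_reference=False,
                        support=10,
                    )
                )
    return calls


def expand_bins_to_binned():
    """One synthetic binned insertion per counted distance-bin entry, with a
    representative distance per bin (0 / 500 / 5000)."""
    from .mobility import BinnedInsertion

    distance = {"inside": 0, "near": 500, "far": 5000}
    binned = []
    pos = 0
    for accession in sorted(GENE_DISTANCE_BINS):
        for bin_name in ("inside", "near", "far"):
            for _ in range(GENE_DISTANCE_BINS[accession][bin_name]):
                pos += 1000
                call = InsertionCall(
                    accession=accession,
                    seq_id="Chr01",
                    position=pos,
                    family="RLG1",
                    zygosity=1.0,
                    in_reference=False,
                    support=10,
                )
                binned.append(
                    BinnedInsertion(call, distance[bin_name], bin_name)
                )
    return binned
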
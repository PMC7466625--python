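"""Synthetic genomes, transcripts, reads and insertion calls with known truth.

The generators emulate the statistical structure the analysis assumes in a
moss-like compact genome: full-length LTR retrotransposons whose two LTRs
were identical at insertion time and have since diverged under a
Kimura-two-parameter substitution process; truncated fragments and
solo-LTRs outnumbering the complete copies; genes adjacent to a fraction of
TE copies; transcript assemblies that are genuine TE mRNAs or one of five
decoy classes; single-end reads with uniform starts and a per-base error
rate; and insertion-call tables with zygosity values and a controlled
false-positive admixture.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomicFeature,
    InsertionCall,
    SeqRecord,
    TEFamily,
    revcomp,
    write_fasta,
)

__all__ = [
    "LTRSimConfig",
    "LTRElement",
    "gen_ltr_element",
    "FamilySpec",
    "GenomeSimConfig",
    "GenomeBundle",
    "gen_te_genome",
    "TranscriptTruth",
    "gen_transcript_set",
    "ReadSet",
    "gen_reads",
    "gen_insertion_calls",
    "TRANSCRIPT_ORIGINS",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: Transcript truth categories: one genuine class and five decoy classes.
TRANSCRIPT_ORIGINS = (
    "genuine_te",
    "solo_ltr_readthrough",
    "antisense",
    "chimeric",
    "gene",
    "te_fragment",
)

# Amino acids excluding stops; used for synthetic domain proteins.
_AA = np.array(list("ARNDCQEGHILKMFPSTWYV"))

# Codon table restricted to one codon per amino acid (enough for synthesis).
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(
    seq: str, per_site_prob: float, rng: np.random.Generator, ts_tv_ratio: float
) -> str:
    """Single-hit substitution process: each site mutates at most once with
    the given probability; a substitution is a transition with probability
    R/(R+1) where R is the expected transition:transversion count ratio."""
    if per_site_prob <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < per_site_prob
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    for i in np.nonzero(hit)[0]:
        base = arr[i]
        if base not in _TRANSITION:  # leave N untouched
            continue
        if rng.random() < p_ts:
            arr[i] = _TRANSITION[base]
        else:
            arr[i] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(arr)


def _orf_for(protein: str) -> str:
    return "ATG" + "".join(_CODON[a] for a in protein) + "TAA"


def _internal_with_orf(
    rng: np.random.Generator, internal_len: int
) -> tuple[str, str]:
    """Random internal region carrying one sense ORF; returns (dna, protein)."""
    n_aa = max(30, internal_len // 3 - 4)
    protein = "".join(rng.choice(_AA, size=n_aa))
    orf = _orf_for(protein)
    if len(orf) > internal_len:
        n_aa = internal_len // 3 - 3
        protein = protein[:n_aa]
        orf = _orf_for(protein)
    pad = internal_len - len(orf)
    left = pad // 2
    return _random_dna(rng, left) + orf + _random_dna(rng, pad - left), protein


# ---------------------------------------------------------------------------
# LTR element generator


@dataclass
class LTRSimConfig:
    """Conditions for one simulated LTR element.

    ``age_T`` in years, ``rate_r`` in substitutions/site/year (default the
    moss estimate 9e-9), ``ts_tv_ratio`` the expected transition:transversion
    count ratio.
    """

    age_T: float
    rate_r: float = 9e-9
    ltr_len: int = 1000
    internal_len: int = 3000
    ts_tv_ratio: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.age_T < 0:
            raise ValueError("age_T must be >= 0")
        if self.rate_r <= 0:
            raise ValueError("rate_r must be > 0")
        if self.ltr_len < 50:
            raise ValueError("ltr_len must be >= 50")


@dataclass
class LTRElement:
    element: SeqRecord
    ltr5: GenomicFeature
    ltr3: GenomicFeature
    true_age: float
    expected_divergence: float  # expected pairwise raw divergence, 2 r T


def gen_ltr_element(
    cfg: LTRSimConfig, rng: np.random.Generator | None = None, copy_id: str = "elem1"
) -> LTRElement:
    """Simulate LTR + internal + LTR where each LTR diverged independently
    from a common ancestor by ``rate_r * age_T`` expected substitutions per
    site (expected pairwise divergence 2 r T). Raises in the saturation
    regime (expected divergence > 0.4) where dating is unreliable."""
    per_ltr = cfg.rate_r * cfg.age_T
    if 2 * per_ltr > 0.4:
        raise ValueError(
            f"saturation regime: expected divergence {2 * per_ltr:.3f} > 0.4"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ancestor = _random_dna(rng, cfg.ltr_len)
    internal, _protein = _internal_with_orf(rng, cfg.internal_len)
    ltr5 = _mutate(ancestor, per_ltr, rng, cfg.ts_tv_ratio)
    ltr3 = _mutate(ancestor, per_ltr, rng, cfg.ts_tv_ratio)
    seq = ltr5 + internal + ltr3
    L, I = cfg.ltr_len, cfg.internal_len
    return LTRElement(
        element=SeqRecord(copy_id, seq),
        ltr5=GenomicFeature(copy_id, 0, L, "+", "ltr5", copy_id=copy_id),
        ltr3=GenomicFeature(copy_id, L + I, L + I + L, "+", "ltr3", copy_id=copy_id),
        true_age=cfg.age_T,
        expected_divergence=2 * per_ltr,
    )


# ---------------------------------------------------------------------------
# Genome generator


@dataclass
class FamilySpec:
    """Per-family plan for the genome simulator.

    ``ages`` (years) may be a scalar or one value per full copy; it drives
    both the LTR-pair divergence and the copy's drift away from the family
    exemplar. ``extra_divergence`` adds lineage-specific degeneration on top
    (whole-copy per-site substitution probability), letting old copies fall
    below the 80/80 similarity rule without saturating the LTR pair.
    """

    name: str
    te_class: str = "I"
    superfamily: str = "Gypsy"
    n_full: int = 2
    n_fragments: int = 6
    n_solo_ltr: int = 2
    ltr_len: int = 1200
    internal_len: int = 3000
    ages: float | Sequence[float] = 5e5
    extra_divergence: float | Sequence[float] = 0.0
    poorly_annotated: bool = False

    def age_of(self, i: int) -> float:
        if np.isscalar(self.ages):
            return float(self.ages)
        return float(self.ages[i % len(self.ages)])

    def extra_of(self, i: int) -> float:
        if np.isscalar(self.extra_divergence):
            return float(self.extra_divergence)
        return float(self.extra_divergence[i % len(self.extra_divergence)])


@dataclass
class GenomeSimConfig:
    """Conditions for a synthetic TE-bearing genome.

    Defaults put fragments + solo-LTRs well above the full-copy count, the
    regime in which read-count-per-annotation expression measures
    overestimate family activity. ``te_gene_adjacency_fraction`` is the
    fraction of TE copies placed within 1 kb of a gene.
    """

    families: Sequence[FamilySpec] = field(default_factory=lambda: [FamilySpec("RLG_A")])
    n_chrom: int = 1
    chrom_len: int = 200_000
    n_genes: int = 10
    gene_len: int = 2000
    te_gene_adjacency_fraction: float = 0.2
    rate_r: float = 9e-9
    ts_tv_ratio: float = 2.0
    seed: int = 0


@dataclass
class GenomeBundle:
    genome: list[SeqRecord]
    te_features: list[GenomicFeature]
    gene_features: list[GenomicFeature]
    families: list[TEFamily]
    truth: pd.DataFrame
    config: GenomeSimConfig

    def chrom(self, seq_id: str) -> str:
        for rec in self.genome:
            if rec.id == seq_id:
                return rec.sequence
        raise KeyError(seq_id)

    def write(self, outdir: str | Path) -> None:
        from .io import write_gff3, write_tsv_report

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gff3(self.te_features, outdir / "te.gff3")
        write_gff3(self.gene_features, outdir / "genes.gff3")
        write_tsv_report(
            self.truth.to_dict("records"), outdir / "truth_placements.tsv"
        )


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


class _Placer:
    """Non-overlapping interval placement with bounded retries."""

    def __init__(self, rng: np.random.Generator, n_chrom: int, chrom_len: int):
        self.rng = rng
        self.n_chrom = n_chrom
        self.chrom_len = chrom_len
        self.occupied: dict[int, list[tuple[int, int]]] = {c: [] for c in range(n_chrom)}

    def _free(self, c: int, start: int, end: int) -> bool:
        if start < 0 or end > self.chrom_len:
            return False
        return all(
            _interval_distance(start, end, s, e) > 20 for s, e in self.occupied[c]
        )

    def place(self, length: int, retries: int = 300) -> tuple[int, int, int]:
        for _ in range(retries):
            c = int(self.rng.integers(self.n_chrom))
            start = int(self.rng.integers(0, self.chrom_len - length))
            if self._free(c, start, start + length):
                self.occupied[c].append((start, start + length))
                return c, start, start + length
        raise ValueError("genome too dense: cannot place feature without overlap")

    def place_near(
        self, length: int, anchor: tuple[int, int, int], max_gap: int, retries: int = 60
    ) -> tuple[int, int, int] | None:
        """Place downstream of anchor (chrom, start, end) within max_gap."""
        c, _a_start, a_end = anchor
        for _ in range(retries):
            gap = int(self.rng.integers(50, max_gap - 50))
            start = a_end + gap
            if self._free(c, start, start + length):
                self.occupied[c].append((start, start + length))
                return c, start, start + length
        return None

    def place_away_from(
        self,
        length: int,
        avoid: Sequence[tuple[int, int, int]],
        min_dist: int,
        retries: int = 300,
    ) -> tuple[int, int, int]:
        for _ in range(retries):
            c = int(self.rng.integers(self.n_chrom))
            start = int(self.rng.integers(0, self.chrom_len - length))
            end = start + length
            if not self._free(c, start, end):
                continue
            if all(
                not (ac == c and _interval_distance(start, end, a_s, a_e) < min_dist)
                for ac, a_s, a_e in avoid
            ):
                self.occupied[c].append((start, end))
                return c, start, end
        raise ValueError("genome too dense: cannot place feature without overlap")


def _build_family(
    spec: FamilySpec, rng: np.random.Generator
) -> tuple[TEFamily, str, str]:
    """Returns (family, ancestral_ltr, internal_dna)."""
    if spec.te_class == "I":
        anc_ltr = _random_dna(rng, spec.ltr_len)
        internal, protein = _internal_with_orf(rng, spec.internal_len)
        exemplar = SeqRecord(spec.name, anc_ltr + internal + anc_ltr)
        L, I = spec.ltr_len, spec.internal_len
        fam = TEFamily(
            name=spec.name,
            te_class="I",
            superfamily=spec.superfamily,
            exemplar=exemplar,
            ltr_regions=((0, L), (L + I, L + I + L)),
            domain_protein=protein,
            poorly_annotated=spec.poorly_annotated,
        )
        return fam, anc_ltr, internal
    internal, protein = _internal_with_orf(rng, spec.internal_len)
    fam = TEFamily(
        name=spec.name,
        te_class="II",
        superfamily=spec.superfamily,
        exemplar=SeqRecord(spec.name, internal),
        domain_protein=protein,
        poorly_annotated=spec.poorly_annotated,
    )
    return fam, "", internal


def gen_te_genome(cfg: GenomeSimConfig) -> GenomeBundle:
    """Simulate chromosomes carrying genes plus full, fragmented and
    solo-LTR TE copies, with a known fraction of TE copies gene-adjacent.

    When solo-LTRs, genes and a nonzero adjacency fraction are all
    requested, the first solo-LTR of each class-I family is guaranteed to
    land within 1 kb downstream of a gene so that read-through decoy
    transcripts are always constructible.
    """
    rng = np.random.default_rng(cfg.seed)
    total_len = sum(
        f.n_full * (2 * f.ltr_len + f.internal_len if f.te_class == "I" else f.internal_len)
        + f.n_fragments * int(0.6 * (2 * f.ltr_len + f.internal_len))
        + f.n_solo_ltr * f.ltr_len
        for f in cfg.families
    ) + cfg.n_genes * cfg.gene_len
    if total_len >= 0.9 * cfg.n_chrom * cfg.chrom_len:
        raise ValueError("genome too dense: planted features exceed 90% of genome")

    placer = _Placer(rng, cfg.n_chrom, cfg.chrom_len)

    # genes first, so TE adjacency can anchor on them
    gene_anchors: list[tuple[int, int, int]] = []
    gene_features: list[GenomicFeature] = []
    for g in range(cfg.n_genes):
        c, s, e = placer.place(cfg.gene_len)
        gene_anchors.append((c, s, e))
        gene_features.append(
            GenomicFeature(f"chr{c + 1}", s, e, "+", "gene", copy_id=f"gene{g + 1}")
        )

    families: list[TEFamily] = []
    te_features: list[GenomicFeature] = []
    placements: list[dict] = []  # copy_id -> sequence to plant
    planted_seqs: dict[str, tuple[int, int, int, str]] = {}

    def _plant(
        seq: str, family: str, category: str, strand: str, copy_id: str, adjacent: bool
    ) -> tuple[int, int, int]:
        if adjacent and gene_anchors:
            order = rng.permutation(len(gene_anchors))
            for gi in order:
                loc = placer.place_near(len(seq), gene_anchors[gi], max_gap=1000)
                if loc is not None:
                    break
            else:
                loc = placer.place(len(seq))
        else:
            loc = placer.place_away_from(len(seq), gene_anchors, min_dist=2000)
        planted = seq if strand == "+" else revcomp(seq)
        planted_seqs[copy_id] = (*loc, planted)
        return loc

    for spec in cfg.families:
        fam, anc_ltr, internal = _build_family(spec, rng)
        families.append(fam)
        L = spec.ltr_len
        elem_len = 2 * L + spec.internal_len if spec.te_class == "I" else spec.internal_len

        for i in range(spec.n_full):
            copy_id = f"{spec.name}_full{i + 1}"
            age = spec.age_of(i)
            per_ltr = cfg.rate_r * age
            if spec.te_class == "I":
                l5 = _mutate(anc_ltr, per_ltr, rng, cfg.ts_tv_ratio)
                l3 = _mutate(anc_ltr, per_ltr, rng, cfg.ts_tv_ratio)
                body = _mutate(internal, per_ltr, rng, cfg.ts_tv_ratio)
                seq = l5 + body + l3
            else:
                seq = _mutate(internal, per_ltr, rng, cfg.ts_tv_ratio)
            extra = spec.extra_of(i)
            if extra > 0:
                seq = _mutate(seq, extra, rng, cfg.ts_tv_ratio)
            strand = "+" if rng.random() < 0.5 else "-"
            adjacent = bool(rng.random() < cfg.te_gene_adjacency_fraction)
            c, s, e = _plant(seq, spec.name, "full", strand, copy_id, adjacent)
            chrom_id = f"chr{c + 1}"
            te_features.append(
                GenomicFeature(chrom_id, s, e, strand, "te_copy", spec.name, copy_id)
            )
            if spec.te_class == "I":
                if strand == "+":
                    five = (s, s + L)
                    three = (e - L, e)
                else:
                    five = (e - L, e)
                    three = (s, s + L)
                te_features.append(
                    GenomicFeature(chrom_id, *five, strand, "ltr5", spec.name, copy_id)
                )
                te_features.append(
                    GenomicFeature(chrom_id, *three, strand, "ltr3", spec.name, copy_id)
                )
            placements.append(
                dict(copy_id=copy_id, family=spec.name, te_class=spec.te_class,
                     category="full", seq_id=chrom_id, start=s, end=e, strand=strand,
                     age_years=age, extra_divergence=extra)
            )

        for i in range(spec.n_fragments):
            copy_id = f"{spec.name}_frag{i + 1}"
            frac = rng.uniform(0.1, 0.6)
            flen = max(80, int(frac * elem_len))
            off = int(rng.integers(0, elem_len - flen + 1))
            seq = fam.exemplar.sequence[off : off + flen]
            seq = _mutate(seq, cfg.rate_r * spec.age_of(i), rng, cfg.ts_tv_ratio)
            strand = "+" if rng.random() < 0.5 else "-"
            adjacent = bool(rng.random() < cfg.te_gene_adjacency_fraction)
            c, s, e = _plant(seq, spec.name, "fragment", strand, copy_id, adjacent)
            te_features.append(
                GenomicFeature(f"chr{c + 1}", s, e, strand, "te_copy", spec.name, copy_id)
            )
            placements.append(
                dict(copy_id=copy_id, family=spec.name, te_class=spec.te_class,
                     category="fragment", seq_id=f"chr{c + 1}", start=s, end=e,
                     strand=strand, age_years=spec.age_of(i), extra_divergence=0.0)
            )

        for i in range(spec.n_solo_ltr):
            if spec.te_class != "I":
                break
            copy_id = f"{spec.name}_solo{i + 1}"
            seq = _mutate(anc_ltr, cfg.rate_r * spec.age_of(i), rng, cfg.ts_tv_ratio)
            # guarantee one gene-adjacent solo-LTR per family for read-through decoys
            force_adjacent = (
                i == 0 and cfg.n_genes > 0 and cfg.te_gene_adjacency_fraction > 0
            )
            adjacent = force_adjacent or bool(
                rng.random() < cfg.te_gene_adjacency_fraction
            )
            c, s, e = _plant(seq, spec.name, "solo_ltr", "+", copy_id, adjacent)
            te_features.append(
                GenomicFeature(f"chr{c + 1}", s, e, "+", "te_copy", spec.name, copy_id)
            )
            placements.append(
                dict(copy_id=copy_id, family=spec.name, te_class=spec.te_class,
                     category="solo_ltr", seq_id=f"chr{c + 1}", start=s, end=e,
                     strand="+", age_years=spec.age_of(i), extra_divergence=0.0)
            )

    # assemble chromosomes: i.i.d. uniform background, then splice features in
    genome: list[SeqRecord] = []
    for c in range(cfg.n_chrom):
        arr = rng.choice(_BASES, size=cfg.chrom_len)
        for cc, s, e, seq in planted_seqs.values():
            if cc == c:
                arr[s:e] = list(seq)
        genome.append(SeqRecord(f"chr{c + 1}", "".join(arr)))

    # truth: nearest gene distance by brute-force scan
    for row in placements:
        dists = [
            _interval_distance(row["start"], row["end"], g.start, g.end)
            for g in gene_features
            if g.seq_id == row["seq_id"]
        ]
        row["nearest_gene_distance"] = min(dists) if dists else -1
    truth = pd.DataFrame(
        placements,
        columns=[
            "copy_id", "family", "te_class", "category", "seq_id", "start", "end",
            "strand", "age_years", "extra_divergence", "nearest_gene_distance",
        ],
    )
    return GenomeBundle(genome, te_features, gene_features, families, truth, cfg)


# ---------------------------------------------------------------------------
# Transcript generator


@dataclass
class TranscriptTruth:
    transcript_id: str
    origin: str
    source_copy_id: str
    family: str
    condition_abundances: dict[str, int]

    def __post_init__(self) -> None:
        if self.origin not in TRANSCRIPT_ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if any(v < 0 for v in self.condition_abundances.values()):
            raise ValueError("abundances must be >= 0")


def _copy_sense_seq(bundle: GenomeBundle, row: pd.Series) -> str:
    seq = bundle.chrom(row.seq_id)[row.start : row.end]
    return seq if row.strand == "+" else revcomp(seq)


def gen_transcript_set(
    bundle: GenomeBundle,
    plan: Mapping[str, int],
    conditions: Sequence[str] = ("protonema", "gametophore", "green_sporophyte", "protoplast"),
    abundance_range: tuple[int, int] = (10, 200),
    seed: int = 0,
) -> tuple[list[SeqRecord], list[TranscriptTruth]]:
    """Emit transcript assemblies per the decoy plan, with truth.

    Categories: ``genuine_te`` (full element mRNA, sense), ``te_fragment``
    (sense sub-slice < 1000 nt), ``solo_ltr_readthrough`` (gene 3' end plus
    the adjacent downstream solo-LTR, as one read-through transcript),
    ``antisense`` (reverse complement of an element slice covering coding
    sequence), ``chimeric`` (slices of two different families), ``gene``
    (gene sequence only). Raises when the genome lacks what a category
    needs.
    """
    rng = np.random.default_rng(seed)
    truth_df = bundle.truth
    fulls = truth_df[truth_df.category == "full"].reset_index(drop=True)
    transcripts: list[SeqRecord] = []
    truths: list[TranscriptTruth] = []

    def _abundances() -> dict[str, int]:
        lo, hi = abundance_range
        return {c: int(rng.integers(lo, hi + 1)) for c in conditions}

    def _emit(origin: str, seq: str, source: str, family: str) -> None:
        tid = f"ASM_{origin}_{sum(t.origin == origin for t in truths) + 1}"
        transcripts.append(SeqRecord(tid, seq))
        truths.append(TranscriptTruth(tid, origin, source, family, _abundances()))

    solo_pairs: list[tuple[GenomicFeature, pd.Series]] = []
    solos = truth_df[truth_df.category == "solo_ltr"]
    for _, srow in solos.iterrows():
        for g in bundle.gene_features:
            if g.seq_id == srow.seq_id and 0 <= srow.start - g.end <= 1000:
                solo_pairs.append((g, srow))
                break

    for origin, count in plan.items():
        if origin not in TRANSCRIPT_ORIGINS:
            raise ValueError(f"unknown transcript category {origin!r}")
        for _ in range(count):
            if origin == "genuine_te":
                if fulls.empty:
                    raise ValueError("genome has no full TE copies")
                row = fulls.iloc[int(rng.integers(len(fulls)))]
                _emit(origin, _copy_sense_seq(bundle, row), row.copy_id, row.family)
            elif origin == "te_fragment":
                cand = fulls[fulls.te_class == "I"]
                if cand.empty:
                    cand = fulls
                if cand.empty:
                    raise ValueError("genome has no full TE copies")
                row = cand.iloc[int(rng.integers(len(cand)))]
                sense = _copy_sense_seq(bundle, row)
                flen = int(rng.integers(300, 950))
                off = int(rng.integers(0, len(sense) - flen))
                _emit(origin, sense[off : off + flen], row.copy_id, row.family)
            elif origin == "solo_ltr_readthrough":
                if not solo_pairs:
                    raise ValueError("genome lacks a gene-adjacent solo-LTR")
                g, srow = solo_pairs[int(rng.integers(len(solo_pairs)))]
                seq = bundle.chrom(g.seq_id)[g.end - 500 : srow.end]
                _emit(origin, seq, srow.copy_id, srow.family)
            elif origin == "antisense":
                cand = fulls[fulls.te_class == "I"]
                if cand.empty:
                    cand = fulls
                if cand.empty:
                    raise ValueError("genome has no full TE copies")
                row = cand.iloc[int(rng.integers(len(cand)))]
                sense = _copy_sense_seq(bundle, row)
                fam = next(f for f in bundle.families if f.name == row.family)
                lo = fam.ltr_regions[0][1] if fam.ltr_regions else 0
                take = min(1500, len(sense) - lo - 100)
                slice_ = sense[lo + 100 : lo + 100 + take]
                _emit(origin, revcomp(slice_), row.copy_id, row.family)
            elif origin == "chimeric":
                fams = truth_df.family.unique()
                if len(fams) < 2:
                    raise ValueError("chimeric decoys need at least two families")
                fa, fb = rng.choice(fams, size=2, replace=False)
                sa = next(f for f in bundle.families if f.name == fa).exemplar.sequence
                sb = next(f for f in bundle.families if f.name == fb).exemplar.sequence
                # slices long enough that the chimera rule, not the class-I
                # length rule, is what catches the decoy
                la, lb = min(1200, len(sa) - 1), min(1200, len(sb) - 1)
                a_off = int(rng.integers(0, len(sa) - la))
                b_off = int(rng.integers(0, len(sb) - lb))
                _emit(origin, sa[a_off : a_off + la] + sb[b_off : b_off + lb],
                      f"{fa}+{fb}", fa)
            elif origin == "gene":
                if not bundle.gene_features:
                    raise ValueError("genome has no genes")
                g = bundle.gene_features[int(rng.integers(len(bundle.gene_features)))]
                _emit(origin, bundle.chrom(g.seq_id)[g.start : g.end], g.copy_id, "")
    return transcripts, truths


# ---------------------------------------------------------------------------
# Read simulator


@dataclass
class ReadSet:
    by_condition: dict[str, list[SeqRecord]]
    totals: dict[str, int]
    truth_strand: dict[str, str]  # read id -> strand relative to its source

    def write_fastq(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cond, reads in self.by_condition.items():
            p = outdir / f"{cond}.fastq"
            with open(p, "w") as fh:
                for r in reads:
                    fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
            paths[cond] = p
        return paths


def gen_reads(
    transcripts: Sequence[SeqRecord],
    truth: Sequence[TranscriptTruth],
    read_len: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
    antisense_fraction: float = 0.0,
) -> ReadSet:
    """Draw single-end reads per condition from each transcript.

    Read counts equal the planted abundances exactly; starts are uniform;
    each base flips to a random different base with ``error_rate``. Read ids
    encode source transcript, strand and condition
    (``<tid>|<strand>|<cond>|<i>``). ``antisense_fraction`` of reads are
    drawn from the reverse complement (strand '-').
    """
    if error_rate >= 0.5:
        raise ValueError("error_rate must be < 0.5")
    if transcripts:
        min_len = min(len(t) for t in transcripts)
        if read_len > min_len:
            raise ValueError(f"read_len {read_len} exceeds shortest transcript ({min_len})")
    rng = np.random.default_rng(seed)
    seqs = {t.id: t.sequence for t in transcripts}
    conditions = sorted({c for t in truth for c in t.condition_abundances})
    by_cond: dict[str, list[SeqRecord]] = {c: [] for c in conditions}
    strand_of: dict[str, str] = {}
    for t in truth:
        src = seqs[t.transcript_id]
        for cond in conditions:
            n = t.condition_abundances.get(cond, 0)
            for i in range(n):
                start = int(rng.integers(0, len(src) - read_len + 1))
                seq = src[start : start + read_len]
                strand = "+"
                if antisense_fraction > 0 and rng.random() < antisense_fraction:
                    seq = revcomp(seq)
                    strand = "-"
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                if len(errs):
                    arr = list(seq)
                    for p in errs:
                        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
                    seq = "".join(arr)
                rid = f"{t.transcript_id}|{strand}|{cond}|{i}"
                by_cond[cond].append(SeqRecord(rid, seq))
                strand_of[rid] = strand
    totals = {c: len(rs) for c, rs in by_cond.items()}
    return ReadSet(by_cond, totals, strand_of)


# ---------------------------------------------------------------------------
# Insertion-call generator


def _sampler(dist) -> Callable[[np.random.Generator], float]:
    if callable(dist):
        return dist
    if np.isscalar(dist):
        return lambda rng: float(dist)
    kind, *params = dist
    if kind == "uniform":
        a, b = params
        return lambda rng: float(rng.uniform(a, b))
    if kind == "beta":
        a, b = params
        return lambda rng: float(rng.beta(a, b))
    raise ValueError(f"unknown zygosity distribution {dist!r}")


def gen_insertion_calls(
    truth_per_accession: Mapping[str, Sequence[tuple]],
    zygosity_dist=("uniform", 0.8, 1.0),
    fp_rate: float = 0.0,
    fp_zygosity_dist=("uniform", 0.0, 0.7),
    seed: int = 0,
    chrom_len: int = 200_000,
) -> tuple[list[InsertionCall], pd.DataFrame]:
    """Emit an insertion-call table: every true insertion with zygosity from
    ``zygosity_dist``, plus ``round(fp_rate * n_true)`` spurious calls with
    zygosity from ``fp_zygosity_dist`` (default: below the 0.7 confidence
    threshold). Truth tuples are (seq_id, position, family) with an optional
    fourth in_reference flag. Returns calls plus a truth table flagging
    which rows are genuine."""
    rng = np.random.default_rng(seed)
    draw_true = _sampler(zygosity_dist)
    draw_fp = _sampler(fp_zygosity_dist)
    calls: list[InsertionCall] = []
    rows: list[dict] = []
    seq_ids: list[str] = []
    families: list[str] = []
    for acc in sorted(truth_per_accession):
        for t in truth_per_accession[acc]:
            seq_id, pos, family = t[:3]
            in_ref = bool(t[3]) if len(t) > 3 else False
            zyg = min(1.0, max(0.0, draw_true(rng)))
            calls.append(
                InsertionCall(acc, seq_id, int(pos), family, zyg, in_ref,
                              support=int(rng.integers(5, 40)))
            )
            rows.append(dict(accession=acc, seq_id=seq_id, position=int(pos),
                             family=family, zygosity=zyg, in_reference=in_ref,
                             is_true=True))
            seq_ids.append(seq_id)
            families.append(family)
    n_fp = round(fp_rate * len(calls))
    accs = sorted(truth_per_accession)
    for _ in range(n_fp):
        acc = accs[int(rng.integers(len(accs)))]
        seq_id = seq_ids[int(rng.integers(len(seq_ids)))] if seq_ids else "chr1"
        family = families[int(rng.integers(len(families)))] if families else "RLG_A"
        pos = int(rng.integers(0, chrom_len))
        zyg = min(1.0, max(0.0, draw_fp(rng)))
        calls.append(
            InsertionCall(acc, seq_id, pos, family, zyg, False,
                          support=int(rng.integers(1, 6)))
        )
        rows.append(dict(accession=acc, seq_id=seq_id, position=pos, family=family,
                         zygosity=zyg, in_reference=False, is_true=False))
    return calls, pd.DataFrame(rows)
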
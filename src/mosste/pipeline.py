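"""End-to-end orchestration of the three analysis arms plus a synthetic demo.

* expression arm: classify assemblies -> filter decoys -> assign reads
  sense-only -> normalized expression table;
* dating arm: find copies compatible with each kept assembly -> date all
  complete copies from their LTR pairs -> summarize the age shift of the
  expressed subset;
* mobility arm: filter insertion calls -> bin by nearest-gene distance ->
  accession x family count matrix -> near-gene percentage.

Every TSV output starts with a comment header recording the tool version,
a hash of the configuration and the seed, so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .dating import (
    ExpressedCopyRule,
    date_all_copies,
    find_expressed_copies,
    summarize_age_shift,
)
from .expression import AssignConfig, assign_reads, expression_table
from .io import (
    GenomicFeature,
    InsertionCall,
    SeqRecord,
    write_tsv_report,
)
from .mobility import (
    MobilityConfig,
    bin_insertions,
    filter_insertions,
    near_gene_fraction,
    polymorphism_count_matrix,
)
from .transcripts import ClassifierConfig, filter_assemblies, verdicts_table

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "output_header",
    "run_expression_arm",
    "run_dating_arm",
    "run_mobility_arm",
    "run_demo",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    rate_r: float = 9e-9
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    expressed_rule: ExpressedCopyRule = field(default_factory=ExpressedCopyRule)
    mobility: MobilityConfig = field(default_factory=MobilityConfig)

    def hash(self) -> str:
        def _clean(d):
            return {k: v for k, v in d.items() if not isinstance(v, dict) or v}

        blob = json.dumps(
            {
                "seed": self.seed,
                "rate_r": self.rate_r,
                "classifier": {k: str(v) for k, v in asdict(self.classifier).items()},
                "assign": asdict(self.assign),
                "rule": asdict(self.expressed_rule),
                "mobility": {k: str(v) for k, v in asdict(self.mobility).items()},
            },
            sort_keys=True,
        )
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def output_header(cfg: PipelineConfig) -> str:
    return f"mosste v{__version__} | config={cfg.hash()} | seed={cfg.seed}"


def run_expression_arm(
    assemblies: Sequence[SeqRecord],
    te_library,
    reads_by_condition: Mapping[str, Sequence[SeqRecord]],
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify -> filter -> assign -> quantify; writes verdicts.tsv and
    expression.tsv; returns both tables."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = output_header(cfg)

    classified = filter_assemblies(assemblies, te_library, cfg.classifier)
    kept = [ca.assembly for ca in classified if ca.verdict == "kept"]
    logger.info(
        "expression arm: %d assemblies in, %d kept", len(assemblies), len(kept)
    )
    rows = verdicts_table(classified)
    write_tsv_report(rows, outdir / "verdicts.tsv", header_comment=header)

    totals = {c: len(rs) for c, rs in reads_by_condition.items()}
    if kept:
        assignments = assign_reads(reads_by_condition, kept, cfg.assign)
        logger.info("expression arm: %d reads assigned", len(assignments))
        expr = expression_table(assignments, kept, totals)
    else:
        expr = pd.DataFrame(
            columns=[
                "assembly_id", "condition", "sense_read_count",
                "assembly_len_kb", "total_trimmed_reads", "value",
            ]
        )
    write_tsv_report(
        expr.to_dict("records"),
        outdir / "expression.tsv",
        columns=list(expr.columns),
        header_comment=header,
    )
    return pd.DataFrame(rows), expr


def run_dating_arm(
    genome: Sequence[SeqRecord],
    te_features: Sequence[GenomicFeature],
    kept_assemblies: Sequence[SeqRecord],
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Date all complete copies, mark the expressed-compatible subset, and
    summarize the age shift. Writes ages.tsv and age_shift.json."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = output_header(cfg)

    ages = date_all_copies(genome, te_features, cfg.rate_r)
    expressed_ids: set[str] = set()
    for asm in kept_assemblies:
        expressed_ids.update(
            find_expressed_copies(asm, genome, te_features, cfg.expressed_rule)
        )
    ages["expressed_flag"] = ages["copy_id"].isin(expressed_ids).astype(int)
    logger.info(
        "dating arm: %d complete copies dated, %d expressed-compatible",
        len(ages), int(ages["expressed_flag"].sum()),
    )
    write_tsv_report(
        ages.to_dict("records"),
        outdir / "ages.tsv",
        columns=list(ages.columns),
        header_comment=header,
    )
    summary = None
    expressed = ages[ages.expressed_flag == 1]
    if not expressed.empty and not ages.empty:
        summary = summarize_age_shift(expressed, ages)
        with open(outdir / "age_shift.json", "w") as fh:
            json.dump({"_header": header, **summary}, fh, indent=1, sort_keys=True)
    return ages, summary


def run_mobility_arm(
    calls: Sequence[InsertionCall],
    genes: Sequence[GenomicFeature],
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Filter -> bin -> count matrix -> near-gene summary. Writes
    filtered.tsv, binned.tsv, count_matrix.tsv and summary.tsv."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = output_header(cfg)

    kept = filter_insertions(calls, cfg.mobility)
    logger.info("mobility arm: %d calls in, %d kept", len(calls), len(kept))
    from .io import write_insertion_table

    write_insertion_table(kept, outdir / "filtered.tsv", header_comment=header)

    binned = bin_insertions(kept, genes, cfg.mobility)
    write_tsv_report(
        [
            {
                "accession": b.call.accession,
                "seq_id": b.call.seq_id,
                "position": b.call.position,
                "family": b.call.family,
                "distance_bp": b.distance_bp,
                "bin": b.bin,
            }
            for b in binned
        ],
        outdir / "binned.tsv",
        columns=["accession", "seq_id", "position", "family", "distance_bp", "bin"],
        header_comment=header,
    )
    mat = polymorphism_count_matrix(kept, cfg.mobility)
    mat_rows = (
        mat.reset_index().to_dict("records") if not mat.empty else []
    )
    write_tsv_report(
        mat_rows,
        outdir / "count_matrix.tsv",
        columns=(["accession"] + list(mat.columns)) if not mat.empty else ["accession"],
        header_comment=header,
    )
    if binned:
        pct = near_gene_fraction(binned)
        summary_rows = [
            {
                "n_calls_in": len(calls),
                "n_kept": len(kept),
                "near_gene_percent": pct,
            }
        ]
        logger.info("mobility arm: %.1f%% of insertions inside/near genes", pct)
    else:
        summary_rows = [
            {"n_calls_in": len(calls), "n_kept": 0, "near_gene_percent": "no calls"}
        ]
        logger.info("mobility arm: no calls after filtering")
    write_tsv_report(
        summary_rows,
        outdir / "summary.tsv",
        columns=["n_calls_in", "n_kept", "near_gene_percent"],
        header_comment=header,
    )
    return {
        "filtered": kept,
        "binned": binned,
        "matrix": mat,
        "summary": summary_rows[0],
    }


# ---------------------------------------------------------------------------
# One-command synthetic demo


def demo_bundle(seed: int = 42):
    """The demo's synthetic study system: one Gypsy-like and one Copia-like
    LTR family (the Copia-like family mixing young and degenerate old
    copies) plus one Mariner-like DNA family, genes, transcripts of every
    category, reads, and insertion calls for three accessions."""
    from .simulate import (
        FamilySpec,
        GenomeSimConfig,
        gen_insertion_calls,
        gen_reads,
        gen_te_genome,
        gen_transcript_set,
    )
    import numpy as np

    families = [
        FamilySpec("RLG_A", te_class="I", superfamily="Gypsy", n_full=4,
                   n_fragments=10, n_solo_ltr=3, ages=4e5),
        FamilySpec("RLC_B", te_class="I", superfamily="Copia", n_full=6,
                   n_fragments=8, n_solo_ltr=2,
                   ages=[4e5, 4e5, 4e5, 5e6, 5e6, 5e6],
                   extra_divergence=[0.0, 0.0, 0.0, 0.25, 0.25, 0.25]),
        FamilySpec("PpTc_C", te_class="II", superfamily="Mariner", n_full=2,
                   n_fragments=5, n_solo_ltr=0, internal_len=2400),
    ]
    bundle = gen_te_genome(
        GenomeSimConfig(families=families, n_chrom=2, chrom_len=250_000,
                        n_genes=12, te_gene_adjacency_fraction=0.2, seed=seed)
    )
    transcripts, truth = gen_transcript_set(
        bundle,
        {"genuine_te": 3, "te_fragment": 6, "solo_ltr_readthrough": 2,
         "antisense": 2, "chimeric": 2, "gene": 2},
        seed=seed + 1,
        abundance_range=(10, 120),
    )
    reads = gen_reads(transcripts, truth, read_len=100, error_rate=0.005,
                      seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    copies = bundle.truth
    ins_truth = {}
    for acc in ("Reute", "Kaskaskia", "Villersexel"):
        picks = copies.sample(frac=0.6, random_state=int(rng.integers(2**31)))
        ins_truth[acc] = [
            (row.seq_id, int(row.start), row.family) for row in picks.itertuples()
        ]
    calls, call_truth = gen_insertion_calls(
        ins_truth, fp_rate=0.15, seed=seed + 4,
        chrom_len=bundle.config.chrom_len,
    )
    return bundle, transcripts, truth, reads, calls, call_truth


def run_demo(seed: int = 42, outdir: str | Path = "demo") -> dict:
    """Generate the synthetic bundle and run all three arms end to end."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle, transcripts, truth, reads, calls, _ = demo_bundle(seed)
    cfg = PipelineConfig(seed=seed)

    bundle.write(outdir / "inputs")
    from .io import write_fasta

    write_fasta(transcripts, outdir / "inputs" / "assemblies.fa")
    reads.write_fastq(outdir / "inputs" / "reads")

    verdicts, expr = run_expression_arm(
        transcripts, bundle.families, reads.by_condition, outdir / "expression", cfg
    )
    kept_ids = set(verdicts.loc[verdicts.verdict == "kept", "assembly_id"])
    kept = [t for t in transcripts if t.id in kept_ids]
    ages, shift = run_dating_arm(
        bundle.genome, bundle.te_features, kept, outdir / "dating", cfg
    )
    mob = run_mobility_arm(calls, bundle.gene_features, outdir / "mobility", cfg)
    return {
        "verdicts": verdicts,
        "expression": expr,
        "ages": ages,
        "age_shift": shift,
        "mobility": mob,
        "truth": truth,
        "bundle": bundle,
    }
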
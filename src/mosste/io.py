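"""Domain types and readers/writers for the formats every pipeline stage touches.

All coordinates are 0-based half-open in memory; GFF3 on disk is 1-based
inclusive, converted on read and write. Sequences are uppercase DNA over
``{A, C, G, T, N}``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "GenomicFeature",
    "TEFamily",
    "InsertionCall",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_insertion_table",
    "write_insertion_table",
    "write_tsv_report",
    "read_tsv_report",
    "expression_matrix",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

#: GFF3 feature kinds with pipeline semantics; anything else is kept verbatim
#: but ignored by downstream filters.
KNOWN_KINDS = ("gene", "te_copy", "ltr5", "ltr3", "internal")


def revcomp(seq: str) -> str:
    """Reverse-complement an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence (genome contig, TE exemplar or transcript assembly)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)} in record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicFeature:
    """An interval on a named sequence: a gene, a TE copy, or one of its parts.

    ``ltr5``/``ltr3`` features reference their parent element through
    ``copy_id``; ``family`` is empty for genes.
    """

    seq_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."
    kind: str = "te_copy"
    family: str = ""
    copy_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.copy_id or self.kind}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TEFamily:
    """A TE family: classification plus an exemplar (consensus-like) sequence.

    Class I (retrotransposon) families may carry the exemplar's LTR
    coordinates in ``ltr_regions`` (0-based half-open pairs); these drive the
    solo-LTR discard rule, which is skipped for families without them.
    ``domain_protein`` is the family's protein-domain consensus (RT,
    transposase, ...) used for orientation calling. ``poorly_annotated``
    flags library entries that are not genuine TEs (e.g. repetitive genes).
    """

    name: str
    te_class: str  # "I" or "II"
    superfamily: str
    exemplar: SeqRecord
    ltr_regions: tuple[tuple[int, int], ...] = ()
    domain_protein: str = ""
    poorly_annotated: bool = False

    def __post_init__(self) -> None:
        if self.te_class not in ("I", "II"):
            raise ValueError(f"te_class must be 'I' or 'II', got {self.te_class!r}")
        for s, e in self.ltr_regions:
            if not (0 <= s < e <= len(self.exemplar)):
                raise ValueError(f"LTR region ({s}, {e}) outside exemplar {self.name}")


@dataclass(frozen=True)
class InsertionCall:
    """One TE insertion predicted in a resequenced accession.

    ``zygosity`` is the fraction of reads at the locus supporting the
    insertion; ``in_reference`` marks insertions present in the reference
    assembly (the mobility filter keeps non-reference calls only).
    """

    accession: str
    seq_id: str
    position: int  # 0-based point estimate
    family: str
    zygosity: float
    in_reference: bool
    support: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.zygosity <= 1.0):
            raise ValueError(
                f"zygosity {self.zygosity} outside [0, 1] "
                f"({self.accession}:{self.seq_id}:{self.position})"
            )
        if self.support < 0:
            raise ValueError("support must be >= 0")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Sequences are uppercased; duplicate ids and empty files are errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_KIND_ALIASES = {"mrna": "gene"}


def _parse_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GenomicFeature]:
    """Read GFF3 (1-based inclusive on disk) into 0-based half-open features.

    The attribute keys ``ID``, ``Parent`` and ``Family`` populate ``copy_id``
    and ``family``. Lines with start > end are rejected with a warning and
    skipped; unknown feature types are stored as-is.
    """
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seq_id, _src, kind, start, end, _score, strand, _phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                warnings.warn(f"{path}:{lineno}: start > end, line skipped")
                continue
            a = _parse_attributes(attrs)
            kind = _KIND_ALIASES.get(kind.lower(), kind)
            copy_id = a.get("ID", a.get("Parent", ""))
            feats.append(
                GenomicFeature(
                    seq_id=seq_id,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand if strand in ("+", "-") else ".",
                    kind=kind,
                    family=a.get("Family", ""),
                    copy_id=copy_id,
                )
            )
    return feats


def write_gff3(
    features: Iterable[GenomicFeature], path: str | Path, source: str = "mosste"
) -> None:
    """Write features as GFF3, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.copy_id:
                key = "Parent" if f.kind in ("ltr5", "ltr3", "internal") else "ID"
                attrs.append(f"{key}={f.copy_id}")
            if f.family:
                attrs.append(f"Family={f.family}")
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        source,
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Insertion-call TSV (frozen 7-column dialect)

INSERTION_COLUMNS = (
    "accession",
    "seq_id",
    "position",
    "family",
    "zygosity",
    "in_reference",
    "support",
)


def read_insertion_table(path: str | Path) -> list[InsertionCall]:
    """Read the 7-column insertion-call TSV dialect.

    Real PoPoolationTE2 output is converted to this dialect upstream; see the
    methods note for the column mapping.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in INSERTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    calls: list[InsertionCall] = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        zyg = float(row.zygosity)
        if not (0.0 <= zyg <= 1.0):
            raise ValueError(f"{path}: line {i}: zygosity {zyg} outside [0, 1]")
        calls.append(
            InsertionCall(
                accession=row.accession,
                seq_id=row.seq_id,
                position=int(row.position),
                family=row.family,
                zygosity=zyg,
                in_reference=str(row.in_reference).strip().lower() in ("1", "true", "yes"),
                support=int(row.support),
            )
        )
    return calls


def write_insertion_table(
    calls: Iterable[InsertionCall], path: str | Path, header_comment: str | None = None
) -> None:
    rows = [
        {
            "accession": c.accession,
            "seq_id": c.seq_id,
            "position": c.position,
            "family": c.family,
            "zygosity": c.zygosity,
            "in_reference": int(c.in_reference),
            "support": c.support,
        }
        for c in calls
    ]
    write_tsv_report(rows, path, columns=list(INSERTION_COLUMNS), header_comment=header_comment)


# ---------------------------------------------------------------------------
# Generic TSV reports


def write_tsv_report(
    table: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write rows of named fields as a TSV that round-trips through
    :func:`read_tsv_report`. All rows must share one field set."""
    table = list(table)
    if table:
        keys = set(table[0].keys())
        for row in table[1:]:
            if set(row.keys()) != keys:
                raise ValueError("heterogeneous rows: all rows must share field names")
        if columns is None:
            columns = list(table[0].keys())
    elif columns is None:
        raise ValueError("empty table needs explicit columns for a header-only file")
    df = pd.DataFrame(table, columns=list(columns))
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv_report(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv_report` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def expression_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long expression table (assembly_id, condition, value) into an
    assembly x condition matrix; validates non-negativity and uniqueness."""
    if df.duplicated(subset=["assembly_id", "condition"]).any():
        raise ValueError("duplicate (assembly_id, condition) pairs")
    mat = df.pivot(index="assembly_id", columns="condition", values="value").fillna(0.0)
    if (mat.values < 0).any():
        raise ValueError("expression values must be >= 0")
    return mat
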
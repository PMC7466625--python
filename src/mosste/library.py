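"""Read/write a TE family library: exemplar FASTA plus a metadata TSV.

The metadata TSV carries per-family classification, optional exemplar LTR
coordinates (``start-end`` pairs joined by ``;``, 0-based half-open) and a
poorly-annotated flag; a separate protein FASTA carries the domain
consensus sequences keyed by family name.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .io import SeqRecord, TEFamily, read_fasta, read_tsv_report, write_tsv_report

__all__ = ["read_te_library", "write_te_library"]


def _parse_regions(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text == ".":
        return ()
    out = []
    for chunk in text.split(";"):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _format_regions(regions) -> str:
    return ";".join(f"{s}-{e}" for s, e in regions) or "."


def read_te_library(
    fasta: str | Path,
    meta_tsv: str | Path | None = None,
    domains_fasta: str | Path | None = None,
) -> list[TEFamily]:
    """Load a family library. Without metadata every family defaults to
    class I with no LTR coordinates (the solo-LTR rule is then skipped)."""
    exemplars = {r.id: r for r in read_fasta(fasta)}
    meta: dict[str, dict] = {}
    if meta_tsv is not None:
        df = read_tsv_report(meta_tsv)
        for row in df.to_dict("records"):
            meta[str(row["name"])] = row
    domains: dict[str, str] = {}
    if domains_fasta is not None:
        for rec in SeqIO.parse(str(domains_fasta), "fasta"):
            domains[rec.id] = str(rec.seq).upper()
    families = []
    for name, ex in exemplars.items():
        m = meta.get(name, {})
        families.append(
            TEFamily(
                name=name,
                te_class=str(m.get("te_class", "I")),
                superfamily=str(m.get("superfamily", "unknown")),
                exemplar=ex,
                ltr_regions=_parse_regions(str(m.get("ltr_regions", ""))),
                domain_protein=domains.get(name, ""),
                poorly_annotated=bool(int(m.get("poorly_annotated", 0))),
            )
        )
    return families


def write_te_library(
    families: list[TEFamily],
    fasta: str | Path,
    meta_tsv: str | Path,
    domains_fasta: str | Path | None = None,
) -> None:
    from .io import write_fasta

    write_fasta([f.exemplar for f in families], fasta)
    write_tsv_report(
        [
            {
                "name": f.name,
                "te_class": f.te_class,
                "superfamily": f.superfamily,
                "ltr_regions": _format_regions(f.ltr_regions),
                "poorly_annotated": int(f.poorly_annotated),
            }
            for f in families
        ],
        meta_tsv,
    )
    if domains_fasta is not None:
        with open(domains_fasta, "w") as fh:
            for f in families:
                if f.domain_protein:
                    fh.write(f">{f.name}\n{f.domain_protein}\n")
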
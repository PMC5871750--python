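"""Gene association: link called sites to genes overlapping or within 10 kb.

Genes are supplied as a local table (BED6 or a 5/6-column TSV) rather than
queried from a remote annotation service, so runs are reproducible and
offline.  Association is strand-blind and measured to the gene body: a gene
is associated with a site when the gap between the two half-open intervals
is zero (overlap) or at most ``gene_dist`` bp.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sites import SiteSet

__all__ = [
    "read_genes",
    "interval_gap",
    "associate_genes",
    "summarize_annotation",
]

GENE_COLUMNS = ["gene_id", "gene_name", "chrom", "start", "end", "strand"]


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read a gene table.

    Accepts BED6 (chrom, start, end, name, score, strand; name used as both
    id and symbol) or a TSV with columns gene_id, gene_name, chrom, start,
    end[, strand].
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    ncol = df.shape[1]
    first = df.iloc[0].tolist() if len(df) else []
    if list(df.columns) != list(range(ncol)):  # pragma: no cover - defensive
        raise ValueError("unexpected gene table shape")
    if ncol >= 5 and first and not str(first[1]).lstrip("-").isdigit():
        # headered TSV: gene_id gene_name chrom start end [strand]
        df.columns = GENE_COLUMNS[:ncol]
        df = df.iloc[1:].reset_index(drop=True)
    elif ncol >= 4 and str(first[1]).lstrip("-").isdigit():
        # BED-like: chrom start end name [score] [strand]
        names = ["chrom", "start", "end", "gene_id", "score", "strand"][:ncol]
        df.columns = names
        df["gene_name"] = df["gene_id"]
    else:
        raise ValueError("unrecognized gene table format")
    if "strand" not in df.columns:
        df["strand"] = "."
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
        raise ValueError("genes must satisfy start < end")
    return df[GENE_COLUMNS].reset_index(drop=True)


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int):
    """Gap between half-open intervals; 0 iff they overlap by >= 1 bp."""
    return np.maximum(0, np.maximum(a_start, b_start) - np.minimum(a_end, b_end))


def associate_genes(
    sites: SiteSet,
    genes: pd.DataFrame,
    gene_dist: int = 10_000,
    known_chroms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All (site, gene) pairs with gap <= ``gene_dist``.

    Returns a table site_id, chrom, site_start, site_end, gene_id, gene_name,
    distance (0 when overlapping).  ``known_chroms``, when given, validates
    gene chromosomes against the genome layout.
    """
    if gene_dist < 0:
        raise ValueError("gene_dist must be >= 0")
    if known_chroms is not None:
        unknown = set(genes["chrom"]) - set(known_chroms)
        if unknown:
            raise ValueError(f"genes on chromosomes absent from layout: {sorted(unknown)}")
    out_cols = ["site_id", "chrom", "site_start", "site_end", "gene_id", "gene_name", "distance"]
    rows = []
    for chrom, sub_sites in sites.sites.groupby("chrom", sort=False):
        sub_genes = genes[genes["chrom"] == chrom]
        if len(sub_genes) == 0:
            continue
        ss = sub_sites["start"].to_numpy(np.int64)[:, None]
        se = sub_sites["end"].to_numpy(np.int64)[:, None]
        gs = sub_genes["start"].to_numpy(np.int64)[None, :]
        ge = sub_genes["end"].to_numpy(np.int64)[None, :]
        gap = interval_gap(ss, se, gs, ge)
        si, gi = np.nonzero(gap <= gene_dist)
        for a, b in zip(si, gi):
            site_row = sub_sites.iloc[a]
            gene_row = sub_genes.iloc[b]
            rows.append(
                (
                    f"{sites.kind}:{site_row.name}",
                    chrom,
                    int(site_row["start"]),
                    int(site_row["end"]),
                    gene_row["gene_id"],
                    gene_row["gene_name"],
                    int(gap[a, b]),
                )
            )
    return pd.DataFrame(rows, columns=out_cols)


def summarize_annotation(sites: SiteSet, annotations: pd.DataFrame) -> dict:
    """Counts of annotated sites and the deduplicated, sorted gene list."""
    n_total = len(sites)
    n_with = annotations["site_id"].nunique() if len(annotations) else 0
    genes = sorted(set(annotations["gene_id"])) if len(annotations) else []
    return {
        "n_sites_total": int(n_total),
        "n_sites_with_genes": int(n_with),
        "genes": genes,
    }


def write_annotation(
    annotations: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    annotations.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
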
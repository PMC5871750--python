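"""Site calling: DHRs, conserved, per-individual, and universal core sites.

A *differential histone retention region* (DHR) starts from runs of windows
whose differential-coverage p-value falls below a stringent threshold
(1e-7 or 1e-6 depending on the comparison) and is then extended: any window
with p < 0.1 lying within 1000 bp of a region edge is absorbed, repeatedly,
until no such window remains in range (a fixpoint).  *Conserved* retention
sites use the same merge/extension machinery but qualify windows by raw read
depth (>= 150 reads, alternate 25) in every sample of a group; *individual*
sites do the same for a single sample.  The *universal core* is the subset of
a representative group's conserved sites that overlap a site in every other
group.

Because the stringent-seed set is a subset of the extension-qualifying set,
the fixpoint is exactly the single-linkage clustering of qualifying windows
at the extension distance, restricted to clusters containing at least one
seed window.  An exhaustive re-scanning implementation is kept in the test
suite as an independent oracle.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .differential import DifferentialResult
from .genome import WindowCountMatrix, WindowTiling

__all__ = [
    "AnalysisParams",
    "SiteSet",
    "call_dhrs",
    "sweep_dhr_thresholds",
    "call_conserved_sites",
    "call_individual_sites",
    "intersect_core_sites",
    "window_venn",
    "overlap_site_sets",
    "length_summary",
    "qualifying_windows",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisParams:
    """The analysis constants.

    window_size: 100 bp tiles.
    dhr_p_threshold: seed-window p cutoff (1e-7 for the DDT H3 comparison,
        1e-6 for vinclozolin and the H3K27me3 comparison).
    edge_p: extension cutoff (0.1).
    edge_dist / merge_dist: 1000 bp extension and merge range.
    depth_threshold: raw reads per window for retention (150; alternate 25).
    gene_dist: gene association distance (10 kb).
    edge_rule: "strict" counts a window as within range when its gap to the
        region edge is < edge_dist; "closed" uses <=.
    """

    window_size: int = 100
    dhr_p_threshold: float = 1e-7
    edge_p: float = 0.1
    edge_dist: int = 1000
    depth_threshold: int = 150
    merge_dist: int = 1000
    gene_dist: int = 10_000
    edge_rule: str = "strict"

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.edge_dist < 1 or self.merge_dist < 1:
            raise ValueError("window_size, edge_dist and merge_dist must be positive")
        if not 0 < self.edge_p < 1:
            raise ValueError("edge_p must lie in (0, 1)")
        if not 0 < self.dhr_p_threshold < self.edge_p:
            raise ValueError("dhr_p_threshold must lie in (0, edge_p)")
        if self.depth_threshold < 1 or self.gene_dist < 0:
            raise ValueError("depth_threshold must be >= 1 and gene_dist >= 0")
        if self.edge_rule not in ("strict", "closed"):
            raise ValueError("edge_rule must be 'strict' or 'closed'")


SITE_COLUMNS = ["chrom", "start", "end", "n_sig_windows", "score", "length_kb"]


@dataclass
class SiteSet:
    """Sorted, non-overlapping genomic intervals of one kind.

    ``kind`` is one of DHR / conserved / individual / core; ``provenance``
    labels the comparison, group, or individual the set came from.  The
    ``score`` column holds -log10(min p) for DHRs and the minimum qualifying
    depth for depth-based sites.
    """

    kind: str
    sites: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.sites.reset_index(drop=True)
        for col in SITE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"site table missing column {col!r}")
        if len(df):
            if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
                raise ValueError("sites must satisfy start < end")
            order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
            df = df.iloc[order].reset_index(drop=True)
            for chrom, sub in df.groupby("chrom", sort=False):
                s = sub["start"].to_numpy()
                e = sub["end"].to_numpy()
                if np.any(s[1:] < e[:-1]):
                    raise ValueError(f"overlapping sites on {chrom}")
        self.sites = df[SITE_COLUMNS]

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def empty(cls, kind: str, provenance: str = "") -> "SiteSet":
        return cls(kind, pd.DataFrame(columns=SITE_COLUMNS), provenance)

    @classmethod
    def from_intervals(
        cls,
        kind: str,
        intervals: Iterable[tuple[str, int, int]],
        provenance: str = "",
    ) -> "SiteSet":
        rows = list(intervals)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["n_sig_windows"] = 0
        df["score"] = 0.0
        df["length_kb"] = (df["end"] - df["start"]) / 1000.0
        return cls(kind, df, provenance)

    def intervals(self, chrom: str | None = None) -> pd.DataFrame:
        if chrom is None:
            return self.sites[["chrom", "start", "end"]]
        sub = self.sites[self.sites["chrom"] == chrom]
        return sub[["chrom", "start", "end"]]

    def lengths_bp(self) -> np.ndarray:
        return (self.sites["end"] - self.sites["start"]).to_numpy(np.int64)

    def to_bed(self, path: str | Path, header_comment: str | None = None) -> None:
        """BED6: name = kind:ordinal, score = site score, strand '.'."""
        buf = io.StringIO()
        if header_comment:
            buf.write(f"# {header_comment}\n")
        for i, row in self.sites.iterrows():
            buf.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{self.kind}:{i}\t{row['score']:.4g}\t.\n"
            )
        Path(path).write_text(buf.getvalue())

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        buf = io.StringIO()
        if header_comment:
            buf.write(f"# {header_comment}\n")
        self.sites.to_csv(buf, sep="\t", index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_bed(cls, path: str | Path, kind: str | None = None, provenance: str = "") -> "SiteSet":
        rows = []
        inferred = kind
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                score = float(parts[4]) if len(parts) > 4 else 0.0
                if inferred is None and len(parts) > 3 and ":" in parts[3]:
                    inferred = parts[3].split(":", 1)[0]
                rows.append((chrom, start, end, score))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        df["n_sig_windows"] = 0
        df["length_kb"] = (df["end"] - df["start"]) / 1000.0
        return cls(inferred or "site", df, provenance)


# ---------------------------------------------------------------------------
# Core clustering / extension machinery
# ---------------------------------------------------------------------------

def _call_sites_one_chrom(
    starts: np.ndarray,
    ends: np.ndarray,
    qualifying: np.ndarray,
    seed: np.ndarray,
    max_dist: int,
    strict: bool,
) -> list[tuple[int, int, np.ndarray]]:
    """Single-linkage clusters of qualifying windows; keep seeded clusters.

    Returns (start, end, member window positions) per called site.  ``seed``
    must be a subset of ``qualifying``.
    """
    q = np.flatnonzero(qualifying)
    if q.size == 0:
        return []
    gaps = starts[q[1:]] - ends[q[:-1]]
    linked = gaps < max_dist if strict else gaps <= max_dist
    cluster_id = np.concatenate([[0], np.cumsum(~linked)])
    out = []
    for cid in range(cluster_id[-1] + 1):
        members = q[cluster_id == cid]
        if not seed[members].any():
            continue
        out.append((int(starts[members[0]]), int(ends[members[-1]]), members))
    return out


def _threshold_call(
    tiling: WindowTiling,
    qualifying: np.ndarray,
    seed: np.ndarray,
    max_dist: int,
    strict: bool,
    kind: str,
    provenance: str,
    score_of: "callable",
    n_sig_of: "callable",
) -> SiteSet:
    rows = []
    for chrom in tiling.layout.names:
        sl = tiling.chrom_slice(chrom)
        calls = _call_sites_one_chrom(
            tiling.starts(chrom),
            tiling.ends(chrom),
            qualifying[sl],
            seed[sl],
            max_dist,
            strict,
        )
        for start, end, members in calls:
            g_members = members + sl.start
            rows.append(
                (
                    chrom,
                    start,
                    end,
                    int(n_sig_of(g_members)),
                    float(score_of(g_members)),
                    (end - start) / 1000.0,
                )
            )
    if not rows:
        return SiteSet.empty(kind, provenance)
    return SiteSet(kind, pd.DataFrame(rows, columns=SITE_COLUMNS), provenance)


# ---------------------------------------------------------------------------
# DHR calling
# ---------------------------------------------------------------------------

def call_dhrs(
    diff: DifferentialResult,
    params: AnalysisParams,
    p_threshold: float | None = None,
) -> SiteSet:
    """Call DHRs from per-window p-values.

    Seed regions are runs of windows with p below the stringent threshold;
    edges are extended to absorb any window with p < ``edge_p`` within
    ``edge_dist`` of an edge, iterated to a fixpoint; touching regions merge.
    ``n_sig_windows`` counts seed windows per final region.
    """
    thr = params.dhr_p_threshold if p_threshold is None else float(p_threshold)
    if not 0 < thr < params.edge_p:
        raise ValueError("p threshold must lie in (0, edge_p)")
    p = np.asarray(diff.p_value)
    if len(p) != diff.tiling.n_windows:
        raise ValueError("p-value vector length mismatch with window tiling")
    seed = p < thr
    qualifying = p < params.edge_p
    provenance = f"{diff.control_group}_vs_{diff.exposure_group}"
    return _threshold_call(
        diff.tiling,
        qualifying,
        seed,
        params.edge_dist,
        params.edge_rule == "strict",
        "DHR",
        provenance,
        score_of=lambda m: -np.log10(max(p[m][seed[m]].min(), 1e-300)),
        n_sig_of=lambda m: seed[m].sum(),
    )


def sweep_dhr_thresholds(
    diff: DifferentialResult,
    thresholds: Sequence[float],
    params: AnalysisParams,
) -> pd.DataFrame:
    """DHR counts per p cutoff: all DHRs and those with >= 2 seed windows."""
    if len(thresholds) == 0:
        raise ValueError("threshold list must be non-empty")
    rows = []
    for thr in thresholds:
        sites = call_dhrs(diff, params, p_threshold=thr)
        n_all = len(sites)
        n_multi = int((sites.sites["n_sig_windows"] >= 2).sum())
        rows.append((thr, n_all, n_multi))
    return pd.DataFrame(rows, columns=["threshold", "all_window_count", "multiple_window_count"])


# ---------------------------------------------------------------------------
# Depth-thresholded sites
# ---------------------------------------------------------------------------

def _depth_qualifying(
    matrix: WindowCountMatrix,
    sample_ids: Sequence[str],
    depth_threshold: int,
) -> np.ndarray:
    """Windows whose raw count meets the threshold in every named sample."""
    if len(sample_ids) == 0:
        raise ValueError("sample group must be non-empty")
    cols = np.column_stack([matrix.column(s) for s in sample_ids])
    return (cols >= depth_threshold).all(axis=1)


def qualifying_windows(
    matrix: WindowCountMatrix,
    sample_ids: Sequence[str] | str,
    depth_threshold: int,
) -> np.ndarray:
    """Global indices of windows meeting the depth threshold in all samples."""
    if isinstance(sample_ids, str):
        sample_ids = [sample_ids]
    return np.flatnonzero(_depth_qualifying(matrix, sample_ids, depth_threshold))


def _call_depth_sites(
    matrix: WindowCountMatrix,
    sample_ids: Sequence[str],
    params: AnalysisParams,
    kind: str,
    provenance: str,
) -> SiteSet:
    qual = _depth_qualifying(matrix, sample_ids, params.depth_threshold)
    cols = np.column_stack([matrix.column(s) for s in sample_ids])
    min_depth = cols.min(axis=1)
    return _threshold_call(
        matrix.tiling,
        qual,
        qual,  # qualifying windows are their own seeds
        params.merge_dist,
        params.edge_rule == "strict",
        kind,
        provenance,
        score_of=lambda m: min_depth[m].min(),
        n_sig_of=lambda m: len(m),
    )


def call_conserved_sites(
    matrix: WindowCountMatrix,
    group: str | Sequence[str],
    params: AnalysisParams,
) -> SiteSet:
    """Conserved retention sites for one sample group.

    A window qualifies when its raw count meets ``depth_threshold`` in every
    sample of the group; qualifying windows merge/extend exactly as DHRs do.
    ``group`` is a group label or an explicit list of sample ids.
    """
    if isinstance(group, str):
        sample_ids = [s.sample_id for s in matrix.samples if s.group == group]
        if not sample_ids:
            raise KeyError(f"no samples in group {group!r}")
        provenance = group
    else:
        sample_ids = list(group)
        for sid in sample_ids:
            if sid not in matrix.sample_ids:
                raise KeyError(f"unknown sample {sid!r}")
        provenance = ",".join(sample_ids)
    return _call_depth_sites(matrix, sample_ids, params, "conserved", provenance)


def call_individual_sites(
    matrix: WindowCountMatrix,
    sample_id: str,
    params: AnalysisParams,
) -> SiteSet:
    """Retention sites of a single sample (depth threshold on that sample)."""
    if sample_id not in matrix.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    return _call_depth_sites(matrix, [sample_id], params, "individual", sample_id)


# ---------------------------------------------------------------------------
# Overlap algebra
# ---------------------------------------------------------------------------

def _overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """For each interval of ``a``, whether it overlaps (>= 1 bp) any of ``b``."""
    out = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return out
    a = a.reset_index(drop=True)
    for chrom, sub_a in a.groupby("chrom", sort=False):
        sub_b = b[b["chrom"] == chrom]
        if len(sub_b) == 0:
            continue
        bs = np.sort(sub_b["start"].to_numpy(np.int64))
        be = np.sort(sub_b["end"].to_numpy(np.int64))
        s = sub_a["start"].to_numpy(np.int64)
        e = sub_a["end"].to_numpy(np.int64)
        # number of b starting before a ends minus number of b ending at/before a starts
        n_open = np.searchsorted(bs, e, side="left") - np.searchsorted(be, s, side="right")
        out[sub_a.index.to_numpy()] = n_open > 0
    return out


def intersect_core_sites(site_sets: Sequence[SiteSet], representative: str) -> SiteSet:
    """Universal core: representative sites overlapping a site in every other set.

    ``representative`` names the provenance of one input set whose intervals
    are reported verbatim.
    """
    if len(site_sets) < 2:
        raise ValueError("need at least two site sets")
    labels = [s.provenance for s in site_sets]
    if representative not in labels:
        raise KeyError(f"unknown representative {representative!r}")
    rep = site_sets[labels.index(representative)]
    keep = np.ones(len(rep), dtype=bool)
    for other in site_sets:
        if other is rep:
            continue
        keep &= _overlaps_any(rep.sites, other.sites)
    df = rep.sites[keep].copy()
    return SiteSet("core", df, provenance=representative)


def overlap_site_sets(a: SiteSet, b: SiteSet) -> dict[str, int]:
    """Two-set overlap bookkeeping (sites overlapping >= 1 bp count as shared)."""
    a_shared = int(_overlaps_any(a.sites, b.sites).sum())
    b_shared = int(_overlaps_any(b.sites, a.sites).sum())
    return {
        "a_total": len(a),
        "b_total": len(b),
        "a_shared": a_shared,
        "b_shared": b_shared,
        "a_only": len(a) - a_shared,
        "b_only": len(b) - b_shared,
    }


# ---------------------------------------------------------------------------
# Venn partition over qualifying windows
# ---------------------------------------------------------------------------

def window_venn(
    window_sets: Sequence[np.ndarray] | Sequence[SiteSet],
    labels: Sequence[str] | None = None,
    tiling: WindowTiling | None = None,
) -> dict:
    """n-set Venn partition of qualifying-window sets.

    Inputs are arrays of global window indices (or SiteSets, reduced to their
    constituent windows via ``tiling``).  Returns counts for every non-empty
    membership region plus ``fraction_common`` = |intersection| / |union|.
    """
    if len(window_sets) < 2:
        raise ValueError("need at least two sets")
    if len(window_sets) > 7:
        raise ValueError("more than 7 sets: Venn partition not supported")
    sets = []
    for ws in window_sets:
        if isinstance(ws, SiteSet):
            if tiling is None:
                raise ValueError("tiling required to reduce SiteSets to windows")
            idx: list[np.ndarray] = []
            for _, row in ws.sites.iterrows():
                idx.append(tiling.windows_overlapping(row["chrom"], int(row["start"]), int(row["end"])))
            sets.append(np.unique(np.concatenate(idx)) if idx else np.empty(0, np.int64))
        else:
            sets.append(np.unique(np.asarray(ws, dtype=np.int64)))
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(sets))]
    union = np.unique(np.concatenate(sets)) if any(len(s) for s in sets) else np.empty(0, np.int64)
    code = np.zeros(len(union), dtype=np.int64)
    for i, s in enumerate(sets):
        code[np.isin(union, s)] |= 1 << i
    counts = {}
    for combo_size in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), combo_size):
            mask = sum(1 << i for i in combo)
            key = "&".join(labels[i] for i in combo)
            counts[key] = int(np.sum(code == mask))
    n_union = int(len(union))
    n_common = int(np.sum(code == (1 << len(sets)) - 1))
    return {
        "labels": list(labels),
        "region_counts": counts,
        "union": n_union,
        "intersection": n_common,
        "fraction_common": (n_common / n_union) if n_union else 0.0,
    }


# ---------------------------------------------------------------------------
# Length summaries
# ---------------------------------------------------------------------------

def length_summary(sites: SiteSet, bin_edges_kb: Sequence[float]) -> pd.DataFrame:
    """Histogram of site lengths in kb over left-closed bins.

    ``bin_edges_kb`` gives the left edges plus a final right edge (use
    ``np.inf`` for an open last bin).
    """
    edges = np.asarray(bin_edges_kb, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = sites.lengths_bp() / 1000.0
    counts, _ = np.histogram(lengths, bins=edges)
    # np.histogram closes the final bin on the right; keep left-closed semantics
    if len(lengths) and not np.isinf(edges[-1]):
        counts[-1] -= int(np.sum(lengths == edges[-1]))
    return pd.DataFrame(
        {
            "bin_left_kb": edges[:-1],
            "bin_right_kb": edges[1:],
            "count": counts,
        }
    )
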
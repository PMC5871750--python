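"""Genome layout, fixed-width window tiling, and per-window fragment counting.

The atomic unit of the whole analysis is a fixed 100 bp genomic window.  A
genome (any genome; the method was developed on rat) is tiled exhaustively
with non-overlapping windows, mapped chromatin fragments are counted into the
windows they overlap, and every downstream step -- the differential coverage
test, read-depth thresholding, site calling -- operates on the resulting
window x sample count matrix.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "WindowTiling",
    "FragmentSet",
    "SampleInfo",
    "WindowCountMatrix",
    "make_windows",
    "count_fragments",
    "build_count_matrix",
]


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths.

    The chromosome order is significant: it fixes the global window indexing
    used as the join key across samples.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("genome layout must contain at least one chromosome")
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        for name, length in zip(self.names, self.lengths):
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column whitespace-separated ``chrom.sizes`` file."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"malformed chrom.sizes line: {line!r}")
                names.append(parts[0])
                lengths.append(int(parts[1]))
        return cls(tuple(names), tuple(lengths))

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


# ---------------------------------------------------------------------------
# Window tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowTiling:
    """Exhaustive fixed-width window tiling of a genome.

    Windows tile each chromosome without gaps or overlaps; the last window of
    a chromosome may be shorter than ``window_size``.  Windows are globally
    indexed by chromosome order then start coordinate.
    """

    layout: GenomeLayout
    window_size: int
    n_per_chrom: tuple[int, ...] = field(init=False)
    offsets: tuple[int, ...] = field(init=False)  # first global index per chrom

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        n = tuple(-(-length // self.window_size) for length in self.layout.lengths)
        object.__setattr__(self, "n_per_chrom", n)
        object.__setattr__(self, "offsets", tuple(np.concatenate([[0], np.cumsum(n)[:-1]]).tolist()))

    @property
    def n_windows(self) -> int:
        return sum(self.n_per_chrom)

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global index range covering one chromosome."""
        i = self.layout.names.index(chrom)
        return slice(self.offsets[i], self.offsets[i] + self.n_per_chrom[i])

    def starts(self, chrom: str) -> np.ndarray:
        i = self.layout.names.index(chrom)
        return np.arange(self.n_per_chrom[i], dtype=np.int64) * self.window_size

    def ends(self, chrom: str) -> np.ndarray:
        i = self.layout.names.index(chrom)
        e = self.starts(chrom) + self.window_size
        e[-1] = min(int(e[-1]), self.layout.lengths[i])
        return e

    def to_dataframe(self) -> pd.DataFrame:
        """Window table with columns chrom, start, end, index."""
        frames = []
        for chrom in self.layout.names:
            s = self.starts(chrom)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": s,
                        "end": self.ends(chrom),
                        "index": np.arange(len(s)) + self.offsets[self.layout.names.index(chrom)],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing base ``pos``."""
        i = self.layout.names.index(chrom)
        if not 0 <= pos < self.layout.lengths[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[i] + pos // self.window_size

    def windows_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of all windows overlapping [start, end) by >= 1 bp."""
        i = self.layout.names.index(chrom)
        if end <= start:
            raise ValueError("empty interval")
        first = max(0, start // self.window_size)
        last = min(self.n_per_chrom[i] - 1, (end - 1) // self.window_size)
        return np.arange(first, last + 1, dtype=np.int64) + self.offsets[i]


def make_windows(layout: GenomeLayout, window_size: int) -> WindowTiling:
    """Tile *layout* into fixed windows of *window_size* bp (default analysis: 100)."""
    return WindowTiling(layout, int(window_size))


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

@dataclass
class FragmentSet:
    """Mapped chromatin fragments for one sample.

    Fragments are whole-insert intervals (paired-end mates already merged
    upstream); strand is irrelevant for occupancy counting.
    """

    sample_id: str
    chroms: np.ndarray  # object/str array
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("fragments must satisfy start < end")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_intervals(cls, sample_id: str, intervals: Iterable[tuple[str, int, int]]) -> "FragmentSet":
        rows = list(intervals)
        if not rows:
            return cls(sample_id, np.empty(0, object), np.empty(0, np.int64), np.empty(0, np.int64))
        c, s, e = zip(*rows)
        return cls(sample_id, np.array(c, object), np.array(s, np.int64), np.array(e, np.int64))

    @classmethod
    def from_bed(cls, path: str | Path, sample_id: str | None = None) -> "FragmentSet":
        """Read fragments from a >= 3 column BED file (extra columns ignored)."""
        name = sample_id if sample_id is not None else Path(path).stem
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        return cls(name, df["chrom"].to_numpy(object), df["start"].to_numpy(), df["end"].to_numpy())

    def to_bed(self, path: str | Path) -> None:
        df = pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})
        df.to_csv(path, sep="\t", header=False, index=False)

    def validate(self, layout: GenomeLayout, on_out_of_bounds: str = "error") -> "FragmentSet":
        """Check fragments against the layout.

        ``on_out_of_bounds``: "error" (default) rejects fragments exceeding
        chromosome bounds, "clip" truncates them.  Unknown chromosomes are
        always an error.
        """
        if on_out_of_bounds not in ("error", "clip"):
            raise ValueError("on_out_of_bounds must be 'error' or 'clip'")
        lengths = np.empty(len(self), dtype=np.int64)
        known = dict(zip(layout.names, layout.lengths))
        for chrom in np.unique(self.chroms.astype(str)) if len(self) else []:
            if chrom not in known:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        for i, chrom in enumerate(self.chroms):
            lengths[i] = known[str(chrom)]
        bad = (self.starts < 0) | (self.ends > lengths)
        if not bad.any():
            return self
        if on_out_of_bounds == "error":
            i = int(np.argmax(bad))
            raise ValueError(
                f"fragment {self.chroms[i]}:{self.starts[i]}-{self.ends[i]} outside chromosome bounds"
            )
        starts = np.maximum(self.starts, 0)
        ends = np.minimum(self.ends, lengths)
        keep = ends > starts
        return FragmentSet(self.sample_id, self.chroms[keep], starts[keep], ends[keep])


def count_fragments(
    tiling: WindowTiling,
    frags: FragmentSet,
    mode: str = "overlap",
    on_out_of_bounds: str = "error",
) -> np.ndarray:
    """Count fragments into windows, returning one integer per global window.

    In the default ``overlap`` mode a fragment increments every window it
    overlaps by at least one base (region-coverage semantics).  ``midpoint``
    assigns each fragment to the single window containing its midpoint.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError("mode must be 'overlap' or 'midpoint'")
    frags = frags.validate(tiling.layout, on_out_of_bounds=on_out_of_bounds)
    w = tiling.window_size
    counts = np.zeros(tiling.n_windows, dtype=np.int64)
    if len(frags) == 0:
        return counts
    chrom_arr = frags.chroms.astype(str)
    for ci, chrom in enumerate(tiling.layout.names):
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        s = frags.starts[mask]
        e = frags.ends[mask]
        off = tiling.offsets[ci]
        nwin = tiling.n_per_chrom[ci]
        if mode == "midpoint":
            idx = ((s + e) // 2) // w
            np.clip(idx, 0, nwin - 1, out=idx)
            counts[off : off + nwin] += np.bincount(idx, minlength=nwin)
        else:
            first = s // w
            last = (e - 1) // w
            np.clip(last, None, nwin - 1, out=last)
            offset = 0
            while True:
                sel = first + offset <= last
                if not sel.any():
                    break
                counts[off : off + nwin] += np.bincount(first[sel] + offset, minlength=nwin)
                offset += 1
    return counts


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str  # e.g. "control" / "exposure", or an individual label


@dataclass
class WindowCountMatrix:
    """Integer fragment counts per window per sample, with group labels."""

    tiling: WindowTiling
    samples: tuple[SampleInfo, ...]
    counts: np.ndarray  # (n_windows, n_samples) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.tiling.n_windows, len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{self.tiling.n_windows} windows x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.samples]

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def group_columns(self, group: str) -> np.ndarray:
        """Submatrix of all samples with the given group label."""
        idx = [i for i, s in enumerate(self.samples) if s.group == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return self.counts[:, idx]

    def library_sizes(self) -> dict[str, int]:
        return {s.sample_id: int(t) for s, t in zip(self.samples, self.counts.sum(axis=0))}

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        df = self.tiling.to_dataframe()
        for j, s in enumerate(self.samples):
            df[f"{s.sample_id}:{s.group}"] = self.counts[:, j]
        buf = io.StringIO()
        if header_comment:
            buf.write(f"# {header_comment}\n")
        df.to_csv(buf, sep="\t", index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WindowCountMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        meta = {"chrom", "start", "end", "index"}
        sample_cols = [c for c in df.columns if c not in meta]
        names, lengths = [], []
        for chrom, sub in df.groupby("chrom", sort=False):
            names.append(str(chrom))
            lengths.append(int(sub["end"].max()))
        window_size = int((df["end"] - df["start"]).max())
        tiling = WindowTiling(GenomeLayout(tuple(names), tuple(lengths)), window_size)
        samples = tuple(SampleInfo(*c.split(":", 1)) for c in sample_cols)
        return cls(tiling, samples, df[sample_cols].to_numpy(np.int64))


def build_count_matrix(
    tiling: WindowTiling,
    fragment_sets: Sequence[FragmentSet],
    groups: Mapping[str, str],
    mode: str = "overlap",
    on_out_of_bounds: str = "error",
) -> WindowCountMatrix:
    """Count every sample's fragments and assemble the window count matrix.

    ``groups`` maps sample_id -> group label; every fragment set must be
    covered.
    """
    samples = []
    cols = []
    for fs in fragment_sets:
        if fs.sample_id not in groups:
            raise KeyError(f"no group label for sample {fs.sample_id!r}")
        samples.append(SampleInfo(fs.sample_id, groups[fs.sample_id]))
        cols.append(count_fragments(tiling, fs, mode=mode, on_out_of_bounds=on_out_of_bounds))
    return WindowCountMatrix(tiling, tuple(samples), np.column_stack(cols))
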
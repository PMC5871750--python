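"""Seeded synthetic data: genomes, planted retention sites, and fragments.

The generator emulates the statistical structure the analysis assumes, at
desk scale, so every pipeline stage can be exercised against known truth:

* a small genome (default two 5 Mb chromosomes) tiled by 100 bp windows;
* planted *core* retention sites (present in every sample of every group)
  whose lengths favour ~1 kb with a tail to 10 kb;
* planted *differential* sites per exposure, elevated only in exposure
  samples by a configurable fold change;
* pooled replicate samples (default 2 groups x 3 pools) with
  negative-binomial replicate noise;
* fragments of 200-250 bp, the chromatin fragment size of the assay.

Rates are expected per-window *coverage* (fragments overlapping a window --
the quantity the pipeline's count matrix and the 150-read threshold see).
Each planted or background window draws a fragment count at one third of its
coverage rate with dispersion ``phi``, and every fragment is placed to span
exactly its home window plus both neighbours (length 200-250, position
jittered).  Summing the three adjacent draws gives window coverage with mean
equal to the declared rate, symmetric sub-window edge spill, and
replicate-to-replicate overdispersion ~ phi/3 (adjacent-window smoothing).
The intensity profile of a planted site is widened by one window on each
side so realized coverage plateaus across the whole truth interval; truth
boundaries are therefore recovered to within one window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import FragmentSet, GenomeLayout, WindowTiling, make_windows
from .sites import SiteSet

__all__ = [
    "SimulationSpec",
    "TruthSet",
    "simulate_truth",
    "simulate_fragments",
    "simulate_individuals",
    "write_truth",
    "read_truth",
    "coverage_rate_profile",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Generator parameters; the defaults are the study conditions.

    Rates are expected fragments per 100 bp window (coverage).  ``phi`` is
    the NB dispersion of the per-window fragment draws (variance =
    mu + phi * mu^2).  ``control_mode`` selects what differential sites look
    like in controls: "background" (exposure-gained sites; exposure mean =
    background_rate * fold_change) or "reduced" (retention in both lineages,
    control mean = retained_rate / fold_change, exposure = retained_rate).
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    window_size: int = 100
    n_core_sites: int = 50
    n_differential_sites: int = 20
    fold_change: float = 4.0
    background_rate: float = 30.0
    retained_rate: float = 250.0
    phi: float = 0.05
    fragment_length: tuple[int, int] = (200, 250)
    n_replicates: int = 3
    control_group: str = "control"
    exposure_groups: tuple[str, ...] = ("exposure",)
    control_mode: str = "background"
    # site length law: lognormal around 1 kb, clipped to [min, max], whole windows
    length_log_mean: float = math.log(1000.0)
    length_log_sigma: float = 0.6
    min_site_length: int = 300
    max_site_length: int = 10_000
    min_site_separation: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0 or self.retained_rate <= 0:
            raise ValueError("rates must be positive")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        lo, hi = self.fragment_length
        if not (self.window_size + 2 <= lo <= hi <= 3 * self.window_size - 2):
            raise ValueError(
                "fragment lengths must lie between window_size + 2 and 3 * window_size - 2"
            )
        if self.n_core_sites < 0 or self.n_differential_sites < 0:
            raise ValueError("site counts must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per group")
        if self.control_mode not in ("background", "reduced"):
            raise ValueError("control_mode must be 'background' or 'reduced'")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict(dict(self.chrom_lengths))

    @property
    def groups(self) -> tuple[str, ...]:
        return (self.control_group, *self.exposure_groups)

    def sample_ids(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs in deterministic order."""
        return [
            (f"{g}_{r + 1}", g)
            for g in self.groups
            for r in range(self.n_replicates)
        ]


@dataclass
class TruthSet:
    """Planted sites: one core set plus one differential set per exposure."""

    core: SiteSet
    differential: dict[str, SiteSet]
    spec: SimulationSpec

    def all_planted(self) -> pd.DataFrame:
        frames = [self.core.sites.assign(kind="core")]
        frames += [s.sites.assign(kind=f"differential:{g}") for g, s in self.differential.items()]
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

def sample_site_lengths(rng: np.random.Generator, spec: SimulationSpec, n: int) -> np.ndarray:
    """Draw site lengths (bp, whole windows) from the declared mixture law."""
    raw = rng.lognormal(spec.length_log_mean, spec.length_log_sigma, size=n)
    raw = np.clip(raw, spec.min_site_length, spec.max_site_length)
    w = spec.window_size
    return (np.round(raw / w).astype(np.int64) * w).clip(w, (spec.max_site_length // w) * w)


def _place_sites(
    rng: np.random.Generator,
    spec: SimulationSpec,
    lengths: np.ndarray,
    occupied: list[tuple[int, int, int]],
) -> list[tuple[str, int, int]]:
    """Place sites uniformly, window-aligned, respecting the separation buffer.

    ``occupied`` holds (chrom_index, start, end) of already-placed sites and
    is updated in place.  Raises when the genome is too small.
    """
    names = list(spec.layout.names)
    chrom_lengths = list(spec.layout.lengths)
    w = spec.window_size
    buffer = spec.min_site_separation
    placed: list[tuple[str, int, int]] = []
    weights = np.array(chrom_lengths, dtype=float)
    weights /= weights.sum()
    for length in lengths:
        for attempt in range(10_000):
            ci = int(rng.choice(len(names), p=weights))
            limit = chrom_lengths[ci] - int(length) - buffer
            if limit <= buffer:
                continue
            start = (int(rng.integers(buffer, limit)) // w) * w
            end = start + int(length)
            clash = any(
                c == ci and start - buffer < oe and os < end + buffer
                for c, os, oe in occupied
            )
            if not clash:
                occupied.append((ci, start, end))
                placed.append((names[ci], start, end))
                break
        else:
            raise ValueError("genome too small to place requested sites without overlap")
    return placed


def simulate_truth(spec: SimulationSpec) -> TruthSet:
    """Draw planted core and differential sites; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    occupied: list[tuple[int, int, int]] = []
    core_lengths = sample_site_lengths(rng, spec, spec.n_core_sites)
    core = SiteSet.from_intervals(
        "core", _place_sites(rng, spec, core_lengths, occupied), provenance="truth"
    )
    differential: dict[str, SiteSet] = {}
    for g in spec.exposure_groups:
        lengths = sample_site_lengths(rng, spec, spec.n_differential_sites)
        differential[g] = SiteSet.from_intervals(
            "differential", _place_sites(rng, spec, lengths, occupied), provenance=f"truth:{g}"
        )
    return TruthSet(core, differential, spec)


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------

def coverage_rate_profile(
    truth: TruthSet, spec: SimulationSpec, group: str, tiling: WindowTiling | None = None
) -> np.ndarray:
    """Expected per-window coverage for samples of ``group``.

    Background everywhere, ``retained_rate`` across core sites, and the
    group-dependent differential rate across that exposure's sites.  Planted
    intervals are dilated by one window per side (edge compensation).
    """
    if tiling is None:
        tiling = make_windows(spec.layout, spec.window_size)
    rate = np.full(tiling.n_windows, spec.background_rate, dtype=float)

    def paint(sites: SiteSet, value: float) -> None:
        w = spec.window_size
        for _, row in sites.sites.iterrows():
            chrom = row["chrom"]
            start = max(0, int(row["start"]) - w)
            end = min(spec.layout.length_of(chrom), int(row["end"]) + w)
            rate[tiling.windows_overlapping(chrom, start, end)] = value

    paint(truth.core, spec.retained_rate)
    if spec.control_mode == "background":
        diff_control = spec.background_rate
        diff_exposure = spec.background_rate * spec.fold_change
    else:
        diff_control = spec.retained_rate / spec.fold_change
        diff_exposure = spec.retained_rate
    for g, sites in truth.differential.items():
        paint(sites, diff_exposure if g == group else diff_control)
    return rate


def _materialize_fragments(
    rng: np.random.Generator,
    tiling: WindowTiling,
    rate: np.ndarray,
    spec: SimulationSpec,
    sample_id: str,
) -> FragmentSet:
    """Draw per-window fragment counts and lay out the fragments.

    Each window draws ``NB(rate/3, phi)`` fragments; a fragment homed at
    window [w0, w0+100) has length L ~ U{200..250} and start
    w0 - s_off with s_off ~ U{L-199..99}, so it covers exactly the home
    window and its two neighbours (clipped at chromosome ends).
    """
    w = tiling.window_size
    lo, hi = spec.fragment_length
    nu = rate / 3.0
    if spec.phi > 0:
        r = 1.0 / spec.phi
        counts = rng.negative_binomial(r, r / (r + nu))
    else:
        counts = rng.poisson(nu)
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for ci, chrom in enumerate(tiling.layout.names):
        sl = tiling.chrom_slice(chrom)
        c = counts[sl]
        total = int(c.sum())
        if total == 0:
            continue
        home = np.repeat(tiling.starts(chrom), c)
        length = rng.integers(lo, hi + 1, size=total)
        # left spill s_off and right spill L - w - s_off both stay within
        # [1, w-1], so exactly the home window and its two neighbours are hit
        base = np.maximum(1, length - (2 * w - 1))
        top = np.minimum(w - 1, length - w - 1)
        s_off = rng.integers(base, top + 1)
        frag_start = home - s_off
        frag_end = frag_start + length
        clen = tiling.layout.lengths[ci]
        np.clip(frag_start, 0, None, out=frag_start)
        np.clip(frag_end, None, clen, out=frag_end)
        keep = frag_end > frag_start
        chroms.append(np.full(int(keep.sum()), chrom, dtype=object))
        starts.append(frag_start[keep])
        ends.append(frag_end[keep])
    if not chroms:
        return FragmentSet(sample_id, np.empty(0, object), np.empty(0, np.int64), np.empty(0, np.int64))
    return FragmentSet(
        sample_id,
        np.concatenate(chroms),
        np.concatenate(starts),
        np.concatenate(ends),
    )


def simulate_fragments(truth: TruthSet, spec: SimulationSpec | None = None) -> dict[str, FragmentSet]:
    """One FragmentSet per sample (groups x replicates), deterministic.

    A single seeded generator stream drives all draws; samples are generated
    in the fixed order of ``spec.sample_ids()``.
    """
    spec = truth.spec if spec is None else spec
    tiling = make_windows(spec.layout, spec.window_size)
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from truth placement
    rates = {g: coverage_rate_profile(truth, spec, g, tiling) for g in spec.groups}
    out: dict[str, FragmentSet] = {}
    for sample_id, group in spec.sample_ids():
        out[sample_id] = _materialize_fragments(rng, tiling, rates[group], spec, sample_id)
    return out


def simulate_individuals(
    truth: TruthSet, n_individuals: int = 5, spec: SimulationSpec | None = None
) -> dict[str, FragmentSet]:
    """Independent control-lineage individuals drawn from one truth.

    Emulates the biological-variation trial: several animals sharing the same
    underlying retention landscape, each sequenced separately.
    """
    spec = truth.spec if spec is None else spec
    tiling = make_windows(spec.layout, spec.window_size)
    rng = np.random.default_rng(spec.seed + 2)
    rate = coverage_rate_profile(truth, spec, spec.control_group, tiling)
    return {
        f"individual_{i + 1}": _materialize_fragments(rng, tiling, rate, spec, f"individual_{i + 1}")
        for i in range(n_individuals)
    }


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write truth BEDs (one per category); round-trips losslessly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"core": outdir / "truth_core.bed"}
    truth.core.to_bed(paths["core"])
    for g, sites in truth.differential.items():
        p = outdir / f"truth_differential_{g}.bed"
        sites.to_bed(p)
        paths[f"differential:{g}"] = p
    return paths


def read_truth(outdir: str | Path, spec: SimulationSpec) -> TruthSet:
    outdir = Path(outdir)
    core = SiteSet.from_bed(outdir / "truth_core.bed", kind="core", provenance="truth")
    differential = {}
    for g in spec.exposure_groups:
        differential[g] = SiteSet.from_bed(
            outdir / f"truth_differential_{g}.bed", kind="differential", provenance=f"truth:{g}"
        )
    return TruthSet(core, differential, spec)
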
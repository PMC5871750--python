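"""Shared fixtures: small genomes, and one default-scale simulation reused
across the recovery tests (expensive, session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from dhrcall import (
    AnalysisParams,
    GenomeLayout,
    SimulationSpec,
    WindowCountMatrix,
    build_count_matrix,
    make_windows,
    run_differential,
    simulate_fragments,
    simulate_truth,
)
from dhrcall.genome import SampleInfo


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (2_000, 1_250))


def make_matrix(counts: np.ndarray, groups: list[str], window_size: int = 100) -> WindowCountMatrix:
    """Count matrix over a single synthetic chromosome sized to fit."""
    n = counts.shape[0]
    tiling = make_windows(GenomeLayout(("chrT",), (n * window_size,)), window_size)
    samples = tuple(SampleInfo(f"s{i}", g) for i, g in enumerate(groups))
    return WindowCountMatrix(tiling, samples, np.asarray(counts, dtype=np.int64))


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    return SimulationSpec(seed=20_260_927)


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return simulate_truth(default_spec)


@pytest.fixture(scope="session")
def default_fragments(default_truth):
    return simulate_fragments(default_truth)


@pytest.fixture(scope="session")
def default_matrix(default_spec, default_fragments) -> WindowCountMatrix:
    tiling = make_windows(default_spec.layout, default_spec.window_size)
    groups = dict(default_spec.sample_ids())
    return build_count_matrix(tiling, list(default_fragments.values()), groups)


@pytest.fixture(scope="session")
def default_differential(default_matrix):
    return run_differential(default_matrix)


@pytest.fixture(scope="session")
def default_params() -> AnalysisParams:
    # the vinclozolin-style seed cutoff; depth 150 as in the primary analysis
    return AnalysisParams(dhr_p_threshold=1e-6)
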
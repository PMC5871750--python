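"""Per-window differential coverage testing between two sample groups.

The test is a conditional negative-binomial exact test with a single common
dispersion, in the style of the classic two-group exact test for sequencing
count data:

1. every sample is scaled to a common effective library size,
2. scaled counts are summed within each group and rounded to integers,
3. conditional on the grand total ``n``, the group-A total follows a
   distribution proportional to ``C(k + r_a - 1, k) * C(n - k + r_b - 1, n - k)``
   where ``r_g = w_g / phi`` and ``w_g`` is the group's summed effective size
   in common-library units (for ``phi = 0`` this degenerates to
   ``Binomial(n, w_a / (w_a + w_b))``),
4. the two-sided p-value is the total probability of all outcomes whose
   probability is less than or equal to that of the observed outcome
   (minimum-likelihood rule).

The common dispersion ``phi`` (variance = mu + phi * mu^2) is estimated by
maximizing the summed conditional NB log-likelihood over windows, on counts
scaled to a common library size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .genome import WindowCountMatrix, WindowTiling

__all__ = [
    "NormalizationFactors",
    "DifferentialResult",
    "normalize_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_pvalue",
    "exact_test_window",
    "run_differential",
]

# Outcomes with probability <= p_obs * (1 + TIE_REL) count as "as or less
# likely"; guards against float noise splitting exact ties.
TIE_REL = 1e-7

# Grand totals above this are enumerated only over the central
# 1 - ~1e-13 of the conditional distribution (bounded runtime).
TRUNCATE_ABOVE = 100_000


NormalizationFactors = Mapping[str, float]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_library_sizes(
    matrix: WindowCountMatrix,
    mode: str = "total",
    trim: float = 0.3,
) -> dict[str, float]:
    """Effective library size per sample.

    ``total`` (default): the total fragment count of the sample.
    ``trimmed-mean``: total count times a trimmed mean of per-window count
    ratios against a reference sample (the sample whose total is closest to
    the median total), computed over windows positive in both samples with
    the top and bottom ``trim`` fraction of ratios discarded.  This damps the
    influence of a few extreme windows on the effective size.
    """
    if mode not in ("total", "trimmed-mean"):
        raise ValueError("mode must be 'total' or 'trimmed-mean'")
    totals = matrix.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = matrix.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    if mode == "total":
        return dict(zip(matrix.sample_ids, totals))
    ref = int(np.argmin(np.abs(totals - np.median(totals))))
    ref_cpm = matrix.counts[:, ref] / totals[ref]
    factors: dict[str, float] = {}
    for j, sid in enumerate(matrix.sample_ids):
        if j == ref:
            factors[sid] = float(totals[j])
            continue
        cpm = matrix.counts[:, j] / totals[j]
        ok = (cpm > 0) & (ref_cpm > 0)
        if not ok.any():
            factors[sid] = float(totals[j])
            continue
        ratios = np.sort(cpm[ok] / ref_cpm[ok])
        lo = int(np.floor(trim * len(ratios)))
        hi = len(ratios) - lo
        factors[sid] = float(totals[j] * ratios[lo:hi].mean())
    return factors


def _common_size(factors: Mapping[str, float]) -> float:
    vals = np.array(list(factors.values()), dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("effective library sizes must be positive and finite")
    return float(np.exp(np.mean(np.log(vals))))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# Common dispersion (conditional likelihood)
# ---------------------------------------------------------------------------

def _group_conditional_loglik(pseudo: np.ndarray, phi: float) -> float:
    """Summed NB conditional log-likelihood of one group's pseudo-counts.

    ``pseudo``: (windows, samples) integer counts scaled to a common library
    size.  The likelihood of the counts conditional on their row sum is free
    of the mean parameter; only ``phi`` remains.
    """
    y = pseudo.astype(float)
    m = y.shape[1]
    z = y.sum(axis=1)
    if phi <= 0:
        # Poisson limit: symmetric multinomial
        return float(np.sum(gammaln(z + 1) - gammaln(y + 1).sum(axis=1) - z * np.log(m)))
    r = 1.0 / phi
    ll = (
        gammaln(y + r).sum(axis=1)
        - m * gammaln(r)
        + gammaln(m * r)
        - gammaln(z + m * r)
        + gammaln(z + 1)
        - gammaln(y + 1).sum(axis=1)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    matrix: WindowCountMatrix,
    factors: NormalizationFactors | None = None,
    grid_max: float = 2.0,
    tol: float = 1e-4,
    max_windows: int = 200_000,
) -> float:
    """Estimate a single NB dispersion shared by all windows.

    Samples are scaled to a common library size; the conditional
    log-likelihood of each group's counts given their sum is summed over
    windows and maximized over ``phi`` in [0, grid_max] (coarse grid, then
    bounded refinement to ``tol``).  Requires at least one group with >= 2
    samples.  With many windows a deterministic even stride of at most
    ``max_windows`` windows is used.
    """
    if factors is None:
        factors = normalize_library_sizes(matrix)
    groups = {}
    for j, s in enumerate(matrix.samples):
        groups.setdefault(s.group, []).append(j)
    usable = {g: idx for g, idx in groups.items() if len(idx) >= 2}
    if not usable:
        raise ValueError(
            "common dispersion needs >= 2 samples in at least one group; "
            "supply phi explicitly"
        )
    common = _common_size(factors)
    scale = np.array([common / factors[s.sample_id] for s in matrix.samples])
    pseudo = _round_half_up(matrix.counts * scale[None, :])
    keep = pseudo.sum(axis=1) > 0  # all-zero windows contribute a constant
    pseudo = pseudo[keep]
    if pseudo.shape[0] > max_windows:
        stride = int(np.ceil(pseudo.shape[0] / max_windows))
        pseudo = pseudo[::stride]
    mats = [pseudo[:, idx] for idx in usable.values()]

    def negll(phi: float) -> float:
        return -sum(_group_conditional_loglik(m, phi) for m in mats)

    grid = np.concatenate([[0.0], np.geomspace(1e-4, grid_max, 25)])
    vals = [negll(p) for p in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(negll, bounds=(lo, hi), method="bounded", options={"xatol": tol})
        best_phi, best_val = float(res.x), float(res.fun)
    else:
        best_phi, best_val = float(grid[i]), vals[i]
    if vals[0] <= best_val:  # Poisson boundary wins
        return 0.0
    return max(best_phi, 0.0) if best_phi > tol else 0.0


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _conditional_logpmf(k: np.ndarray, n: int, w_a: float, w_b: float, phi: float) -> np.ndarray:
    """Unnormalized log pmf of the group-A total at outcomes ``k``."""
    k = np.asarray(k, dtype=float)
    if phi == 0.0:
        p_a = w_a / (w_a + w_b)
        return (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + k * np.log(p_a)
            + (n - k) * np.log1p(-p_a)
        )
    r_a = w_a / phi
    r_b = w_b / phi
    return (
        gammaln(k + r_a)
        - gammaln(k + 1)
        - gammaln(r_a)
        + gammaln(n - k + r_b)
        - gammaln(n - k + 1)
        - gammaln(r_b)
    )


def _support(n: int, w_a: float, w_b: float, phi: float) -> np.ndarray:
    """Outcome range to enumerate; full 0..n unless n is very large."""
    if n <= TRUNCATE_ABOVE:
        return np.arange(n + 1)
    p_a = w_a / (w_a + w_b)
    mean = n * p_a
    # conditional variance bounded above by the unconditional NB variance scale
    sd = np.sqrt(max(mean * (1 - p_a) * (1 + phi * mean / max(w_a, 1e-12)), 1.0))
    lo = max(0, int(mean - 60 * sd))
    hi = min(n, int(mean + 60 * sd))
    return np.arange(lo, hi + 1)


def _pvalue_vector(n: int, w_a: float, w_b: float, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pmf over the enumerated support and the p-value for each k.

    p(k) = 1 - sum of probabilities strictly greater than p(k); outcomes
    outside the enumerated support carry negligible mass and are implicitly
    counted as "as or less likely".
    """
    support = _support(n, w_a, w_b, phi)
    logpmf = _conditional_logpmf(support, n, w_a, w_b, phi)
    pmf = np.exp(logpmf - logsumexp(logpmf))
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # rank of the largest sorted pmf still <= pmf_k * (1 + TIE_REL)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + TIE_REL), side="right")
    pvals = np.where(idx > 0, cum[np.minimum(idx, len(cum)) - 1], 0.0)
    # include mass outside the enumerated support (always less likely)
    pvals += max(0.0, 1.0 - float(cum[-1]))
    np.clip(pvals, 0.0, 1.0, out=pvals)
    return support, pvals


class _PvalueCache:
    """Memoizes the per-total p-value vectors for fixed (w_a, w_b, phi)."""

    def __init__(self, w_a: float, w_b: float, phi: float):
        if phi < 0:
            raise ValueError("phi must be >= 0")
        if w_a <= 0 or w_b <= 0:
            raise ValueError("group effective sizes must be positive")
        self.w_a = float(w_a)
        self.w_b = float(w_b)
        self.phi = float(phi)
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def pvalue(self, k_a: int, k_b: int) -> float:
        if k_a < 0 or k_b < 0:
            raise ValueError("counts must be non-negative")
        n = k_a + k_b
        if n == 0:
            return 1.0
        if n not in self._cache:
            self._cache[n] = _pvalue_vector(n, self.w_a, self.w_b, self.phi)
        support, pvals = self._cache[n]
        pos = int(np.searchsorted(support, k_a))
        if pos >= len(support) or support[pos] != k_a:
            # observed outcome outside the enumerated bulk: everything in the
            # bulk is more likely, so only the ~1e-13 tail mass remains
            return 0.0
        return float(pvals[pos])


def nb_exact_pvalue(k_a: int, k_b: int, w_a: float, w_b: float, phi: float) -> float:
    """Two-sided conditional NB exact p-value for grouped totals.

    ``k_a``/``k_b`` are the group totals (integer, in common-library units),
    ``w_a``/``w_b`` the groups' summed effective sizes in the same units, and
    ``phi`` the common dispersion (0 = Poisson/binomial limit).
    """
    return _PvalueCache(w_a, w_b, phi).pvalue(int(k_a), int(k_b))


def exact_test_window(
    counts_control: Sequence[int],
    counts_exposure: Sequence[int],
    factors_control: Sequence[float],
    factors_exposure: Sequence[float],
    phi: float,
) -> float:
    """Exact-test p-value for one window given per-sample counts and sizes."""
    cc = np.asarray(counts_control, dtype=np.int64)
    ce = np.asarray(counts_exposure, dtype=np.int64)
    if len(cc) == 0 or len(ce) == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(cc < 0) or np.any(ce < 0):
        raise ValueError("counts must be non-negative")
    fc = np.asarray(factors_control, dtype=float)
    fe = np.asarray(factors_exposure, dtype=float)
    common = float(np.exp(np.mean(np.log(np.concatenate([fc, fe])))))
    k_a = int(_round_half_up(np.array([(cc * (common / fc)).sum()]))[0])
    k_b = int(_round_half_up(np.array([(ce * (common / fe)).sum()]))[0])
    return nb_exact_pvalue(k_a, k_b, float(len(cc)), float(len(ce)), phi)


# ---------------------------------------------------------------------------
# Full differential run
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-window differential coverage result, aligned with the tiling."""

    tiling: WindowTiling
    control_group: str
    exposure_group: str
    p_value: np.ndarray
    log2fc: np.ndarray  # exposure vs control; +/-inf when one group all-zero
    mean_norm_control: np.ndarray
    mean_norm_exposure: np.ndarray
    phi: float

    def __post_init__(self) -> None:
        n = self.tiling.n_windows
        for arr in (self.p_value, self.log2fc, self.mean_norm_control, self.mean_norm_exposure):
            if len(arr) != n:
                raise ValueError("result arrays must have one entry per window")
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        df = self.tiling.to_dataframe()
        df["p_value"] = self.p_value
        df["log2fc"] = self.log2fc
        df["mean_norm_control"] = self.mean_norm_control
        df["mean_norm_exposure"] = self.mean_norm_exposure
        return df

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        buf = io.StringIO()
        if header_comment:
            buf.write(f"# {header_comment}\n")
        self.to_dataframe().to_csv(buf, sep="\t", index=False)
        Path(path).write_text(buf.getvalue())


def run_differential(
    matrix: WindowCountMatrix,
    control_group: str = "control",
    exposure_group: str = "exposure",
    phi: float | None = None,
    normalization: str = "total",
    min_total_count: int = 0,
) -> DifferentialResult:
    """Run the windowed exact test over the whole count matrix.

    Normalizes library sizes, estimates the common dispersion unless ``phi``
    is supplied, and computes one two-sided p-value per window.  Windows with
    grand (pseudo-count) total below ``min_total_count`` -- including all-zero
    windows -- receive p = 1 so window indices stay aligned with the tiling.
    """
    groups = set(matrix.groups)
    for g in (control_group, exposure_group):
        if g not in groups:
            raise KeyError(f"group {g!r} absent from matrix")
    factors = normalize_library_sizes(matrix, mode=normalization)
    if phi is None:
        phi = estimate_common_dispersion(matrix, factors)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    common = _common_size(factors)
    idx_c = [j for j, s in enumerate(matrix.samples) if s.group == control_group]
    idx_e = [j for j, s in enumerate(matrix.samples) if s.group == exposure_group]
    scale = np.array([common / factors[s.sample_id] for s in matrix.samples])
    pseudo = _round_half_up(matrix.counts * scale[None, :])
    k_a = pseudo[:, idx_c].sum(axis=1)
    k_b = pseudo[:, idx_e].sum(axis=1)
    n = k_a + k_b
    cache = _PvalueCache(float(len(idx_c)), float(len(idx_e)), float(phi))
    pvals = np.ones(matrix.tiling.n_windows)
    threshold = max(int(min_total_count), 1)
    for total in np.unique(n):
        if total < threshold:
            continue
        sel = n == total
        sub_k = k_a[sel]
        support, pv = cache._cache.setdefault(
            int(total), _pvalue_vector(int(total), cache.w_a, cache.w_b, cache.phi)
        )
        pos = np.searchsorted(support, sub_k)
        inside = (pos < len(support)) & (support[np.minimum(pos, len(support) - 1)] == sub_k)
        out = np.zeros(sel.sum())
        out[inside] = pv[pos[inside]]
        out[~inside] = 0.0  # far outside the enumerated bulk: p ~ tail mass
        pvals[sel] = out

    mean_c = (matrix.counts[:, idx_c] * scale[idx_c][None, :]).mean(axis=1)
    mean_e = (matrix.counts[:, idx_e] * scale[idx_e][None, :]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_e) - np.log2(mean_c)
    log2fc = np.where((mean_c == 0) & (mean_e == 0), 0.0, log2fc)
    return DifferentialResult(
        matrix.tiling,
        control_group,
        exposure_group,
        pvals,
        log2fc,
        mean_c,
        mean_e,
        float(phi),
    )
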
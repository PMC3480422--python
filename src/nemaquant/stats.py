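"""Seasonal-survey analytics: trends, dispersion, site comparisons, Mantel.

These are the statistics used to compare nematode assemblages between an
open-canopy field and a closed-canopy forest over a season: two-period
moving-average trend lines, coefficients of variation of total density,
Mann-Whitney U comparisons per taxon/guild, Welch t on log-transformed
totals, and (partial) Mantel permutation tests between community distance
matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# trends and dispersion


def moving_average(
    values: Sequence[float], window: int = 2, alignment: str = "shifted"
) -> np.ndarray:
    """Moving-average trend of a seasonal series.

    The default "shifted" alignment follows the survey-plot convention: the
    value plotted at position i is the mean of raw points i+1 .. i+window
    (1-based: points 2 and 3 are portrayed at position 1, and so forth), so
    the first raw point never enters the trend and the output has
    ``len(values) - window`` elements. At the boundary ``window ==
    len(values)`` a single truncated element — the mean of points 2..n — is
    returned. ``alignment="trailing"`` gives the conventional trailing
    moving average of length ``n - window + 1``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if alignment == "trailing":
        kernel = np.full(window, 1.0 / window)
        return np.convolve(x, kernel, mode="valid")
    if alignment != "shifted":
        raise ValueError(f"unknown alignment {alignment!r}")
    if window == n:
        return np.array([x[1:].mean()])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(x[1:], kernel, mode="valid")


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV as a percentage, reported to one decimal."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    return round(100.0 * sd / mean, 1)


# ---------------------------------------------------------------------------
# two-sample comparisons


@dataclass(frozen=True)
class MWUResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided
    method: str  # "exact" | "normal-approx-tie-corrected"


def compare_sites_mwu(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 12
) -> MWUResult:
    """Independent two-sided Mann-Whitney U test between two sites.

    Exact enumeration when the combined sample is small (n+m <= 12) and
    tie-free; otherwise the tie-corrected normal approximation (without
    continuity correction, so identical samples give p = 1). The method
    actually used is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (x.size + y.size) <= exact_limit and not has_ties
    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MWUResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return MWUResult(
        u=float(res.statistic),
        p=float(res.pvalue),
        method="normal-approx-tie-corrected",
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def compare_log_totals(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch t-test (unequal variances) on log10-transformed totals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("totals must be positive for the log transform")
    lx, ly = np.log10(x), np.log10(y)
    res = sps.ttest_ind(lx, ly, equal_var=False)
    vx, vy = lx.var(ddof=1) / lx.size, ly.var(ddof=1) / ly.size
    if vx + vy == 0:
        df = float(lx.size + ly.size - 2)
        return WelchResult(t=0.0, df=df, p=1.0)
    df = (vx + vy) ** 2 / (
        vx**2 / (lx.size - 1) + vy**2 / (ly.size - 1)
    )
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Mantel tests


@dataclass(frozen=True)
class MantelResult:
    z_observed: float
    r_observed: float
    z_random_mean: float
    p: float
    n_permutations: int
    partial: bool
    seed: int | None = None
    method: str = "random"  # "random" | "exhaustive"


def _check_distance_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return m


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _residual_matrix(m: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Elementwise OLS residuals of one distance matrix on another."""
    n = m.shape[0]
    mask = _offdiag_mask(n)
    a, b = np.polyfit(control[mask], m[mask], 1)
    resid = np.zeros_like(m)
    resid[mask] = m[mask] - (a * control[mask] + b)
    return resid


def mantel_test(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray | None = None,
    n_permutations: int | str = 9999,
    seed: int | None = None,
) -> MantelResult:
    """(Partial) Mantel permutation test between distance matrices.

    The statistic is the classic Mantel Z — the sum of elementwise products
    of the off-diagonal entries — with the normalized correlation r also
    reported. With a control matrix ``Z`` the partial form correlates the
    residuals of X|Z and Y|Z. The null distribution permutes rows and
    columns of X simultaneously; ``n_permutations="all"`` enumerates every
    non-identity permutation (feasible for small matrices). The one-tailed
    p-value uses the add-one convention, (#{Z_perm >= Z_obs} + 1) /
    (n_permutations + 1), so it can never be 0.
    """
    X = _check_distance_matrix(X, "X")
    Y = _check_distance_matrix(Y, "Y")
    if X.shape != Y.shape:
        raise ValueError("X and Y must have matching dimensions")
    n = X.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 entities")
    partial = Z is not None
    if partial:
        Z = _check_distance_matrix(Z, "Z")
        if Z.shape != X.shape:
            raise ValueError("control matrix must match X and Y")
        X = _residual_matrix(X, Z)
        Y = _residual_matrix(Y, Z)

    mask = _offdiag_mask(n)

    def zstat(xm: np.ndarray) -> float:
        return float((xm[mask] * Y[mask]).sum())

    z_obs = zstat(X)
    r_obs = float(np.corrcoef(X[mask], Y[mask])[0, 1])

    if n_permutations == "all":
        perms = [
            np.array(p)
            for p in itertools.permutations(range(n))
            if p != tuple(range(n))
        ]
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_permutations))]
        method = "random"
    z_perm = np.array([zstat(X[np.ix_(p, p)]) for p in perms])
    n_perm = len(perms)
    p = (float((z_perm >= z_obs - 1e-12).sum()) + 1.0) / (n_perm + 1.0)
    return MantelResult(
        z_observed=z_obs,
        r_observed=r_obs,
        z_random_mean=float(z_perm.mean()),
        p=p,
        n_permutations=n_perm,
        partial=partial,
        seed=seed,
        method=method,
    )


def squared_euclidean_distances(profiles: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance matrix between rows (entities)."""
    profiles = np.asarray(profiles, dtype=float)
    diff = profiles[:, None, :] - profiles[None, :, :]
    return (diff**2).sum(axis=-1)


# ---------------------------------------------------------------------------
# environmental covariates


def covariate_window_sum(
    daily_values: Mapping[int, float] | "object",
    sampling_day: int,
    window_days: int = 21,
) -> float:
    """Sum a daily covariate over the window strictly before a sampling day.

    E.g. cumulative rainfall over the latest 21 days before sampling: days
    ``sampling_day - window_days .. sampling_day - 1``. Every day in the
    window must be present.
    """
    try:  # pandas Series support without importing pandas up front
        getter = daily_values.get  # Mapping or Series both expose .get
    except AttributeError as exc:
        raise TypeError("daily_values must be a mapping or Series") from exc
    days = range(sampling_day - window_days, sampling_day)
    total = 0.0
    missing = []
    for d in days:
        v = getter(d)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            missing.append(d)
        else:
            total += float(v)
    if missing:
        raise ValueError(f"daily series incomplete over the window: days {missing}")
    return total
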
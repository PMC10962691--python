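"""Driver-response time-lag analysis and permutation ANOVA.

Soil respiration tracks its diel drivers (PAR, soil temperature, soil water
content) with delays set by how fast photosynthate moves belowground.  The
lag between a driver and a response series is found by scanning stepwise time
shifts on the measurement-cycle grid (2.4 h steps spanning +/-20 h): at each
shift both series are z-scored over their overlap and the response is
regressed on the shifted driver; the standardized coefficient (the Pearson
correlation in the univariate case) traces a curve over shifts whose maximum
marks the most probable lag.  Negative shifts mean the driver leads the
response; ties break toward zero shift.

Treatment effects on the per-plot best lags are tested with a permutational
one-way ANOVA: the F statistic of the observed grouping is referred to the
distribution obtained by permuting group labels, exhaustively when the number
of distinct assignments is small, otherwise by seeded Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from ._errors import DesignError, InsufficientOverlapError

#: Measurement-cycle step of the lag grid, hours.
LAG_STEP_H = 2.4
#: Half-span of the lag grid, hours (shifts run over multiples of the step
#: within +/- this span: -19.2 ... +19.2 h at the 2.4 h step).
LAG_SPAN_H = 20.0
#: Minimum number of overlapping bins after the maximal shift.
MIN_OVERLAP_BINS = 20


@dataclass(frozen=True)
class LagScan:
    """Standardized coefficient vs imposed shift, with the best lag.

    ``shifts`` (hours) are symmetric about zero; negative = driver leads.
    """

    shifts: np.ndarray
    coefficients: np.ndarray
    best_lag: float
    best_coefficient: float
    mode: str = "signed"


@dataclass(frozen=True)
class PermTestResult:
    """Permutation one-way ANOVA outcome."""

    f_observed: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: Optional[int] = None


def default_shift_grid(step_h: float = LAG_STEP_H, span_h: float = LAG_SPAN_H) -> np.ndarray:
    """Symmetric shift grid: multiples of ``step_h`` within +/- ``span_h``."""
    k = int(np.floor(span_h / step_h + 1e-9))
    return np.arange(-k, k + 1) * step_h


def bin_series(times_h, values, step_h: float = LAG_STEP_H):
    """Average an (irregular) series onto the measurement-cycle grid.

    Returns ``(bin_centers_h, bin_means)`` for the contiguous range of bins
    between the first and last observation; bins with no data are NaN (they
    are dropped pairwise during the scan).
    """
    times_h = np.asarray(times_h, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_h.size != values.size:
        raise ValueError("times and values must have equal length")
    # epsilon guards samples sitting numerically on a bin boundary
    idx = np.floor(times_h / step_h + 1e-9).astype(int)
    lo, hi = idx.min(), idx.max()
    n = hi - lo + 1
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, idx - lo, values)
    np.add.at(counts, idx - lo, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(lo, hi + 1) + 0.5) * step_h
    return centers, means


def _std_coefficient(resp: np.ndarray, drv: np.ndarray) -> float:
    """Standardized univariate regression coefficient (= Pearson r)."""
    ok = np.isfinite(resp) & np.isfinite(drv)
    r, d = resp[ok], drv[ok]
    if r.size < 3:
        return float("nan")
    rs, ds = np.std(r), np.std(d)
    if rs == 0.0 or ds == 0.0:
        return float("nan")
    return float(np.mean((r - r.mean()) / rs * (d - d.mean()) / ds))


def _remove_diel_trend(values: np.ndarray, step_h: float) -> np.ndarray:
    """Subtract a centered one-day moving mean (slow trend) from a binned series.

    The same linear filter is applied to response and driver, so an exact
    integer-bin shift between them survives detrending exactly; bins whose
    window is incomplete become NaN and drop out of the scan.
    """
    import pandas as pd

    w = max(1, int(round(24.0 / step_h)))
    ma = pd.Series(values).rolling(w, center=True, min_periods=w).mean().to_numpy()
    return values - ma


def lag_scan(times_h, response, driver, step_h: float = LAG_STEP_H,
             span_h: float = LAG_SPAN_H, mode: str = "signed",
             prebinned: bool = False, detrend: Optional[str] = None,
             min_overlap: int = MIN_OVERLAP_BINS) -> LagScan:
    """Scan stepwise time shifts of a driver against a response series.

    At shift s the driver is displaced so that coefficient(s) correlates
    response(t) with driver(t + s); a maximum at negative s therefore means
    the driver's diel cycle runs ahead of the response.

    Parameters
    ----------
    times_h, response, driver : aligned series (hours; any sampling).
    step_h, span_h : shift grid (defaults: 2.4 h steps within +/-20 h).
    mode : "signed" picks the maximum signed coefficient (positive drivers);
        "absolute" picks the maximum |coefficient|.
    prebinned : set True when the series are already regular bin means on the
        ``step_h`` grid (skips re-binning).
    detrend : None, or "diel" to remove each series' one-day moving mean
        before scanning -- needed when a strong slow trend (e.g. a decaying
        tracer pulse) would otherwise mask the diel alignment.
    min_overlap : minimum overlapping bins at the extreme shift.
    """
    if prebinned:
        resp = np.asarray(response, dtype=float)
        drv = np.asarray(driver, dtype=float)
    else:
        _, resp = bin_series(times_h, response, step_h)
        _, drv = bin_series(times_h, driver, step_h)
    if detrend == "diel":
        resp = _remove_diel_trend(resp, step_h)
        drv = _remove_diel_trend(drv, step_h)
    elif detrend is not None:
        raise ValueError(f"unknown detrend mode {detrend!r}")
    shifts = default_shift_grid(step_h, span_h)
    kmax = int(round(shifts[-1] / step_h))
    n = resp.size
    if n - kmax < min_overlap:
        raise InsufficientOverlapError(
            f"only {max(n - kmax, 0)} overlapping bins at the extreme shift; "
            f"need >= {min_overlap}")

    coeffs = np.empty(shifts.size)
    for i, k in enumerate(range(-kmax, kmax + 1)):
        # driver shifted by k bins: compare response[j] with driver[j + k]
        if k >= 0:
            r, d = resp[: n - k], drv[k:]
        else:
            r, d = resp[-k:], drv[: n + k]
        coeffs[i] = _std_coefficient(r, d)

    score = np.abs(coeffs) if mode == "absolute" else coeffs
    finite = np.isfinite(score)
    if not np.any(finite):
        raise InsufficientOverlapError("no shift produced a defined coefficient")
    best_score = np.nanmax(score[finite])
    # ties (to numerical precision) break toward zero shift
    cand = np.where(finite & (score >= best_score - 1e-12))[0]
    best_i = cand[np.argmin(np.abs(shifts[cand]))]
    return LagScan(shifts=shifts, coefficients=coeffs,
                   best_lag=float(shifts[best_i]),
                   best_coefficient=float(coeffs[best_i]), mode=mode)


def lag_scan_multivariate(times_h, response, drivers: dict, scan_driver: str,
                          step_h: float = LAG_STEP_H, span_h: float = LAG_SPAN_H,
                          min_overlap: int = MIN_OVERLAP_BINS) -> LagScan:
    """Joint-regression variant: shift one driver, hold the others at lag 0.

    At each shift, the response is regressed on all z-scored drivers jointly
    and the coefficient of the scanned driver is recorded.  Magnitudes are no
    longer bounded by 1 when drivers are collinear.
    """
    _, resp = bin_series(times_h, response, step_h)
    binned = {name: bin_series(times_h, v, step_h)[1] for name, v in drivers.items()}
    if scan_driver not in binned:
        raise KeyError(f"scan_driver {scan_driver!r} not among drivers")
    shifts = default_shift_grid(step_h, span_h)
    kmax = int(round(shifts[-1] / step_h))
    n = resp.size
    if n - kmax < min_overlap:
        raise InsufficientOverlapError("insufficient overlap for the joint scan")

    def z(v):
        s = np.std(v)
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    coeffs = np.empty(shifts.size)
    for i, k in enumerate(range(-kmax, kmax + 1)):
        sl_r = slice(0, n - k) if k >= 0 else slice(-k, n)
        sl_d = slice(k, n) if k >= 0 else slice(0, n + k)
        cols, r = [], resp[sl_r]
        for name, v in binned.items():
            cols.append(v[sl_d] if name == scan_driver else v[sl_r])
        X = np.column_stack(cols)
        ok = np.isfinite(r) & np.all(np.isfinite(X), axis=1)
        if ok.sum() < len(binned) + 2:
            coeffs[i] = float("nan")
            continue
        Xz = np.column_stack([z(c[ok]) for c in X.T])
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(ok.sum()), Xz]), z(r[ok]), rcond=None)
        coeffs[i] = beta[1 + list(binned).index(scan_driver)]

    finite = np.isfinite(coeffs)
    best_score = np.nanmax(coeffs[finite])
    cand = np.where(finite & (coeffs >= best_score - 1e-12))[0]
    best_i = cand[np.argmin(np.abs(shifts[cand]))]
    return LagScan(shifts=shifts, coefficients=coeffs,
                   best_lag=float(shifts[best_i]),
                   best_coefficient=float(coeffs[best_i]), mode="multivariate")


# ---------------------------------------------------------------------------
# permutation ANOVA


@lru_cache(maxsize=32)
def _partitions(n: int, sizes: tuple) -> tuple:
    """All distinct assignments of n indices into ordered groups of given sizes.

    Returns a tuple of assignments; each assignment is a tuple of index tuples,
    one per group.  The count is the multinomial coefficient.
    """
    def rec(avail: tuple, sizes: tuple):
        if len(sizes) == 1:
            yield (avail,)
            return
        for first in combinations(avail, sizes[0]):
            rest = tuple(i for i in avail if i not in set(first))
            for tail in rec(rest, sizes[1:]):
                yield (first,) + tail
    return tuple(rec(tuple(range(n)), sizes))


@lru_cache(maxsize=32)
def _comb_index_array(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=int)


def n_distinct_assignments(sizes: Sequence[int]) -> int:
    """Multinomial count of distinct group assignments."""
    from math import factorial
    total = factorial(sum(sizes))
    for s in sizes:
        total //= factorial(s)
    return total


def _group_stats(values: np.ndarray, groups: list[np.ndarray]):
    """(F, between-group SS) for a one-way layout.

    Between-group SS is the permutation statistic: the total SS is invariant
    under label permutation, so ordering by SSB is ordering by F, and SSB
    stays defined when every group has a single observation (F would not).
    """
    grand = values.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = values.size - len(groups)
    if df_w > 0 and ssw > 0:
        f = (ssb / df_b) / (ssw / df_w)
    else:
        f = float("inf") if ssb > 0 else float("nan")
    return f, ssb


def permutation_anova(values, labels, n_perm: int = 9999,
                      seed: Optional[int] = None,
                      exhaustive_limit: int = 10000) -> PermTestResult:
    """One-way permutation ANOVA of ``values`` grouped by ``labels``.

    The p-value is the proportion of label assignments whose statistic is at
    least the observed one, the observed assignment included.  When the number
    of distinct assignments is at most ``exhaustive_limit`` the null is
    enumerated exactly; otherwise ``n_perm`` Monte-Carlo permutations are
    drawn with the given seed and p = (1 + #exceedances) / (1 + n_perm).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise DesignError("permutation ANOVA needs at least 2 groups")
    sizes = tuple(int((inv == g).sum()) for g in range(uniq.size))
    if min(sizes) < 1:
        raise DesignError("every group needs at least one observation")

    obs_groups = [values[inv == g] for g in range(uniq.size)]
    f_obs, ssb_obs = _group_stats(values, obs_groups)

    total = n_distinct_assignments(sizes)
    if total <= exhaustive_limit:
        if len(sizes) == 2:
            # vectorized: SSB is determined by the first group's sum
            n1, n = sizes[0], values.size
            idx = _comb_index_array(n, n1)
            s1 = values[idx].sum(axis=1)
            grand = values.mean()
            m1 = s1 / n1
            m2 = (values.sum() - s1) / sizes[1]
            ssb = n1 * (m1 - grand) ** 2 + sizes[1] * (m2 - grand) ** 2
            count = int(np.sum(ssb >= ssb_obs - 1e-12))
        else:
            count = 0
            for assignment in _partitions(values.size, sizes):
                groups = [values[np.asarray(ix, dtype=int)] for ix in assignment]
                _, ssb = _group_stats(values, groups)
                if ssb >= ssb_obs - 1e-12:
                    count += 1
        return PermTestResult(f_observed=f_obs, p_value=count / total,
                              n_permutations=total, exhaustive=True, seed=seed)

    rng = np.random.default_rng(seed)
    count = 0
    bounds = np.cumsum(sizes)
    for _ in range(n_perm):
        perm = rng.permutation(values)
        groups = np.split(perm, bounds[:-1])
        _, ssb = _group_stats(values, groups)
        if ssb >= ssb_obs - 1e-12:
            count += 1
    return PermTestResult(f_observed=f_obs, p_value=(1 + count) / (1 + n_perm),
                          n_permutations=n_perm, exhaustive=False, seed=seed)
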
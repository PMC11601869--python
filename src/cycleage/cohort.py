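"""Cohort-level statistics: bimodality, survival, and association tests.

The age-at-diagnosis bimodality question is tested with the
Hartigan-Hartigan dip statistic -- the minimal sup-norm distance between
the empirical CDF and the nearest unimodal CDF -- calibrated by Monte
Carlo against the classical Uniform(0,1) null.  Survival separation
between signature-high and -low groups uses the Kaplan-Meier
product-limit estimator and the two-group log-rank test, and
clinico-pathological association uses Fisher's exact test.

Dip computation
---------------
For sorted unique values ``u_1 < ... < u_T`` with empirical CDF steps
``F_t`` (and left limits ``Fprev_t``), a unimodal CDF within sup-band
``d`` of the empirical CDF exists iff, for some modal split, a convex
function fits the band on the left of the mode and a concave one on the
right.  The least feasible ``d`` for a left prefix is half the largest
gap between the step's upper corners' greatest convex minorant and its
lower corners; the right side is the mirror image (least concave
majorant).  The dip is the minimum over all modal splits (between points
and at a point, where the mode may carry an atom) of the larger of the
two sides.  The scan over prefixes/suffixes is O(T^2) and is compiled
with numba.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ComputationError, InputError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "DipResult",
    "SurvivalCurve",
    "LogrankResult",
    "dip_statistic",
    "dip_test",
    "km_estimate",
    "logrank_test",
    "fisher_exact",
    "age_density",
]


@njit(cache=True)
def _prefix_pass(xs, hull_y, target_y, full, drop_last):
    """For every prefix length t, half the max positive gap between the
    target values and the lower convex hull of the hull points.

    ``full[t]`` uses targets 1..t; ``drop_last[t]`` omits the target at
    the newest point (mode-at-point split).  Index 0 is 0 (empty side).
    """
    t_n = xs.shape[0]
    hx = np.empty(t_n)
    hy = np.empty(t_n)
    m = 0
    full[0] = 0.0
    drop_last[0] = 0.0
    for t in range(t_n):
        # incremental lower hull append (slopes must strictly increase)
        while m >= 2:
            s1 = (hy[m - 1] - hy[m - 2]) / (hx[m - 1] - hx[m - 2])
            s2 = (hull_y[t] - hy[m - 1]) / (xs[t] - hx[m - 1])
            if s1 >= s2:
                m -= 1
            else:
                break
        hx[m] = xs[t]
        hy[m] = hull_y[t]
        m += 1

        dev_all = 0.0
        dev_excl = 0.0
        seg = 0
        for i in range(t + 1):
            while seg < m - 1 and xs[i] > hx[seg + 1]:
                seg += 1
            if seg < m - 1 and xs[i] >= hx[seg]:
                frac = (xs[i] - hx[seg]) / (hx[seg + 1] - hx[seg])
                hval = hy[seg] + frac * (hy[seg + 1] - hy[seg])
            else:
                hval = hy[seg]
            dv = target_y[i] - hval
            if dv > dev_all:
                dev_all = dv
            if i < t and dv > dev_excl:
                dev_excl = dv
        full[t + 1] = dev_all / 2.0
        drop_last[t + 1] = dev_excl / 2.0


@njit(cache=True)
def _dip_core(u, f_hi, f_lo):
    """Dip of an empirical CDF given unique points and step levels.

    ``f_hi[t]`` is the CDF at u_t, ``f_lo[t]`` its left limit.
    """
    t_n = u.shape[0]
    l_full = np.empty(t_n + 1)
    l_drop = np.empty(t_n + 1)
    _prefix_pass(u, f_lo, f_hi, l_full, l_drop)

    # mirror: suffix concave-majorant pass == prefix pass on negated axes
    xs_r = np.empty(t_n)
    hull_r = np.empty(t_n)
    targ_r = np.empty(t_n)
    for j in range(t_n):
        xs_r[j] = -u[t_n - 1 - j]
        hull_r[j] = -f_hi[t_n - 1 - j]
        targ_r[j] = -f_lo[t_n - 1 - j]
    r_full = np.empty(t_n + 1)
    r_drop = np.empty(t_n + 1)
    _prefix_pass(xs_r, hull_r, targ_r, r_full, r_drop)

    best = 1.0
    # mode strictly between u_s and u_{s+1}: left prefix s, right suffix s+1..T
    for s in range(t_n + 1):
        left = l_full[s]
        right = r_full[t_n - s]
        hi = left if left > right else right
        if hi < best:
            best = hi
    # mode at u_t (atom allowed): drop the inner constraint on both sides
    for t in range(t_n):
        left = l_drop[t + 1]
        right = r_drop[t_n - t]
        hi = left if left > right else right
        if hi < best:
            best = hi
    return best


def _dip_sorted_distinct(x: np.ndarray) -> float:
    n = x.shape[0]
    f_hi = np.arange(1, n + 1, dtype=np.float64) / n
    f_lo = np.arange(0, n, dtype=np.float64) / n
    return float(_dip_core(x, f_hi, f_lo))


def dip_statistic(x) -> float:
    """Hartigan-Hartigan dip: sup-distance to the nearest unimodal CDF.

    Deterministic; for a sample of n distinct values the dip lies in
    ``[1/(2n), 1/4]``.  Tied values are collapsed into single CDF steps
    (a pure point mass is perfectly unimodal, dip 0).
    """
    arr = np.sort(np.asarray(x, dtype=float))
    if arr.ndim != 1 or arr.size < 2:
        raise InputError("dip needs a 1-d sample with n >= 2")
    if not np.isfinite(arr).all():
        raise InputError("dip input must be finite")
    u, counts = np.unique(arr, return_counts=True)
    if u.size == 1:
        return 0.0
    cum = np.cumsum(counts).astype(np.float64)
    f_hi = cum / arr.size
    f_lo = (cum - counts) / arr.size
    return float(_dip_core(u, f_hi, f_lo))


@dataclass
class DipResult:
    """Dip statistic with its Monte-Carlo uniform-null p-value."""

    dip: float
    p: float
    n_boot: int
    seed: int | None = None


def dip_test(x, n_boot: int = 2000, seed: int | None = None) -> DipResult:
    """Monte-Carlo dip test against the Uniform(0,1) null.

    ``p = (1 + #{dip(U_b) >= dip(x)}) / (n_boot + 1)`` with ``U_b``
    i.i.d. uniform samples of the same size.  The uniform null is the
    classical calibration and is conservative for lighter-tailed
    unimodal data such as the normal.  Deterministic under ``seed``.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n < 4:
        warnings.warn("dip test is unreliable below n = 4")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value")
    observed = dip_statistic(arr)
    rng = np.random.default_rng(seed)
    boots = np.sort(rng.random((n_boot, n)), axis=1)
    f_hi = np.arange(1, n + 1, dtype=np.float64) / n
    f_lo = np.arange(0, n, dtype=np.float64) / n
    count = 0
    for b in range(n_boot):
        row = boots[b]
        if (np.diff(row) == 0.0).any():
            d = dip_statistic(row)
        else:
            d = float(_dip_core(row, f_hi, f_lo))
        if d >= observed:
            count += 1
    p = (1 + count) / (n_boot + 1)
    return DipResult(dip=observed, p=p, n_boot=n_boot, seed=seed)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate."""

    times: np.ndarray  # distinct event times, increasing
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function lookup; S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate from follow-up times and event flags.

    Censored subjects leave the risk set after their time; at tied
    times events are handled before censorings (both count as at risk
    at that time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.shape != e.shape:
        raise InputError("times and events must have equal length")
    if (t < 0).any():
        raise InputError("negative follow-up time")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    s = 1.0
    for i, et in enumerate(event_times):
        r = int((t >= et).sum())
        di = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - di / r
        at_risk[i], d[i], surv[i] = r, di, s
    return SurvivalCurve(times=event_times, at_risk=at_risk, events=d, survival=surv)


@dataclass
class LogrankResult:
    chi_square: float
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test with hypergeometric variance.

    Ties are grouped at identical times; the statistic is
    ``(sum(O_a - E_a))^2 / sum(V)`` referred to chi-square with 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a).astype(int)
    eb = np.asarray(events_b).astype(int)
    if ta.size == 0 or tb.size == 0:
        raise InputError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ComputationError("log-rank statistic undefined with no events")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = e_a = v = 0.0
    o_b = e_b = 0.0
    for et in event_times:
        r_a = int((ta >= et).sum())
        r_b = int((tb >= et).sum())
        r = r_a + r_b
        d_a = int(((ta == et) & (ea == 1)).sum())
        d_b = int(((tb == et) & (eb == 1)).sum())
        d = d_a + d_b
        o_a += d_a
        o_b += d_b
        e_a += d * r_a / r
        e_b += d * r_b / r
        if r > 1:
            v += d * (r - d) * r_a * r_b / (r * r * (r - 1))
    if v == 0:
        chi2 = 0.0
    else:
        chi2 = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return LogrankResult(chi_square=float(chi2), p=p, observed=(o_a, o_b), expected=(e_a, e_b))


def fisher_exact(table, method: str = "point") -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    ``method="point"`` (default) sums hypergeometric probabilities of
    tables no more likely than the observed one; ``method="double"``
    doubles the smaller one-sided tail (capped at 1).  A zero margin
    makes the table degenerate: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or (t != np.floor(t)).any():
            raise InputError("table must be 2x2 non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    row1, col1, total = a + b, a + c, a + b + c + d
    if 0 in (row1, col1, c + d, b + d):
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0

    k_min = max(0, row1 + col1 - total)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    p_obs = pmf[a - k_min]
    if method == "point":
        # numerical tolerance mirrors the usual implementation practice
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif method == "double":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise InputError("method must be 'point' or 'double'")
    return min(1.0, p)


def age_density(
    ages,
    groups=None,
    n_bins: int = 20,
    grid_size: int = 256,
) -> dict[str, pd.DataFrame]:
    """Histogram and Gaussian-KDE density tables of age at diagnosis.

    Shared bin edges across groups; KDE bandwidth by Silverman's rule.
    Returns plot-ready tables (``hist`` long-format and ``density`` on a
    common grid); rendering is left to the caller.
    """
    a = np.asarray(ages, dtype=float)
    g = np.asarray(groups) if groups is not None else np.full(a.size, "all")
    edges = np.histogram_bin_edges(a, bins=n_bins)
    grid = np.linspace(a.min() - 3 * a.std(), a.max() + 3 * a.std(), grid_size)

    hist_rows = []
    dens = {"age": grid}
    for name in pd.unique(g):
        sub = a[g == name]
        if sub.size < 2:
            raise InputError(f"group {name!r} has fewer than 2 ages")
        h, _ = np.histogram(sub, bins=edges, density=True)
        for lo, hi, v in zip(edges[:-1], edges[1:], h):
            hist_rows.append((name, lo, hi, v))
        if np.ptp(sub) == 0:
            # all-equal ages: histogram carries the mass; KDE undefined
            dens[str(name)] = np.zeros_like(grid)
        else:
            kde = stats.gaussian_kde(sub, bw_method="silverman")
            dens[str(name)] = kde(grid)
    hist = pd.DataFrame(hist_rows, columns=["group", "bin_left", "bin_right", "density"])
    return {"hist": hist, "density": pd.DataFrame(dens)}
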
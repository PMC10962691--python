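"""Exponential decay of excess 13C and mean residence time.

After the labeling pulse, the tracer in a well-mixed pool drains as

    y(t) = A * exp(-b * t)

with A the excess at the peak and b the decay constant; the mean residence
time of the tracer is MRT = 1/b, the time for the excess to fall to 1/e of
its peak.  Shoot series are fitted in days, soil-respiration series in hours
(each fit records its unit).

Immediately after labeling, tracer that physically back-diffuses from the
soil pore space inflates the 13C excess of soil-respired CO2; that component
is small (a few percent of the label) and turns over within tens of minutes,
so soil-respiration fits drop the first measurement cycle (t <= 2.4 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._errors import InsufficientDataError, UndefinedMRTError, UnfittableError

#: Duration of the first post-label measurement cycle, hours; soil-respiration
#: decay fits exclude all points with t <= this (closed boundary).
FIRST_CYCLE_H = 2.4

#: A fitted decay constant below this is treated as the b -> 0 boundary
#: (no resolvable decay) and the fit is marked unconverged.
_B_FLOOR = 1e-8


@dataclass(frozen=True)
class DecayFit:
    """Fitted single-exponential decay with its derived mean residence time."""

    A: float
    b: float              # per `units`
    mrt: float            # 1/b, in `units`
    rss: float
    n_points: int
    converged: bool
    units: str = "d"


def _log_linear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(A0, b0) from OLS of log(y) on t over the positive observations."""
    pos = y > 0
    tp, yp = t[pos], np.log(y[pos])
    if tp.size >= 2 and np.ptp(tp) > 0:
        slope, intercept = np.polyfit(tp, yp, 1)
        a0 = float(np.exp(intercept))
        b0 = float(max(-slope, _B_FLOOR))
    else:
        a0 = float(np.max(y[pos]))
        b0 = _B_FLOOR
    return a0, b0


def fit_exponential(t, y, units: str = "d", max_nfev: int = 5000) -> DecayFit:
    """Fit y = A*exp(-b*t) by bounded nonlinear least squares.

    Initialization comes from log-linear OLS over the positive observations;
    b is constrained positive.  A fit that collapses onto the b -> 0 boundary
    (no measurable decay, e.g. constant y) is returned with
    ``converged=False`` and NaN MRT rather than raising.

    Parameters
    ----------
    t, y : array-like, same length >= 3; at least one y must be positive.
    units : time unit label carried into the fit ("d" or "h").
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 3:
        raise InsufficientDataError("decay fit needs at least 3 points")
    if not np.any(y > 0):
        raise UnfittableError("decay fit needs at least one positive value")

    a0, b0 = _log_linear_init(t, y)
    model = lambda tt, a, b: a * np.exp(-b * tt)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=(a0, b0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
        )
        a_hat, b_hat = float(popt[0]), float(popt[1])
        ok = True
    except RuntimeError:
        a_hat, b_hat, ok = a0, b0, False

    rss = float(np.sum((model(t, a_hat, b_hat) - y) ** 2))
    converged = ok and b_hat > _B_FLOOR
    mrt_val = 1.0 / b_hat if converged else float("nan")
    return DecayFit(A=a_hat, b=b_hat, mrt=mrt_val, rss=rss,
                    n_points=int(t.size), converged=converged, units=units)


def mrt(fit: DecayFit) -> float:
    """Mean residence time 1/b of a converged decay fit, in the fit's units."""
    if not fit.converged or fit.b <= 0:
        raise UndefinedMRTError("MRT undefined: fit not converged or b <= 0")
    return 1.0 / fit.b


def prepare_sr_series(t_h, y, cutoff_h: float = FIRST_CYCLE_H):
    """Drop the first post-label measurement cycle from an SR excess series.

    Removes every point with t <= ``cutoff_h`` (closed boundary), screening
    out physically back-diffused tracer; raises if nothing remains.

    Returns ``(t_kept, y_kept)`` as arrays.
    """
    t_h = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = t_h > cutoff_h
    if not np.any(keep):
        raise InsufficientDataError(
            f"no data remain after excluding the first cycle (t <= {cutoff_h} h)")
    return t_h[keep], y[keep]
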
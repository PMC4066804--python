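"""Stage 1: fluorescence time courses -> k_app -> k_a.

Under pseudo-first-order conditions (D_tot << P_tot << C_tot) target
association makes the fluorescence time course mono-exponential,

    I(t) = I_inf + (I0 - I_inf) * exp(-k_app * t),

and the apparent rate k_app grows linearly with protein concentration,
k_app = k_a * P_tot (+ optional intercept).  This module fits both
stages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "KineticTrace",
    "MonoExpFit",
    "TitrationSeries",
    "TitrationFit",
    "TraceFitError",
    "fit_monoexponential",
    "k_a_from_titration",
]


class TraceFitError(RuntimeError):
    """Raised when a fluorescence trace cannot be fit."""


@dataclass(frozen=True)
class KineticTrace:
    """One stopped-flow fluorescence time course."""

    time: np.ndarray  # s, strictly increasing, >= 0
    intensity: np.ndarray  # arbitrary fluorescence units
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        i = np.asarray(self.intensity, float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", i)
        if t.ndim != 1 or i.shape != t.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if t.size < 10:
            raise ValueError(f"trace needs >= 10 points, got {t.size}")
        if not (np.isfinite(t).all() and np.isfinite(i).all()):
            raise ValueError("trace contains non-finite values")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing and >= 0")


@dataclass(frozen=True)
class MonoExpFit:
    """Result of a mono-exponential fit to one trace."""

    k_app: float  # s^-1
    I0: float
    I_inf: float
    rss: float
    converged: bool
    label: str = ""


@dataclass(frozen=True)
class TitrationSeries:
    """(P_tot, k_app) pairs from a protein titration."""

    P_tot: np.ndarray  # M
    k_app: np.ndarray  # s^-1
    se: Optional[np.ndarray] = None  # s^-1
    label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.P_tot, float)
        k = np.asarray(self.k_app, float)
        object.__setattr__(self, "P_tot", p)
        object.__setattr__(self, "k_app", k)
        if self.se is not None:
            s = np.asarray(self.se, float)
            object.__setattr__(self, "se", s)
            if s.shape != p.shape or np.any(s <= 0):
                raise ValueError("se must match P_tot and be positive")
        if p.ndim != 1 or k.shape != p.shape:
            raise ValueError("P_tot and k_app must be 1-D arrays of equal length")
        if np.any(p <= 0):
            raise ValueError("all P_tot must be > 0")
        if np.unique(p).size < 2:
            raise ValueError("need >= 2 distinct protein concentrations")


@dataclass(frozen=True)
class TitrationFit:
    """Second-order rate constant from a k_app vs P_tot regression."""

    k_a: float  # slope, M^-1 s^-1
    se: float
    intercept: float  # s^-1; 0.0 when fit through the origin
    intercept_se: float
    rss: float
    n: int
    with_intercept: bool


def _model(t: np.ndarray, k: float, i0: float, iinf: float) -> np.ndarray:
    return iinf + (i0 - iinf) * np.exp(-k * t)


def fit_monoexponential(trace: KineticTrace) -> MonoExpFit:
    """Least-squares mono-exponential fit of one fluorescence trace.

    The amplitude sign is free (fluorescence may rise or fall on
    binding).  Starting values: plateau from the tail mean, amplitude
    from the first point, rate from a log-linearised early decay;
    log-spaced multi-start fallback if the first attempt fails.
    """
    t, I = trace.time, trace.intensity
    if np.ptp(I) == 0:
        raise TraceFitError(
            f"trace {trace.label!r}: constant intensity, no kinetics to fit"
        )

    n_tail = max(3, t.size // 10)
    iinf0 = float(I[-n_tail:].mean())
    i00 = float(I[0])
    t_span = t[-1] - t[0]

    # Log-linearised initial rate from the early part of the decay.
    amp = I - iinf0
    sign = 1.0 if abs(i00 - iinf0) == 0 or i00 - iinf0 > 0 else -1.0
    early = amp * sign > 0.05 * abs(i00 - iinf0) if i00 != iinf0 else np.zeros_like(t, bool)
    if early.sum() >= 3:
        k0 = max(
            1e-12,
            -float(np.polyfit(t[early], np.log(np.abs(amp[early])), 1)[0]),
        )
    else:
        k0 = 1.0 / max(t_span, 1e-12)

    def resid(theta: np.ndarray) -> np.ndarray:
        logk, i0, iinf = theta
        return _model(t, math.exp(logk), i0, iinf) - I

    starts = [np.array([math.log(k0), i00, iinf0])]
    starts += [
        np.array([math.log(kk / t_span), i00, iinf0])
        for kk in (0.1, 1.0, 10.0, 100.0)
    ]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise TraceFitError(f"trace {trace.label!r}: mono-exponential fit failed")
    k_app = math.exp(best.x[0])
    rss = float(2 * best.cost)
    # Reject fits indistinguishable from a constant (no decay resolved).
    const_rss = float(((I - I.mean()) ** 2).sum())
    if const_rss > 0 and rss > 0.999 * const_rss:
        raise TraceFitError(
            f"trace {trace.label!r}: no exponential decay resolved "
            "(fit no better than a constant)"
        )
    return MonoExpFit(
        k_app=k_app,
        I0=float(best.x[1]),
        I_inf=float(best.x[2]),
        rss=rss,
        converged=bool(best.success),
        label=trace.label,
    )


def k_a_from_titration(
    series: TitrationSeries, allow_intercept: bool = True
) -> TitrationFit:
    """Apparent second-order rate constant from k_app vs P_tot.

    Weighted (1/se^2 when errors are given) linear regression; the
    slope is k_a.  With ``allow_intercept`` a constant term absorbs
    any protein-independent relaxation (e.g. target dissociation);
    without it the line is forced through the origin.
    """
    p, k = series.P_tot, series.k_app
    n_distinct = np.unique(p).size
    need = 3 if allow_intercept else 2
    if n_distinct < need:
        raise ValueError(
            f"need >= {need} distinct protein concentrations for this fit, "
            f"got {n_distinct}"
        )
    X = sm.add_constant(p) if allow_intercept else p[:, None]
    w = 1.0 / series.se**2 if series.se is not None else None
    model = sm.WLS(k, X, weights=w) if w is not None else sm.OLS(k, X)
    res = model.fit()
    bse = res.bse
    if w is not None:
        # Known measurement errors: absolute-sigma covariance
        # (X' W X)^-1 rather than the residual-scaled estimate.
        bse = bse / math.sqrt(res.scale)
    if allow_intercept:
        intercept, slope = res.params
        intercept_se, slope_se = bse
    else:
        slope, slope_se = res.params[0], bse[0]
        intercept, intercept_se = 0.0, 0.0
    return TitrationFit(
        k_a=float(slope),
        se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        rss=float(res.ssr),
        n=int(p.size),
        with_intercept=allow_intercept,
    )
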
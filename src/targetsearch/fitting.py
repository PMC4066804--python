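"""Stage 2: nonlinear least-squares estimation of the search parameters.

Three fits, mirroring the experimental design:

* DNA-length dependence of k_a at fixed concentrations -> (D1, lambda),
  with tau_N = lambda^2 / D1 so the length fit never references the
  dissociation/transfer rates;
* competitor-concentration dependence at fixed probe -> (k_off,N,
  k_IT,N) given D1, with tau_N (and hence lambda and S) recomputed at
  every C_tot;
* simultaneous fit of both series -> (D1, k_off,N, k_IT,N).

All rate-like parameters are optimised in natural-log space
(positivity by construction) from a deterministic log-spaced
multi-start grid.  Standard errors come from the Gauss-Newton
covariance at the optimum; a seeded residual bootstrap is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import AssayCondition, site_count

__all__ = [
    "RateDataset",
    "FitResult",
    "FitError",
    "fit_length_dependence",
    "fit_competition",
    "fit_simultaneous",
    "k_a_length_model",
    "k_a_competition_model",
    "predict",
    "bootstrap_se",
]

COVARIATE_KINDS = ("length", "competitor", "KCl", "protein")

# Deterministic multi-start grids (log10 ranges), 5 nodes per parameter.
_GRID_D1 = np.logspace(2, 8, 5)  # bp^2 s^-1
_GRID_LAMBDA = np.logspace(-0.5, 3.5, 5)  # bp
_GRID_KOFF = np.logspace(-2, 5, 5)  # s^-1
_GRID_KIT = np.logspace(4, 10, 5)  # M^-1 s^-1

# log-SE above which an estimate is flagged as practically unidentifiable
# (one natural-log unit of 2.3 spans a decade).
_NONIDENT_LOG_SE = 2.3


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be completed."""


@dataclass(frozen=True)
class RateDataset:
    """An observed or synthetic (covariate, k_a) series.

    ``covariate`` is stored in internal units: bp for ``length``,
    molar for ``competitor`` and ``protein``, mM for ``KCl``.  The
    ``condition`` template supplies every geometry/concentration field
    that is not the covariate, and ``K_d_N`` the fixed per-site
    nonspecific dissociation constant used in the model.
    """

    covariate_kind: str
    covariate: np.ndarray
    k_a: np.ndarray  # M^-1 s^-1
    condition: AssayCondition
    K_d_N: float  # M
    se: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.covariate_kind not in COVARIATE_KINDS:
            raise ValueError(
                f"covariate_kind must be one of {COVARIATE_KINDS}, "
                f"got {self.covariate_kind!r}"
            )
        x = np.asarray(self.covariate, float)
        y = np.asarray(self.k_a, float)
        object.__setattr__(self, "covariate", x)
        object.__setattr__(self, "k_a", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("covariate and k_a must be 1-D arrays of equal length")
        if np.any(x <= 0):
            raise ValueError("covariate values must be positive")
        if not self.K_d_N > 0:
            raise ValueError("K_d_N must be positive")
        if self.se is not None:
            s = np.asarray(self.se, float)
            object.__setattr__(self, "se", s)
            if s.shape != x.shape or np.any(s <= 0):
                raise ValueError("se must match the covariate and be positive")

    @property
    def n(self) -> int:
        return int(self.covariate.size)


@dataclass(frozen=True)
class FitResult:
    """Estimates, uncertainties and provenance of one nonlinear fit."""

    estimates: Dict[str, float]
    se: Dict[str, float]
    fixed: Dict[str, float]
    rss: float
    converged: bool
    variant: str  # "with_IT" | "without_IT" | "length" | "joint"
    n_obs: int
    warnings: List[str] = field(default_factory=list)


def _antenna_np(lambda_bp, L, m):
    """Vectorised antenna size (same hyperbolic form as model.antenna_size)."""
    lam = np.asarray(lambda_bp, float)
    L = np.asarray(L, float)
    t = 0.5 / (lam * lam)
    u = np.log1p(t + np.sqrt(t * (t + 2.0)))
    S = (np.tanh((m - 0.5) * u) + np.tanh((L - m + 0.5) * u)) / (
        2.0 * np.tanh(0.5 * u)
    )
    return np.where(lam < 1e-6, 1.0, S)


def k_a_length_model(
    probe_len_bp,
    D1: float,
    lambda_bp: float,
    *,
    cond: AssayCondition,
    K_d_N: float,
    phi: int = 2,
) -> np.ndarray:
    """Model k_a versus probe length at fixed concentrations.

    Length-fit convention: tau_N = lambda^2 / D1, so lambda is shared
    by all lengths in the series (the fixed concentrations are
    absorbed into lambda).
    """
    A = np.asarray(probe_len_bp, float)
    L = A - cond.footprint_B + 1
    M = cond.M_sites
    S = _antenna_np(lambda_bp, L, cond.target_pos_m)
    tau = lambda_bp * lambda_bp / D1
    denom = K_d_N + (phi * L - S) * cond.D_tot + phi * M * cond.C_tot
    return S / (denom * tau)


def k_a_competition_model(
    C_tot,
    k_off_N: float,
    k_IT_N: float,
    *,
    D1: float,
    cond: AssayCondition,
    K_d_N: float,
    phi: int = 2,
) -> np.ndarray:
    """Model k_a versus competitor concentration at fixed probe length.

    tau_N from the full lifetime expression, so lambda and the antenna
    S shrink as the competitor pool grows.
    """
    C = np.asarray(C_tot, float)
    L, M = cond.L, cond.M_sites
    conc = phi * (L * cond.D_tot + M * C)
    tau = 1.0 / (k_off_N + k_IT_N * conc)
    lam = np.sqrt(D1 * tau)
    S = _antenna_np(lam, L, cond.target_pos_m)
    denom = K_d_N + (phi * L - S) * cond.D_tot + phi * M * C
    return S / (denom * tau)


def _run_nls(resid, starts, names, n_obs, absolute_sigma=False):
    """Multi-start Levenberg–Marquardt in log-parameter space.

    With ``absolute_sigma`` the residuals are assumed pre-scaled by
    known standard errors, so the covariance is (J^T J)^-1 without the
    estimated variance factor (the convention of
    ``curve_fit(absolute_sigma=True)``).
    """
    def safe_resid(theta):
        with np.errstate(all="ignore"):
            r = np.asarray(resid(theta), float)
        return np.where(np.isfinite(r), r, 1e30)

    best = None
    with np.errstate(all="ignore"):
        for x0 in starts:
            try:
                sol = least_squares(
                    safe_resid,
                    np.log(x0),
                    method="lm",
                    max_nfev=5000,
                    ftol=1e-15,
                    xtol=1e-15,
                    gtol=1e-15,
                )
            except Exception:
                continue
            if not np.isfinite(sol.cost):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("all multi-start attempts failed")
    p = len(names)
    rss = float(2 * best.cost)
    dof = max(n_obs - p, 1)
    s2 = 1.0 if absolute_sigma else rss / dof
    J = best.jac
    try:
        cov_log = s2 * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(p, np.inf)
    est = {nm: float(math.exp(v)) for nm, v in zip(names, best.x)}
    se = {nm: est[nm] * float(sl) for nm, sl in zip(names, se_log)}
    warns = [
        f"{nm}: practically unidentifiable (log-SE {sl:.2g} spans decades)"
        for nm, sl in zip(names, se_log)
        if not sl < _NONIDENT_LOG_SE
    ]
    return est, se, rss, bool(best.success), warns


def _weights(data: RateDataset, weighted: bool) -> np.ndarray:
    if weighted:
        if data.se is None:
            raise ValueError("weighted fit requested but dataset has no SEs")
        return 1.0 / data.se
    return np.ones(data.n)


def fit_length_dependence(
    data: RateDataset, *, phi: int = 2, weighted: bool = False
) -> FitResult:
    """Estimate (D1, lambda) from the DNA-length dependence of k_a.

    The asymptote of k_a(L) sets 2*lambda; data that never bend
    (lambda far beyond the longest probe) leave lambda practically
    unidentifiable, which is reported in ``warnings``.
    """
    if data.covariate_kind != "length":
        raise ValueError(f"expected a length dataset, got {data.covariate_kind!r}")
    if np.unique(data.covariate).size < 3:
        raise ValueError("length fit needs >= 3 distinct probe lengths")
    w = _weights(data, weighted)
    cond, K_d_N = data.condition, data.K_d_N

    def resid(theta):
        D1, lam = np.exp(theta)
        return w * (
            k_a_length_model(
                data.covariate, D1, lam, cond=cond, K_d_N=K_d_N, phi=phi
            )
            - data.k_a
        )

    starts = [(d, l) for d in _GRID_D1 for l in _GRID_LAMBDA]
    est, se, rss, ok, warns = _run_nls(
        resid, starts, ["D1", "lambda"], data.n, absolute_sigma=weighted
    )
    return FitResult(
        estimates=est,
        se=se,
        fixed={"K_d_N": K_d_N, "phi": phi},
        rss=rss,
        converged=ok,
        variant="length",
        n_obs=data.n,
        warnings=warns,
    )


def fit_competition(
    data: RateDataset,
    D1: float,
    *,
    variant: str = "with_IT",
    phi: int = 2,
    weighted: bool = False,
) -> FitResult:
    """Estimate (k_off,N, k_IT,N) from the competitor dependence of k_a.

    ``variant="without_IT"`` pins k_IT,N = 0, the nested model used to
    demonstrate that intersegment transfer is required by the data.
    """
    if data.covariate_kind != "competitor":
        raise ValueError(f"expected a competitor dataset, got {data.covariate_kind!r}")
    if variant not in ("with_IT", "without_IT"):
        raise ValueError(f"unknown variant {variant!r}")
    C = data.covariate
    if C.max() / C.min() < 4.0:
        raise ValueError(
            "competitor concentrations span less than 4-fold; "
            "k_off,N and k_IT,N are not separable on such a design"
        )
    if not D1 > 0:
        raise ValueError("D1 must be positive")
    w = _weights(data, weighted)
    cond, K_d_N = data.condition, data.K_d_N

    if variant == "with_IT":
        def resid(theta):
            koff, kit = np.exp(theta)
            return w * (
                k_a_competition_model(
                    C, koff, kit, D1=D1, cond=cond, K_d_N=K_d_N, phi=phi
                )
                - data.k_a
            )

        starts = [(ko, ki) for ko in _GRID_KOFF for ki in _GRID_KIT]
        names = ["k_off_N", "k_IT_N"]
    else:
        def resid(theta):
            (koff,) = np.exp(theta)
            return w * (
                k_a_competition_model(
                    C, koff, 0.0, D1=D1, cond=cond, K_d_N=K_d_N, phi=phi
                )
                - data.k_a
            )

        starts = [(ko,) for ko in _GRID_KOFF]
        names = ["k_off_N"]

    est, se, rss, ok, warns = _run_nls(
        resid, starts, names, data.n, absolute_sigma=weighted
    )
    fixed = {"D1": D1, "K_d_N": K_d_N, "phi": phi}
    if variant == "without_IT":
        est = dict(est)
        fixed["k_IT_N"] = 0.0
    return FitResult(
        estimates=est,
        se=se,
        fixed=fixed,
        rss=rss,
        converged=ok,
        variant=variant,
        n_obs=data.n,
        warnings=warns,
    )


def fit_simultaneous(
    length_data: Optional[RateDataset],
    competitor_data: Optional[RateDataset],
    *,
    phi: int = 2,
    weighted: bool = False,
) -> FitResult:
    """Joint (D1, k_off,N, k_IT,N) fit to both series.

    In the joint model lambda = sqrt(D1 * tau_N) with the full
    lifetime evaluated at each point's own concentrations, for the
    length series as well as the competitor series.  Both datasets
    must share K_d,N and the geometry conventions.
    """
    if length_data is None or competitor_data is None:
        raise ValueError(
            "joint fit needs both the length and the competitor series; "
            "three parameters are not identifiable from one design"
        )
    if length_data.covariate_kind != "length":
        raise ValueError("first dataset must have covariate_kind='length'")
    if competitor_data.covariate_kind != "competitor":
        raise ValueError("second dataset must have covariate_kind='competitor'")
    if not math.isclose(length_data.K_d_N, competitor_data.K_d_N, rel_tol=1e-12):
        raise ValueError("datasets disagree on the fixed K_d_N")
    lcond, ccond = length_data.condition, competitor_data.condition
    if lcond.footprint_B != ccond.footprint_B or lcond.target_pos_m != ccond.target_pos_m:
        raise ValueError("datasets disagree on footprint/target conventions")
    K_d_N = length_data.K_d_N
    wl = _weights(length_data, weighted)
    wc = _weights(competitor_data, weighted)
    A = length_data.covariate
    Llen = A - lcond.footprint_B + 1
    Mlen = lcond.M_sites
    C = competitor_data.covariate

    def joint_model(D1, koff, kit):
        # length series: fixed concentrations, L varies
        conc_l = phi * (Llen * lcond.D_tot + Mlen * lcond.C_tot)
        tau_l = 1.0 / (koff + kit * conc_l)
        lam_l = np.sqrt(D1 * tau_l)
        S_l = _antenna_np(lam_l, Llen, lcond.target_pos_m)
        den_l = K_d_N + (phi * Llen - S_l) * lcond.D_tot + phi * Mlen * lcond.C_tot
        ka_l = S_l / (den_l * tau_l)
        ka_c = k_a_competition_model(
            C, koff, kit, D1=D1, cond=ccond, K_d_N=K_d_N, phi=phi
        )
        return ka_l, ka_c

    def resid(theta):
        D1, koff, kit = np.exp(theta)
        ka_l, ka_c = joint_model(D1, koff, kit)
        return np.concatenate(
            [wl * (ka_l - length_data.k_a), wc * (ka_c - competitor_data.k_a)]
        )

    starts = [
        (d, ko, ki) for d in _GRID_D1 for ko in _GRID_KOFF for ki in _GRID_KIT
    ]
    n_obs = length_data.n + competitor_data.n
    est, se, rss, ok, warns = _run_nls(
        resid, starts, ["D1", "k_off_N", "k_IT_N"], n_obs, absolute_sigma=weighted
    )
    return FitResult(
        estimates=est,
        se=se,
        fixed={"K_d_N": K_d_N, "phi": phi},
        rss=rss,
        converged=ok,
        variant="joint",
        n_obs=n_obs,
        warnings=warns,
    )


def predict(data: RateDataset, fit: FitResult) -> np.ndarray:
    """Model k_a at the dataset's covariates for a fitted result."""
    phi = int(fit.fixed.get("phi", 2))
    if fit.variant == "length":
        return k_a_length_model(
            data.covariate,
            fit.estimates["D1"],
            fit.estimates["lambda"],
            cond=data.condition,
            K_d_N=data.K_d_N,
            phi=phi,
        )
    if fit.variant in ("with_IT", "without_IT"):
        kit = fit.estimates.get("k_IT_N", fit.fixed.get("k_IT_N", 0.0))
        return k_a_competition_model(
            data.covariate,
            fit.estimates["k_off_N"],
            kit,
            D1=fit.fixed["D1"],
            cond=data.condition,
            K_d_N=data.K_d_N,
            phi=phi,
        )
    raise ValueError(f"cannot predict for variant {fit.variant!r}")


def bootstrap_se(
    data: RateDataset,
    fit_fn,
    n_boot: int = 100,
    seed: int = 0,
) -> Dict[str, float]:
    """Residual-bootstrap standard errors for a single-dataset fit.

    ``fit_fn`` maps a RateDataset to a FitResult (e.g. a partial of
    :func:`fit_length_dependence`).  Residuals of the base fit are
    resampled with replacement around the fitted curve; the SE is the
    standard deviation of the refitted estimates.  Deterministic per
    seed.
    """
    base = fit_fn(data)
    pred = predict(data, base)
    resid = data.k_a - pred
    rng = np.random.default_rng(seed)
    samples: Dict[str, List[float]] = {k: [] for k in base.estimates}
    for _ in range(n_boot):
        idx = rng.integers(0, data.n, data.n)
        boot = RateDataset(
            covariate_kind=data.covariate_kind,
            covariate=data.covariate,
            k_a=pred + resid[idx],
            condition=data.condition,
            K_d_N=data.K_d_N,
            se=data.se,
            metadata=data.metadata,
        )
        try:
            res = fit_fn(boot)
        except FitError:
            continue
        for k, v in res.estimates.items():
            samples[k].append(v)
    return {
        k: float(np.std(v, ddof=1)) if len(v) > 1 else math.inf
        for k, v in samples.items()
    }
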
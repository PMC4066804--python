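"""Stage 3: ionic-strength profiles of the search decomposition.

Counterion-condensation theory predicts log–log linear dependence of
the microscopic constants on salt:  log10(value) = a*log10([KCl]) + b.
Given fitted power laws for k_off,N, k_IT,N, D1 and K_d,N, this module
evaluates the antenna/trapping/transfer decomposition across a KCl
grid and locates the ionic strength at which the composed
k_a = rho*eta*S*k_on,N is maximal — the model's account of why a
searcher can be fastest at an intermediate (physiological) salt
concentration: S, eta and k_on,N fall with salt while rho rises.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import golden

from .model import (
    AssayCondition,
    NonspecificParams,
    SearchDecomposition,
    decompose,
)

__all__ = [
    "PowerLaw",
    "IonicProfile",
    "OptimumResult",
    "LAW_QUANTITIES",
    "fit_power_law",
    "eval_power_law",
    "decomposition_profile",
    "find_optimum",
]

LAW_QUANTITIES = ("k_off_N", "k_IT_N", "D1", "K_d_N")


@dataclass(frozen=True)
class PowerLaw:
    """log10(value) = a * log10(KCl_mM) + b over a stated KCl domain."""

    quantity: str
    a: float
    b: float
    domain_mM: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("slope and intercept must be finite")
        lo, hi = self.domain_mM
        if not (0 < lo < hi):
            raise ValueError(f"degenerate KCl domain {self.domain_mM}")


@dataclass(frozen=True)
class OptimumResult:
    """Location of the fastest search condition on a profile."""

    KCl_mM: float
    k_a: float
    on_boundary: bool
    multimodal: bool
    bracket_mM: Tuple[float, float]


@dataclass(frozen=True)
class IonicProfile:
    """Decomposition evaluated on a KCl grid, with its provenance."""

    KCl_mM: np.ndarray
    decompositions: List[SearchDecomposition]
    laws: Dict[str, PowerLaw]
    condition: AssayCondition
    phi: int = 2

    def __post_init__(self) -> None:
        g = np.asarray(self.KCl_mM, float)
        object.__setattr__(self, "KCl_mM", g)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("KCl grid must be a non-empty 1-D array")
        if np.any(np.diff(g) <= 0):
            raise ValueError("KCl grid must be strictly increasing")

    @property
    def k_a(self) -> np.ndarray:
        return np.array([d.k_a for d in self.decompositions])


def fit_power_law(
    points: Sequence[Tuple[float, float]], quantity: str = ""
) -> PowerLaw:
    """Least-squares log10–log10 line through (KCl mM, value) points.

    With exactly two points the line interpolates them exactly.
    """
    pts = [(float(x), float(v)) for x, v in points]
    if len(pts) < 2:
        raise ValueError("need >= 2 points to fit a power law")
    x = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.any(x <= 0) or np.any(v <= 0):
        raise ValueError("KCl concentrations and values must be positive")
    a, b = np.polyfit(np.log10(x), np.log10(v), 1)
    return PowerLaw(
        quantity=quantity, a=float(a), b=float(b),
        domain_mM=(float(x.min()), float(x.max())),
    )


def eval_power_law(law: PowerLaw, KCl_mM: float) -> float:
    """Value of the law at a KCl concentration (mM); warns when extrapolating."""
    if not KCl_mM > 0:
        raise ValueError(f"KCl must be positive, got {KCl_mM}")
    lo, hi = law.domain_mM
    if not (lo <= KCl_mM <= hi):
        warnings.warn(
            f"{law.quantity or 'power law'}: extrapolating to {KCl_mM:g} mM "
            f"outside the fitted domain [{lo:g}, {hi:g}] mM",
            stacklevel=2,
        )
    return 10.0 ** (law.a * math.log10(KCl_mM) + law.b)


def _params_at(laws: Dict[str, PowerLaw], KCl_mM: float, phi: int) -> NonspecificParams:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # domain warnings handled by caller
        vals = {q: eval_power_law(laws[q], KCl_mM) for q in LAW_QUANTITIES}
    return NonspecificParams(
        D1=vals["D1"],
        k_off_N=vals["k_off_N"],
        K_d_N=vals["K_d_N"],
        k_IT_N=vals["k_IT_N"],
        phi=phi,
    )


def decomposition_profile(
    laws: Dict[str, PowerLaw],
    cond: AssayCondition,
    KCl_grid_mM: Sequence[float],
    phi: int = 2,
) -> IonicProfile:
    """Evaluate rho, eta, S and k_a across a KCl grid.

    At each grid point the four power laws supply the microscopic
    parameters, and the full decomposition (with lambda recomputed
    from D1 and tau_N at the profile's concentrations) is evaluated.
    """
    missing = [q for q in LAW_QUANTITIES if q not in laws]
    if missing:
        raise ValueError(f"missing power laws for {missing}")
    grid = np.asarray(KCl_grid_mM, float)
    decs = [
        decompose(_params_at(laws, float(x), phi), replace(cond, KCl_mM=float(x)))
        for x in grid
    ]
    return IonicProfile(
        KCl_mM=grid, decompositions=decs, laws=laws, condition=cond, phi=phi
    )


def find_optimum(profile: IonicProfile) -> OptimumResult:
    """Ionic strength maximising the composed k_a.

    Takes the grid argmax and refines interior maxima by
    golden-section search on the continuous composition (in log KCl).
    Boundary maxima are flagged rather than refined; a non-unimodal
    grid triggers a warning and returns the global grid maximum.
    """
    grid = profile.KCl_mM
    if grid.size < 5:
        raise ValueError("need >= 5 grid points to locate an optimum")
    ka = profile.k_a
    i = int(np.argmax(ka))

    d = np.diff(ka)
    sign_changes = int(np.sum(np.diff(np.sign(d[d != 0])) != 0))
    multimodal = sign_changes > 1
    if multimodal:
        warnings.warn(
            "k_a(KCl) is not unimodal on the grid; returning the global "
            "grid maximum",
            stacklevel=2,
        )

    def neg_ka(log_x: float) -> float:
        x = math.exp(log_x)
        p = _params_at(profile.laws, x, profile.phi)
        return -decompose(p, replace(profile.condition, KCl_mM=x)).k_a

    if i == 0 or i == grid.size - 1:
        j0, j1 = max(i - 1, 0), min(i + 1, grid.size - 1)
        return OptimumResult(
            KCl_mM=float(grid[i]),
            k_a=float(ka[i]),
            on_boundary=True,
            multimodal=multimodal,
            bracket_mM=(float(grid[j0]), float(grid[j1])),
        )

    lo, mid, hi = math.log(grid[i - 1]), math.log(grid[i]), math.log(grid[i + 1])
    try:
        x_best = math.exp(golden(neg_ka, brack=(lo, mid, hi), tol=1e-10))
        k_best = -neg_ka(math.log(x_best))
    except ValueError:  # flat bracket; the grid point already is the optimum
        x_best, k_best = float(grid[i]), float(ka[i])
    if k_best < ka[i]:  # refinement must never fall below the grid value
        x_best, k_best = float(grid[i]), float(ka[i])
    return OptimumResult(
        KCl_mM=float(x_best),
        k_a=float(k_best),
        on_boundary=False,
        multimodal=multimodal,
        bracket_mM=(float(grid[i - 1]), float(grid[i + 1])),
    )
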
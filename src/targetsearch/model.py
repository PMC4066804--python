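"""Closed-form theory of sequence-specific target search on DNA.

A protein locates its target site by combining three-dimensional
association with one-dimensional sliding along nonspecific DNA and
direct intersegment transfer between duplexes.  The apparent
second-order rate constant for target association is

    k_a = S / (K_d,N + (phi*L - S)*D_tot + phi*M*C_tot) * (1 / tau_N)

where ``S`` is the effective antenna size (the number of sites that
funnel the protein into the target by sliding), ``tau_N`` the mean
lifetime of a nonspecific complex, ``L`` and ``M`` the site counts of
the target-bearing probe duplex and the competitor duplex, ``phi`` the
number of binding orientations per site, and ``K_d,N`` the per-site
nonspecific dissociation constant.  The same rate constant factorises
as

    k_a = rho * eta * S * k_on,N

with ``rho`` the fraction of protein not trapped on nonspecific sites
(attenuation, 0 < rho <= 1), ``eta`` the enhancement from intersegment
transfer (eta >= 1), and ``k_on,N = k_off,N / K_d,N`` the intrinsic
per-site association rate constant.

Units are strictly molar, base pairs, and seconds throughout this
module; file-level unit conversion lives in :mod:`targetsearch.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "NonspecificParams",
    "AssayCondition",
    "SearchDecomposition",
    "site_count",
    "y_of_lambda",
    "antenna_size",
    "antenna_size_midpoint",
    "lifetime_tau_N",
    "sliding_length",
    "k_a_full",
    "decompose",
]

# Below this sliding length the antenna is the target site alone; Eq-2
# arithmetic is skipped to avoid needless extreme hyperbolic arguments.
_LAMBDA_DEGENERATE = 1e-6


@dataclass(frozen=True)
class NonspecificParams:
    """Microscopic parameters of nonspecific protein–DNA interaction.

    Attributes
    ----------
    D1 : float
        One-dimensional diffusion coefficient for sliding, bp^2 s^-1.
        On a 1-bp lattice this equals the per-direction single-step
        sliding rate k_sl,N in s^-1.
    k_off_N : float
        Dissociation rate constant of a nonspecific complex, s^-1.
    K_d_N : float
        Per-site nonspecific dissociation constant, M.
    k_IT_N : float
        Second-order rate constant for intersegment (direct) transfer
        between sites on distinct duplexes, M^-1 s^-1.
    phi : int
        Binding orientations per nonspecific site: 2 for a monomer on
        pseudo-C2-symmetric duplex DNA, 1 for a symmetric dimer.
    """

    D1: float
    k_off_N: float
    K_d_N: float
    k_IT_N: float = 0.0
    phi: int = 2

    def __post_init__(self) -> None:
        if not (self.D1 > 0 and math.isfinite(self.D1)):
            raise ValueError(f"D1 must be positive and finite, got {self.D1}")
        if self.k_off_N < 0:
            raise ValueError(f"k_off_N must be >= 0, got {self.k_off_N}")
        if self.k_IT_N < 0:
            raise ValueError(f"k_IT_N must be >= 0, got {self.k_IT_N}")
        if not (self.K_d_N > 0 and math.isfinite(self.K_d_N)):
            raise ValueError(f"K_d_N must be positive and finite, got {self.K_d_N}")
        if self.phi not in (1, 2):
            raise ValueError(f"phi must be 1 or 2, got {self.phi}")

    @property
    def k_on_N(self) -> float:
        """Intrinsic per-site association rate constant k_off,N / K_d,N (M^-1 s^-1)."""
        return self.k_off_N / self.K_d_N


@dataclass(frozen=True)
class AssayCondition:
    """Geometry and concentrations of one stopped-flow measurement.

    The probe duplex carries the target at 1-based site ``target_pos_m``
    counted from the duplex edge; the competitor duplex is entirely
    nonspecific.  A protein footprint of ``footprint_B`` bp converts a
    duplex of A bp into A - B + 1 binding sites.
    """

    probe_len_bp: int
    competitor_len_bp: int
    D_tot: float  # probe duplex concentration, M
    C_tot: float  # competitor duplex concentration, M
    footprint_B: int = 9
    target_pos_m: int = 2
    P_tot: Optional[float] = None  # protein concentration, M
    KCl_mM: Optional[float] = None  # ionic-strength label

    def __post_init__(self) -> None:
        if self.probe_len_bp < self.footprint_B:
            raise ValueError(
                f"probe of {self.probe_len_bp} bp is shorter than the "
                f"{self.footprint_B}-bp footprint"
            )
        if self.competitor_len_bp < self.footprint_B:
            raise ValueError(
                f"competitor of {self.competitor_len_bp} bp is shorter than "
                f"the {self.footprint_B}-bp footprint"
            )
        if not (1 <= self.target_pos_m <= self.L):
            raise ValueError(
                f"target position m={self.target_pos_m} outside 1..L={self.L}"
            )
        for name in ("D_tot", "C_tot"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.P_tot is not None and self.P_tot < 0:
            raise ValueError(f"P_tot must be >= 0, got {self.P_tot}")

    @property
    def L(self) -> int:
        """Binding sites on the probe duplex."""
        return site_count(self.probe_len_bp, self.footprint_B)

    @property
    def M_sites(self) -> int:
        """Binding sites on the competitor duplex."""
        return site_count(self.competitor_len_bp, self.footprint_B)


@dataclass(frozen=True)
class SearchDecomposition:
    """Derived quantities of one evaluation of the search model."""

    y: float  # characteristic root of the sliding recursion, in (0, 1)
    lambda_bp: float  # effective sliding length, bp
    tau_N: float  # nonspecific-complex lifetime, s
    S: float  # antenna size, sites
    rho: float  # untrapped fraction
    eta: float  # intersegment-transfer enhancement
    k_on_N: float  # intrinsic per-site association rate, M^-1 s^-1
    k_a: float  # apparent target-association rate constant, M^-1 s^-1


def site_count(duplex_len_bp: int, footprint_B: int) -> int:
    """Number of protein binding sites on a duplex: A - B + 1.

    A protein covering ``footprint_B`` bp has A - B + 1 distinct
    positions on an A-bp duplex.  E.g. a 113-bp probe with B = 9 has
    105 sites; a 28-bp competitor has 20.
    """
    if footprint_B < 1:
        raise ValueError(f"footprint_B must be >= 1, got {footprint_B}")
    if duplex_len_bp < footprint_B:
        raise ValueError(
            f"duplex of {duplex_len_bp} bp cannot accommodate a "
            f"{footprint_B}-bp footprint"
        )
    return int(duplex_len_bp) - int(footprint_B) + 1


def _check_lambda(lambda_bp: float) -> None:
    if not (lambda_bp > 0 and math.isfinite(lambda_bp)):
        raise ValueError(f"sliding length must be positive and finite, got {lambda_bp}")


def _u_of_lambda(lambda_bp: float) -> float:
    """Decay constant u = -ln y, where cosh u = 1 + lambda^-2 / 2.

    Computed via log1p so that u ~ 1/lambda remains accurate for large
    sliding lengths where y approaches 1.
    """
    t = 0.5 / (lambda_bp * lambda_bp)
    return math.log1p(t + math.sqrt(t * (t + 2.0)))


def y_of_lambda(lambda_bp: float) -> float:
    """Characteristic root y in (0, 1) of the sliding recursion.

    y solves y^2 - (2 + lambda^-2) y + 1 = 0, equivalently
    y = 1 + lambda^-2/2 - sqrt(lambda^-2 + lambda^-4/4).  It is the
    per-site decay factor of the capture probability away from the
    target.
    """
    _check_lambda(lambda_bp)
    return math.exp(-_u_of_lambda(lambda_bp))


def antenna_size(lambda_bp: float, L: int, m: int) -> float:
    """Effective antenna size S for a target at site m of an L-site duplex.

    S counts how many sites' worth of association flux the sliding
    antenna funnels into the target:

        S = y(1+y)(y^-L - y^L) /
            [(1-y)(y^(1-m) + y^m)(y^(1+L-m) + y^(m-L))]

    evaluated here in the equivalent hyperbolic form

        S = [tanh((m-1/2)u) + tanh((L-m+1/2)u)] / (2 tanh(u/2)),

    u = -ln y, which is exact and overflow-free for small lambda and
    large L.  S = 1 when L = 1 (the antenna is the target alone) and
    S -> L as lambda -> infinity.
    """
    _check_lambda(lambda_bp)
    L = int(L)
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if not (1 <= m <= L):
        raise ValueError(f"target position m={m} outside 1..L={L}")
    if lambda_bp < _LAMBDA_DEGENERATE:
        return 1.0
    u = _u_of_lambda(lambda_bp)
    a = (m - 0.5) * u
    b = (L - m + 0.5) * u
    return (math.tanh(a) + math.tanh(b)) / (2.0 * math.tanh(0.5 * u))


def antenna_size_midpoint(lambda_bp: float, L: int) -> float:
    """Mid-target antenna approximation S ~ 2*lambda*tanh(L / (2*lambda)).

    Valid when the target sits near the middle of the duplex; reduces
    to L when lambda >> L and to 2*lambda when L >> lambda.
    """
    _check_lambda(lambda_bp)
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return 2.0 * lambda_bp * math.tanh(L / (2.0 * lambda_bp))


def _site_conc(params: NonspecificParams, cond: AssayCondition) -> float:
    """Total nonspecific site-orientation concentration phi*L*D_tot + phi*M*C_tot (M)."""
    return params.phi * (cond.L * cond.D_tot + cond.M_sites * cond.C_tot)


def lifetime_tau_N(params: NonspecificParams, cond: AssayCondition) -> float:
    """Mean lifetime of a nonspecific complex, s.

    tau_N = 1 / [k_off,N + k_IT,N * (phi*L*D_tot + phi*M*C_tot)]:
    the complex decays by dissociation or by intersegment transfer to
    any other duplex in solution.
    """
    decay = params.k_off_N + params.k_IT_N * _site_conc(params, cond)
    if decay <= 0:
        raise ValueError(
            "nonspecific complex has no decay channel "
            "(k_off_N = 0 and k_IT_N * site concentration = 0)"
        )
    return 1.0 / decay


def sliding_length(params: NonspecificParams, cond: AssayCondition) -> float:
    """Effective sliding length lambda = sqrt(D1 * tau_N), bp.

    Recomputed per condition: tau_N, hence lambda, depends on the DNA
    concentrations through the intersegment-transfer channel.
    """
    return math.sqrt(params.D1 * lifetime_tau_N(params, cond))


def k_a_full(params: NonspecificParams, cond: AssayCondition) -> float:
    """Apparent second-order target-association rate constant, M^-1 s^-1.

    Evaluates the closed form without assuming quasi-equilibrium of
    nonspecific binding.  The antenna S is counted once among the
    phi*L site-orientations of the probe; (phi*L - S) is the trapping
    remainder on the target-bearing duplex.
    """
    tau = lifetime_tau_N(params, cond)
    lam = math.sqrt(params.D1 * tau)
    S = antenna_size(lam, cond.L, cond.target_pos_m)
    denom = (
        params.K_d_N
        + (params.phi * cond.L - S) * cond.D_tot
        + params.phi * cond.M_sites * cond.C_tot
    )
    return S / (denom * tau)


def decompose(params: NonspecificParams, cond: AssayCondition) -> SearchDecomposition:
    """Factorise k_a into rho * eta * S * k_on,N.

    Requires k_off_N > 0 so that the intrinsic rate k_on,N and the
    transfer enhancement eta are finite; the product reproduces
    :func:`k_a_full` exactly.
    """
    if params.k_off_N <= 0:
        raise ValueError(
            "decomposition requires k_off_N > 0 (k_on_N and eta are "
            "otherwise undefined); use k_a_full for the rate alone"
        )
    tau = lifetime_tau_N(params, cond)
    lam = math.sqrt(params.D1 * tau)
    S = antenna_size(lam, cond.L, cond.target_pos_m)
    conc = _site_conc(params, cond)
    rho = params.K_d_N / (
        params.K_d_N + (params.phi * cond.L - S) * cond.D_tot
        + params.phi * cond.M_sites * cond.C_tot
    )
    eta = 1.0 + params.k_IT_N * conc / params.k_off_N
    k_on = params.k_on_N
    return SearchDecomposition(
        y=y_of_lambda(lam),
        lambda_bp=lam,
        tau_N=tau,
        S=S,
        rho=rho,
        eta=eta,
        k_on_N=k_on,
        k_a=rho * eta * S * k_on,
    )
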
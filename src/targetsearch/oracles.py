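"""Independent numerical validators of the closed-form search theory.

Two oracles, both deliberately free of the closed-form algebra they
check:

* :func:`antenna_oracle` — solves the backward (splitting-probability)
  linear system for a random walker on a reflecting L-site chain that
  hops at ``hop_rate`` per direction and leaves the chain at
  ``death_rate``.  The summed capture probabilities equal the antenna
  size S.
* :func:`gillespie_k_a` — exact stochastic simulation of the full
  search scheme (3-D association, sliding, dissociation, intersegment
  transfer) for a single protein under pseudo-first-order conditions;
  the mean first-passage time to the target yields k_a.

Conventions match the analytical model: the per-direction hop rate on
a 1-bp lattice equals D1 (bp^2 s^-1 == s^-1), so the discrete
characteristic equation y + 1/y = 2 + 1/(hop * tau) reproduces the
closed form with lambda^2 = hop * tau.  Wrong-orientation probe sites
are pure nonspecific traps; transfer lands uniformly on the
destination duplex's site-orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .model import AssayCondition, NonspecificParams

__all__ = [
    "ChainSpec",
    "SimConfig",
    "GillespieResult",
    "antenna_oracle",
    "capture_probabilities",
    "gillespie_k_a",
]


@dataclass(frozen=True)
class ChainSpec:
    """A reflecting 1-D chain with a target site and a death channel.

    ``hop_rate`` is the per-direction sliding rate (s^-1, numerically
    D1 on a 1-bp lattice); ``death_rate`` is the total rate of leaving
    the chain (1/tau_N).
    """

    L: int
    target_pos_m: int
    hop_rate: float
    death_rate: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not (1 <= self.target_pos_m <= self.L):
            raise ValueError(
                f"target position {self.target_pos_m} outside 1..{self.L}"
            )
        if self.hop_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.hop_rate + self.death_rate <= 0:
            raise ValueError("hop_rate + death_rate must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Stochastic-simulation controls."""

    n_traj: int = 10_000
    seed: int = 0
    max_time: float = math.inf

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if not self.max_time > 0:
            raise ValueError("max_time must be > 0")


@dataclass(frozen=True)
class GillespieResult:
    """Ensemble summary of a first-passage simulation."""

    k_a: float  # 1 / (mean FPT * D_tot), M^-1 s^-1
    se: float  # delta-method standard error on k_a
    mfpt: float  # mean first-passage time, s
    mfpt_se: float
    n_traj: int
    n_censored: int
    seed: int
    flagged: bool = field(default=False)  # >1% of trajectories censored

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n_traj


def capture_probabilities(chain: ChainSpec) -> np.ndarray:
    """Per-site probabilities of reaching the target before leaving the chain.

    Site i (1-based) hops to each existing neighbour at ``hop_rate``
    and dies at ``death_rate``; ends are reflecting.  The backward
    equations give, for i != m,

        (death + sum of hop rates) p_i = hop * (p_left + p_right),

    with p_m = 1.  Solved as a tridiagonal system.
    """
    L, m = chain.L, chain.target_pos_m
    h, d = chain.hop_rate, chain.death_rate
    if L == 1:
        return np.ones(1)
    # Banded storage: row 0 superdiag, row 1 diag, row 2 subdiag.
    ab = np.zeros((3, L))
    b = np.zeros(L)
    for i in range(L):
        if i == m - 1:
            ab[1, i] = 1.0
            b[i] = 1.0
            continue
        n_left = 1.0 if i > 0 else 0.0
        n_right = 1.0 if i < L - 1 else 0.0
        ab[1, i] = d + h * (n_left + n_right)
        if i > 0:
            ab[2, i - 1] = -h * n_left  # coefficient of p_{i-1}
        if i < L - 1:
            ab[0, i + 1] = -h * n_right  # coefficient of p_{i+1}
    # Neighbour couplings into the fixed row m must not leak: zero the
    # off-diagonals of row m itself (handled above by construction) —
    # rows i != m keep their -h coupling to p_m, which is correct.
    if d == 0.0 and h == 0.0:
        raise ValueError("all rates zero: singular system")
    p = solve_banded((1, 1), ab, b)
    return p


def antenna_oracle(chain: ChainSpec) -> float:
    """Antenna size S as the sum of capture probabilities over the chain."""
    return float(capture_probabilities(chain).sum())


def gillespie_k_a(
    params: NonspecificParams, cond: AssayCondition, sim: SimConfig
) -> GillespieResult:
    """Estimate k_a by exact stochastic simulation of the search scheme.

    One protein searches among probe duplexes (concentration D_tot,
    L sites, target at site m in one designated orientation) and
    competitor duplexes (C_tot, M sites).  From free solution it
    associates to any site-orientation at k_on,N times that species'
    duplex concentration; while bound it slides at D1 per direction
    (reflecting ends), dissociates at k_off,N, or transfers out at
    k_IT,N times the total site-orientation concentration, landing on
    a site-orientation drawn proportionally to concentration.
    Reaching the target ends the trajectory; k_a = 1/(MFPT * D_tot).

    Vectorised over trajectories; bit-identical for a fixed seed.
    """
    if cond.D_tot <= 0:
        raise ValueError("gillespie_k_a requires D_tot > 0")
    L, M, m = cond.L, cond.M_sites, cond.target_pos_m
    phi = params.phi
    D1, koff, kit = params.D1, params.k_off_N, params.k_IT_N
    kon = params.k_on_N
    if kon <= 0:
        raise ValueError("association requires k_on_N > 0")

    conc_probe = phi * L * cond.D_tot  # probe site-orientation concentration
    conc_comp = phi * M * cond.C_tot
    conc_tot = conc_probe + conc_comp
    r_assoc = kon * conc_tot  # total association rate from free
    r_it = kit * conc_tot  # transfer-out rate while bound
    p_probe = conc_probe / conc_tot  # landing goes to a probe duplex

    n = sim.n_traj
    rng = np.random.default_rng(sim.seed)

    # State arrays.  bound: False = free.  mol: 0 probe / 1 competitor.
    # site: 1-based.  orient: 0..phi-1; target is (probe, m, orient 0).
    bound = np.zeros(n, bool)
    mol = np.zeros(n, np.int8)
    site = np.ones(n, np.int64)
    orient = np.zeros(n, np.int8)
    t = np.zeros(n)
    done = np.zeros(n, bool)
    censored = np.zeros(n, bool)

    def land(rng: np.random.Generator, k: int):
        """Sample k landing site-orientations (mol, site, orient)."""
        to_probe = rng.random(k) < p_probe
        new_mol = np.where(to_probe, 0, 1).astype(np.int8)
        n_sites = np.where(to_probe, L, M)
        new_site = rng.integers(1, n_sites + 1)
        new_orient = rng.integers(0, phi, size=k).astype(np.int8)
        return new_mol, new_site, new_orient

    while True:
        act = np.flatnonzero(~done)
        if act.size == 0:
            break
        b = bound[act]
        # Hop availability depends on position within the molecule.
        n_sites_here = np.where(mol[act] == 0, L, M)
        can_left = b & (site[act] > 1)
        can_right = b & (site[act] < n_sites_here)
        r_left = np.where(can_left, D1, 0.0)
        r_right = np.where(can_right, D1, 0.0)
        total = np.where(b, r_left + r_right + koff + r_it, r_assoc)
        dt = rng.exponential(1.0 / total)
        t[act] += dt
        over = t[act] > sim.max_time
        if over.any():
            oi = act[over]
            done[oi] = True
            censored[oi] = True
            t[oi] = sim.max_time
            keep = ~over
            act = act[keep]
            if act.size == 0:
                continue
            b = b[keep]
            r_left, r_right, total = r_left[keep], r_right[keep], total[keep]
        u = rng.random(act.size) * total

        # Free proteins associate; bound proteins hop/dissociate/transfer.
        free_idx = act[~b]
        if free_idx.size:
            nm, ns, no = land(rng, free_idx.size)
            bound[free_idx] = True
            mol[free_idx] = nm
            site[free_idx] = ns
            orient[free_idx] = no

        bidx = act[b]
        if bidx.size:
            ub = u[b]
            rl, rr = r_left[b], r_right[b]
            ev_left = ub < rl
            ev_right = (~ev_left) & (ub < rl + rr)
            ev_off = (~ev_left) & (~ev_right) & (ub < rl + rr + koff)
            ev_it = ~(ev_left | ev_right | ev_off)
            site[bidx[ev_left]] -= 1
            site[bidx[ev_right]] += 1
            off_i = bidx[ev_off]
            bound[off_i] = False
            it_i = bidx[ev_it]
            if it_i.size:
                nm, ns, no = land(rng, it_i.size)
                mol[it_i] = nm
                site[it_i] = ns
                orient[it_i] = no

        # Absorption: target reached (probe, site m, designated orientation).
        hit = bound & (mol == 0) & (site == m) & (orient == 0) & ~done
        done[hit] = True

    fpt = t[~censored]
    n_cens = int(censored.sum())
    if fpt.size == 0:
        raise RuntimeError("all trajectories censored; raise max_time")
    mfpt = float(fpt.mean())
    mfpt_se = float(fpt.std(ddof=1) / math.sqrt(fpt.size)) if fpt.size > 1 else math.inf
    k_a = 1.0 / (mfpt * cond.D_tot)
    se = mfpt_se / (mfpt * mfpt * cond.D_tot)
    return GillespieResult(
        k_a=k_a,
        se=se,
        mfpt=mfpt,
        mfpt_se=mfpt_se,
        n_traj=n,
        n_censored=n_cens,
        seed=sim.seed,
        flagged=n_cens > 0.01 * n,
    )
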
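"""Mean-field model of receptor methylation with enzyme localization.

The lattice model averaged over a single, maximally large assistance
neighborhood: every localized enzyme sees the population-mean activity
``a``.  CheR exists in three states — bulk ``R``, tether-bound ``R*`` and
doubly bound ``R**`` (tether + modification site); phosphorylated CheB
(``B_p``, ``B*``, ``B**``) behaves analogously, with unphosphorylated CheB
confined to the bulk.  Local modification-site binding is fast, so the
doubly bound fractions are in quasi-equilibrium,

    R** = R*_tot (1-a) / ((1-a) + K_r),    B** = B*_tot a / (a + K_b),

with dimensionless Michaelis-like constants ``K_r``, ``K_b``.  The mean
methylation per 2N-receptor complex, ``m = M (2N / T_tot)``, follows
Goldbeter-Koshland kinetics driven by the doubly bound enzymes; the
tether-localized pools exchange slowly with the bulk with an
activity-dependent effective unbinding step.  Because dm/dt depends on the
receptors only through ``a``, the model adapts precisely: the stationary
activity ``a0`` is independent of ligand.

Eliminating the localized pools at steady state gives again a
Goldbeter-Koshland balance in terms of *total* enzyme counts with effective
inverse affinities

    K~_r = K_r (1 + k_t-_r / k_t+_r),
    K~_b = K_b (1 + (k_t-_b / k_t+_b)(1 + d_p / (a_p a))),

so slow tether binding (k_t+ << k_t-) keeps the steady state robust
(K~ >~ 1) even when the localized kinetics are saturated (K << 1).

The well-mixed baselines B1/B2 (no tethering, no lattice) live here too:
Goldbeter-Koshland kinetics on total enzyme pools with moderate (B1) or
ten-fold higher (B2) enzyme-substrate affinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .mwc import MWCParams, calibrate, complex_activity
from .reaction_system import NOMINAL_CHEB, NOMINAL_CHER, NOMINAL_DIMERS, RateSet

__all__ = [
    "MeanFieldParams",
    "MeanFieldState",
    "EffectiveConstants",
    "WellMixedParams",
    "bound_enzymes",
    "bulk_cheBp",
    "rhs",
    "steady_state",
    "steady_state_relax",
    "effective_constants",
    "gk_root",
    "b1_rhs",
    "b1_steady_state",
]

_ACT_EPS = 1e-12  # activity clamp keeping rates finite at the boundaries

#: Assistance-neighborhood size entering the local Michaelis constant when
#: mapping simulator rates to the mean-field model.
AN_SIZE = 7


def _clamp(a: float) -> float:
    return min(max(a, _ACT_EPS), 1.0 - _ACT_EPS)


@dataclass(frozen=True)
class MeanFieldParams:
    """Parameters of the localized mean-field model.

    Tether rates are per enzyme (1/s); ``big_k_r``/``big_k_b`` are the
    dimensionless local Michaelis-like constants; ``k_r``/``k_b`` the
    catalytic rates of doubly bound CheR (methylation) and CheB-P
    (demethylation).  Counts are per cell: ``r_tot`` CheR, ``b_tot`` CheB,
    ``t_tot`` receptor monomers (2 per dimer, ``2 n`` per MWC complex).
    """

    k_t_plus_r: float = 1.0 / 15.0
    k_t_minus_r: float = 0.9
    k_t_plus_b: float = 1.0 / 15.0
    k_t_minus_b: float = 0.9
    big_k_r: float = 102.5 / (7 * 200.0)
    big_k_b: float = 103.6 / (7 * 200.0)
    k_r: float = 2.5
    k_b: float = 3.6
    a_p: float = 0.1
    d_p: float = 0.01
    r_tot: float = float(NOMINAL_CHER)
    b_tot: float = float(NOMINAL_CHEB)
    t_tot: float = float(2 * NOMINAL_DIMERS)
    mwc: MWCParams = field(default_factory=calibrate)

    def __post_init__(self) -> None:
        for name in ("k_t_plus_r", "k_t_minus_r", "k_t_plus_b", "k_t_minus_b",
                     "k_r", "k_b", "a_p", "d_p", "r_tot", "b_tot", "t_tot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.big_k_r <= 0 or self.big_k_b <= 0:
            raise ValueError("Michaelis-like constants must be > 0")

    @property
    def n_mwc(self) -> int:
        return int(self.mwc.n_dimers)

    @property
    def n_complexes(self) -> float:
        """T_tot / 2N — the number of MWC complexes."""
        return self.t_tot / (2.0 * self.n_mwc)

    @classmethod
    def from_rate_set(
        cls,
        rates: RateSet,
        r_tot: float = float(NOMINAL_CHER),
        b_tot: float = float(NOMINAL_CHEB),
        t_tot: float = float(2 * NOMINAL_DIMERS),
        mwc: MWCParams | None = None,
        an_size: int = AN_SIZE,
    ) -> "MeanFieldParams":
        """Map simulator rates onto mean-field constants.

        The local Michaelis-like constant aggregates the per-site
        neighborhood binding rate over the ``an_size`` reachable dimers:
        ``K = (k_m_unbind + k_cat) / (an_size * k_m_bind_local)``; catalytic
        and tether rates carry over directly.
        """
        return cls(
            k_t_plus_r=rates.k_t_bind_r,
            k_t_minus_r=rates.k_t_unbind_r,
            k_t_plus_b=rates.k_t_bind_b,
            k_t_minus_b=rates.k_t_unbind_b,
            big_k_r=(rates.k_m_unbind_r + rates.k_cat_r) / (an_size * rates.k_m_bind_local_r),
            big_k_b=(rates.k_m_unbind_b + rates.k_cat_b) / (an_size * rates.k_m_bind_local_b),
            k_r=rates.k_cat_r,
            k_b=rates.k_cat_b,
            a_p=rates.a_p,
            d_p=rates.d_p,
            r_tot=r_tot, b_tot=b_tot, t_tot=t_tot,
            mwc=mwc or calibrate(),
        )

    def scaled(self, multiplier: float) -> "MeanFieldParams":
        """Co-scale all protein counts (expression-level multiplier)."""
        return replace(self, r_tot=self.r_tot * multiplier,
                       b_tot=self.b_tot * multiplier, t_tot=self.t_tot * multiplier)


@dataclass
class MeanFieldState:
    """(m, R*_tot, B*_tot) with the quasi-steady bulk CheB-P count."""

    m: float
    rstar_tot: float
    bstar_tot: float
    b_p: float
    m_in_range: bool = True

    def as_vector(self) -> np.ndarray:
        return np.array([self.m, self.rstar_tot, self.bstar_tot], dtype=float)


@dataclass(frozen=True)
class EffectiveConstants:
    """Effective inverse affinities governing total-ratio sensitivity."""

    k_tilde_r: float
    k_tilde_b: float


def activity(m: float, L: float, params: MeanFieldParams) -> float:
    """Population-mean MWC activity, clamped inside (0, 1)."""
    m = min(max(m, 0.0), 8.0 * params.n_mwc)
    return _clamp(complex_activity(m, L, params.mwc))


def bound_enzymes(rstar_tot: float, bstar_tot: float, a: float,
                  params: MeanFieldParams) -> tuple[float, float]:
    """Doubly bound (tether + modification site) enzyme counts.

    Quasi-equilibrium of the fast local binding step:
    ``R** = R* (1-a)/((1-a)+K_r)``, ``B** = B* a/(a+K_b)``.
    """
    a = _clamp(a)
    rdd = rstar_tot * (1.0 - a) / ((1.0 - a) + params.big_k_r)
    bdd = bstar_tot * a / (a + params.big_k_b)
    return rdd, bdd


def bulk_cheBp(a: float, bstar_tot: float, params: MeanFieldParams) -> float:
    """Quasi-steady bulk CheB-P count.

    Only bulk CheB participates in the phosphorylation cycle (rate
    ``a_p * a`` forward, ``d_p`` back), so with ``phi = a_p a / d_p``:
    ``B_p = phi (B_tot - B*_tot) / (1 + phi)``.
    """
    phi = params.a_p * _clamp(a) / params.d_p
    return phi * (params.b_tot - bstar_tot) / (1.0 + phi)


def rhs(y, L: float, params: MeanFieldParams) -> np.ndarray:
    """Time derivatives of (m, R*_tot, B*_tot)."""
    m, rstar, bstar = float(y[0]), float(y[1]), float(y[2])
    p = params
    a = activity(m, L, p)
    rdd, bdd = bound_enzymes(rstar, bstar, a, p)
    b_p = bulk_cheBp(a, bstar, p)
    inv_c = 1.0 / p.n_complexes  # = 2N / T_tot
    dm = inv_c * (p.k_r * rdd - p.k_b * bdd)
    drstar = p.k_t_plus_r * (p.r_tot - rstar) \
        - p.k_t_minus_r * rstar * p.big_k_r / ((1.0 - a) + p.big_k_r)
    dbstar = p.k_t_plus_b * b_p \
        - p.k_t_minus_b * bstar * p.big_k_b / (a + p.big_k_b)
    return np.array([dm, drstar, dbstar], dtype=float)


def _balance(a: float, params: MeanFieldParams) -> float:
    """Net methylation velocity at stationary localized pools, as f(a)."""
    p = params
    eff = effective_constants(p, a)
    v_up = p.k_r * p.r_tot * (1.0 - a) / ((1.0 - a) + eff.k_tilde_r)
    v_dn = p.k_b * p.b_tot * a / (a + eff.k_tilde_b)
    return v_up - v_dn


def _state_at(a0: float, L: float, params: MeanFieldParams) -> MeanFieldState:
    p = params
    a0 = _clamp(a0)
    # invert the MWC relation for the stationary methylation
    lig = p.n_mwc * (np.log1p(L / p.mwc.k_off) - np.log1p(L / p.mwc.k_on))
    m0 = p.mwc.m_half + (lig - np.log((1.0 - a0) / a0)) / p.mwc.eps_m
    in_range = 0.0 <= m0 <= 8.0 * p.n_mwc
    rstar = p.k_t_plus_r * p.r_tot / (
        p.k_t_plus_r + p.k_t_minus_r * p.big_k_r / ((1.0 - a0) + p.big_k_r)
    )
    phi = p.a_p * a0 / p.d_p
    alpha = p.k_t_plus_b * phi / (1.0 + phi)
    beta = p.k_t_minus_b * p.big_k_b / (a0 + p.big_k_b)
    bstar = alpha * p.b_tot / (alpha + beta) if (alpha + beta) > 0 else 0.0
    return MeanFieldState(
        m=float(m0), rstar_tot=float(rstar), bstar_tot=float(bstar),
        b_p=float(bulk_cheBp(a0, bstar, p)), m_in_range=bool(in_range),
    )


def steady_state(L: float, params: MeanFieldParams,
                 verify: bool = False) -> tuple[float, MeanFieldState]:
    """Stationary point of the localized model.

    ``a0`` solves the effective Goldbeter-Koshland balance (independent of
    ``L`` — precise adaptation); the stationary methylation ``m0`` absorbs
    the ligand free energy.  ``m_in_range`` is False when the required
    methylation exceeds the physical range [0, 8N] ("nonfunctional" — the
    stimulus exceeds the adaptable range).

    With ``verify=True`` the root is cross-checked against long ODE
    relaxation (agreement to 1e-8 in ``a0``).
    """
    lo, hi = _ACT_EPS, 1.0 - _ACT_EPS
    f_lo, f_hi = _balance(lo, params), _balance(hi, params)
    if not (f_lo > 0 > f_hi):
        raise RuntimeError(
            "no interior steady state: system pinned fully "
            f"{'active' if f_lo > 0 else 'inactive'} (nonfunctional regime)"
        )
    a0 = brentq(_balance, lo, hi, args=(params,), xtol=1e-14, rtol=1e-15)
    state = _state_at(a0, L, params)
    if verify:
        a_relax, _ = steady_state_relax(L, params)
        if abs(a_relax - a0) > 1e-8:
            raise RuntimeError(
                f"root/relaxation cross-check failed: {a0} vs {a_relax}"
            )
    return float(a0), state


def steady_state_relax(L: float, params: MeanFieldParams,
                       t_max: float = 2.0e4) -> tuple[float, MeanFieldState]:
    """Steady state by long ODE relaxation (independent cross-check path)."""
    p = params
    y0 = np.array([p.mwc.m_half, 0.25 * p.r_tot, 0.1 * p.b_tot])
    sol = solve_ivp(
        lambda t, y: rhs(y, L, p), (0.0, t_max), y0,
        method="LSODA", rtol=1e-12, atol=1e-10,
    )
    y = sol.y[:, -1]
    a0 = activity(y[0], L, p)
    return float(a0), MeanFieldState(
        m=float(y[0]), rstar_tot=float(y[1]), bstar_tot=float(y[2]),
        b_p=float(bulk_cheBp(a0, y[2], p)),
        m_in_range=bool(0.0 <= y[0] <= 8.0 * p.n_mwc),
    )


def effective_constants(params: MeanFieldParams, a: float) -> EffectiveConstants:
    """Effective inverse affinities of the total-enzyme balance.

    Obtained by eliminating the localized pools at stationarity:
    ``K~_r = K_r (1 + k_t-/k_t+)`` and, for CheB-P, the same with the
    phosphorylation feedback factor ``(1 + d_p/(a_p a))``.  Localization can
    only reduce the effective affinity (``K~ >= K``); ``K~ >~ 1`` marks the
    robust regime.
    """
    p = params
    a = _clamp(a)
    k_tilde_r = p.big_k_r * (1.0 + p.k_t_minus_r / p.k_t_plus_r)
    k_tilde_b = p.big_k_b * (
        1.0 + (p.k_t_minus_b / p.k_t_plus_b) * (1.0 + p.d_p / (p.a_p * a))
    )
    return EffectiveConstants(k_tilde_r=float(k_tilde_r), k_tilde_b=float(k_tilde_b))


def gk_root(ratio: float, k1: float, k2: float) -> float:
    """Admissible root in (0, 1) of the Goldbeter-Koshland balance.

    Solves ``ratio * (1-a)/((1-a)+k1) = a/(a+k2)``; ``ratio`` is the
    forward/backward maximal-velocity ratio.  Monotone increasing in
    ``ratio``; small ``k1, k2`` give the zero-order ultrasensitive regime.
    """
    if ratio <= 0 or k1 <= 0 or k2 <= 0:
        raise ValueError("ratio, k1, k2 must be > 0")
    v = ratio
    # quadratic a^2 (1 - v) + a (v - 1 - v k2 - k1) + v k2 = 0
    A = 1.0 - v
    B = v - 1.0 - v * k2 - k1
    C = v * k2
    if abs(A) < 1e-14:
        # ratio -> 1: the quadratic degenerates to a linear balance
        return float(-C / B)
    disc = B * B - 4.0 * A * C
    disc = max(disc, 0.0)
    sq = np.sqrt(disc)
    # numerically stable pair of roots
    q = -0.5 * (B + np.copysign(sq, B))
    roots = [q / A, C / q] if q != 0 else [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
    valid = [r for r in roots if 0.0 <= r <= 1.0]
    if not valid:
        raise RuntimeError(f"no Goldbeter-Koshland root in [0,1] for {ratio}, {k1}, {k2}")
    return float(min(valid, key=lambda r: abs(r - 0.5)) if len(valid) > 1 else valid[0])


# --------------------------------------------------------------------------
# well-mixed baselines (B1/B2)

@dataclass(frozen=True)
class WellMixedParams:
    """Baseline without tethering or lattice structure.

    Activity-dependent Michaelis binding of total enzyme pools to the
    modification sites, the CheB phosphorylation feedback retained with a
    quasi-steady bulk CheB-P pool.  B2 derives from B1 by a ten-fold
    affinity increase (``big_k`` divided by 10).
    """

    k_r: float = 1.45
    k_b: float = 1.7
    big_k_r: float = 0.5
    big_k_b: float = 0.5
    a_p: float = 0.1
    d_p: float = 0.01
    r_tot: float = float(NOMINAL_CHER)
    b_tot: float = float(NOMINAL_CHEB)
    t_tot: float = float(2 * NOMINAL_DIMERS)
    mwc: MWCParams = field(default_factory=calibrate)

    @property
    def n_mwc(self) -> int:
        return int(self.mwc.n_dimers)

    @property
    def n_complexes(self) -> float:
        return self.t_tot / (2.0 * self.n_mwc)

    def as_b2(self, affinity_factor: float = 10.0) -> "WellMixedParams":
        return replace(self, big_k_r=self.big_k_r / affinity_factor,
                       big_k_b=self.big_k_b / affinity_factor)

    def scaled(self, multiplier: float) -> "WellMixedParams":
        return replace(self, r_tot=self.r_tot * multiplier,
                       b_tot=self.b_tot * multiplier, t_tot=self.t_tot * multiplier)


def b1_velocities(a: float, params: WellMixedParams) -> tuple[float, float]:
    p = params
    a = _clamp(a)
    phi = p.a_p * a / p.d_p
    b_p = phi * p.b_tot / (1.0 + phi)
    v_up = p.k_r * p.r_tot * (1.0 - a) / ((1.0 - a) + p.big_k_r)
    v_dn = p.k_b * b_p * a / (a + p.big_k_b)
    return v_up, v_dn


def b1_rhs(m: float, L: float, params: WellMixedParams) -> float:
    """dm/dt of the well-mixed baseline (per-complex methylation units)."""
    a = _clamp(complex_activity(min(max(m, 0.0), 8.0 * params.n_mwc), L, params.mwc))
    v_up, v_dn = b1_velocities(a, params)
    return (v_up - v_dn) / params.n_complexes


def b1_steady_state(L: float, params: WellMixedParams) -> tuple[float, float]:
    """(a0, m0) of the well-mixed baseline; a0 is ligand-independent."""
    def g(a):
        v_up, v_dn = b1_velocities(a, params)
        return v_up - v_dn

    lo, hi = _ACT_EPS, 1.0 - _ACT_EPS
    if not (g(lo) > 0 > g(hi)):
        raise RuntimeError("no interior steady state for the well-mixed baseline")
    a0 = brentq(g, lo, hi, args=(), xtol=1e-14, rtol=1e-15)
    p = params
    lig = p.n_mwc * (np.log1p(L / p.mwc.k_off) - np.log1p(L / p.mwc.k_on))
    m0 = p.mwc.m_half + (lig - np.log((1.0 - a0) / a0)) / p.mwc.eps_m
    return float(a0), float(m0)
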
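"""Linear noise approximation around the mean-field steady state.

Small displacements x = (delta m, delta R*, delta B*) from the stationary
point obey the Ito system dx = A x dt + B dW with Jacobian A and diffusion
D = B^T B = S diag(v) S^T assembled from the elementary noise-carrying
events (methylation/demethylation of single sites, tether bind/unbind of
single CheR and CheB-P molecules) at their stationary propensities.  The
stationary covariance of this multivariate Ornstein-Uhlenbeck process
solves the Lyapunov equation A sigma + sigma A^T + D = 0.

The variance of the output activity is sigma_aa = (da/dm)^2 sigma_mm, and
because the Lyapunov equation is linear in D, sigma_aa decomposes exactly
into contributions from the three noise channels: CheR tether exchange,
CheB-P tether exchange, and intrinsic methylation shot noise.  The bulk
CheB-P pool is adiabatically eliminated before linearization (consistent
with the mean-field reduction); its fluctuations fold into the CheB
channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .meanfield import (
    MeanFieldParams,
    MeanFieldState,
    WellMixedParams,
    activity,
    b1_steady_state,
    b1_velocities,
    bound_enzymes,
    bulk_cheBp,
    rhs,
    steady_state,
)

__all__ = [
    "LinearizedSystem",
    "CovarianceResult",
    "linearize",
    "solve_lyapunov",
    "activity_variance",
    "noise_analysis",
    "b1_noise",
    "simulate_langevin",
]

# noise-channel order (columns of S): methylation +/-, CheR tether +/-,
# CheB-P tether +/-
CHANNEL_GROUPS = {"r": (2, 3), "b": (4, 5), "m": (0, 1)}


@dataclass
class LinearizedSystem:
    """Jacobian, stoichiometry and stationary propensities at the fixed point."""

    A: np.ndarray            # (3, 3) Jacobian, state order (m, R*, B*)
    S: np.ndarray            # (3, 6) stoichiometry of elementary events
    v: np.ndarray            # (6,) stationary propensities
    a0: float
    steady: MeanFieldState
    params: MeanFieldParams

    @property
    def D(self) -> np.ndarray:
        return self.S @ np.diag(self.v) @ self.S.T

    def D_channel(self, group: str) -> np.ndarray:
        cols = CHANNEL_GROUPS[group]
        s = self.S[:, cols]
        return s @ np.diag(self.v[list(cols)]) @ s.T


@dataclass
class CovarianceResult:
    """Stationary covariance and the activity-variance decomposition."""

    sigma: np.ndarray
    sigma_aa: float
    parts: tuple[float, float, float]   # (CheR, CheB-P, methylation) channels
    rel_noise: float
    a0: float


def linearize(params: MeanFieldParams, L: float = 0.0,
              steady: tuple[float, MeanFieldState] | None = None) -> LinearizedSystem:
    """Analytic Jacobian and diffusion matrix at the steady state."""
    p = params
    a0, st = steady if steady is not None else steady_state(L, p)
    m0, rstar, bstar = st.m, st.rstar_tot, st.bstar_tot
    kr_, kb_ = p.big_k_r, p.big_k_b
    inv_c = 1.0 / p.n_complexes

    u = (1.0 - a0) / ((1.0 - a0) + kr_)          # doubly bound CheR fraction
    w = a0 / (a0 + kb_)                          # doubly bound CheB-P fraction
    du = -kr_ / ((1.0 - a0) + kr_) ** 2
    dw = kb_ / (a0 + kb_) ** 2
    q_r = kr_ / ((1.0 - a0) + kr_)               # tether-only CheR fraction
    q_b = kb_ / (a0 + kb_)
    dq_r = kr_ / ((1.0 - a0) + kr_) ** 2
    dq_b = -kb_ / (a0 + kb_) ** 2
    g_prime = p.mwc.eps_m * a0 * (1.0 - a0)      # da/dm at the fixed point

    phi = p.a_p * a0 / p.d_p
    dphi = p.a_p / p.d_p
    b_p = bulk_cheBp(a0, bstar, p)
    dbp_da = dphi * (p.b_tot - bstar) / (1.0 + phi) ** 2
    dbp_dbstar = -phi / (1.0 + phi)

    A = np.empty((3, 3), dtype=float)
    A[0, 0] = inv_c * (p.k_r * rstar * du - p.k_b * bstar * dw) * g_prime
    A[0, 1] = inv_c * p.k_r * u
    A[0, 2] = -inv_c * p.k_b * w
    A[1, 0] = -p.k_t_minus_r * rstar * dq_r * g_prime
    A[1, 1] = -p.k_t_plus_r - p.k_t_minus_r * q_r
    A[1, 2] = 0.0
    A[2, 0] = (p.k_t_plus_b * dbp_da - p.k_t_minus_b * bstar * dq_b) * g_prime
    A[2, 1] = 0.0
    A[2, 2] = p.k_t_plus_b * dbp_dbstar - p.k_t_minus_b * q_b

    rdd, bdd = bound_enzymes(rstar, bstar, a0, p)
    v = np.array([
        p.k_r * rdd,                          # methylation events (+1 site)
        p.k_b * bdd,                          # demethylation events (-1 site)
        p.k_t_plus_r * (p.r_tot - rstar),     # CheR localization (+1)
        p.k_t_minus_r * rstar * q_r,          # CheR delocalization (-1)
        p.k_t_plus_b * b_p,                   # CheB-P localization (+1)
        p.k_t_minus_b * bstar * q_b,          # CheB-P delocalization (-1)
    ], dtype=float)
    S = np.array([
        [inv_c, -inv_c, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, -1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, -1.0],
    ], dtype=float)
    return LinearizedSystem(A=A, S=S, v=v, a0=float(a0), steady=st, params=p)


def solve_lyapunov(A: np.ndarray, D: np.ndarray,
                   residual_tol: float = 1e-10) -> np.ndarray:
    """Stationary OU covariance: solve A sigma + sigma A^T + D = 0.

    Requires A Hurwitz; verifies the residual and symmetrizes the result.
    """
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise RuntimeError(f"A is not Hurwitz (eigenvalues {eig})")
    sigma = solve_continuous_lyapunov(A, -np.asarray(D, dtype=float))
    sigma = 0.5 * (sigma + sigma.T)
    resid = A @ sigma + sigma @ A.T + D
    scale = max(1.0, float(np.abs(D).max()))
    if float(np.abs(resid).max()) > residual_tol * scale:
        raise RuntimeError("Lyapunov residual above tolerance")
    return sigma


def activity_variance(lin: LinearizedSystem) -> CovarianceResult:
    """Activity variance and its exact three-channel decomposition.

    Each part solves the Lyapunov equation with the diffusion matrix
    restricted to one channel's columns; linearity in D makes the parts sum
    to the full solution (to solver precision).
    """
    sigma = solve_lyapunov(lin.A, lin.D)
    g_prime = lin.params.mwc.eps_m * lin.a0 * (1.0 - lin.a0)
    sigma_aa = g_prime ** 2 * sigma[0, 0]
    parts = []
    for group in ("r", "b", "m"):
        s_g = solve_lyapunov(lin.A, lin.D_channel(group))
        parts.append(g_prime ** 2 * s_g[0, 0])
    rel = float(np.sqrt(max(sigma_aa, 0.0)) / lin.a0)
    return CovarianceResult(
        sigma=sigma, sigma_aa=float(sigma_aa),
        parts=(float(parts[0]), float(parts[1]), float(parts[2])),
        rel_noise=rel, a0=lin.a0,
    )


def noise_analysis(params: MeanFieldParams, L: float = 0.0) -> CovarianceResult:
    """Steady state -> linearization -> Lyapunov solve, in one call."""
    return activity_variance(linearize(params, L))


def b1_noise(params: WellMixedParams, L: float = 0.0) -> CovarianceResult:
    """One-dimensional LNA of the well-mixed baseline.

    The only noise channel is methylation shot noise; the scalar OU
    stationary variance is D / (2 |lambda|).
    """
    a0, m0 = b1_steady_state(L, params)
    p = params
    inv_c = 1.0 / p.n_complexes
    g_prime = p.mwc.eps_m * a0 * (1.0 - a0)
    h = 1e-7
    lam = (b1_dmdt_of_a(a0 + h, p) - b1_dmdt_of_a(a0 - h, p)) / (2 * h) * g_prime
    if lam >= 0:
        raise RuntimeError("well-mixed baseline not linearly stable")
    v_up, v_dn = b1_velocities(a0, p)
    D = inv_c ** 2 * (v_up + v_dn)
    sigma_mm = D / (2.0 * abs(lam))
    sigma_aa = g_prime ** 2 * sigma_mm
    return CovarianceResult(
        sigma=np.array([[sigma_mm]]), sigma_aa=float(sigma_aa),
        parts=(0.0, 0.0, float(sigma_aa)),
        rel_noise=float(np.sqrt(sigma_aa) / a0), a0=float(a0),
    )


def b1_dmdt_of_a(a: float, params: WellMixedParams) -> float:
    v_up, v_dn = b1_velocities(a, params)
    return (v_up - v_dn) / params.n_complexes


def simulate_langevin(
    params: MeanFieldParams,
    duration: float,
    dt: float,
    seed: int,
    L: float = 0.0,
    record_every: int = 10,
    initial: MeanFieldState | None = None,
) -> dict:
    """Euler-Maruyama integration of the nonlinear mean-field SDE.

    State-dependent noise amplitudes are rebuilt each step from the same
    elementary-event propensities used by the LNA; serves as the
    independent simulation oracle for the Lyapunov solution.
    """
    p = params
    a0, st = steady_state(L, p)
    y = (initial.as_vector() if initial is not None else st.as_vector()).copy()
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    n_rec = n_steps // record_every
    out_t = np.empty(n_rec)
    out_y = np.empty((n_rec, 3))
    out_a = np.empty(n_rec)
    inv_c = 1.0 / p.n_complexes
    sqdt = np.sqrt(dt)
    j = 0
    for i in range(n_steps):
        a = activity(y[0], L, p)
        rdd, bdd = bound_enzymes(y[1], y[2], a, p)
        b_p = bulk_cheBp(a, y[2], p)
        q_r = p.big_k_r / ((1.0 - a) + p.big_k_r)
        q_b = p.big_k_b / (a + p.big_k_b)
        v = np.array([
            p.k_r * rdd, p.k_b * bdd,
            p.k_t_plus_r * (p.r_tot - y[1]), p.k_t_minus_r * y[1] * q_r,
            p.k_t_plus_b * b_p, p.k_t_minus_b * y[2] * q_b,
        ])
        v = np.maximum(v, 0.0)
        drift = rhs(y, L, p)
        xi = rng.standard_normal(6)
        amp = np.sqrt(v) * xi
        y[0] += drift[0] * dt + inv_c * (amp[0] - amp[1]) * sqdt
        y[1] += drift[1] * dt + (amp[2] - amp[3]) * sqdt
        y[2] += drift[2] * dt + (amp[4] - amp[5]) * sqdt
        y[1] = min(max(y[1], 0.0), p.r_tot)
        y[2] = min(max(y[2], 0.0), p.b_tot)
        y[0] = min(max(y[0], 0.0), 8.0 * p.n_mwc)
        if (i + 1) % record_every == 0 and j < n_rec:
            out_t[j] = (i + 1) * dt
            out_y[j] = y
            out_a[j] = activity(y[0], L, p)
            j += 1
    return {"t": out_t[:j], "y": out_y[:j], "activity": out_a[:j], "a0": a0}
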
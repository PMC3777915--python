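"""Equilibrium Monod-Wyman-Changeux activity of a chemoreceptor signaling complex.

A signaling complex of ``n_dimers`` receptor dimers switches cooperatively
between an active and an inactive conformation.  The free-energy difference
``F`` (in units of kT) between the two states decreases by ``eps_m`` per
methyl group carried by the complex and increases with attractant ligand
``L`` through the standard MWC log-occupancy term.  The fraction of time the
complex spends active is the Boltzmann probability ``a = 1/(1 + exp(F))``.

Because ligand (un)binding and conformational switching are fast compared
with the methylation kinetics, activity is treated as an instantaneous
equilibrium property of the current methylation state.  This module is
shared by the lattice simulator (per-complex activity) and by the mean-field
model (population-average activity).

Conventions
-----------
* ``m_total`` is the summed methylation of all dimers in the complex.  Each
  dimer carries 0-8 methyl groups, so ``m_total`` ranges over ``[0, 8 n]``.
* Energies are in kT; ligand concentrations in micromolar (attractant
  methyl-aspartate sensed by the Tar receptor).
* ``k_off < k_on``: the inactive state binds attractant more tightly, so
  ligand stabilizes the inactive state (activity decreases with ``L``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["MWCParams", "free_energy", "complex_activity", "calibrate", "activity_table"]

#: Default free-energy decrement per methyl group (kT).  Together with the
#: anchor a(6, 0) = 0.5 this reproduces dose-response-style calibrations of
#: the Tar/MeAsp system while leaving enough methylation range (8 * 6 = 48)
#: to absorb the ligand free energy of a 1 mM methyl-aspartate stimulus.
DEFAULT_EPS_M = 0.6
#: Tar/MeAsp dissociation constants (uM), dose-response-style calibration:
#: inactive-state (high-affinity) and active-state (low-affinity).
DEFAULT_K_OFF = 18.0
DEFAULT_K_ON = 3000.0
#: Calibration anchor: complex methylation level at which the free energy
#: vanishes in the absence of stimulus (a = 0.5 at m_total = 6 out of 48).
ANCHOR_M = 6.0


@dataclass(frozen=True)
class MWCParams:
    """Allosteric parameters of one signaling complex.

    Attributes
    ----------
    n_dimers:
        Receptor dimers per cooperative complex (6 for the standard lattice).
    eps_m:
        Free-energy decrement per methyl group (kT), > 0.
    m_half:
        Complex methylation at which F = 0 at zero ligand (calibration
        offset housing the free-energy intercept).
    k_off, k_on:
        Ligand dissociation constants (uM) of the inactive and active
        conformations; ``0 < k_off < k_on`` for an attractant.
    """

    n_dimers: int = 6
    eps_m: float = DEFAULT_EPS_M
    m_half: float = ANCHOR_M
    k_off: float = DEFAULT_K_OFF
    k_on: float = DEFAULT_K_ON

    def __post_init__(self) -> None:
        if int(self.n_dimers) != self.n_dimers or self.n_dimers < 1:
            raise ValueError(f"n_dimers must be a positive integer, got {self.n_dimers}")
        if not self.eps_m > 0:
            raise ValueError(f"eps_m must be > 0, got {self.eps_m}")
        if not (0 < self.k_off < self.k_on):
            raise ValueError(
                f"attractant convention requires 0 < k_off < k_on, got {self.k_off}, {self.k_on}"
            )
        if not (0 <= self.m_half <= 8 * self.n_dimers):
            raise ValueError(f"m_half must lie in [0, {8 * self.n_dimers}], got {self.m_half}")

    @property
    def m_max(self) -> int:
        return 8 * int(self.n_dimers)


def _check_inputs(m_total, L, params: MWCParams) -> None:
    m = np.asarray(m_total, dtype=float)
    lig = np.asarray(L, dtype=float)
    if np.any(m < 0) or np.any(m > params.m_max):
        raise ValueError(f"m_total outside [0, {params.m_max}]")
    if np.any(lig < 0):
        raise ValueError("ligand concentration must be non-negative")


def free_energy(m_total, L, params: MWCParams):
    """Free-energy difference F (kT) between active and inactive states.

    ``F = eps_m * (m_half - m_total) + n * ln[(1 + L/k_off)/(1 + L/k_on)]``.
    Strictly decreasing in ``m_total``, strictly increasing in ``L``.
    """
    _check_inputs(m_total, L, params)
    m = np.asarray(m_total, dtype=float)
    lig = np.asarray(L, dtype=float)
    f = params.eps_m * (params.m_half - m) + params.n_dimers * (
        np.log1p(lig / params.k_off) - np.log1p(lig / params.k_on)
    )
    return f if f.ndim else float(f)


def complex_activity(m_total, L, params: MWCParams):
    """Probability that the complex is active: ``1 / (1 + exp(F))`` in (0, 1)."""
    f = free_energy(m_total, L, params)
    a = 1.0 / (1.0 + np.exp(f))
    return a if np.ndim(a) else float(a)


def calibrate(
    n_dimers: int = 6,
    eps_m: float = DEFAULT_EPS_M,
    k_off: float = DEFAULT_K_OFF,
    k_on: float = DEFAULT_K_ON,
) -> MWCParams:
    """Return parameters with the offset fixed by the zero-stimulus anchor.

    The free-energy intercept is pinned by requiring
    ``complex_activity(6, 0) = 0.5`` (half activation at one methyl group
    per dimer of a 6-dimer complex), i.e. ``m_half = 6``.
    """
    return MWCParams(n_dimers=n_dimers, eps_m=eps_m, m_half=ANCHOR_M, k_off=k_off, k_on=k_on)


def activity_table(L: float, params: MWCParams) -> np.ndarray:
    """Activity at every integer complex methylation 0..8*n (lookup table).

    Used by the stochastic kernel: between ligand updates the activity of a
    complex is a pure function of its integer methylation level.
    """
    m = np.arange(params.m_max + 1, dtype=float)
    return np.asarray(complex_activity(m, float(L), params), dtype=np.float64)


def with_anchor(params: MWCParams, m_half: float) -> MWCParams:
    """Copy of ``params`` with a different free-energy offset."""
    return replace(params, m_half=m_half)
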
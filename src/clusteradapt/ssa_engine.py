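"""Exact stochastic simulation of the lattice model under ligand protocols.

Thin, typed wrappers around the compiled Gillespie core: they marshal the
dataclasses of :mod:`clusteradapt.reaction_system` into flat arrays, run the
kernel, and wrap the output in :class:`Trace`.  Identical inputs (geometry,
parameters, protocol, seed) give bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .lattice import LatticeGeometry
from .mwc import MWCParams
from .reaction_system import (
    CopyNumbers,
    RateSet,
    SystemState,
    VariantFlags,
    init_state,
)

__all__ = ["LigandProtocol", "Trace", "simulate", "equilibrate", "simulate_wellmixed"]

_EVENT_NAMES = (
    "tether_bind_bulk", "mod_bind_bulk", "mod_bind_local", "tether_bind_local",
    "tether_unbind", "mod_unbind", "catalysis_R", "catalysis_B",
    "phosphorylate", "dephosphorylate",
)


@dataclass(frozen=True)
class LigandProtocol:
    """Time course of the attractant concentration (uM).

    kind ``constant``: L = L0 throughout.
    kind ``step``: L0 before ``t_step``, L1 after (e.g. 5 uM or 1000 uM
    steps applied at t = 200 s).
    kind ``exponential_ramp``: from ``t_step`` on, ``L = L0 exp(r (t -
    t_step))`` clipped to ``[L_min, L_max]`` (the ramp-calibration window
    84-620 uM); updated on the recording grid.
    """

    kind: str = "constant"
    L0: float = 0.0
    L1: float = 0.0
    t_step: float = 0.0
    ramp_rate: float = 0.0
    L_min: float = 84.0
    L_max: float = 620.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "exponential_ramp"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if min(self.L0, self.L1, self.L_min, self.L_max) < 0:
            raise ValueError("ligand concentrations must be non-negative")
        if self.kind == "exponential_ramp" and not (self.L_min <= self.L_max):
            raise ValueError("ramp bounds must be ordered")

    @classmethod
    def constant(cls, L: float = 0.0) -> "LigandProtocol":
        return cls("constant", L0=L)

    @classmethod
    def step(cls, L1: float, t_step: float = 200.0, L0: float = 0.0) -> "LigandProtocol":
        return cls("step", L0=L0, L1=L1, t_step=t_step)

    @classmethod
    def ramp(cls, rate: float, L0: float = 84.0, t_start: float = 0.0,
             L_min: float = 84.0, L_max: float = 620.0) -> "LigandProtocol":
        return cls("exponential_ramp", L0=L0, t_step=t_start, ramp_rate=rate,
                   L_min=L_min, L_max=L_max)

    def _packed(self):
        kind = {"constant": _kernel.PROTO_CONST, "step": _kernel.PROTO_STEP,
                "exponential_ramp": _kernel.PROTO_RAMP}[self.kind]
        return (kind, float(self.L0), float(self.L1), float(self.t_step),
                float(self.ramp_rate), float(self.L_min), float(self.L_max))

    def ligand_at(self, t) -> np.ndarray:
        """Ligand level at time(s) ``t`` (vectorized convenience)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.L0)
        if self.kind == "step":
            return np.where(t >= self.t_step, self.L1, self.L0)
        L = self.L0 * np.exp(self.ramp_rate * np.maximum(t - self.t_step, 0.0))
        return np.where(t < self.t_step, self.L0, np.clip(L, self.L_min, self.L_max))


@dataclass
class Trace:
    """Recorded time series of one stochastic run."""

    t: np.ndarray
    activity: np.ndarray
    m_per_complex: np.ndarray
    localized_cheR: np.ndarray
    localized_cheBp: np.ndarray
    bulk_cheBp: np.ndarray
    inert_cheR: np.ndarray
    inert_cheBp: np.ndarray
    event_counts: dict = field(default_factory=dict)
    visit_log: pd.DataFrame | None = None
    final_state: SystemState | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "activity": self.activity,
            "m_per_complex": self.m_per_complex,
            "localized_cheR": self.localized_cheR,
            "localized_cheBp": self.localized_cheBp,
            "bulk_cheBp": self.bulk_cheBp,
            "inert_cheR": self.inert_cheR,
            "inert_cheBp": self.inert_cheBp,
        })


def pack_rates(rates: RateSet) -> np.ndarray:
    vec = np.zeros(_kernel.N_RATES, dtype=np.float64)
    vec[_kernel.R_T_BIND_R] = rates.k_t_bind_r
    vec[_kernel.R_T_BIND_B] = rates.k_t_bind_b
    vec[_kernel.R_M_BIND_BULK_R] = rates.k_m_bind_bulk_r
    vec[_kernel.R_M_BIND_BULK_B] = rates.k_m_bind_bulk_b
    vec[_kernel.R_T_UNBIND_R] = rates.k_t_unbind_r
    vec[_kernel.R_T_UNBIND_B] = rates.k_t_unbind_b
    vec[_kernel.R_M_BIND_LOC_R] = rates.k_m_bind_local_r
    vec[_kernel.R_M_BIND_LOC_B] = rates.k_m_bind_local_b
    vec[_kernel.R_T_BIND_LOC_R] = rates.k_t_bind_local_r
    vec[_kernel.R_T_BIND_LOC_B] = rates.k_t_bind_local_b
    vec[_kernel.R_M_UNBIND_R] = rates.k_m_unbind_r
    vec[_kernel.R_M_UNBIND_B] = rates.k_m_unbind_b
    vec[_kernel.R_CAT_R] = rates.k_cat_r
    vec[_kernel.R_CAT_B] = rates.k_cat_b
    vec[_kernel.R_A_P] = rates.a_p
    vec[_kernel.R_D_P] = rates.d_p
    return vec


def simulate(
    geometry: LatticeGeometry,
    rates: RateSet,
    flags: VariantFlags,
    mwc_params: MWCParams,
    copy_numbers: CopyNumbers,
    protocol: LigandProtocol,
    duration: float,
    seed: int,
    record_dt: float = 0.1,
    initial_state: SystemState | None = None,
    initial_methyl: int = 1,
    log_visits: bool = False,
    log_cap: int = 5_000_000,
    resync_every: int = 200_000,
    check_consistency: bool = False,
) -> Trace:
    """Run one exact SSA trajectory and return its recorded trace.

    ``initial_state`` (e.g. from :func:`equilibrate`) overrides the uniform
    initial condition; it is copied, never mutated.  ``seed`` drives a
    dedicated deterministic stream.
    """
    if duration <= 0 or record_dt <= 0:
        raise ValueError("duration and record_dt must be positive")
    if mwc_params.n_dimers != geometry.dimers_per_complex:
        raise ValueError(
            f"MWC n_dimers={mwc_params.n_dimers} does not match geometry "
            f"complex size {geometry.dimers_per_complex}"
        )
    state = (initial_state.copy() if initial_state is not None
             else init_state(geometry, copy_numbers, initial_methyl))
    if state.n_r != copy_numbers.che_r or state.n_b != copy_numbers.che_b:
        raise ValueError("initial_state enzyme counts disagree with copy_numbers")

    out = _kernel.run_lattice_ssa(
        geometry.neighbors, geometry.n_neighbors, geometry.complex_of,
        geometry.n_complexes,
        state.methyl, state.enz_teth, state.enz_mod, state.b_phos,
        state.n_r, state.n_b,
        pack_rates(rates), flags.neighbor_binding, float(flags.tether_unbind_scale),
        rates.release_on_catalysis,
        float(mwc_params.eps_m), float(mwc_params.m_half),
        float(mwc_params.n_dimers), float(mwc_params.k_off), float(mwc_params.k_on),
        *protocol._packed(),
        float(duration), float(record_dt), np.uint64(seed),
        log_visits, log_cap, resync_every, check_consistency,
    )
    (rec_t, rec_a, rec_m, loc_r, loc_bp, bulk_bp, inert_r, inert_bp,
     log_enz, log_dimer, log_time, ev_counts, status) = out
    if status == 1:
        raise RuntimeError("propensity sum became non-finite; state dump in final_state")
    if status == 2:
        raise RuntimeError("internal aggregate consistency check failed")
    if status == 3:
        raise RuntimeError(f"visit log overflowed its capacity ({log_cap})")

    visit_log = None
    if log_visits:
        visit_log = pd.DataFrame({
            "enzyme": log_enz, "dimer": log_dimer, "t": log_time,
        })
        visit_log["species"] = np.where(visit_log["enzyme"] < state.n_r, "CheR", "CheB-P")
    return Trace(
        t=rec_t, activity=rec_a, m_per_complex=rec_m,
        localized_cheR=loc_r, localized_cheBp=loc_bp, bulk_cheBp=bulk_bp,
        inert_cheR=inert_r, inert_cheBp=inert_bp,
        event_counts=dict(zip(_EVENT_NAMES, (int(x) for x in ev_counts))),
        visit_log=visit_log,
        final_state=state,
        meta={
            "variant": flags.name, "seed": int(seed), "duration": float(duration),
            "record_dt": float(record_dt), "n_dimers": geometry.n_dimers,
            "che_r": copy_numbers.che_r, "che_b": copy_numbers.che_b,
            "protocol": protocol.kind,
        },
    )


def equilibrate(
    geometry: LatticeGeometry,
    rates: RateSet,
    flags: VariantFlags,
    mwc_params: MWCParams,
    copy_numbers: CopyNumbers,
    duration: float,
    seed: int,
    burn_in: float = 500.0,
    L: float = 0.0,
    record_dt: float = 0.1,
    **kwargs,
) -> tuple[SystemState, Trace]:
    """Burn in at constant ligand, then record a stationary trace.

    Returns the post-burn-in state and the post-burn-in trace.  A burn-in
    short relative to the ~15 s tether-exchange time (or zero) is flagged
    in the trace metadata rather than rejected.
    """
    proto = LigandProtocol.constant(L)
    trace = None
    state = kwargs.pop("initial_state", None)
    if burn_in > 0:
        warm = simulate(
            geometry, rates, flags, mwc_params, copy_numbers, proto,
            duration=burn_in, seed=seed, record_dt=record_dt,
            initial_state=state, **kwargs,
        )
        state = warm.final_state
    trace = simulate(
        geometry, rates, flags, mwc_params, copy_numbers, proto,
        duration=duration, seed=seed + 1, record_dt=record_dt,
        initial_state=state, **kwargs,
    )
    trace.meta["burn_in"] = float(burn_in)
    if burn_in < 150.0:
        trace.meta["burn_in_warning"] = (
            "burn-in shorter than ~10 tether-exchange times; trace may not be stationary"
        )
    return trace.final_state, trace


def simulate_wellmixed(
    params,
    protocol: LigandProtocol,
    duration: float,
    seed: int,
    record_dt: float = 0.1,
    m_init: int | None = None,
) -> Trace:
    """Stochastic trajectory of the well-mixed baseline (variants B1/B2).

    ``params`` is a :class:`clusteradapt.meanfield.WellMixedParams`.  Total
    methylation performs a birth-death walk with Goldbeter-Koshland rates on
    total enzyme pools; there is no lattice and no localization, so the
    per-enzyme trace columns are zero.
    """
    mwc = params.mwc
    n_complexes = int(round(params.t_tot / (2 * params.n_mwc)))
    if m_init is None:
        m_init = int(round(mwc.m_half * n_complexes))
    rec_t, rec_a, rec_m = _kernel.run_wellmixed_ssa(
        n_complexes, 8 * mwc.n_dimers, int(m_init),
        float(params.r_tot), float(params.b_tot),
        float(params.k_r), float(params.k_b),
        float(params.big_k_r), float(params.big_k_b),
        float(params.a_p), float(params.d_p),
        float(mwc.eps_m), float(mwc.m_half), float(mwc.n_dimers),
        float(mwc.k_off), float(mwc.k_on),
        *protocol._packed(),
        float(duration), float(record_dt), np.uint64(seed),
    )
    z = np.zeros_like(rec_t, dtype=np.int32)
    return Trace(
        t=rec_t, activity=rec_a, m_per_complex=rec_m,
        localized_cheR=z, localized_cheBp=z, bulk_cheBp=z,
        inert_cheR=z, inert_cheBp=z,
        meta={"variant": "B1", "seed": int(seed), "duration": float(duration),
              "record_dt": float(record_dt), "protocol": protocol.kind},
    )
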
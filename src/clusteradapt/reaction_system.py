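"""State and rule set of the enzyme/receptor kinetics on the lattice.

Each receptor dimer carries a methylation level (0-8), one tether site and
one modification site; each site holds at most one enzyme.  CheR and
phosphorylated CheB (CheB-P) are explicit agents that may be free in the
cytoplasmic bulk, bound to a tether, bound to a modification site, or bound
to both (the modification site must then lie in the assistance neighborhood
of the tether).  Unphosphorylated CheB never touches the lattice; CheB
phosphorylation and CheB-P autodephosphorylation happen in the bulk, with
the phosphorylation rate proportional to the mean receptor activity.

Binding of an enzyme to a modification site is activity-weighted: CheR
binds in proportion to ``1 - a`` of the target's complex, CheB-P in
proportion to ``a``.  Catalysis increments (CheR) or decrements (CheB-P)
methylation of the occupied dimer and, by default, releases the
modification-site bond (``release_on_catalysis``), so processivity in the
no-neighborhood variant arises from tether residence rather than permanent
modification-site binding.

Variants
--------
M1  reference: assistance neighborhoods + brachiation.
M2  tethered enzymes reach only their own dimer (no neighborhoods, no
    brachiation).
M3  tether unbinding slowed (``tether_unbind_scale < 1``): neighborhoods
    kept, brachiation inefficient.

This module holds the pure-Python reference implementation of the rule set
(used by tests and exact micro-model oracles); the production simulator in
:mod:`clusteradapt._kernel` implements the identical semantics in a
compiled loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import LatticeGeometry, assistance_neighborhood
from .mwc import MWCParams, activity_table

__all__ = [
    "RateSet",
    "VariantFlags",
    "CopyNumbers",
    "SystemState",
    "init_state",
    "enumerate_event_channels",
    "apply_event",
    "mean_activity",
]

# species codes
CHE_R = 0
CHE_B = 1

#: Nominal per-cell copy numbers (immunoblotting-style estimates the model
#: is built around): 7200 receptor dimers, 140 CheR, 240 CheB.
NOMINAL_DIMERS = 7200
NOMINAL_CHER = 140
NOMINAL_CHEB = 240


@dataclass(frozen=True)
class RateSet:
    """Kinetic constants of the lattice model (all 1/s).

    Bulk localization is slow (tether binding ~15 s per enzyme, direct
    modification-site binding slower still); reactions within the ~5 nm
    tether radius are fast (1-10 ms).  Local modification-site binding
    rates are per target site and carry the activity weight; the resulting
    local Michaelis-like constant is
    ``(k_m_unbind + k_cat) / (7 * k_m_bind_local) ~ 0.07``.
    """

    # bulk -> lattice (per enzyme)
    k_t_bind_r: float = 1.0 / 15.0
    k_t_bind_b: float = 1.0 / 15.0
    k_m_bind_bulk_r: float = 1.0 / 60.0
    k_m_bind_bulk_b: float = 1.0 / 60.0
    # tether release (scaled by VariantFlags.tether_unbind_scale)
    k_t_unbind_r: float = 0.9
    k_t_unbind_b: float = 0.9
    # local (tether-radius) reactions, per target site
    k_m_bind_local_r: float = 200.0
    k_m_bind_local_b: float = 200.0
    k_t_bind_local_r: float = 200.0
    k_t_bind_local_b: float = 200.0
    k_m_unbind_r: float = 100.0
    k_m_unbind_b: float = 100.0
    # catalysis
    k_cat_r: float = 2.5
    k_cat_b: float = 3.6
    # bulk CheB phosphorylation cycle
    a_p: float = 0.1
    d_p: float = 0.01
    release_on_catalysis: bool = True

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if name != "release_on_catalysis" and v < 0:
                raise ValueError(f"rate {name} must be >= 0, got {v}")


@dataclass(frozen=True)
class VariantFlags:
    """Switches selecting the model variant."""

    neighbor_binding: bool = True
    tether_unbind_scale: float = 1.0
    name: str = "M1"

    @classmethod
    def m1(cls) -> "VariantFlags":
        return cls(True, 1.0, "M1")

    @classmethod
    def m2(cls) -> "VariantFlags":
        return cls(False, 1.0, "M2")

    @classmethod
    def m3(cls, scale: float = 0.05) -> "VariantFlags":
        return cls(True, scale, "M3")


def variant(name: str) -> VariantFlags:
    name = name.upper()
    if name == "M1":
        return VariantFlags.m1()
    if name == "M2":
        return VariantFlags.m2()
    if name == "M3":
        return VariantFlags.m3()
    raise ValueError(f"unknown lattice variant {name!r} (expected M1, M2 or M3)")


@dataclass(frozen=True)
class CopyNumbers:
    """Enzyme copy numbers accompanying a lattice of given size."""

    che_r: int
    che_b: int

    @classmethod
    def for_dimers(cls, n_dimers: int, multiplier: float = 1.0) -> "CopyNumbers":
        """Counts at the nominal per-dimer density, co-scaled by ``multiplier``.

        Scaling by lattice size preserves the receptor:CheR:CheB ratio, the
        quantity conserved under the population-sampling protocol.
        """
        scale = multiplier * n_dimers / NOMINAL_DIMERS
        return cls(
            che_r=max(1, round(NOMINAL_CHER * scale)),
            che_b=max(1, round(NOMINAL_CHEB * scale)),
        )


@dataclass
class SystemState:
    """Full mutable state of the stochastic model.

    Enzyme ids: CheR occupy ``0..n_r-1``, CheB ``n_r..n_r+n_b-1``.  Empty
    site/bond slots are -1.  ``b_phos`` flags phosphorylated CheB.
    """

    methyl: np.ndarray        # int32 per dimer, 0..8
    tether_occ: np.ndarray    # int32 per dimer, enzyme id or -1
    mod_occ: np.ndarray       # int32 per dimer, enzyme id or -1
    enz_teth: np.ndarray      # int32 per enzyme, dimer id or -1
    enz_mod: np.ndarray       # int32 per enzyme, dimer id or -1
    b_phos: np.ndarray        # uint8 per enzyme (CheR entries stay 0)
    n_r: int
    n_b: int

    @property
    def n_enzymes(self) -> int:
        return self.n_r + self.n_b

    def species(self, e: int) -> int:
        return CHE_R if e < self.n_r else CHE_B

    def is_bulk(self, e: int) -> bool:
        return self.enz_teth[e] == -1 and self.enz_mod[e] == -1

    def counts(self) -> dict:
        bulk_r = sum(1 for e in range(self.n_r) if self.is_bulk(e))
        bulk_bp = sum(
            1 for e in range(self.n_r, self.n_enzymes) if self.is_bulk(e) and self.b_phos[e]
        )
        bulk_b0 = sum(
            1 for e in range(self.n_r, self.n_enzymes) if self.is_bulk(e) and not self.b_phos[e]
        )
        return {
            "bulk_cheR": bulk_r,
            "bulk_cheBp": bulk_bp,
            "bulk_cheB": bulk_b0,
            "localized_cheR": self.n_r - bulk_r,
            "localized_cheBp": self.n_b - bulk_bp - bulk_b0,
        }

    def copy(self) -> "SystemState":
        return SystemState(
            self.methyl.copy(), self.tether_occ.copy(), self.mod_occ.copy(),
            self.enz_teth.copy(), self.enz_mod.copy(), self.b_phos.copy(),
            self.n_r, self.n_b,
        )


def init_state(geometry: LatticeGeometry, copies: CopyNumbers, initial_methyl: int = 1) -> SystemState:
    """All enzymes in the bulk (CheB unphosphorylated), uniform methylation."""
    n = geometry.n_dimers
    n_e = copies.che_r + copies.che_b
    if not (0 <= initial_methyl <= 8):
        raise ValueError("initial_methyl must be in 0..8")
    return SystemState(
        methyl=np.full(n, initial_methyl, dtype=np.int32),
        tether_occ=np.full(n, -1, dtype=np.int32),
        mod_occ=np.full(n, -1, dtype=np.int32),
        enz_teth=np.full(n_e, -1, dtype=np.int32),
        enz_mod=np.full(n_e, -1, dtype=np.int32),
        b_phos=np.zeros(n_e, dtype=np.uint8),
        n_r=copies.che_r,
        n_b=copies.che_b,
    )


def _check_consistency(state: SystemState, geometry: LatticeGeometry) -> None:
    for e in range(state.n_enzymes):
        d = state.enz_teth[e]
        if d >= 0 and state.tether_occ[d] != e:
            raise RuntimeError(f"enzyme {e} claims tether of dimer {d} but site disagrees")
        d = state.enz_mod[e]
        if d >= 0 and state.mod_occ[d] != e:
            raise RuntimeError(f"enzyme {e} claims modsite of dimer {d} but site disagrees")
    for d in range(geometry.n_dimers):
        e = state.tether_occ[d]
        if e >= 0 and state.enz_teth[e] != d:
            raise RuntimeError(f"tether of dimer {d} claims enzyme {e} but enzyme disagrees")
        e = state.mod_occ[d]
        if e >= 0 and state.enz_mod[e] != d:
            raise RuntimeError(f"modsite of dimer {d} claims enzyme {e} but enzyme disagrees")


def _reachable(state: SystemState, geometry: LatticeGeometry, flags: VariantFlags, anchor: int) -> np.ndarray:
    """Dimers whose sites a bound enzyme can reach from ``anchor``."""
    if flags.neighbor_binding:
        return assistance_neighborhood(geometry, anchor)
    return np.array([anchor], dtype=np.int32)


def enumerate_event_channels(
    state: SystemState,
    geometry: LatticeGeometry,
    rates: RateSet,
    flags: VariantFlags,
    mwc_params: MWCParams,
    L: float,
):
    """Reference enumeration of every event channel with its propensity.

    Returns a list of ``(event, propensity)`` pairs, ``event`` being a tuple
    whose first element names the channel.  Bulk binding channels are
    enumerated per (enzyme, target) so the list doubles as a CTMC generator
    on small systems; their summed propensity equals the aggregate rates
    used by the compiled kernel (bulk enzymes pick targets uniformly /
    activity-weighted, with tether sites treated as in excess).
    """
    _check_consistency(state, geometry)
    a_tab = activity_table(L, mwc_params)
    m_c = np.zeros(geometry.n_complexes, dtype=np.int64)
    np.add.at(m_c, geometry.complex_of, state.methyl)
    a_c = a_tab[m_c]
    mean_a = float(a_c.mean())
    n_dimers = geometry.n_dimers

    free_teth = np.flatnonzero(state.tether_occ == -1)
    free_mod = np.flatnonzero(state.mod_occ == -1)

    bulk_r = [e for e in range(state.n_r) if state.is_bulk(e)]
    bulk_bp = [
        e for e in range(state.n_r, state.n_enzymes) if state.is_bulk(e) and state.b_phos[e]
    ]
    bulk_b0 = [
        e for e in range(state.n_r, state.n_enzymes) if state.is_bulk(e) and not state.b_phos[e]
    ]

    channels = []

    # (1) bulk -> tether, uniform over free tethers, total k * n_bulk
    for species, pool, k in ((CHE_R, bulk_r, rates.k_t_bind_r), (CHE_B, bulk_bp, rates.k_t_bind_b)):
        if pool and len(free_teth):
            per = k / len(free_teth)
            for e in pool:
                for d in free_teth:
                    channels.append((("tether_bind_bulk", e, int(d)), per))

    # (2) bulk -> modification site, activity-weighted, total k * n_bulk * W / n_dimers
    for pool, k, is_r in ((bulk_r, rates.k_m_bind_bulk_r, True), (bulk_bp, rates.k_m_bind_bulk_b, False)):
        for e in pool:
            for d in free_mod:
                w = (1.0 - a_c[geometry.complex_of[d]]) if is_r else a_c[geometry.complex_of[d]]
                if w > 0:
                    channels.append((("mod_bind_bulk", e, int(d)), k * w / n_dimers))

    # (3)-(6) per localized enzyme
    for e in range(state.n_enzymes):
        sp = state.species(e)
        teth, mod = int(state.enz_teth[e]), int(state.enz_mod[e])
        if teth == -1 and mod == -1:
            continue
        k_loc_m = rates.k_m_bind_local_r if sp == CHE_R else rates.k_m_bind_local_b
        k_loc_t = rates.k_t_bind_local_r if sp == CHE_R else rates.k_t_bind_local_b
        k_t_un = (rates.k_t_unbind_r if sp == CHE_R else rates.k_t_unbind_b) * flags.tether_unbind_scale
        k_m_un = rates.k_m_unbind_r if sp == CHE_R else rates.k_m_unbind_b
        k_cat = rates.k_cat_r if sp == CHE_R else rates.k_cat_b

        if teth >= 0 and mod == -1:
            for d in _reachable(state, geometry, flags, teth):
                if state.mod_occ[d] == -1:
                    a = a_c[geometry.complex_of[d]]
                    w = (1.0 - a) if sp == CHE_R else a
                    if w > 0:
                        channels.append((("mod_bind_local", e, int(d)), k_loc_m * w))
        if mod >= 0 and teth == -1:
            for d in _reachable(state, geometry, flags, mod):
                if state.tether_occ[d] == -1:
                    channels.append((("tether_bind_local", e, int(d)), k_loc_t))
        if teth >= 0:
            channels.append((("tether_unbind", e, teth), k_t_un))
        if mod >= 0:
            channels.append((("mod_unbind", e, mod), k_m_un))
            m = state.methyl[mod]
            if sp == CHE_R and m < 8:
                channels.append((("catalysis", e, mod), k_cat))
            if sp == CHE_B and m > 0:
                channels.append((("catalysis", e, mod), k_cat))

    # (7) bulk CheB phosphorylation cycle
    if bulk_b0 and mean_a > 0:
        per = rates.a_p * mean_a
        for e in bulk_b0:
            channels.append((("phosphorylate", e), per))
    for e in bulk_bp:
        channels.append((("dephosphorylate", e), rates.d_p))

    return channels


def apply_event(state: SystemState, event, rates: RateSet | None = None) -> list:
    """Apply one enumerated event in place; return the changelog.

    The changelog lists dimers whose complex activity may have changed
    (methylation events).  Applying a stale event (target site occupied,
    enzyme moved) raises ``RuntimeError``.
    """
    rates = rates or RateSet()
    kind = event[0]
    changed: list[int] = []
    if kind == "tether_bind_bulk":
        _, e, d = event
        if not state.is_bulk(e) or state.tether_occ[d] != -1:
            raise RuntimeError(f"stale event {event}")
        state.tether_occ[d] = e
        state.enz_teth[e] = d
    elif kind == "mod_bind_bulk":
        _, e, d = event
        if not state.is_bulk(e) or state.mod_occ[d] != -1:
            raise RuntimeError(f"stale event {event}")
        state.mod_occ[d] = e
        state.enz_mod[e] = d
    elif kind == "mod_bind_local":
        _, e, d = event
        if state.enz_teth[e] == -1 or state.enz_mod[e] != -1 or state.mod_occ[d] != -1:
            raise RuntimeError(f"stale event {event}")
        state.mod_occ[d] = e
        state.enz_mod[e] = d
    elif kind == "tether_bind_local":
        _, e, d = event
        if state.enz_mod[e] == -1 or state.enz_teth[e] != -1 or state.tether_occ[d] != -1:
            raise RuntimeError(f"stale event {event}")
        state.tether_occ[d] = e
        state.enz_teth[e] = d
    elif kind == "tether_unbind":
        _, e, d = event
        if state.enz_teth[e] != d:
            raise RuntimeError(f"stale event {event}")
        state.tether_occ[d] = -1
        state.enz_teth[e] = -1
    elif kind == "mod_unbind":
        _, e, d = event
        if state.enz_mod[e] != d:
            raise RuntimeError(f"stale event {event}")
        state.mod_occ[d] = -1
        state.enz_mod[e] = -1
    elif kind == "catalysis":
        _, e, d = event
        if state.enz_mod[e] != d:
            raise RuntimeError(f"stale event {event}")
        if state.species(e) == CHE_R:
            if state.methyl[d] >= 8:
                raise RuntimeError(f"stale event {event}: dimer fully methylated")
            state.methyl[d] += 1
        else:
            if state.methyl[d] <= 0:
                raise RuntimeError(f"stale event {event}: dimer fully demethylated")
            state.methyl[d] -= 1
        changed.append(int(d))
        if rates.release_on_catalysis:
            state.mod_occ[d] = -1
            state.enz_mod[e] = -1
    elif kind == "phosphorylate":
        _, e = event
        if not state.is_bulk(e) or state.b_phos[e] or state.species(e) != CHE_B:
            raise RuntimeError(f"stale event {event}")
        state.b_phos[e] = 1
    elif kind == "dephosphorylate":
        _, e = event
        if not state.is_bulk(e) or not state.b_phos[e]:
            raise RuntimeError(f"stale event {event}")
        state.b_phos[e] = 0
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return changed


def mean_activity(state: SystemState, geometry: LatticeGeometry, mwc_params: MWCParams, L: float) -> float:
    """Average MWC activity over all signaling complexes."""
    a_tab = activity_table(L, mwc_params)
    m_c = np.zeros(geometry.n_complexes, dtype=np.int64)
    np.add.at(m_c, geometry.complex_of, state.methyl)
    return float(a_tab[m_c].mean())
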
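import numpy as np
import pytest

from clusteradapt.mwc import activity_table, calibrate
from clusteradapt.reaction_system import (
    CopyNumbers,
    RateSet,
    VariantFlags,
    apply_event,
    enumerate_event_channels,
    init_state,
    mean_activity,
)


def _by_kind(channels):
    out = {}
    for ev, p in channels:
        out.setdefault(ev[0], []).append((ev, p))
    return out


@pytest.fixture()
def setup(small_geometry, slow_rates, mwc_params):
    copies = CopyNumbers(che_r=3, che_b=4)
    state = init_state(small_geometry, copies, initial_methyl=1)
    return state, small_geometry, slow_rates, mwc_params


class TestEnumeration:
    def test_m2_has_no_neighbor_channels(self, setup):
        state, geom, rates, mwc = setup
        state.b_phos[3:] = 1
        # tether enzyme 0 on an interior dimer with all neighbors free
        d = int(np.flatnonzero(geom.n_neighbors == 6)[0])
        state.tether_occ[d] = 0
        state.enz_teth[0] = d
        ch_m1 = _by_kind(enumerate_event_channels(state, geom, rates, VariantFlags.m1(), mwc, 0.0))
        ch_m2 = _by_kind(enumerate_event_channels(state, geom, rates, VariantFlags.m2(), mwc, 0.0))
        targets_m1 = {ev[2] for ev, _ in ch_m1["mod_bind_local"]}
        targets_m2 = {ev[2] for ev, _ in ch_m2["mod_bind_local"]}
        assert targets_m1 == set(
            [d] + geom.neighbors[d, : geom.n_neighbors[d]].tolist()
        )
        assert targets_m2 == {d}

    def test_fully_methylated_dimer_has_no_cheR_catalysis(self, setup):
        state, geom, rates, mwc = setup
        d = 5
        state.methyl[d] = 8
        state.mod_occ[d] = 0
        state.enz_mod[0] = d
        kinds = _by_kind(enumerate_event_channels(state, geom, rates, VariantFlags.m1(), mwc, 0.0))
        assert all(ev[1] != 0 for ev, _ in kinds.get("catalysis", []))

    def test_cheR_binding_weight_vanishes_on_fully_active_complex(self, setup):
        state, geom, rates, mwc = setup
        # drive one complex to near-full activity, leave the rest at zero methyl
        state.methyl[:] = 0
        for d in geom.complexes[0]:
            state.methyl[d] = 8
        state.tether_occ[geom.complexes[0][0]] = 0
        state.enz_teth[0] = geom.complexes[0][0]
        a_tab = activity_table(0.0, mwc)
        a_hot = a_tab[48]
        assert a_hot > 1.0 - 1e-9
        chans = _by_kind(enumerate_event_channels(state, geom, rates, VariantFlags.m2(), mwc, 0.0))
        # under M2 the only reachable modsite sits on the fully active complex
        props = [p for _, p in chans.get("mod_bind_local", [])]
        assert props and max(props) < rates.k_m_bind_local_r * 1e-9

    def test_unphosphorylated_cheB_never_binds(self, setup):
        state, geom, rates, mwc = setup
        chans = enumerate_event_channels(state, geom, rates, VariantFlags.m1(), mwc, 0.0)
        kinds = _by_kind(chans)
        binders = {ev[1] for ev, _ in kinds.get("tether_bind_bulk", [])}
        assert binders <= set(range(state.n_r))  # no CheB while unphosphorylated
        assert "phosphorylate" in kinds

    def test_inconsistent_state_is_hard_failure(self, setup):
        state, geom, rates, mwc = setup
        state.enz_teth[0] = 3  # enzyme claims a site that does not claim it back
        with pytest.raises(RuntimeError):
            enumerate_event_channels(state, geom, rates, VariantFlags.m1(), mwc, 0.0)


class TestApplyEvent:
    def test_tether_bind_moves_enzyme_out_of_bulk(self, setup):
        state, geom, rates, mwc = setup
        apply_event(state, ("tether_bind_bulk", 0, 7), rates)
        assert state.enz_teth[0] == 7 and state.tether_occ[7] == 0
        assert not state.is_bulk(0)

    def test_catalysis_increments_and_releases(self, setup):
        state, geom, rates, mwc = setup
        state.mod_occ[2] = 0
        state.enz_mod[0] = 2
        state.methyl[2] = 3
        changed = apply_event(state, ("catalysis", 0, 2), rates)
        assert state.methyl[2] == 4
        assert changed == [2]
        assert state.enz_mod[0] == -1 and state.mod_occ[2] == -1

    def test_stale_event_rejected(self, setup):
        state, geom, rates, mwc = setup
        apply_event(state, ("tether_bind_bulk", 0, 7), rates)
        with pytest.raises(RuntimeError):
            apply_event(state, ("tether_bind_bulk", 1, 7), rates)

    def test_demethylation_at_zero_never_enumerated(self, setup):
        state, geom, rates, mwc = setup
        state.methyl[:] = 0
        state.b_phos[3:] = 1
        state.mod_occ[2] = 3
        state.enz_mod[3] = 2
        kinds = _by_kind(enumerate_event_channels(state, geom, rates, VariantFlags.m1(), mwc, 0.0))
        assert "catalysis" not in kinds


def test_random_event_streams_preserve_invariants(setup):
    """Fuzz: apply long random event sequences; occupancy and bounds hold."""
    state, geom, rates, mwc = setup
    rng = np.random.default_rng(42)
    flags = VariantFlags.m1()
    n_r, n_b = state.n_r, state.n_b
    for _ in range(400):
        channels = enumerate_event_channels(state, geom, rates, flags, mwc, 0.0)
        props = np.array([p for _, p in channels])
        ev = channels[rng.choice(len(channels), p=props / props.sum())][0]
        apply_event(state, ev, rates)
        assert state.methyl.min() >= 0 and state.methyl.max() <= 8
        # site exclusivity and cross-consistency
        bound_t = state.enz_teth[state.enz_teth >= 0]
        bound_m = state.enz_mod[state.enz_mod >= 0]
        assert len(set(bound_t.tolist())) == len(bound_t)
        assert len(set(bound_m.tolist())) == len(bound_m)
        # conservation of enzymes across pools
        counts = state.counts()
        assert counts["bulk_cheR"] + counts["localized_cheR"] == n_r
        assert (counts["bulk_cheB"] + counts["bulk_cheBp"]
                + counts["localized_cheBp"]) == n_b
        # a doubly bound enzyme reaches only its assistance neighborhood
        for e in range(state.n_enzymes):
            if state.enz_teth[e] >= 0 and state.enz_mod[e] >= 0:
                t, m = state.enz_teth[e], state.enz_mod[e]
                assert m == t or m in geom.neighbors[t, : geom.n_neighbors[t]]


def test_mean_activity_matches_bruteforce(setup):
    state, geom, rates, mwc = setup
    rng = np.random.default_rng(3)
    state.methyl[:] = rng.integers(0, 9, geom.n_dimers)
    from clusteradapt.mwc import complex_activity

    expected = np.mean([
        complex_activity(int(state.methyl[geom.complexes[c]].sum()), 30.0, mwc)
        for c in range(geom.n_complexes)
    ])
    assert mean_activity(state, geom, mwc, 30.0) == pytest.approx(expected, rel=1e-12)


def test_mean_activity_anchor_and_saturation(setup):
    state, geom, rates, mwc = setup
    state.methyl[:] = 1  # every 6-dimer complex at total methylation 6
    assert mean_activity(state, geom, mwc, 0.0) == pytest.approx(0.5, abs=1e-14)
    state.methyl[:] = 0
    assert mean_activity(state, geom, mwc, 1e5) < 1e-6


def test_inert_cheBp_occupies_but_cannot_catalyze(setup):
    state, geom, rates, mwc = setup
    state.methyl[:] = 0
    state.b_phos[3] = 1
    d = int(np.flatnonzero(geom.n_neighbors == 6)[0])
    state.tether_occ[d] = 3
    state.enz_teth[3] = d
    kinds = _by_kind(enumerate_event_channels(state, geom, rates, VariantFlags.m1(), mwc, 0.0))
    assert "catalysis" not in kinds
    # it still blocks its tether site for others
    assert state.tether_occ[d] == 3
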
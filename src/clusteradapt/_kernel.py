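"""Compiled Gillespie core for the lattice model (and the well-mixed baseline).

Implements exactly the rule semantics of :mod:`clusteradapt.reaction_system`
as a flat numba loop.  Design notes:

* Activity of a complex is a pure function of its integer methylation, so a
  lookup table ``a_tab[m]`` is rebuilt only when the ligand level changes.
* The propensity sweep recomputes every channel from per-enzyme state each
  step (tens of enzymes, O(7) neighborhood scans) on top of three running
  lattice aggregates: ``S_a`` (summed complex activity), ``W_R``/``W_B``
  (activity-weighted free modification sites).  Aggregates are updated
  incrementally per event and rebuilt from scratch periodically to guard
  against floating-point drift (with an optional consistency check).
* Randomness is a self-contained xorshift128+ stream seeded via splitmix64,
  so identical inputs give bit-identical trajectories on any platform.
* Time-varying ligand is piecewise constant on the recording grid; the
  exponential-waiting-time draw is restarted at each ligand update
  (memorylessness makes this exact for the frozen ligand level).
* Records that fall inside an event's waiting interval are written with the
  pre-event state (the state is constant between events).

The kernel is deliberately free of Python objects: wrappers in
:mod:`clusteradapt.ssa_engine` marshal dataclasses to arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# rate-vector layout (keep in sync with ssa_engine.pack_rates)
R_T_BIND_R, R_T_BIND_B = 0, 1
R_M_BIND_BULK_R, R_M_BIND_BULK_B = 2, 3
R_T_UNBIND_R, R_T_UNBIND_B = 4, 5
R_M_BIND_LOC_R, R_M_BIND_LOC_B = 6, 7
R_T_BIND_LOC_R, R_T_BIND_LOC_B = 8, 9
R_M_UNBIND_R, R_M_UNBIND_B = 10, 11
R_CAT_R, R_CAT_B = 12, 13
R_A_P, R_D_P = 14, 15
N_RATES = 16

# event-counter layout
EV_T_BIND_BULK, EV_M_BIND_BULK, EV_M_BIND_LOC, EV_T_BIND_LOC = 0, 1, 2, 3
EV_T_UNBIND, EV_M_UNBIND, EV_CAT_R, EV_CAT_B, EV_PHOS, EV_DEPHOS = 4, 5, 6, 7, 8, 9
N_EV = 10

PROTO_CONST, PROTO_STEP, PROTO_RAMP = 0, 1, 2


@njit(cache=False, inline="always")
def _next_u64(rng):
    s1 = rng[0]
    s0 = rng[1]
    rng[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    rng[1] = s1
    return s0 + s1


@njit(cache=False, inline="always")
def _next_f64(rng):
    # uniform in [0, 1)
    return float(_next_u64(rng) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=False)
def _seed_rng(seed):
    # splitmix64 expansion of a single integer seed
    rng = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
        rng[i] = x
    if rng[0] == np.uint64(0) and rng[1] == np.uint64(0):
        rng[0] = np.uint64(1)
    return rng


@njit(cache=False)
def _activity_table(m_max, L, eps_m, m_half, n_mwc, k_off, k_on):
    tab = np.empty(m_max + 1, dtype=np.float64)
    lig = n_mwc * (np.log1p(L / k_off) - np.log1p(L / k_on))
    for m in range(m_max + 1):
        f = eps_m * (m_half - m) + lig
        tab[m] = 1.0 / (1.0 + np.exp(f))
    return tab


@njit(cache=False)
def _build_aggregates(methyl, complex_of, mod_occ, tether_occ, a_tab, n_complexes):
    n = methyl.shape[0]
    m_c = np.zeros(n_complexes, dtype=np.int64)
    free_mod = np.zeros(n_complexes, dtype=np.int64)
    n_free_teth = 0
    m_tot = 0
    for d in range(n):
        c = complex_of[d]
        m_c[c] += methyl[d]
        m_tot += methyl[d]
        if mod_occ[d] == -1:
            free_mod[c] += 1
        if tether_occ[d] == -1:
            n_free_teth += 1
    s_a = 0.0
    w_r = 0.0
    w_b = 0.0
    for c in range(n_complexes):
        a = a_tab[m_c[c]]
        s_a += a
        w_r += (1.0 - a) * free_mod[c]
        w_b += a * free_mod[c]
    return m_c, free_mod, s_a, w_r, w_b, n_free_teth, m_tot


@njit(cache=False)
def _sweep(
    rates, neighbor_binding, tether_scale,
    neighbors, n_neighbors, complex_of, a_tab, m_c, methyl, mod_occ, tether_occ,
    enz_teth, enz_mod, b_phos, n_r, n_enz,
    n_bulk_r, n_bulk_bp, n_bulk_b0, n_free_teth,
    s_a, w_r, w_b, n_complexes, n_dimers,
    scal, p_mod_loc, p_teth_loc, p_t_un, p_m_un, p_cat,
):
    """Fill per-channel propensities; return the total."""
    scal[0] = rates[R_T_BIND_R] * n_bulk_r if n_free_teth > 0 else 0.0
    scal[1] = rates[R_T_BIND_B] * n_bulk_bp if n_free_teth > 0 else 0.0
    scal[2] = rates[R_M_BIND_BULK_R] * n_bulk_r * w_r / n_dimers
    scal[3] = rates[R_M_BIND_BULK_B] * n_bulk_bp * w_b / n_dimers
    scal[4] = rates[R_A_P] * (s_a / n_complexes) * n_bulk_b0
    scal[5] = rates[R_D_P] * n_bulk_bp
    total = scal[0] + scal[1] + scal[2] + scal[3] + scal[4] + scal[5]

    for e in range(n_enz):
        p_mod_loc[e] = 0.0
        p_teth_loc[e] = 0.0
        p_t_un[e] = 0.0
        p_m_un[e] = 0.0
        p_cat[e] = 0.0
        teth = enz_teth[e]
        mod = enz_mod[e]
        if teth == -1 and mod == -1:
            continue
        is_r = e < n_r
        if teth >= 0 and mod == -1:
            k_loc = rates[R_M_BIND_LOC_R] if is_r else rates[R_M_BIND_LOC_B]
            s = 0.0
            if mod_occ[teth] == -1:
                a = a_tab[m_c[complex_of[teth]]]
                s += (1.0 - a) if is_r else a
            if neighbor_binding:
                for k in range(n_neighbors[teth]):
                    d2 = neighbors[teth, k]
                    if mod_occ[d2] == -1:
                        a = a_tab[m_c[complex_of[d2]]]
                        s += (1.0 - a) if is_r else a
            p_mod_loc[e] = k_loc * s
        if mod >= 0 and teth == -1:
            k_loc = rates[R_T_BIND_LOC_R] if is_r else rates[R_T_BIND_LOC_B]
            cnt = 0
            if tether_occ[mod] == -1:
                cnt += 1
            if neighbor_binding:
                for k in range(n_neighbors[mod]):
                    d2 = neighbors[mod, k]
                    if tether_occ[d2] == -1:
                        cnt += 1
            p_teth_loc[e] = k_loc * cnt
        if teth >= 0:
            p_t_un[e] = (rates[R_T_UNBIND_R] if is_r else rates[R_T_UNBIND_B]) * tether_scale
        if mod >= 0:
            p_m_un[e] = rates[R_M_UNBIND_R] if is_r else rates[R_M_UNBIND_B]
            m = methyl[mod]
            if is_r:
                if m < 8:
                    p_cat[e] = rates[R_CAT_R]
            else:
                if m > 0:
                    p_cat[e] = rates[R_CAT_B]
        total += p_mod_loc[e] + p_teth_loc[e] + p_t_un[e] + p_m_un[e] + p_cat[e]
    return total


@njit(cache=False)
def channel_totals(
    rates, neighbor_binding, tether_scale,
    neighbors, n_neighbors, complex_of, n_complexes,
    methyl, tether_occ, mod_occ, enz_teth, enz_mod, b_phos, n_r, n_b,
    a_tab,
):
    """Per-class propensity totals for a given state (testing aid).

    Order: tether-bind-bulk R, tether-bind-bulk B, mod-bind-bulk R,
    mod-bind-bulk B, phosphorylation, dephosphorylation, local mod bind,
    local tether bind, tether unbind, mod unbind, catalysis.
    """
    n_dimers = methyl.shape[0]
    n_enz = n_r + n_b
    m_c, free_mod, s_a, w_r, w_b, n_free_teth, m_tot = _build_aggregates(
        methyl, complex_of, mod_occ, tether_occ, a_tab, n_complexes
    )
    n_bulk_r = 0
    for e in range(n_r):
        if enz_teth[e] == -1 and enz_mod[e] == -1:
            n_bulk_r += 1
    n_bulk_bp = 0
    n_bulk_b0 = 0
    for e in range(n_r, n_enz):
        if enz_teth[e] == -1 and enz_mod[e] == -1:
            if b_phos[e] == 1:
                n_bulk_bp += 1
            else:
                n_bulk_b0 += 1
    scal = np.zeros(6, dtype=np.float64)
    p_mod_loc = np.zeros(n_enz, dtype=np.float64)
    p_teth_loc = np.zeros(n_enz, dtype=np.float64)
    p_t_un = np.zeros(n_enz, dtype=np.float64)
    p_m_un = np.zeros(n_enz, dtype=np.float64)
    p_cat = np.zeros(n_enz, dtype=np.float64)
    _sweep(
        rates, neighbor_binding, tether_scale,
        neighbors, n_neighbors, complex_of, a_tab, m_c, methyl, mod_occ, tether_occ,
        enz_teth, enz_mod, b_phos, n_r, n_enz,
        n_bulk_r, n_bulk_bp, n_bulk_b0, n_free_teth,
        s_a, w_r, w_b, n_complexes, n_dimers,
        scal, p_mod_loc, p_teth_loc, p_t_un, p_m_un, p_cat,
    )
    out = np.zeros(11, dtype=np.float64)
    for i in range(6):
        out[i] = scal[i]
    out[6] = p_mod_loc.sum()
    out[7] = p_teth_loc.sum()
    out[8] = p_t_un.sum()
    out[9] = p_m_un.sum()
    out[10] = p_cat.sum()
    return out


@njit(cache=False)
def _ligand_at(proto_kind, L0, L1, t_step, ramp_r, L_min, L_max, t):
    if proto_kind == PROTO_CONST:
        return L0
    if proto_kind == PROTO_STEP:
        return L1 if t >= t_step else L0
    # exponential ramp, clipped to its bounds
    if t < t_step:
        return L0
    L = L0 * np.exp(ramp_r * (t - t_step))
    if L < L_min:
        L = L_min
    if L > L_max:
        L = L_max
    return L


@njit(cache=False)
def _write_record(
    rec_i, tr, rec_t, rec_a, rec_m, rec_loc_r, rec_loc_bp, rec_bulk_bp,
    rec_inert_r, rec_inert_bp,
    s_a, m_tot, n_complexes, n_loc_r, n_loc_bp, n_bulk_bp,
    enz_teth, enz_mod, methyl, neighbors, n_neighbors, neighbor_binding, n_r, n_enz,
):
    rec_t[rec_i] = tr
    rec_a[rec_i] = s_a / n_complexes
    rec_m[rec_i] = m_tot / float(n_complexes)
    rec_loc_r[rec_i] = n_loc_r
    rec_loc_bp[rec_i] = n_loc_bp
    rec_bulk_bp[rec_i] = n_bulk_bp
    # inert enzymes: localized with every reachable dimer saturated
    # (fully demethylated neighborhoods for CheB-P, fully methylated for CheR)
    ir = 0
    ib = 0
    for e in range(n_enz):
        anchor = enz_teth[e]
        if anchor == -1:
            anchor = enz_mod[e]
        if anchor == -1:
            continue
        is_r = e < n_r
        inert = True
        if is_r:
            if methyl[anchor] < 8:
                inert = False
        else:
            if methyl[anchor] > 0:
                inert = False
        if inert and neighbor_binding:
            for k in range(n_neighbors[anchor]):
                d2 = neighbors[anchor, k]
                if is_r:
                    if methyl[d2] < 8:
                        inert = False
                        break
                else:
                    if methyl[d2] > 0:
                        inert = False
                        break
        if inert:
            if is_r:
                ir += 1
            else:
                ib += 1
    rec_inert_r[rec_i] = ir
    rec_inert_bp[rec_i] = ib


@njit(cache=False)
def run_lattice_ssa(
    neighbors, n_neighbors, complex_of, n_complexes,
    methyl, enz_teth, enz_mod, b_phos, n_r, n_b,
    rates, neighbor_binding, tether_scale, release_on_cat,
    eps_m, m_half, n_mwc, k_off, k_on,
    proto_kind, L0, L1, t_step, ramp_r, L_min, L_max,
    duration, record_dt, seed,
    log_visits, log_cap, resync_every, check_consistency,
):
    """Exact SSA trajectory of the lattice model.

    State arrays are taken as the initial condition and mutated in place
    (pass copies to preserve an input state).  Returns record arrays, the
    visit log, per-class event counts and a status code (0 ok, 1 propensity
    non-finite, 2 aggregate-consistency failure, 3 visit log overflow).
    """
    n_dimers = methyl.shape[0]
    n_enz = n_r + n_b
    rng = _seed_rng(seed)
    m_max = 8 * (n_dimers // n_complexes)

    tether_occ = np.full(n_dimers, -1, dtype=np.int32)
    mod_occ = np.full(n_dimers, -1, dtype=np.int32)
    for e in range(n_enz):
        if enz_teth[e] >= 0:
            tether_occ[enz_teth[e]] = e
        if enz_mod[e] >= 0:
            mod_occ[enz_mod[e]] = e

    t = 0.0
    L = _ligand_at(proto_kind, L0, L1, t_step, ramp_r, L_min, L_max, 0.0)
    a_tab = _activity_table(m_max, L, eps_m, m_half, n_mwc, k_off, k_on)
    m_c, free_mod, s_a, w_r, w_b, n_free_teth, m_tot = _build_aggregates(
        methyl, complex_of, mod_occ, tether_occ, a_tab, n_complexes
    )
    n_bulk_r = 0
    n_loc_r = 0
    for e in range(n_r):
        if enz_teth[e] == -1 and enz_mod[e] == -1:
            n_bulk_r += 1
        else:
            n_loc_r += 1
    n_bulk_bp = 0
    n_bulk_b0 = 0
    n_loc_bp = 0
    for e in range(n_r, n_enz):
        if enz_teth[e] == -1 and enz_mod[e] == -1:
            if b_phos[e] == 1:
                n_bulk_bp += 1
            else:
                n_bulk_b0 += 1
        else:
            n_loc_bp += 1

    n_rec = int(np.floor(duration / record_dt + 1e-9)) + 1
    rec_t = np.empty(n_rec, dtype=np.float64)
    rec_a = np.empty(n_rec, dtype=np.float64)
    rec_m = np.empty(n_rec, dtype=np.float64)
    rec_loc_r = np.empty(n_rec, dtype=np.int32)
    rec_loc_bp = np.empty(n_rec, dtype=np.int32)
    rec_bulk_bp = np.empty(n_rec, dtype=np.int32)
    rec_inert_r = np.empty(n_rec, dtype=np.int32)
    rec_inert_bp = np.empty(n_rec, dtype=np.int32)

    cap = log_cap if log_visits else 1
    log_enz = np.empty(cap, dtype=np.int32)
    log_dimer = np.empty(cap, dtype=np.int32)
    log_time = np.empty(cap, dtype=np.float64)
    n_log = 0
    log_overflow = False

    ev_counts = np.zeros(N_EV, dtype=np.int64)
    scal = np.zeros(6, dtype=np.float64)
    p_mod_loc = np.zeros(n_enz, dtype=np.float64)
    p_teth_loc = np.zeros(n_enz, dtype=np.float64)
    p_t_un = np.zeros(n_enz, dtype=np.float64)
    p_m_un = np.zeros(n_enz, dtype=np.float64)
    p_cat = np.zeros(n_enz, dtype=np.float64)

    rec_i = 0
    status = 0
    events_since_resync = 0

    # next ligand-update pause
    if proto_kind == PROTO_CONST:
        next_pause = duration
    elif proto_kind == PROTO_STEP:
        next_pause = t_step if 0.0 < t_step < duration else duration
    else:
        next_pause = t_step if t_step > 0.0 else record_dt
        if next_pause > duration:
            next_pause = duration

    while status == 0:
        total = _sweep(
            rates, neighbor_binding, tether_scale,
            neighbors, n_neighbors, complex_of, a_tab, m_c, methyl, mod_occ, tether_occ,
            enz_teth, enz_mod, b_phos, n_r, n_enz,
            n_bulk_r, n_bulk_bp, n_bulk_b0, n_free_teth,
            s_a, w_r, w_b, n_complexes, n_dimers,
            scal, p_mod_loc, p_teth_loc, p_t_un, p_m_un, p_cat,
        )
        if not np.isfinite(total):
            status = 1
            break

        if total > 0.0:
            t_event = t - np.log(1.0 - _next_f64(rng)) / total
        else:
            t_event = np.inf
        t_stop = t_event
        if next_pause < t_stop:
            t_stop = next_pause
        if duration < t_stop:
            t_stop = duration

        # flush records in (t, t_stop] using the pre-event state
        while rec_i < n_rec and rec_i * record_dt <= t_stop + 1e-12:
            _write_record(
                rec_i, rec_i * record_dt, rec_t, rec_a, rec_m, rec_loc_r, rec_loc_bp,
                rec_bulk_bp, rec_inert_r, rec_inert_bp,
                s_a, m_tot, n_complexes, n_loc_r, n_loc_bp, n_bulk_bp,
                enz_teth, enz_mod, methyl, neighbors, n_neighbors, neighbor_binding,
                n_r, n_enz,
            )
            rec_i += 1

        if t_stop >= duration - 1e-12 and t_event >= duration and next_pause >= duration:
            t = duration
            break
        if t_event > next_pause:
            # ligand update
            t = next_pause
            L_new = _ligand_at(proto_kind, L0, L1, t_step, ramp_r, L_min, L_max, t)
            if L_new != L:
                L = L_new
                a_tab = _activity_table(m_max, L, eps_m, m_half, n_mwc, k_off, k_on)
                m_c, free_mod, s_a, w_r, w_b, n_free_teth, m_tot = _build_aggregates(
                    methyl, complex_of, mod_occ, tether_occ, a_tab, n_complexes
                )
            if proto_kind == PROTO_STEP:
                next_pause = duration
            else:
                next_pause = next_pause + record_dt
                if next_pause > duration:
                    next_pause = duration
            continue

        # an event fires at t_event
        t = t_event
        r = _next_f64(rng) * total
        s01 = scal[0] + scal[1]
        s03 = s01 + scal[2] + scal[3]
        s04 = s03 + scal[4]
        s05 = s04 + scal[5]
        if r < s01:
            # bulk -> tether (R if first window, else B-P)
            is_r = r < scal[0]
            if is_r:
                k_pick = int(_next_f64(rng) * n_bulk_r)
                if k_pick >= n_bulk_r:
                    k_pick = n_bulk_r - 1
                e_sel = -1
                cnt = 0
                for e in range(n_r):
                    if enz_teth[e] == -1 and enz_mod[e] == -1:
                        if cnt == k_pick:
                            e_sel = e
                            break
                        cnt += 1
            else:
                k_pick = int(_next_f64(rng) * n_bulk_bp)
                if k_pick >= n_bulk_bp:
                    k_pick = n_bulk_bp - 1
                e_sel = -1
                cnt = 0
                for e in range(n_r, n_enz):
                    if enz_teth[e] == -1 and enz_mod[e] == -1 and b_phos[e] == 1:
                        if cnt == k_pick:
                            e_sel = e
                            break
                        cnt += 1
            # pick free tether uniformly (rejection, then scan fallback)
            d_sel = -1
            for _ in range(256):
                d = int(_next_f64(rng) * n_dimers)
                if d >= n_dimers:
                    d = n_dimers - 1
                if tether_occ[d] == -1:
                    d_sel = d
                    break
            if d_sel == -1:
                k_pick = int(_next_f64(rng) * n_free_teth)
                cnt = 0
                for d in range(n_dimers):
                    if tether_occ[d] == -1:
                        if cnt == k_pick:
                            d_sel = d
                            break
                        cnt += 1
            tether_occ[d_sel] = e_sel
            enz_teth[e_sel] = d_sel
            n_free_teth -= 1
            if is_r:
                n_bulk_r -= 1
                n_loc_r += 1
            else:
                n_bulk_bp -= 1
                n_loc_bp += 1
            ev_counts[EV_T_BIND_BULK] += 1
            if log_visits:
                if n_log < cap:
                    log_enz[n_log] = e_sel
                    log_dimer[n_log] = d_sel
                    log_time[n_log] = t
                    n_log += 1
                else:
                    log_overflow = True
        elif r < s03:
            is_r = r < s01 + scal[2]
            if is_r:
                k_pick = int(_next_f64(rng) * n_bulk_r)
                if k_pick >= n_bulk_r:
                    k_pick = n_bulk_r - 1
                e_sel = -1
                cnt = 0
                for e in range(n_r):
                    if enz_teth[e] == -1 and enz_mod[e] == -1:
                        if cnt == k_pick:
                            e_sel = e
                            break
                        cnt += 1
            else:
                k_pick = int(_next_f64(rng) * n_bulk_bp)
                if k_pick >= n_bulk_bp:
                    k_pick = n_bulk_bp - 1
                e_sel = -1
                cnt = 0
                for e in range(n_r, n_enz):
                    if enz_teth[e] == -1 and enz_mod[e] == -1 and b_phos[e] == 1:
                        if cnt == k_pick:
                            e_sel = e
                            break
                        cnt += 1
            # pick free modsite with activity weight (rejection sampling)
            d_sel = -1
            for _ in range(4096):
                d = int(_next_f64(rng) * n_dimers)
                if d >= n_dimers:
                    d = n_dimers - 1
                if mod_occ[d] != -1:
                    continue
                a = a_tab[m_c[complex_of[d]]]
                w = (1.0 - a) if is_r else a
                if _next_f64(rng) < w:
                    d_sel = d
                    break
            if d_sel == -1:
                # weighted scan fallback
                target_w = w_r if is_r else w_b
                u = _next_f64(rng) * target_w
                acc = 0.0
                for d in range(n_dimers):
                    if mod_occ[d] == -1:
                        a = a_tab[m_c[complex_of[d]]]
                        acc += (1.0 - a) if is_r else a
                        if acc >= u:
                            d_sel = d
                            break
                if d_sel == -1:
                    for d in range(n_dimers - 1, -1, -1):
                        if mod_occ[d] == -1:
                            d_sel = d
                            break
            c = complex_of[d_sel]
            a = a_tab[m_c[c]]
            mod_occ[d_sel] = e_sel
            enz_mod[e_sel] = d_sel
            free_mod[c] -= 1
            w_r -= 1.0 - a
            w_b -= a
            if is_r:
                n_bulk_r -= 1
                n_loc_r += 1
            else:
                n_bulk_bp -= 1
                n_loc_bp += 1
            ev_counts[EV_M_BIND_BULK] += 1
            if log_visits:
                if n_log < cap:
                    log_enz[n_log] = e_sel
                    log_dimer[n_log] = d_sel
                    log_time[n_log] = t
                    n_log += 1
                else:
                    log_overflow = True
        elif r < s04:
            # phosphorylation of a bulk CheB
            k_pick = int(_next_f64(rng) * n_bulk_b0)
            if k_pick >= n_bulk_b0:
                k_pick = n_bulk_b0 - 1
            cnt = 0
            for e in range(n_r, n_enz):
                if enz_teth[e] == -1 and enz_mod[e] == -1 and b_phos[e] == 0:
                    if cnt == k_pick:
                        b_phos[e] = 1
                        break
                    cnt += 1
            n_bulk_b0 -= 1
            n_bulk_bp += 1
            ev_counts[EV_PHOS] += 1
        elif r < s05:
            # dephosphorylation of a bulk CheB-P
            k_pick = int(_next_f64(rng) * n_bulk_bp)
            if k_pick >= n_bulk_bp:
                k_pick = n_bulk_bp - 1
            cnt = 0
            for e in range(n_r, n_enz):
                if enz_teth[e] == -1 and enz_mod[e] == -1 and b_phos[e] == 1:
                    if cnt == k_pick:
                        b_phos[e] = 0
                        break
                    cnt += 1
            n_bulk_bp -= 1
            n_bulk_b0 += 1
            ev_counts[EV_DEPHOS] += 1
        else:
            # --- per-enzyme channels ---
            r -= s05
            e_sel = -1
            ch = -1
            for e in range(n_enz):
                if r < p_mod_loc[e]:
                    e_sel = e
                    ch = 0
                    break
                r -= p_mod_loc[e]
                if r < p_teth_loc[e]:
                    e_sel = e
                    ch = 1
                    break
                r -= p_teth_loc[e]
                if r < p_t_un[e]:
                    e_sel = e
                    ch = 2
                    break
                r -= p_t_un[e]
                if r < p_m_un[e]:
                    e_sel = e
                    ch = 3
                    break
                r -= p_m_un[e]
                if r < p_cat[e]:
                    e_sel = e
                    ch = 4
                    break
                r -= p_cat[e]
            if e_sel == -1:
                # numerical remainder; attribute to the last positive channel
                for e in range(n_enz - 1, -1, -1):
                    if p_cat[e] > 0:
                        e_sel = e
                        ch = 4
                        break
                    if p_m_un[e] > 0:
                        e_sel = e
                        ch = 3
                        break
                    if p_t_un[e] > 0:
                        e_sel = e
                        ch = 2
                        break
                    if p_teth_loc[e] > 0:
                        e_sel = e
                        ch = 1
                        break
                    if p_mod_loc[e] > 0:
                        e_sel = e
                        ch = 0
                        break
            if e_sel == -1:
                status = 1
                break
            is_r = e_sel < n_r
            if ch == 0:
                # tethered enzyme binds a reachable free modification site
                anchor = enz_teth[e_sel]
                u = _next_f64(rng) * p_mod_loc[e_sel]
                k_loc = rates[R_M_BIND_LOC_R] if is_r else rates[R_M_BIND_LOC_B]
                acc = 0.0
                d_sel = -1
                if mod_occ[anchor] == -1:
                    a = a_tab[m_c[complex_of[anchor]]]
                    acc += k_loc * ((1.0 - a) if is_r else a)
                    if acc >= u:
                        d_sel = anchor
                if d_sel == -1 and neighbor_binding:
                    for k in range(n_neighbors[anchor]):
                        d2 = neighbors[anchor, k]
                        if mod_occ[d2] == -1:
                            a = a_tab[m_c[complex_of[d2]]]
                            acc += k_loc * ((1.0 - a) if is_r else a)
                            if acc >= u:
                                d_sel = d2
                                break
                if d_sel == -1:
                    if mod_occ[anchor] == -1:
                        d_sel = anchor
                    else:
                        for k in range(n_neighbors[anchor] - 1, -1, -1):
                            d2 = neighbors[anchor, k]
                            if mod_occ[d2] == -1:
                                d_sel = d2
                                break
                c = complex_of[d_sel]
                a = a_tab[m_c[c]]
                mod_occ[d_sel] = e_sel
                enz_mod[e_sel] = d_sel
                free_mod[c] -= 1
                w_r -= 1.0 - a
                w_b -= a
                ev_counts[EV_M_BIND_LOC] += 1
                if log_visits:
                    if n_log < cap:
                        log_enz[n_log] = e_sel
                        log_dimer[n_log] = d_sel
                        log_time[n_log] = t
                        n_log += 1
                    else:
                        log_overflow = True
            elif ch == 1:
                # modsite-bound enzyme grabs a reachable free tether
                anchor = enz_mod[e_sel]
                u = _next_f64(rng) * p_teth_loc[e_sel]
                k_loc = rates[R_T_BIND_LOC_R] if is_r else rates[R_T_BIND_LOC_B]
                acc = 0.0
                d_sel = -1
                if tether_occ[anchor] == -1:
                    acc += k_loc
                    if acc >= u:
                        d_sel = anchor
                if d_sel == -1 and neighbor_binding:
                    for k in range(n_neighbors[anchor]):
                        d2 = neighbors[anchor, k]
                        if tether_occ[d2] == -1:
                            acc += k_loc
                            if acc >= u:
                                d_sel = d2
                                break
                if d_sel == -1:
                    if tether_occ[anchor] == -1:
                        d_sel = anchor
                    else:
                        for k in range(n_neighbors[anchor] - 1, -1, -1):
                            d2 = neighbors[anchor, k]
                            if tether_occ[d2] == -1:
                                d_sel = d2
                                break
                tether_occ[d_sel] = e_sel
                enz_teth[e_sel] = d_sel
                n_free_teth -= 1
                ev_counts[EV_T_BIND_LOC] += 1
                if log_visits:
                    if n_log < cap:
                        log_enz[n_log] = e_sel
                        log_dimer[n_log] = d_sel
                        log_time[n_log] = t
                        n_log += 1
                    else:
                        log_overflow = True
            elif ch == 2:
                # tether release
                d = enz_teth[e_sel]
                tether_occ[d] = -1
                enz_teth[e_sel] = -1
                n_free_teth += 1
                ev_counts[EV_T_UNBIND] += 1
                if enz_mod[e_sel] == -1:
                    if is_r:
                        n_bulk_r += 1
                        n_loc_r -= 1
                    else:
                        n_bulk_bp += 1
                        n_loc_bp -= 1
                    if log_visits:
                        if n_log < cap:
                            log_enz[n_log] = e_sel
                            log_dimer[n_log] = -1
                            log_time[n_log] = t
                            n_log += 1
                        else:
                            log_overflow = True
            elif ch == 3:
                # modification-site release
                d = enz_mod[e_sel]
                c = complex_of[d]
                a = a_tab[m_c[c]]
                mod_occ[d] = -1
                enz_mod[e_sel] = -1
                free_mod[c] += 1
                w_r += 1.0 - a
                w_b += a
                ev_counts[EV_M_UNBIND] += 1
                if enz_teth[e_sel] == -1:
                    if is_r:
                        n_bulk_r += 1
                        n_loc_r -= 1
                    else:
                        n_bulk_bp += 1
                        n_loc_bp -= 1
                    if log_visits:
                        if n_log < cap:
                            log_enz[n_log] = e_sel
                            log_dimer[n_log] = -1
                            log_time[n_log] = t
                            n_log += 1
                        else:
                            log_overflow = True
            else:
                # catalysis: CheR methylates, CheB-P demethylates
                d = enz_mod[e_sel]
                c = complex_of[d]
                a_old = a_tab[m_c[c]]
                if is_r:
                    methyl[d] += 1
                    m_c[c] += 1
                    m_tot += 1
                    ev_counts[EV_CAT_R] += 1
                else:
                    methyl[d] -= 1
                    m_c[c] -= 1
                    m_tot -= 1
                    ev_counts[EV_CAT_B] += 1
                a_new = a_tab[m_c[c]]
                s_a += a_new - a_old
                w_r += (a_old - a_new) * free_mod[c]
                w_b += (a_new - a_old) * free_mod[c]
                if release_on_cat:
                    mod_occ[d] = -1
                    enz_mod[e_sel] = -1
                    free_mod[c] += 1
                    w_r += 1.0 - a_new
                    w_b += a_new
                    if enz_teth[e_sel] == -1:
                        if is_r:
                            n_bulk_r += 1
                            n_loc_r -= 1
                        else:
                            n_bulk_bp += 1
                            n_loc_bp -= 1
                        if log_visits:
                            if n_log < cap:
                                log_enz[n_log] = e_sel
                                log_dimer[n_log] = -1
                                log_time[n_log] = t
                                n_log += 1
                            else:
                                log_overflow = True

        events_since_resync += 1
        if events_since_resync >= resync_every:
            events_since_resync = 0
            m_c2, free_mod2, s_a2, w_r2, w_b2, n_free_teth2, m_tot2 = _build_aggregates(
                methyl, complex_of, mod_occ, tether_occ, a_tab, n_complexes
            )
            if check_consistency:
                scale = 1.0 + abs(s_a2) + abs(w_r2) + abs(w_b2)
                if abs(s_a - s_a2) > 1e-9 * scale:
                    status = 21
                    break
                if abs(w_r - w_r2) > 1e-9 * scale:
                    status = 22
                    break
                if abs(w_b - w_b2) > 1e-9 * scale:
                    status = 23
                    break
                if n_free_teth != n_free_teth2:
                    status = 24
                    break
                if m_tot != m_tot2:
                    status = 25
                    break
            m_c, free_mod, s_a, w_r, w_b, n_free_teth, m_tot = (
                m_c2, free_mod2, s_a2, w_r2, w_b2, n_free_teth2, m_tot2,
            )

    if log_overflow and status == 0:
        status = 3
    return (
        rec_t[:rec_i], rec_a[:rec_i], rec_m[:rec_i],
        rec_loc_r[:rec_i], rec_loc_bp[:rec_i], rec_bulk_bp[:rec_i],
        rec_inert_r[:rec_i], rec_inert_bp[:rec_i],
        log_enz[:n_log], log_dimer[:n_log], log_time[:n_log],
        ev_counts, status,
    )


@njit(cache=False)
def run_wellmixed_ssa(
    n_complexes, m_per_complex_max, m_init,
    r_tot, b_tot, k_r, k_b, big_k_r, big_k_b, a_p, d_p,
    eps_m, m_half, n_mwc, k_off, k_on,
    proto_kind, L0, L1, t_step, ramp_r, L_min, L_max,
    duration, record_dt, seed,
):
    """Birth-death SSA of the no-localization (well-mixed) baseline.

    Total methylation ``M`` performs a jump process with Goldbeter-Koshland
    rates on total enzyme pools; the bulk CheB-P feedback is adiabatic
    (deterministic function of activity).  Returns (t, a, m) records.
    """
    rng = _seed_rng(seed)
    m_cap = n_complexes * m_per_complex_max
    M = m_init
    t = 0.0

    n_rec = int(np.floor(duration / record_dt + 1e-9)) + 1
    rec_t = np.empty(n_rec, dtype=np.float64)
    rec_a = np.empty(n_rec, dtype=np.float64)
    rec_m = np.empty(n_rec, dtype=np.float64)
    rec_i = 0

    while True:
        L = _ligand_at(proto_kind, L0, L1, t_step, ramp_r, L_min, L_max, t)
        m = M / n_complexes
        f = eps_m * (m_half - m) + n_mwc * (np.log1p(L / k_off) - np.log1p(L / k_on))
        a = 1.0 / (1.0 + np.exp(f))
        phi = a_p * a / d_p
        b_p = phi * b_tot / (1.0 + phi)
        v_up = k_r * r_tot * (1.0 - a) / ((1.0 - a) + big_k_r) if M < m_cap else 0.0
        v_dn = k_b * b_p * a / (a + big_k_b) if M > 0 else 0.0
        total = v_up + v_dn
        if total > 0.0:
            t_next = t - np.log(1.0 - _next_f64(rng)) / total
        else:
            t_next = duration
        fire = total > 0.0
        # ligand discontinuities: cap the jump at the next update time
        if proto_kind == PROTO_STEP and t < t_step and t_next > t_step:
            t_next = t_step
            fire = False
        elif proto_kind == PROTO_RAMP and t_next > t + record_dt:
            t_next = t + record_dt
            fire = False
        if t_next > duration:
            t_next = duration
            fire = False

        while rec_i < n_rec and rec_i * record_dt <= t_next + 1e-12:
            rec_t[rec_i] = rec_i * record_dt
            rec_a[rec_i] = a
            rec_m[rec_i] = m
            rec_i += 1
        t = t_next
        if t >= duration - 1e-12 or rec_i >= n_rec:
            break
        if fire:
            if _next_f64(rng) * total < v_up:
                M += 1
            else:
                M -= 1
    return rec_t[:rec_i], rec_a[:rec_i], rec_m[:rec_i]
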
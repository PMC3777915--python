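"""In-silico protocols: noise statistics, step/ramp responses, parameter
scans, population sampling with conserved stoichiometry, and processivity
metrics.

All outputs are pure functions of (configuration, seeds): rerunning with the
same inputs reproduces every table bit-identically.  Stochastic-lattice
protocols default to a reduced 1152-dimer lattice (an 8x8-unit patch of the
7200-dimer cluster) with enzyme counts scaled by the dimer ratio, which
preserves all intensive quantities (densities, rates per enzyme) while
keeping desk-scale runtimes; lattice size is configurable throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import lna as lna_mod
from . import meanfield as mf
from .lattice import LatticeGeometry, build_lattice
from .mwc import MWCParams, calibrate
from .reaction_system import CopyNumbers, RateSet, SystemState, VariantFlags, variant
from .ssa_engine import LigandProtocol, Trace, equilibrate, simulate, simulate_wellmixed

__all__ = [
    "NoiseStats",
    "PopulationSpec",
    "ProcessivityStats",
    "LatticeConfig",
    "noise_stats",
    "sliding_window",
    "adaptation_precision",
    "ramp_response",
    "scan",
    "sample_multipliers",
    "population_run",
    "processivity_rate",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Bundle of lattice-model settings shared by the protocols."""

    units: tuple[int, int] = (8, 8)
    rates: RateSet = field(default_factory=RateSet)
    flags: VariantFlags = field(default_factory=VariantFlags.m1)
    mwc: MWCParams = field(default_factory=calibrate)
    record_dt: float = 0.1
    burn_in: float = 500.0
    duration: float = 800.0
    initial_methyl: int = 1

    def geometry(self) -> LatticeGeometry:
        return build_lattice(*self.units)

    def copies(self, multiplier_r: float = 1.0, multiplier_all: float = 1.0) -> CopyNumbers:
        base = CopyNumbers.for_dimers(18 * self.units[0] * self.units[1], multiplier_all)
        return CopyNumbers(che_r=max(1, round(base.che_r * multiplier_r)), che_b=base.che_b)


@dataclass(frozen=True)
class NoiseStats:
    """Stationary fluctuation statistics of a recorded activity trace."""

    a0: float
    sigma_aa: float
    rel_noise: float
    n_samples: int


@dataclass(frozen=True)
class PopulationSpec:
    """Cell-to-cell expression variability with conserved stoichiometry.

    Multipliers are drawn from a log-normal (median 1, log-sd ``sigma_ln``)
    or laid out on a geometric grid spanning ``[lo, hi]``; with
    ``ratio_preserved`` CheR, CheB and receptor counts co-scale exactly.
    """

    n_cells: int = 8
    sigma_ln: float = 0.35
    ratio_preserved: bool = True
    seed: int = 0
    kind: str = "grid"          # "grid" | "lognormal"
    lo: float = 0.5
    hi: float = 2.0


@dataclass(frozen=True)
class ProcessivityStats:
    """Unique receptor dimers visited by localized enzymes per second."""

    rate: float
    rate_cheR: float
    rate_cheBp: float
    unique_visits: int
    localized_time: float


def noise_stats(trace: Trace, burn_in: float = 0.0) -> NoiseStats:
    """Mean and variance of the raw (unsmoothed) activity after ``burn_in``."""
    mask = trace.t >= burn_in
    a = np.asarray(trace.activity)[mask]
    if a.size < 2:
        raise ValueError("trace shorter than the burn-in window")
    a0 = float(a.mean())
    var = float(a.var())
    return NoiseStats(a0=a0, sigma_aa=var,
                      rel_noise=float(np.sqrt(var) / a0) if a0 > 0 else np.inf,
                      n_samples=int(a.size))


def sliding_window(t: np.ndarray, x: np.ndarray, window: float = 30.0) -> np.ndarray:
    """Centered sliding-window average (display smoothing only)."""
    dt = float(np.median(np.diff(t)))
    n = max(1, int(round(window / dt)))
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def adaptation_precision(trace: Trace, protocol: LigandProtocol,
                         tail_fraction: float = 0.2) -> float:
    """Precision of adaptation to a step: 1 - |a_adapted - a_pre| / a_pre.

    ``a_pre`` is the mean activity before the step, ``a_adapted`` the mean
    over the final ``tail_fraction`` of the post-step window.
    """
    if protocol.kind != "step":
        raise ValueError("adaptation precision is defined for step protocols")
    t = np.asarray(trace.t)
    a = np.asarray(trace.activity)
    pre = a[t < protocol.t_step]
    post_t0 = protocol.t_step + (1.0 - tail_fraction) * (t[-1] - protocol.t_step)
    tail = a[t >= post_t0]
    if pre.size < 2 or tail.size < 2:
        raise ValueError("trace does not bracket the step with enough samples")
    a_pre = float(pre.mean())
    a_adapted = float(tail.mean())
    return 1.0 - abs(a_adapted - a_pre) / a_pre


def _exp_plateau(t, a_inf, delta, tau):
    return a_inf + delta * np.exp(-t / tau)


def ramp_response(
    ramp_rates,
    engine: str = "meanfield",
    params: mf.MeanFieldParams | None = None,
    config: LatticeConfig | None = None,
    n_seeds: int = 10,
    seed: int = 1,
    ramp_window: float = 150.0,
) -> pd.DataFrame:
    """Steady ramp activity versus exponential ramp rate.

    For each rate ``r`` the model is driven by ``L = 84 exp(r t) uM``
    (clipped to the 84-620 uM calibration window) and the activity during
    the ramp is fitted by an exponential approach to a plateau; the plateau
    is the steady ramp activity.  Engine ``meanfield`` integrates the ODEs;
    ``ssa`` averages the lattice response over ``n_seeds`` matched runs.
    """
    rows = []
    p = params or mf.MeanFieldParams()
    for r in np.atleast_1d(np.asarray(ramp_rates, dtype=float)):
        window = min(ramp_window, np.log(620.0 / 84.0) / abs(r)) if r != 0 else ramp_window
        proto = LigandProtocol.ramp(rate=r, L0=84.0)
        if engine == "meanfield":
            from scipy.integrate import solve_ivp

            a0, st = mf.steady_state(84.0, p)
            sol = solve_ivp(
                lambda t, y: mf.rhs(y, float(proto.ligand_at(t)), p),
                (0.0, window), st.as_vector(), method="LSODA",
                rtol=1e-10, atol=1e-10, dense_output=True,
            )
            tt = np.linspace(0.05 * window, window, 200)
            aa = np.array([mf.activity(sol.sol(t)[0], float(proto.ligand_at(t)), p) for t in tt])
        elif engine == "ssa":
            cfg = config or LatticeConfig()
            geom = cfg.geometry()
            copies = cfg.copies()
            traces = []
            for k in range(n_seeds):
                state, _ = equilibrate(
                    geom, cfg.rates, cfg.flags, cfg.mwc, copies,
                    duration=1.0, seed=seed + 1000 * k, burn_in=cfg.burn_in,
                    L=84.0, record_dt=cfg.record_dt,
                )
                tr = simulate(
                    geom, cfg.rates, cfg.flags, cfg.mwc, copies, proto,
                    duration=window, seed=seed + 1000 * k + 7,
                    record_dt=cfg.record_dt, initial_state=state,
                )
                traces.append(tr.activity)
            aa_full = np.mean(traces, axis=0)
            tt_full = traces and np.arange(aa_full.size) * cfg.record_dt
            keep = tt_full >= 0.05 * window
            tt, aa = tt_full[keep], aa_full[keep]
        else:
            raise ValueError(f"unknown engine {engine!r}")
        a_start = float(aa[0])
        try:
            import warnings
            from scipy.optimize import OptimizeWarning

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                _exp_plateau, tt, aa,
                p0=(float(aa[-1]), a_start - float(aa[-1]), max(window / 5.0, 1.0)),
                    maxfev=20000,
                )
            plateau = float(popt[0])
        except RuntimeError:
            plateau = float(np.mean(aa[-max(5, aa.size // 5):]))
        rows.append({"ramp_rate": float(r), "plateau_activity": plateau,
                     "engine": engine})
    return pd.DataFrame(rows)


def scan(
    values,
    param: str = "r_tot",
    engine: str = "lna",
    params: mf.MeanFieldParams | None = None,
    b1_params: mf.WellMixedParams | None = None,
    config: LatticeConfig | None = None,
    seeds=(1, 2, 3),
    L: float = 0.0,
) -> pd.DataFrame:
    """Tidy table of steady-state / noise quantities along a parameter sweep.

    ``values`` are multipliers applied to the nominal value of ``param``
    (``r_tot`` or ``ratio`` = CheR/CheB with CheB fixed).  Engines:
    ``meanfield`` (deterministic steady states), ``lna`` (adds the
    Lyapunov noise solution), ``b1``/``b1_ssa`` (well-mixed baseline,
    analytic / stochastic), ``ssa`` (lattice simulation; rows carry seed
    and window metadata).
    """
    rows = []
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if engine in ("meanfield", "lna"):
        base = params or mf.MeanFieldParams()
        for x in values:
            p = replace(base, r_tot=base.r_tot * x) if param in ("r_tot", "ratio") \
                else replace(base, **{param: getattr(base, param) * x})
            try:
                a0, st = mf.steady_state(L, p)
            except RuntimeError:
                rows.append({"multiplier": x, "a0": np.nan, "pinned": True})
                continue
            eff = mf.effective_constants(p, a0)
            row = {
                "multiplier": float(x), "r_tot": p.r_tot, "a0": a0, "m0": st.m,
                "rstar": st.rstar_tot, "bstar": st.bstar_tot, "b_p": st.b_p,
                "k_tilde_r": eff.k_tilde_r, "k_tilde_b": eff.k_tilde_b,
                "pinned": False,
            }
            if engine == "lna":
                res = lna_mod.activity_variance(lna_mod.linearize(p, L, steady=(a0, st)))
                row.update({
                    "sigma_aa": res.sigma_aa, "rel_noise": res.rel_noise,
                    "sigma_aa_R": res.parts[0], "sigma_aa_B": res.parts[1],
                    "sigma_aa_m": res.parts[2],
                })
            rows.append(row)
    elif engine == "b1":
        base = b1_params or mf.WellMixedParams()
        for x in values:
            p = replace(base, r_tot=base.r_tot * x)
            try:
                res = lna_mod.b1_noise(p, L)
            except RuntimeError:
                rows.append({"multiplier": x, "a0": np.nan, "pinned": True})
                continue
            rows.append({
                "multiplier": float(x), "r_tot": p.r_tot, "a0": res.a0,
                "sigma_aa": res.sigma_aa, "rel_noise": res.rel_noise,
                "pinned": False,
            })
    elif engine == "b1_ssa":
        base = b1_params or mf.WellMixedParams()
        cfg = config or LatticeConfig()
        for x in values:
            p = replace(base, r_tot=base.r_tot * x)
            for sd in seeds:
                tr = simulate_wellmixed(
                    p, LigandProtocol.constant(L),
                    duration=cfg.burn_in + cfg.duration, seed=sd,
                    record_dt=cfg.record_dt,
                )
                ns = noise_stats(tr, burn_in=cfg.burn_in)
                rows.append({
                    "multiplier": float(x), "r_tot": p.r_tot, "seed": int(sd),
                    "a0": ns.a0, "sigma_aa": ns.sigma_aa,
                    "rel_noise": ns.rel_noise, "window": cfg.duration,
                })
    elif engine == "ssa":
        cfg = config or LatticeConfig()
        geom = cfg.geometry()
        for x in values:
            copies = cfg.copies(multiplier_r=x)
            for sd in seeds:
                _, tr = equilibrate(
                    geom, cfg.rates, cfg.flags, cfg.mwc, copies,
                    duration=cfg.duration, seed=int(sd), burn_in=cfg.burn_in,
                    L=L, record_dt=cfg.record_dt,
                    initial_methyl=cfg.initial_methyl,
                )
                ns = noise_stats(tr)
                loc_r = float(np.mean(tr.localized_cheR))
                loc_b = float(np.mean(tr.localized_cheBp))
                inert_b = float(np.mean(tr.inert_cheBp))
                inert_r = float(np.mean(tr.inert_cheR))
                active_ratio = ((loc_r - inert_r) / max(loc_b - inert_b, 1e-12))
                rows.append({
                    "multiplier": float(x), "che_r": copies.che_r,
                    "che_b": copies.che_b, "seed": int(sd),
                    "a0": ns.a0, "sigma_aa": ns.sigma_aa,
                    "rel_noise": ns.rel_noise,
                    "localized_cheR": loc_r, "localized_cheBp": loc_b,
                    "inert_cheBp": inert_b,
                    "localized_ratio": active_ratio,
                    "window": cfg.duration, "burn_in": cfg.burn_in,
                    "variant": cfg.flags.name,
                })
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return pd.DataFrame(rows)


def sample_multipliers(spec: PopulationSpec) -> np.ndarray:
    """Expression multipliers for a sampled population (sorted ascending)."""
    if spec.kind == "grid":
        return np.geomspace(spec.lo, spec.hi, spec.n_cells)
    if spec.kind == "lognormal":
        rng = np.random.default_rng(spec.seed)
        return np.sort(rng.lognormal(mean=0.0, sigma=spec.sigma_ln, size=spec.n_cells))
    raise ValueError(f"unknown population kind {spec.kind!r}")


def population_run(
    spec: PopulationSpec,
    model: str = "M1",
    config: LatticeConfig | None = None,
    b1_params: mf.WellMixedParams | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Per-cell stationary noise across an expression-level population.

    Every cell's CheR, CheB and receptor counts are co-scaled by its
    multiplier (stoichiometry conserved; intrinsic expression noise
    ignored).  Lattice cells scale their receptor count by adjusting the
    lattice height in whole hexagonal units, so the realized multiplier is
    reported alongside the requested one.
    """
    if not spec.ratio_preserved:
        raise NotImplementedError("only the ratio-preserved protocol is implemented")
    mults = sample_multipliers(spec)
    rows = []
    if model.upper() in ("M1", "M2", "M3"):
        cfg = config or LatticeConfig()
        cfg = replace(cfg, flags=variant(model))
        w, h = cfg.units
        for i, mult in enumerate(mults):
            h_cell = max(1, round(h * mult))
            geom = build_lattice(w, h_cell)
            realized = h_cell / h
            copies = CopyNumbers.for_dimers(geom.n_dimers)
            _, tr = equilibrate(
                geom, cfg.rates, cfg.flags, cfg.mwc, copies,
                duration=cfg.duration, seed=seed + 100 * i, burn_in=cfg.burn_in,
                L=0.0, record_dt=cfg.record_dt, initial_methyl=cfg.initial_methyl,
            )
            ns = noise_stats(tr)
            rows.append({
                "cell": i, "multiplier": float(mult), "realized_multiplier": realized,
                "n_dimers": geom.n_dimers, "che_r": copies.che_r, "che_b": copies.che_b,
                "a0": ns.a0, "sigma_aa": ns.sigma_aa, "rel_noise": ns.rel_noise,
                "model": model.upper(), "sigma_ln": spec.sigma_ln,
            })
    elif model.upper() in ("B1", "B2"):
        base = b1_params or mf.WellMixedParams()
        if model.upper() == "B2":
            base = base.as_b2()
        cfg = config or LatticeConfig()
        for i, mult in enumerate(mults):
            p = base.scaled(mult)
            tr = simulate_wellmixed(
                p, LigandProtocol.constant(0.0),
                duration=cfg.burn_in + cfg.duration, seed=seed + 100 * i,
                record_dt=cfg.record_dt,
            )
            ns = noise_stats(tr, burn_in=cfg.burn_in)
            rows.append({
                "cell": i, "multiplier": float(mult), "realized_multiplier": float(mult),
                "a0": ns.a0, "sigma_aa": ns.sigma_aa, "rel_noise": ns.rel_noise,
                "model": model.upper(), "sigma_ln": spec.sigma_ln,
            })
    else:
        raise ValueError(f"unknown model {model!r}")
    return pd.DataFrame(rows)


def processivity_rate(
    visit_log: pd.DataFrame,
    window: tuple[float, float],
    n_r: int,
    initial_state: SystemState | None = None,
) -> ProcessivityStats:
    """Unique dimers visited per localized-enzyme-second.

    A visit is a tether or modification-site binding to a dimer not yet
    touched during the enzyme's current residence on the lattice (a new
    residence restarts the count).  The rate is total unique visits divided
    by total localized time, aggregated per species; higher rates mean more
    distributive modification.

    ``initial_state`` marks enzymes already localized when logging began so
    their residence clocks start at the window opening.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window must be ordered")
    unique = {True: 0, False: 0}
    loc_time = {True: 0.0, False: 0.0}

    start: dict[int, float] = {}
    visited: dict[int, set] = {}
    if initial_state is not None:
        for e in range(initial_state.n_enzymes):
            if not initial_state.is_bulk(e):
                start[e] = w0
                v = set()
                if initial_state.enz_teth[e] >= 0:
                    v.add(int(initial_state.enz_teth[e]))
                if initial_state.enz_mod[e] >= 0:
                    v.add(int(initial_state.enz_mod[e]))
                visited[e] = v

    for e_id, dimer, t in zip(visit_log["enzyme"].to_numpy(),
                              visit_log["dimer"].to_numpy(),
                              visit_log["t"].to_numpy()):
        e_id = int(e_id)
        is_r = e_id < n_r
        if dimer < 0:  # returned to bulk
            if e_id in start:
                t0, t1 = max(start[e_id], w0), min(t, w1)
                if t1 > t0:
                    loc_time[is_r] += t1 - t0
                start.pop(e_id)
                visited.pop(e_id, None)
            continue
        if e_id not in start:
            start[e_id] = t
            visited[e_id] = set()
        if int(dimer) not in visited[e_id]:
            visited[e_id].add(int(dimer))
            if w0 <= t <= w1:
                unique[is_r] += 1
    for e_id, t0 in start.items():  # still localized at window close
        t0c, t1c = max(t0, w0), w1
        if t1c > t0c:
            loc_time[e_id < n_r] += t1c - t0c

    tot_time = loc_time[True] + loc_time[False]
    tot_unique = unique[True] + unique[False]
    return ProcessivityStats(
        rate=tot_unique / tot_time if tot_time > 0 else 0.0,
        rate_cheR=unique[True] / loc_time[True] if loc_time[True] > 0 else 0.0,
        rate_cheBp=unique[False] / loc_time[False] if loc_time[False] > 0 else 0.0,
        unique_visits=int(tot_unique),
        localized_time=float(tot_time),
    )
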
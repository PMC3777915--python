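# Methods

## The system being modeled

Chemoreceptor dimers of *E. coli* (Tar only) tile a hexagonal lattice;
groups of six dimers form one cooperative MWC signaling complex, and three
complexes form the basic hexagonal unit, so a lattice of `w x h` units has
`18wh` dimers. Each dimer carries 0–8 methyl groups, one high-affinity
tether site and one modification site. A complex with total methylation
`m` at attractant concentration `L` (µM methyl-aspartate) is active with
probability

    a(m, L) = 1 / (1 + exp(F)),
    F = ε_m (m_half − m) + N ln[(1 + L/K_off) / (1 + L/K_on)],

an equilibrium property because receptor switching and ligand exchange are
much faster than methylation. Adaptation: CheR methylates (binding to
modification sites with weight `1 − a`), CheB-P demethylates (weight `a`);
CheB is phosphorylated in the bulk at a rate proportional to the mean
lattice activity and autodephosphorylates; only CheB-P binds the lattice.
Enzymes localize slowly from the bulk (tether binding, ~15 s), and once
localized react quickly (ms) with the modification sites of the seven
dimers of an assistance neighborhood, or hand themselves across the lattice
by alternately binding tethers and modification sites (brachiation).

Variants: **M1** (reference), **M2** (no neighborhood reactions: tethered
enzymes reach only their own dimer, eliminating neighborhoods and
brachiation), **M3** (tether unbinding slowed 20-fold: neighborhoods kept,
brachiation inefficient). Baselines **B1**/**B2** drop localization
entirely: total enzyme pools act on the receptors with Michaelis kinetics
(`K = 0.5` for B1; ten-fold higher affinity for B2).

## Stochastic simulator

The simulator is an exact Gillespie algorithm over the rule set above,
implemented twice: a pure-Python reference (`reaction_system`) used by
tests and enumeration oracles, and a compiled numba kernel (`_kernel`) with
identical semantics used for production runs. Correctness of the kernel is
established by (i) per-class propensity equality with the reference on
fuzzed states across variants, and (ii) agreement of its stationary
distribution with the brute-force CTMC solution of an enumerable
micro-model (a synthetic two-dimer complex with one CheR and one CheB,
~6,000 states; total-variation distance < 0.04 on methylation and
localization marginals).

Numerical choices:

* Activity is a lookup table over integer complex methylation, rebuilt on
  ligand changes. Time-varying ligand (steps, exponential ramps) is
  piecewise constant on the 0.1 s recording grid; ramp time scales (tens
  of seconds) far exceed event time scales, so the bias is negligible.
* Three running lattice aggregates (summed activity, activity-weighted free
  modification sites per species) are updated incrementally per event and
  rebuilt periodically (every 200k events) to cancel float drift; an
  optional consistency check asserts the incremental and rebuilt values
  agree to 1e-9 relative.
* Randomness is a self-contained xorshift128+ stream seeded via splitmix64:
  identical inputs give bit-identical traces on any platform.
* A catalytic event releases the enzyme's modification-site bond (it keeps
  its tether if it has one; otherwise it returns to the bulk). The
  biochemistry does not pin down the post-catalysis fate; this
  choice (config switch `release_on_catalysis`) makes M2's
  one-receptor-per-residence processivity arise from tether residence
  rather than permanent modification-site binding.
* Tether sites vastly outnumber enzymes, so bulk tether binding proceeds at
  a constant per-enzyme rate with a uniformly chosen free tether; bulk
  modification-site binding is activity-weighted per target complex.

## Mean-field model and noise analysis

Averaging over a single maximal assistance neighborhood (equivalently,
infinitely fast brachiation) gives ODEs for `(m, R*_tot, B*_tot)` with the
doubly bound fractions in quasi-equilibrium and the bulk CheB-P pool
quasi-steady (`B_p = φ(B_tot − B*)/(1+φ)`, `φ = a_p a / d_p`). Because
`dm/dt` depends on receptors only through `a`, the model adapts precisely:
the stationary activity solves a ligand-independent Goldbeter–Koshland
balance. Eliminating the localized pools yields the same balance on *total*
enzyme counts with effective inverse affinities

    K̃_r = K_r (1 + k_t−/k_t+),
    K̃_b = K_b (1 + (k_t−/k_t+)(1 + d_p/(a_p a))),

verified against long ODE relaxation to 1e-8 across three decades of
`K`. The steady state is found by bracketed root solving on `a` (the
balance is monotone), cross-checked by relaxation.

The linear noise approximation linearizes the ODEs at the fixed point
(analytic Jacobian, checked against finite differences to 1e-6) and builds
the diffusion matrix `D = S diag(v) Sᵀ` from six elementary events:
methylation/demethylation of single sites and tether bind/unbind of single
CheR and CheB-P molecules at their stationary propensities. The stationary
covariance solves the Lyapunov equation `Aσ + σAᵀ + D = 0` (dense solve,
residual verified). The activity variance is `σ_aa = (da/dm)² σ_mm`, and
because the Lyapunov equation is linear in `D` it decomposes exactly into
the three channels; the CheR and CheB-P exchange channels dominate the
methylation shot-noise channel several-fold at the defaults. The bulk
CheB-P pool is adiabatically eliminated before linearization; its shot
noise is not carried separately (it folds into the CheB channel through the
quasi-steady feedback), consistent with the model reduction.

The stochastic B1/B2 baseline is a birth–death jump process on total
methylation with the same Goldbeter–Koshland rates and deterministic
CheB-P feedback — the intrinsic-methylation-noise model class, which gives
1–3% relative noise.

## Parameters

Defaults (all rates 1/s, concentrations µM, energies kT):

| parameter | value | basis |
| --- | --- | --- |
| receptor dimers / CheR / CheB per cell | 7200 / 140 / 240 | immunoblotting-scale estimates |
| `N`, dimers per MWC complex | 6 | cryo-EM-scale cluster organization |
| `ε_m` | 0.6 | per-methyl free energy; leaves 48·0.6 ≈ 29 kT of adaptable range, enough to absorb a 1 mM methyl-aspartate step (22.5 kT) |
| `m_half` | 6 | calibration anchor: a = 0.5 at one methyl group per dimer, zero ligand |
| `K_off`, `K_on` | 18, 3000 | Tar/methyl-aspartate dose-response-style constants |
| `k_t_bind` | 1/15 | measured enzyme localization time ~15 s |
| `k_t_unbind` | 0.9 | balanced tether exchange; comparable localized and bulk pools; `K̃_r ≈ 1.06` |
| `k_m_bind_local`, `k_t_bind_local` | 200 (per site) | local reactions on the 1–10 ms scale (~5 ms); local `K_r ≈ 0.07 ≪ 1` |
| `k_m_unbind` | 100 | ~10 ms modification-site residence |
| `k_cat_r`, `k_cat_b` | 2.5, 3.6 | adaptation over ~100 s; operating activity a₀ ≈ 0.28 (mean-field), in the typical 0.3–0.5 band |
| `a_p`, `d_p` | 0.1, 0.01 | phosphorylation feedback factor `1 + d_p/(a_p a) ≈ 1.3`: present but not sufficient for robustness on its own |
| B1: `k_r`, `k_b`, `K` | 1.45, 1.7, 0.5 | matched operating activity and adaptation velocity; 1–3% intrinsic noise |
| M3 tether-unbind scale | 0.05 | brachiation slowed enough to sit between M1 and M2 on every ordering |

Most microscopic rate constants of this system are not individually
measured; the defaults above were fixed once against the well-established
constraints (localization time, local-reaction time scales, saturated local
kinetics with `K̃ ≳ 1`, operating activity, ~7% peak analytical noise) and
are config-overridable throughout. The mapping from simulator rates to
mean-field constants is `K = (k_m_unbind + k_cat)/(7 k_m_bind_local)` with
tether and catalytic rates carried over directly
(`MeanFieldParams.from_rate_set`).

## Scales used in tests and the acceptance script

Stochastic runs use a reduced lattice of 8×8 hexagonal units (1152 dimers,
192 complexes) with enzyme counts scaled by the dimer ratio (22 CheR, 38
CheB), preserving every intensive quantity; population cells rescale the
lattice height so receptor counts co-scale with enzymes in whole units.
Stationary statistics use a 500 s burn-in and 600–1200 s recording windows
at 0.1 s resolution over one to three seeds (the acceptance script pools
three seeds for the low-CheR noise figure). Window lengths comparable to
the slow fluctuation time (~100 s) bias variance estimates slightly
downward, so these figures are conservative.

## What the comparisons do and do not show

* The synthetic conditions cover only Tar receptors, a single contiguous
  lattice, well-mixed bulk, and conserved CheR:CheB:receptor stoichiometry
  across the population (expression multipliers log-normal or on a
  0.5×–2× grid). Receptor heterogeneity, cluster fragmentation, bulk
  diffusion gradients, and downstream CheY/motor dynamics are out of scope.
* The mean-field model and the lattice simulation are *not* expected to
  agree quantitatively at matched copy numbers: explicit lattice binding
  lets enzymes localize in neighborhoods where their substrate affinity is
  low, which raises the effective `K_r`/`K_b` above the mean-field mapping,
  shifts the operating activity up, and reduces the noise roughly
  three-fold relative to a matched-count LNA. Tests therefore check
  same-order agreement and the orderings (localized ≫ well-mixed noise;
  M1 > M3 > M2), not point equality. Within the mean-field tier itself the
  LNA is validated strictly: it matches direct SDE simulation within 10%
  in the weak-noise (up-scaled) regime, and within a factor ~1.6 at
  physiological copy numbers, where the ultrasensitive balance saturates
  large excursions and the Gaussian approximation overestimates variance.
* Precision of adaptation to the large (1 mM) stimulus is limited in all
  lattice variants by finite methylation range and enzyme distribution
  effects; the package's precision metric (`1 − |a_adapted − a_pre|/a_pre`
  over the final 20% of the post-step window) is a scalar summary defined
  here, logged with every result.

## Known limitations

* The mean-field ODEs do not enforce the methylation ceiling `m ≤ 8N`
  during transients; the steady state flags out-of-range methylation
  (`m_in_range=False`, the "nonfunctional" saturated regime) instead.
* The LNA decomposition attributes bulk-CheB-P fluctuations to the CheB-P
  exchange channel by construction (`explicit_Bp` analysis is not
  implemented).
* The finite-brachiation-rate analytical model (interpolating between the
  mean-field limit and the processive limit) is out of scope; the lattice
  simulator covers that regime numerically via the M3 variant.
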
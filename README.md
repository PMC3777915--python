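# clusteradapt

Models of adaptation kinetics in the clustered chemoreceptor array of
*Escherichia coli*, for researchers studying how the spatial organization of
signaling proteins shapes the dynamics — not just the mean — of a sensory
pathway.

Bacterial chemoreceptors form a dense hexagonal lattice. Adaptation is
carried by two low-abundance cytoplasmic enzymes: the methyltransferase CheR
(reactivates inactive receptors) and the phosphorylated methylesterase
CheB-P (deactivates active ones). Both must first *localize* to the cluster
through a high-affinity tether site on the receptors; once tethered, an
enzyme can reach the modification sites of its own dimer and the six
neighboring dimers (its *assistance neighborhood*), and can move
hand-over-hand across the lattice (*brachiation*). This package implements
that system at two levels:

1. **An exact stochastic simulator** (Gillespie-type, compiled with numba)
   of individual CheR/CheB-P molecules binding, moving and catalyzing on an
   explicit receptor lattice, with Monod–Wyman–Changeux (MWC) cooperativity:
   six-dimer complexes switch between active and inactive states with
   probability `a = 1/(1 + e^F)`,
   `F = ε_m (m_half − m) + N ln[(1 + L/K_off)/(1 + L/K_on)]`.
   Variant switches give the reference model **M1** (neighborhoods +
   brachiation), **M2** (enzymes confined to a single dimer) and **M3**
   (slow brachiation), plus well-mixed baselines **B1**/**B2** without any
   localization.
2. **A mean-field analytical model** of the same kinetics, in which the
   localized enzyme pools `R*`, `B*` exchange slowly with the bulk and the
   mean complex methylation `m` follows Goldbeter–Koshland kinetics
   `dm/dt ∝ k_r R*(1−a)/((1−a)+K_r) − k_b B* a/(a+K_b)`, together with its
   linear-noise approximation: Jacobian, diffusion matrix from the
   elementary-event propensities, Lyapunov solve for the stationary
   covariance, and an exact decomposition of the activity variance into
   CheR-exchange, CheB-P-exchange and methylation-shot-noise channels.

The scientific point the package reproduces: distributive methylation
(neighborhoods + brachiation) is required for precise adaptation, and the
same saturated, slowly-exchanging enzyme kinetics produce large spontaneous
activity fluctuations (σ_a/a₀ up to ~7–10%) around a mean that nonetheless
stays robust to enzyme expression levels — because slow tether binding
raises the *effective* Michaelis constants (`K̃ ≳ 1`) entering the
total-enzyme balance even while the localized kinetics stay saturated
(`K ≪ 1`).

## Worked example

```python
from clusteradapt import meanfield as mf, lna
from clusteradapt import experiments as exp
from clusteradapt.ssa_engine import equilibrate

# analytical tier: stationary point, effective constants, noise
p = mf.MeanFieldParams()                      # calibrated defaults
a0, st = mf.steady_state(0.0, p)
eff = mf.effective_constants(p, a0)
res = lna.noise_analysis(p)
print(f"a0={a0:.4f}  m0={st.m:.3f}  R*={st.rstar_tot:.1f}  B*={st.bstar_tot:.1f}")
print(f"K~_r={eff.k_tilde_r:.3f}  K~_b={eff.k_tilde_b:.3f}")
print(f"sigma_aa={res.sigma_aa:.3e}  rel_noise={res.rel_noise:.4f}")

# stochastic tier: reference model M1 on a reduced 1152-dimer lattice
cfg = exp.LatticeConfig()                     # 8x8 hexagonal units
geom, copies = cfg.geometry(), cfg.copies()   # 22 CheR, 38 CheB
_, tr = equilibrate(geom, cfg.rates, cfg.flags, cfg.mwc, copies,
                    duration=600.0, seed=42, burn_in=500.0, L=0.0)
ns = exp.noise_stats(tr)
print(f"SSA: a0={ns.a0:.3f}  rel_noise={ns.rel_noise:.4f}")
```

prints

```
a0=0.2799  m0=4.425  R*=62.3  B*=49.7
K~_r=1.062  K~_b=1.430
sigma_aa=3.884e-04  rel_noise=0.0704
SSA: a0=0.498  rel_noise=0.0580
```

The mean-field model sits at activity 0.28 with about 45% of CheR tethered;
its effective inverse affinities are of order one (robust regime), yet the
relative activity noise is 7% — fluctuations in the handful of localized
enzymes, amplified by the steep dependence of activity on the localized
CheR/CheB-P ratio. The reduced-lattice simulation shows the same picture
with explicit spatial kinetics (the lattice raises the effective constants
further, so its operating activity is higher and its noise slightly lower
at nominal expression; at half the CheR count it exceeds 7–10%).

A command-line interface mirrors the library:

```sh
clusteradapt simulate --variant M1 --lattice 8x8 --protocol step:1000uM@200s \
    --duration 700 --seed 7 --out trace.csv
clusteradapt scan --engine lna --param r_tot --range 0.25:4:25 --out noise.csv
clusteradapt population --model M1 --cells 8 --out population.csv
clusteradapt processivity --variants M1,M2,M3
```

## Layout

| module | contents |
| --- | --- |
| `clusteradapt.mwc` | MWC activity of a signaling complex, calibration anchor |
| `clusteradapt.lattice` | hexagonal lattice, complexes, assistance neighborhoods |
| `clusteradapt.reaction_system` | state, rates, variant switches, reference rule set |
| `clusteradapt.ssa_engine` / `_kernel` | exact SSA (numba), ligand protocols, traces |
| `clusteradapt.meanfield` | localized mean-field model, effective constants, B1/B2 |
| `clusteradapt.lna` | linearization, Lyapunov covariance, variance decomposition |
| `clusteradapt.experiments` | noise stats, steps/ramps, scans, populations, processivity |

See `docs/methods.md` for the model description, parameter choices and
known limitations.
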
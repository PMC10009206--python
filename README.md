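# paleotroph

Quantitative, multi-proxy dietary inference for fossil birds.

Reconstructing what an extinct bird ate is hard because no single line of
evidence is decisive: body size constrains prey, claw shape reflects how the
feet handled food, jaw lever mechanics reflect bite style, and the strain a
jaw experiences under load reflects its strength. `paleotroph` implements
each of these proxies as measured in extant birds of known diet, places
fossils into the extant comparative spaces, and combines the per-proxy
evidence — all under phylogenetic comparative statistics, because bird
species are not independent samples.

## What it computes

**Body mass.** Fossil log₁₀ mass (g) from six log₁₀ skeletal measurements
(mm) via an enantiornithine-specific regression,

log₁₀ *M* = −2.626 + 1.528·HL + 0.34·bcL + 0.828·dHW − 1.451·UL + 0.811·dUW + 0.378·TL,

and optimal mass thresholds between lumped diet groups (invertivores vs
vertebrate-eaters; folivores+frugivores vs granivores+nectarivores) chosen
by maximizing the Youden index *J* = sensitivity + specificity − 1.

**Claw morphometrics.** Outer-arc curvature (°) of the ungual of each pedal
digit and arc lengths relative to digit III, from three landmarks per claw
(base, midpoint, tip) fitted with a circular arc.

**Jaw mechanics.** Mechanical advantage MA = in-lever / out-lever of the
upper and lower jaws at anterior and posterior bite points (AMA, PMA),
opening MA (OMA), and size-free shape indices (AO, ACH, MMH, AMH), plus a
sensitivity analysis that recomputes all levers for alternative quadrate
(articulation) positions.

**FEA intervals.** Each finite-element jaw model is summarized by its
mesh-weighted arithmetic mean strain, MWAM = Σᵢ εᵢaᵢ / Σᵢ aᵢ (με), and by the
percentage of model area in each of *N* equal strain intervals. These
compositions are zero-imputed, log-ratio transformed (clr/ilr) and ordinated;
*N* is chosen by convergence testing.

**Comparative statistics.** Brownian-motion covariance **C** from
time-calibrated phylogenies (with fossil grafting and clade rescaling);
Blomberg's K and its multivariate extension K_mult with permutation tests;
permutation-based pairwise comparison of group means on GLS-whitened data
("phylogenetic HSD") alongside classical Tukey's HSD; correlation-matrix
PCA; flexible discriminant analysis (FDA); and phylogenetic FDA, which
whitens predictors by **C**(λ)^(−1/2) under a profiled Pagel's λ. Fossil
rows are always projected into extant-fitted spaces, never used in fitting.

**Synthesis.** Extant diets are assigned from EltonTraits-style percentage
columns by fixed cut-offs, classifier agreement is scored with Fleiss'
kappa, and per-proxy fossil posteriors are merged into likely / unlikely /
agreed diet sets.

## Worked example

```python
import numpy as np
from paleotroph import mass_proxy, synthetic_data
from paleotroph.comparative_stats import k_mult
from paleotroph.phylo import bm_covariance

# a fossil's mass from six log10 skeletal measurements (mm)
m = mass_proxy.MassMeasurements(HL=2.0, bcL=1.5, dHW=1.6,
                                UL=1.7, dUW=1.5, TL=2.2)
log_mass = mass_proxy.estimate_log_mass(m)
print(round(log_mass, 3), "->", round(10 ** log_mass, 1), "g")

# a mass threshold between diet groups (synthetic extant sample)
masses = synthetic_data.simulate_masses(
    {"Invertivore": (25, 1.8, 0.45), "Piscivore": (25, 2.9, 0.45)}, seed=1)
lo = masses.loc[masses.diet == "Invertivore", "log10_mass_g"].to_numpy()
hi = masses.loc[masses.diet == "Piscivore", "log10_mass_g"].to_numpy()
cp = mass_proxy.youden_cutpoint(lo, hi)
print(f"cut-point {10 ** cp.threshold:.0f} g (J = {cp.youden_j:.2f})")

# phylogenetic signal in Brownian-motion traits
tree = synthetic_data.random_coalescent_tree(32, seed=2)
Y = synthetic_data.simulate_bm_traits(tree, p=4, seed=3)
res = k_mult(Y, bm_covariance(tree), n_perm=1000, seed=4)
print(f"K_mult = {res.statistic:.2f}, p = {res.p_value:.4f}")
```

prints

```
1.846 -> 70.2 g
cut-point 200 g (J = 0.88)
K_mult = 0.87, p = 0.0010
```

The fossil's estimated mass is 70 g; it falls below the 200 g cut-point, so
on mass alone it sits on the small-bodied (invertivore) side of that
contrast. The simulated traits carry significant phylogenetic signal
(p ≈ 0.001, the smallest value 1,000 permutations can resolve), with K_mult
slightly below the Brownian expectation of 1.

## Command line

Each stage of the pipeline runs over plain CSV/Newick files:

```sh
paleotroph simulate --seed 42 --out study        # synthetic study inputs
paleotroph signal   --config config.yaml         # K_mult on a trait table
paleotroph ordinate --config config.yaml         # PCA / FDA / pFDA + fossils
paleotroph synthesize --config config.yaml       # combine proxy posteriors
```

Stages: `simulate`, `mass`, `claws`, `jaws`, `fea`, `signal`, `hsd`,
`ordinate`, `synthesize`. Every run writes a JSON run log (seed, config,
input hashes) and is byte-reproducible for a fixed config and seed.

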
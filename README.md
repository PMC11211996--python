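# netspread

Network diffusion modelling of neurodegenerative pathology over multimodal
brain connectomes.

In Alzheimer's disease, tau aggregates and atrophy do not appear uniformly
across the brain: they spread along connected regions. `netspread` implements
the network diffusion model (NDM) of that process and — its central feature —
a task-driven *fusion* of connectomes from different imaging modalities
(tractography, functional partial correlation, inverse geodesic distance,
microstructural and morphological covariance) into a single combined network
that best explains a measured regional pathology pattern.

The package is written for researchers modelling regional tau-PET SUVR or
structural-MRI atrophy patterns on atlas parcellations (Desikan-Killiany, 68
cortical regions, optionally 18 subcortical).

## The model

Pathology `x(t)` diffuses over a connectome `C` according to

    dx/dt = −β H x(t),        x(t) = expm(−β H t) x₀

where `H = I − D⁻¹C` is the graph Laplacian of the row-sum-normalised
connectome and `β` a diffusivity constant (fixed to 1; β and t are linearly
dependent). The initial condition `x₀` seeds unit pathology bilaterally at
one atlas region. Model time is scanned over a grid; the optimal time
minimises the sum-of-squared error (SSE) between the per-timepoint min-max
normalised prediction and the measured pattern, and `r_max` — the Pearson
correlation at that optimum — is reported.

The multimodal combination is

    Ĉ = Σ_k λ_k C_k,    λ_k ≥ 0,  Σ_k λ_k = 1,

with the simplex weights `λ` optimised by a Gaussian-process minimiser
(expected-improvement acquisition; by default 300 random starts then 500
surrogate-guided iterations) to minimise the NDM's SSE. Fits are benchmarked
against degree-preserving rewired null connectomes, validated out-of-sample
by subject-level k-fold cross-validation, and compared with Pearson
correlations, Hotelling's test for dependent correlations, and the Wilcoxon
signed-rank test.

## Worked example

```python
import netspread as ns
from netspread.synthetic import SyntheticWorld, synth_pathology

# a synthetic study: 4 modality connectomes over the 68 DK cortical
# regions, pathology generated from known weights/seed/time plus noise
world = SyntheticWorld.default(rng_seed=7)
measured = synth_pathology(world)

# fit a single connectome
model = ns.NetworkDiffusionModel(
    world.combined(), measured, seed_region="inferiortemporal"
)
print(model.fit().summary())

# optimise the multimodal combination weights
result = ns.optimize_weights(
    world.thresholded(), ["inferiortemporal"], measured,
    n_random=60, n_iter=100, rng_seed=1,
)
print(result.summary())
```

which prints

```
Network Diffusion Model fit
==========================================
regions (evaluated)                     68
seed region                 inferiortemporal
threshold fraction                    None
optimal model time t_opt           10.0927
SSE at t_opt                     0.0217396
r_max (Pearson at t_opt)            0.9975
p-value (two-sided)               1.08e-77
==========================================
Combined-connectome optimisation
============================================
seed region                 inferiortemporal
r_max                                 0.9980
SSE                                0.0147299
t_opt                                9.81712
--------------------------------------------
  lambda[mod0_distance     ]           0.616
  lambda[mod1_modular      ]           0.185
  lambda[mod2_dense-covariance]           0.142
  lambda[mod3_distance     ]           0.057
============================================
```

The diffusion from the bilateral inferior-temporal seed reproduces the
generated pattern almost perfectly (`r_max = 0.998` at model time ≈ 10.1,
close to the generating time 10); the weight optimisation recovers the
generating modality weights (0.6, 0.2, 0.15, 0.05) to within a few
hundredths each.

A command-line interface mirrors the library:

```bash
netspread simulate --out fixtures --rng-seed 3          # synthetic study
netspread fit --config config.yaml                      # single-connectome fit
netspread grid --config config.yaml                     # seed x threshold table
netspread optimize-weights --config config.yaml         # combination weights
netspread null --config config.yaml                     # rewired-null benchmark
netspread cv --config config.yaml --subjects subj.csv   # cross-validation
```

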
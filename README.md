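# edrnet

Generative models and comparison statistics for interareal cortical
networks under the **exponential distance rule** (EDR): the empirical
law that the probability of an axonal projection of length *d* decays as
*p(d) = λe^(−λd)*.  The package is for computational neuroanatomists and
network scientists who want to ask how much of a connectome's
architecture — motif profiles, core–periphery structure, connection
similarity, wiring cost — follows from its spatial embedding alone, and
to compare brains of very different sizes on a common scale.

## What it does

Given a symmetric interareal distance matrix *D* (mm) and a decay rate
λ, `edrnet` samples random connectomes by repeatedly drawing a length
from *λe^(−λd)*, picking a random area pair at that distance, and adding
a randomly oriented unit of weight until the target binary density is
reached (λ = 0 gives the distance-blind CDR null).  Around this
generator it implements:

- **geometry** — distance statistics q(d), the adimensional template
  (distances rescaled by ⟨d⟩, decay rate γ = λ⟨d⟩), and a permutation
  test on variance ratios of normalized distance distributions;
- **fitting** — decay-rate estimation from binned length samples
  (log-linear or Poisson GLM) and model fitting by *parameter matching*:
  λ_P minimizes |P(G_data) − ⟨P(λ)⟩| over an ensemble, for
  P ∈ {M1, M2, motif census, clique census, second eigenvalue of AAᵀ};
- **measures** — 16-class directed 3-node motif census,
  degree-preserving rewiring nulls with log residuals, all-clique census
  on the reciprocal skeleton, RMS log-ratio deviations;
- **core_periphery** — core = union of maximum cliques, block link
  counts/densities, and the Erdős–Rényi chance likelihood of the core;
- **similarity** — chance-corrected in-link similarity for all area
  pairs versus distance, with EDR-ensemble density clouds;
- **wiring** — total wire length Λ = Σ A_ij·D_ij, yoked-permutation
  nulls, and simulated-annealing placement optimization;
- **synth** — complete synthetic "species" (geometry + ground-truth λ +
  connectome + axon-length sample) emulating the mouse-like (γ = 3.54)
  and macaque-like (γ = 5.0) regimes.

## Worked example

```python
import numpy as np
from edrnet import (mouse_like, sample_edr, EDRParameters, fit_decay,
                    parameter_match, extract_core, total_wire_length,
                    permutation_null)

sp = mouse_like(seed=1)          # 33 areas, <d> = 4.54 mm, rho = 0.68
print(f"gamma = {sp.gamma:.2f}") # gamma = 3.54

# recover the decay rate from the fixture's axon-length sample
fit = fit_decay(sp.axon_lengths, binwidth=0.5)
print(f"lambda = {fit.lambda_hat:.3f}")          # lambda = 0.727  (true 0.78)

# fit lambda to the connectome by matching bidirectional pair counts
res = parameter_match(sp.connectome, sp.distances, "M2",
                      np.arange(0.6, 1.001, 0.05), n_ensemble=200, seed=0)
print(f"lambda_M2 = {res.lambda_p:.2f}")         # lambda_M2 = 0.75

# clique-based core and wiring economy
part = extract_core(sp.connectome)
print(len(part.core), part.rounded_percent())
# 22 {'core': 82, 'periphery': 66, 'between': 55}
lam = total_wire_length(sp.connectome, sp.distances)
null = permutation_null(sp.connectome, sp.distances, n_perm=1000, seed=2)
print(f"{lam:.0f} mm vs null 5th pct {np.percentile(null, 5):.0f} mm")
# 2621 mm vs null 5th pct 3181 mm
```

The fixture's decay-rate recovery lands near the generating 0.78 mm⁻¹
(a single realization carries ~7×10³ lengths; pooled realizations
tighten it), the matched λ_M2 agrees to one grid step, the dense EDR graph
develops a clique core far denser than its periphery, and its total wire
length sits far below the permutation null — the wiring-economy
signature of distance-ruled connectivity.

## Analyses

Numbered drivers under `analysis/` rebuild the full result set into
`results/` (tables only): `01_make_species.py` (fixtures),
`02_fit_decay.py` (decay-rate recovery), `03_match_parameters.py`
(matching consistency across four statistics), `04_core_periphery.py`,
`05_motifs.py` (EDR vs CDR vs rewiring nulls), `06_similarity.py`
(profiles on the adimensional template), `07_wiring.py`.  Each prints a
short narrative of what it found.

## Command line

A thin CLI wraps the library for shell pipelines; every stochastic
subcommand records its seed and parameters in a JSON manifest:

```sh
edrnet synth --preset mouse-like --seed 1 --out fix/
edrnet simulate --distance fix/distances.csv --lambda 0.78 --density 0.68 \
    --seed 2 --out sim/
edrnet core --connectome sim/connectome.csv --out core/
edrnet compare --species-a fix/ --species-b fix2/ --out cmp/
```
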
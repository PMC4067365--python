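# ecotypesim

Individual-based simulation of resource specialization and adaptive
radiation in asexual populations, driven purely by trade-offs in resource
use.

## The scientific problem

Can trade-offs alone — with no geography, no sex, no species interactions
beyond competition — split a well-mixed clonal population into stably
coexisting specialists? `ecotypesim` implements a consumer-resource model
built to answer that question quantitatively: organisms are vectors of
resource affinities `c_ik` on a discrete grid, fitness follows the Monod
equation discounted by an explicit cost of having high and multiple
affinities,

    F_i = 1/(1+D_i) * Σ_k c_ik · r_k/(r_k + γ_k),
    D_i = Σ_k ( σ1·c_ik + σ2·ξ(c_ik) ),    ξ(c) = [c > 0],

and resources obey chemostat dynamics `dr_k/dt = Nλ_k − c0·r_k − Σ_i F_ik`.
The population evolves by a death-birth Moran process (1% of the
population replaced per update, parents drawn proportional to fitness),
with per-trait mutation (rate μ; 70% of mutations are trait-lethals that
zero an affinity, the rest step it by ±0.1). Specialists coexist through
negative frequency-dependent selection: whoever eats a crowded resource
starves, whoever eats an empty one thrives.

The package is aimed at researchers in eco-evolutionary dynamics who want
a fast, reproducible implementation of this model family with the full
measurement apparatus: ecotype counting by zero-mutation competition,
invasion-when-rare experiments, population niche breadth
`B = Σ_{i,k} ξ(c_ik)/(N·R)`, and exact genealogies (MRCA, lines of descent
with per-mutation selection coefficients, Newick phylograms).

## Worked example

Run the exemplar radiation (N=1000, μ=0.05, λ=10⁻³, σ1=1, σ2=0.1,
starting from a homogeneous population of specialists on resource 1), then
count ecotypes:

```python
import numpy as np
from ecotypesim import SimulationConfig, run, zero_mutation_assay

cfg = SimulationConfig(N=1000, mu=0.05, lam=1e-3, sigma1=1.0, sigma2=0.1,
                       updates=40_000, seed=1, record_ancestry=False)
res = run(cfg)
assay = zero_mutation_assay(res.final_state, cfg,
                            rng=np.random.default_rng(2))
print("ecotypes:", assay.n_ecotypes, " niche breadth:", round(assay.niche_breadth, 3))
for pheno, freq in assay.ecotype_phenotypes:
    print(np.round(pheno, 1), round(freq, 3))
```

prints

```
ecotypes: 5  niche breadth: 0.379
[0.4 0.  0.  1.  0.1 0.  0.  0.2 1. ] 0.304
[0.  0.8 0.  0.  0.7 0.  0.4 0.  0. ] 0.235
[0.  0.  0.9 0.  0.  0.  0.  1.  0. ] 0.194
[0.7 0.  0.  0.  0.  0.8 0.  0.1 0. ] 0.182
[0.  0.5 0.  0.  0.4 0.  0.8 0.  0. ] 0.085
```

Five ecotypes survive the zero-mutation competition — distinct affinity
vectors partitioning the nine resources, each held at intermediate
frequency by negative frequency-dependent selection. The niche breadth
0.38 says over a third of all affinity slots in the population are in
use; pure specialists would give 1/9 ≈ 0.11, pure generalists 1.0. Under
strong trade-offs (σ1=10, σ2=1) the same protocol yields one specialist
ecotype per resource (n_t ≈ 9, B ≈ 0.12); at high influx (λ=10⁻¹) it
collapses to a single generalist.

The same protocol is available from the shell:

```bash
ecotypesim run --n 1000 --updates 40000 --lam 1e-3 --seed 1 --no-ancestry --out runs/demo
ecotypesim assay --state runs/demo/state.json --out runs/demo

# shorter run with ancestry recording, then genealogy reconstruction
ecotypesim run --n 1000 --updates 5000 --seed 1 --out runs/lineage
ecotypesim lineage --state runs/lineage/state.json \
    --resource-history runs/lineage/resource_history.tsv --out runs/lineage

ecotypesim sweep --spec sweep.yaml --out sweep.tsv
ecotypesim report --table sweep.tsv --by lam,sigma1,sigma2 --out cells.tsv
```

where `sweep.yaml` describes a grid around a base configuration, e.g.

```yaml
base: {N: 1000, mu: 0.05, updates: 40000, record_ancestry: false}
axes:
  lam: [1.0e-4, 1.0e-3, 1.0e-2, 1.0e-1]
  sigma1,sigma2: [[0, 0], [0.1, 0.01], [1, 0.1], [10, 1]]
replicates: 5
base_seed: 0
```

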
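# clonaldyn

Clonal dynamics and somatic evolution of haematopoiesis, from single-cell
colony phylogenies and duplex variant spectra.

Blood is maintained by a pool of haematopoietic stem cells (HSC) and
multipotent progenitors (MPP). Whole-genome sequencing of single-cell-derived
colonies turns their shared somatic mutations into a phylogeny whose branch
lengths count mutations ("molecular time"), and targeted duplex sequencing of
blood detects clones down to VAF ~1e-5. `clonaldyn` implements the full
inference stack for studying these data in the mouse, together with seeded
synthetic-data generators so every analysis is testable without sequencing
data:

* **variant_filters** — the nine colony-WGS filters (homopolymer, strand
  bias, beta-binomial overdispersion ρ, VAF, germline, indel proximity,
  missing/clustered/non-variable sites), colony QC, depth-corrected burden
  estimation, the burden ~ age + (0 + age | animal) mixed model, and the
  thirteen duplex-table filters.
* **phylotree** — perfect-phylogeny tree building with likelihood variant
  placement, sensitivity normalisation, clade partitions and Shannon
  diversity, the polytomy estimator of mutations per division
  m = −ln(z/n), the HSC/MPP mixing metric with a reshuffling null,
  directional state-change parsimony, crypt-sharing positivity and lineage
  VAF trajectories in blood.
* **hmm_tree** — a three-state (EMB/HSC/MPP) hidden Markov tree: branch
  matrices M^l, the upward (pruning) likelihood, Viterbi decoding,
  maximum-likelihood transition-rate fits and state-probability
  trajectories π·M^t.
* **popdyn** — intercoalescent intervals, the classic skyline inversion
  N/λ = k(k−1)Δt/2, and rejection ABC over a bounded two-epoch birth–death
  model with the published uniform priors (N ∈ [1e2, 1e5] cells,
  λ ∈ [0.01, 0.15]/day, ν ∈ [0, λ]).
* **fitness** — the branching-process log-VAF density
  ρ(l) = θ/(1−2e^l)·exp(−e^l/(φ(1−2e^l))) with θ = Nτμ and
  φ = (e^{st}−1)/(2Nτs); neutral fits for Nτ and μ, non-synonymous rates,
  an exponential-power fitness landscape (shape β = 3), and the
  drift-threshold and annual↔per-division conversion arithmetic.
* **signatures** — 96-channel signature attribution: opportunity
  adjustment, per-mutation Bayesian membership posteriors, branch-level
  proportions and signature-specific burden slopes.
* **synthetic_data** — bounded birth–death Gillespie simulation, genealogy
  sampling with Poisson mutation accrual (default 1.8/division), heritable
  state labelling, genotype matrices with planted artefact classes
  (default depth 14×), and duplex VAF spectra simulated from the exact
  birth–death transition law (floor 5e-5).

## Worked example

```python
from clonaldyn.synthetic_data import (default_mouse_model, label_states,
                                      sample_phylogeny, simulate_population,
                                      StateTransitionParams)
from clonaldyn.phylotree import clades_at_time, shannon_diversity, mixing_null

trace = simulate_population(default_mouse_model(cap=2000), t_end=60.0, seed=1)
phylo = sample_phylogeny(trace, n_tips=40, seed=2)
phylo = label_states(phylo, StateTransitionParams(), seed=3)

part = clades_at_time(phylo, 50)
print(f"{len(part.clades)} clades at 50 mutations, "
      f"H = {shannon_diversity(part):.3f}")
res = mixing_null(phylo, t=25, n_perm=1000, seed=4)
print(f"mixing metric {res['observed']:.3f}, one-tailed p = {res['p']:.3f}")
```

prints

```
39 clades at 50 mutations, H = 3.654
mixing metric 0.471, one-tailed p = 0.378
```

Thirty-nine of forty tips form their own clade at 50 mutations of molecular
time (entropy 3.65, essentially the 40-tip maximum of 3.69): clonal
diversity is high — lineages were established early and none has expanded.
The mixing metric is the mean absolute deviation of each clade's HSC
fraction from the overall sampled HSC fraction; with near-singleton clades
it is high for any labelling, and the reshuffling null is accordingly not
rejected (p = 0.38) — the tree carries no evidence of HSC/MPP segregation
beyond chance at this cutoff.

The same objects feed the rest of the stack: `simulate_genotype_matrix` →
`filter_colony_variants` → `build_tree` reconstructs the tree from reads;
`coalescent_intervals` → `skyline`/`abc_rejection` infers N, λ, ν;
`simulate_duplex_vafs` → `fit_neutral`/`fit_dfe` estimates Nτ, μ and the
fitness landscape.

A CLI mirrors the common one-shot operations:
`clonaldyn simulate {population|tree|matrix|vafs}`,
`clonaldyn filter {colonies|duplex}`,
`clonaldyn tree {diversity|polytomy|mixing}`,
`clonaldyn hmm {fit|decode|trajectory}`,
`clonaldyn popdyn {skyline|abc}`,
`clonaldyn fitness {fit-neutral|convert}`,
`clonaldyn signatures attribute` — all with `--seed`.

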
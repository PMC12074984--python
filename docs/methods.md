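# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices that a user re-deriving results would need to know.

## Population model and genealogies

The stem/progenitor pool is a linear birth–death process started from one
cell: per-cell symmetric division rate λ and exit (death or differentiation)
rate ν, per week, constant within an epoch. Two epochs are used by default —
an embryonic expansion until 10 weeks post-conception and an adult epoch
thereafter — and a hard cap N bounds the size by suppressing births while
the population sits at the cap (cells are never culled). With ν > 0 the
population hovers at the cap with divisions only replacing exits, so the
effective per-cell division rate at the cap is ν; this is what makes ν
identifiable from late-life coalescences.

`simulate_population` is an exact Gillespie simulation with a birth-event
log (time, parent, child). Genealogies of sampled extant cells are
reconstructed by walking that log backward; each division a lineage passes
adds an independent Poisson(m) mutation draw, m = 1.8 mutations per daughter
per division by default (the early-life polytomy estimate; both daughters
mutate). Extinction — possible only while the population is small — is
flagged, and callers resample.

**Coalescent convention.** A forward birth–death/Moran population with
per-cell division rate b has pairwise coalescence rate 2b/N (each division
event creates one daughter pair). The classic skyline inversion
N̂/λ = k(k−1)Δt/2 corresponds to a pairwise rate of 1/(Nτ); the two agree
when τ is read as 1/(2b) — the familiar Moran Ne = N/2 factor. The package
is internally consistent: `kingman_tree` (the oracle for skyline tests) uses
pairwise rate 1/(Nτ) directly, and the ABC compares observed and simulated
genealogies generated under the same 2b/N convention, so the factor cancels
everywhere a quantity is estimated from data the package itself simulated.
Absolute N/λ values quoted against external analyses carry this factor-2
ambiguity.

**Fast path for ABC.** Rejection ABC needs ~2×10⁵ genealogies per
calibration, which an event-level simulation cannot deliver. The fast path
replaces the stochastic population trajectory with its deterministic
piecewise-exponential counterpart (growth λ−ν, clamped at the cap) and
draws the backward coalescent by exact time rescaling within each segment.
A two-sample test in the suite confirms the fast path matches the
event-level genealogies in adult-epoch coalescence counts and mid-life
lineage counts; near the founder (first few cells) the deterministic
trajectory cannot reproduce stochastic early growth, and no agreement is
claimed there — one reason early-epoch parameters are treated as fixed
rather than inferred.

## Cell-state model

Identities EMB (embryonic precursor), HSC and MPP evolve down the tree as a
discrete-time Markov chain with one step per somatic mutation. The root is
EMB and is locked EMB for the first 10 mutations (gastrulation-era molecular
time); the per-step matrix has EMB→HSC, EMB→MPP, HSC→MPP and MPP→HSC
entries, with EMB unreachable once left. Tip phenotypes are emitted with
error ε (match 1−ε, mismatch ε/2); ε defaults to 1e-12 because colonies are
phenotyped by two-stage sorting, essentially error-free.

Branch transition matrices are M^l with l the integer branch length after
excluding overlap with the locked first 10 mutations; because the root prior
pins the state to EMB throughout the lock, treating the locked stretch as an
identity step is exact. The upward (pruning) likelihood and the Viterbi
max-product recursion are both computed in log space; ties in decoding break
toward the lower state index in EMB < HSC < MPP order. Fitting maximises the
summed log-likelihood over the four probabilities on the logit scale
(Nelder-Mead, 8 random restarts by default) — boundary MLEs near zero are
expected, since reverse MPP→HSC transitions are of order 1 in 1,000.

A caveat established while validating recovery: transition rates are only
identifiable when trees are deep enough in molecular time that essentially
every lineage has left EMB by sampling. On shallow trees a fast-mixing model
can dominate the truth because still-EMB tips carry no signal. The recovery
tests therefore simulate adult-depth trees (>100 mutations root-to-tip),
matching real adult colonies.

## Variant filtering

Colony-WGS filters run in their published order with published cutoffs
(homopolymer run ≥5; strand-bias two-sided binomial p < 0.001 together with
>80 % unidirectional mutant reads; beta-binomial ρ < 0.1 for SNVs / 0.15 for
indels with >25 colonies, ρ < 0.20 otherwise; VAF binomial p < 0.001 against
0.5 and VAF < half the median of ρ-passing variants; germline when the
aggregate VAF is not significantly below 0.45 at p < 0.001; SNVs within
10 bp of an indel; coverage <6× in over a third of colonies; clusters within
10 bp; non-variable sites). Each site records the first filter it fails.
The beta-binomial likelihood is parameterised by (mean, ρ) with the mean
fixed at the site's aggregate VAF and ρ maximised on [1e-6, 0.89] by a
coarse log grid plus bounded refinement; a dense-grid oracle in the tests
confirms 3-decimal agreement.

Genotype calls ("Present / Absent / Unknown in a read-depth-specific
manner", details unpublished) use: Present if ≥2 mutant reads and VAF ≥ 0.2;
Absent if depth ≥ 6 and VAF < 0.2; Unknown otherwise. Colony QC excludes
colonies whose passing-variant mean VAF is below 0.4 (exclusive) and
operationalises "evidence of non-clonality" — in the original a visual
call — as a kernel-density mode below 0.35 (Gaussian kernel, bandwidth
0.05 VAF units).

Burdens are corrected for depth-dependent detection by the asymptotic
regression y = a(1 − e^{−k·depth}) per sample; the per-colony sensitivity
1 − e^{−k·d} also rescales branch lengths (terminal branches by their
colony's sensitivity, internal branches by the mean over descendants,
rounded back to integers). The burden–age model is a random-slope linear
mixed model, burden ~ age + (0 + age | animal), fitted by ML through
statsmodels; optimizer fallbacks (bfgs, powell, then OLS with a warning)
guard against singular Hessians on small designs.

Duplex filters implement the thirteen table-level rules with the published
boundary semantics (singleton reads out; mean mismatches > 3.0 out; ≤15 bp
from a read end out; duplex depth ≤ 20,000× out; indels ≥ 15 bp out; VAF ≥
0.4 out as putative germline; recurrence at ≥5 % of a batch — requiring at
least two samples — or ≥5 samples overall). Two cutoffs the source leaves
unstated are configurable with documented defaults: Fisher strand-bias
p < 0.001 and end-repair artefact probability > 0.5. The oxidative-damage
filter is a class flag on the input table, not a signature refit.

## Tree building

Filtered matrices are near conflict-free, so the builder constructs the
perfect phylogeny of the variant carrier sets (laminar family; conflicting
sets resolved by keeping the better-supported ones, erroring above a
configurable conflict fraction with advice to supply an external Newick).
Every variant is then placed on the branch maximising a per-colony binomial
likelihood (carriers at VAF 0.5, non-carriers at an error rate of 1e-3;
zero-depth colonies are uninformative), so Unknown genotypes never veto
placement. Mutationless ancestral divisions are unresolvable from any
genotype matrix; round-trip tests therefore compare against the simulated
truth with zero-length internal edges collapsed, and reconstruction achieves
Robinson–Foulds distance 0 on error-free matrices.

The polytomy mutation-rate estimator counts L lineages by 12 mutations of
molecular time (L−1 binary divisions), scores each polytomy of degree d as
d−2 mutationally silent divisions, and inverts the Poisson zero class:
m̂ = −ln(z/n). The interval maps a Wilson score CI for z/n through −ln; the
original interval construction is unstated, so small differences in CI
endpoints are expected while the point estimate is exact. Trees with fewer
than 10 lineages by 12 mutations are rejected as uninformative.

## Population-size inference

Skyline: per intercoalescent interval, N̂/λ = k(k−1)Δt/2; optional pooling
merges consecutive intervals (zero-length polytomy intervals always pool)
and uses the grouped MLE Σk(k−1)Δt/2 divided by the number of coalescences.

ABC: uniform priors N ∈ [1e2, 1e5] cells, λ ∈ [0.01, 0.15] divisions/day,
ν ∈ [0, λ]; epoch boundary 10 weeks post-conception; the weakly identified
embryonic epoch is fixed (λ = 0.8/week, ν = 0) rather than inferred.
Summaries: lineages-through-time at 12 evenly spaced ages, coalescence
counts per epoch, MRCA age, and Shannon clade entropy at two fixed
chronological cuts (the epoch boundary and 3/4 of life); the entropy cuts
replace a molecular-time cut because ABC trees are simulated in
chronological time and a mutation overlay would add noise without
information. Summaries are standardized by their SD across the simulated
(prior-predictive) set; rejection keeps the closest 5 % by Euclidean
distance, with no regression adjustment. Reported posteriors: N, division
interval τ = 1/λ in weeks, exit interval 1/ν in weeks, and N/λ in HSC-years
(52.18 weeks/year). Simulation-based calibration at the study conditions
(N = 5e4, τ = 6 weeks, ν = λ/3, 40 tips at 130 weeks, 2,000 simulations per
run) covers the true N in ≥85 % of runs; rejection-ABC intervals are
conservative, so coverage exceeds the nominal level.

## Fitness landscape

The duplex variant density over l = ln(VAF) is
ρ(l) = θ/(1−2e^l)·exp(−e^l/(φ(1−2e^l))), θ = Nτμ,
φ = (e^{st}−1)/(2Nτs) (neutral limit t/2Nτ). Fitting separates shape and
amplitude: φ minimises the L2 distance between the model's reverse-
cumulative tail and the empirical tail on Doane-rule log-VAF bin edges
(k = 1 + log2 n + log2(1+|g1|/σ_g1), ceiled; edges from the VAF floor to the
maximum observed log-VAF), then θ is the observed count divided by the
model's total mass over the fitted window and by the cohort size — making
"duplicate every variant" double θ̂ and leave φ̂ fixed (exactly so at fixed
bin edges; Doane adds one bin when n doubles, moving φ̂ by a few percent).
Then Nτ = t/(2φ) and μ = θ/(Nτ). Non-synonymous rates refit the amplitude
with φ frozen, restricted to VAFs below the maximum synonymous VAF
(1.99e-4), where selection has not yet bent the spectrum.

The fitness landscape models non-synonymous variants as an inhomogeneous
Poisson process with intensity θ_ns[(1−w)·shape(φ₀) + w∫g(s; d, β)
shape(φ(s))ds], g the exponential-power density ∝ exp(−(s/d)^β) with β = 3
fixed; 64-point Gauss–Legendre quadrature on s ∈ (0, 4] per year (the upper
limit covers 50–200 %/yr growth with headroom; a Monte-Carlo cross-check at
10⁶ draws agrees to 1 %). d and w are fitted by Nelder-Mead from a 4×3
start grid on (log d, logit w); scales outside (0.1, 8] are rejected as
unidentifiable beyond the quadrature support. The reported strong-effect
fraction is w·(G(2)−G(0.5)) with G the DFE CDF (regularized incomplete
gamma). With ≤5 variants above the neutral range the fit is flagged; with
none, the non-neutral fraction is pinned to 0.

Conversions: per-division advantage = (1+s_annual)^{interval/52.18} − 1;
drift threshold s* = λ/N; establishment time 1/s years; per-bp rates use a
diploid mouse genome of 5.46e9 bp (2 × 2.73 Gb, configurable); panel-to-
genome scaling is the naive ratio panel_rate/panel_bp, which is documented
as not reproducing the published genome-wide figure exactly (the original
scaling route is unstated).

## Synthetic duplex spectra

Variants enter each animal's pool at rate Nμ per year (μ is the panel-wide
rate per cell per year) at uniform times over life; each mutant lineage is a
linear birth–death process with b = 1/τ + s and d = 1/τ per year, sampled
from its exact transition law (extinct with probability α, else geometric
with parameter β) rather than by an event loop — the same process, sampled
exactly, which is what makes paper-scale cohorts (N ≈ 1.3e5, tens of
animals) fast. The entry rate was derived so the low-VAF log-density
amplitude equals θ = Nτμ (beta-integral identity
∫x^{n−1}/(1+x)^{n+1}dx = 1/n); a chi-square GOF test in the suite confirms
the simulated neutral spectrum matches ρ(l). Defaults are the study
conditions: Nτ = 16,500 HSC-years, τ = 6.4 weeks, μ_syn = 1.8e-4/yr,
μ_ns = 3.4e-4/yr, non-neutral fraction 12 % with d = 2, β = 3, cohort age
2 years, VAF floor 5e-5, and a cohort of 60 animals — a realistic aged
duplex cohort giving ~50 synonymous variants above the floor, comfortably
above the fit's 30-variant minimum.

## What the generators do not emulate

No sequence-level reads (FASTQ/BAM), genome coordinates, mapping artefacts
beyond the planted classes, index hopping or cross-colony contamination; no
real phenotyping error by default (ε is a model constant, not a data
property); genotype-matrix artefact classes are stylized exemplars of the
patterns each filter targets, not an empirical artefact mixture. Stem
("truncal") variants carried by every colony are labelled separately in the
truth because the germline and non-variable filters remove them by design —
filter sensitivity is meaningful only for non-truncal somatic variants.
Passing tests therefore demonstrate correctness of the algorithms under the
stated generative assumptions, not robustness to every failure mode of real
sequencing data.

## Signature catalogues

Signature extraction is out of scope; catalogues are inputs in the canonical
pyrimidine-centric 96-channel order. The bundled `synthetic_catalog()` is a
stylized stand-in (CpG-focused C>T for a deamination-like process, a flat
clock-like profile, a C>A-dominated oxidative profile) intended for tests
and examples — substitute measured catalogues for real analyses. Branch
attribution follows the printed arithmetic: posterior ∝ catalogue likelihood
× category prior ('private' vs 'shared' SNVs carry separate priors),
averaged over the SNVs of a branch; branches under 30 SNVs are meant to be
pooled into a shared category upstream.

## Problem sizes

Defaults in tests and examples are chosen so the whole suite runs in a few
minutes on one CPU: populations capped at 5e2–5e3 cells for event-level
simulation, 24–100 tips per tree, 20-seed recovery batches, 100×2,000
simulations for ABC calibration, and duplex cohorts of 60 animals. All are
package choices; every generator and fit accepts larger sizes unchanged.
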
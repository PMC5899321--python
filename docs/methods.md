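# Methods

This note records the models implemented in `chronoforge`, the numerical
and design choices behind them, and what the synthetic benchmarks do and do
not demonstrate.

## Scope and data model

The package covers the core of a Bayesian phylogenomic workflow for
amino-acid data: assembling per-gene alignments into a concatenated
supermatrix of operational taxonomic units (OTUs), inferring rooted trees
under site-homogeneous and site-heterogeneous substitution models by MCMC,
comparing models by cross-validation on held-out sites, and estimating
divergence times on a fixed topology under relaxed molecular clocks with a
birth-death node-age prior, soft fossil calibrations and an exponential
root-age prior. Time is measured in Mya before present (tips at 0), branch
lengths in expected substitutions per site, and rates in
substitutions/site/Mya.

## Supermatrix assembly

OTUs may be chimeric: each gene independently contributes the
representative source taxon. "Slowest-evolving" representative selection
minimises the mean pairwise maximum-likelihood distance to the background
taxa present in the gene (a min–max aggregation is available), with ties
broken lexicographically. Pairwise ML distances use WAG exchangeabilities
with frequencies estimated from the sequence pair ("+F"); the two-sequence
likelihood reduces to a 20×20 pair-count sufficient statistic and the
distance is found by bounded scalar optimisation on [0, 20]
substitutions/site (tolerance 1e-8). Distances are computed without gamma
rate heterogeneity by default (a shape parameter can be supplied).

Genes are kept when at most 15 OTUs lack any source sequence (inclusive
boundary). Missing-data percentages count both gaps (`-`) and unknowns
(`X`/`?`); ambiguity codes B/Z/J/U/O normalise to unknown. Partition
coordinates are 0-based half-open internally and 1-based inclusive in
reports. Gene-jackknife resampling draws k genes (default 130 of 258)
without replacement within a replicate, independently across replicates
(default 100), from a single seeded generator.

## Substitution models and likelihoods

Empirical LG and WAG exchangeabilities and frequencies are shipped as
plain-text data files in the package (residue order ARNDCQEGHILKMFPSTWYV).
Rate matrices are built as q_ij = ρ_ij π_j, normalised to one expected
substitution per unit branch length at stationarity; detailed balance holds
by construction. Among-site rate variation uses the discrete-gamma model
with four equal-weight categories; category rates are conditional means of
equal-probability bins (medians behind a flag), renormalised to mean
exactly one. Note that for shape α the outermost bin means sit about
1.27·α^{-1/2} from 1, which bounds how fast the discretisation approaches
the strict-clock limit.

Likelihoods use Felsenstein pruning with rescaling. Equal-exchangeability
(Poisson/F81-type) models take an O(20)-per-site closed-form transition
fast path; general reversible models use the symmetric eigendecomposition
of the generator. A fixed-topology engine caches per-node partial vectors
and per-branch messages and re-peels only the path from a changed branch to
the root, with full snapshot/revert support — the inner loop of the dating
sampler, where an age move touches at most three branches. The engine
rescales by a single scalar per node (sufficient at these tree depths);
the general-purpose pruning routine rescales per site. A from-scratch
recomputation every 1,000 cycles guards against incremental drift
(tolerance 1e-6).

## CAT profile mixtures

The site-heterogeneous CAT model is a Dirichlet-process mixture over
20-state stationary profiles with shared exchangeabilities (uniform for
CAT-F81, free for CAT-GTR). The base measure is a symmetric Dirichlet(1);
the concentration parameter has an exponential hyperprior with mean 10 and
moves by a log-scale random walk against the Chinese-restaurant marginal.
Allocations are resampled by Gibbs sweeps with m = 3 auxiliary components
redrawn per site (Neal's Algorithm 8); a singleton's own profile occupies
the first auxiliary slot. Component profiles move by Metropolis–Hastings,
alternating a Dirichlet random walk centred on the current profile with an
independence proposal from a Dirichlet fitted to the component's observed
residue counts; the latter is near-conjugate when branches are short and
keeps acceptance healthy when the data are informative. The default
initial state gives every site its own component: Gibbs merges components
far more readily than it splits them, so an over-dispersed start mixes
much better than a single-component start.

## Clock models and priors

Three clock models are implemented:

* **CL** — strict clock at rate μ_r.
* **LN** — autocorrelated log-normal: per-node instantaneous rates with
  ln r_child ~ Normal(ln r_parent − σ²Δt/2, σ²Δt); the mean correction
  keeps E[r_child | r_parent] = r_parent. The root rate is
  LogNormal(ln μ_r, 1). Branch effective rates are arithmetic means of the
  endpoint node rates (geometric mean behind a flag).
* **UGAM** — uncorrelated gamma: i.i.d. branch rates with shape 1/ν and
  scale ν μ_r (mean μ_r, variance ν μ_r²); ν = 0 degenerates to CL.

Node ages carry the birth-death prior conditional on the root age and taxon
count: non-root internal ages are i.i.d. draws from the kernel
g(t) ∝ λ p₁(t) on (0, t₁), with closed forms for the Yule (μ = 0),
critical (λ = μ) and uniform (λ → 0) regimes, and a closed-form inverse
CDF used both for simulation and for probability-integral-transform
checks. The root age has an exponential prior (mean 540 Mya by default,
matching a Cambrian-scale deuterostome root).

Soft fossil calibrations multiply the prior: the factor is flat on the
allowed interval and decays exponentially outside, with tail scales chosen
so each used tail holds mass fraction ε (default 0.025) of the normalised
factor. A minimum-only bound has an unbounded plateau — the birth-death
and root priors bound ages above — so its tail scale references the bound
itself, and the normalised-mass property is only well-defined (and tested)
for bounded-plateau constraints. The packaged fixture
`calibrations_paper13.tsv` carries 13 constraints (12 vertebrate intervals
and one echinoderm minimum, e.g. Chordata [519, 581] Mya, Echinoidea
min 255 Mya), each anchored by two taxa whose MRCA identifies the clade.

Hyperpriors: σ² and ν exponential with mean 1 /Mya; μ_r log-normal with a
wide spread (log-sd 3) around 0.005 subs/site/Mya; when the birth-death
rates are sampled they get exponential priors with means 0.1 and 0.05
/lineage/Mya — weakly informative at the 540-Mya scale.

## MCMC

One cycle is a full sweep of the move schedule. Phylogram mode: ten
branch-length multipliers, two NNI moves, one SPR (with edge-length
Hastings terms), one re-rooting move, a gamma-shape walk (log-uniform
prior on [0.01, 100]), GTR exchangeability/frequency moves, and for CAT
models one Gibbs sweep plus profile and concentration updates. The
re-rooting move places the root uniformly on a uniformly chosen edge;
under reversible models the likelihood is invariant, so the chain mixes
over root placements the data cannot distinguish — consensus supports and
convergence diagnostics then correctly reflect that uncertainty.
Branch lengths have i.i.d. exponential priors (mean 0.1).

Chronogram mode (fixed topology): per-node age slides uniform between the
adjacent node ages, a multiplicative root-gap move plus an independence
root proposal from the truncated exponential prior (whose density cancels
the root-prior factor — this move is what makes prior-only root sampling
mix fast), per-node (LN) or per-branch (UGAM) rate walks, and
hyperparameter walks. Two Jacobian-corrected rescaling moves are
essential for honest posteriors: a **global rate–time rescale** (all
internal ages × c, all rates ÷ c) that leaves every branch length — and
hence the likelihood — unchanged, and a **per-subtree rate–time rescale**
(a subtree's internal ages × c, its rates ÷ c) that changes only the stem
branch. Rate × duration is what the sequence data identify; without these
moves a chain cannot travel along the rate/time ridge, its posteriors are
dramatically overconfident, and simulation-based calibration fails — with
them, posterior ranks of true parameters are uniform. An ages-only global
scaling is additionally used in prior-only runs (with the likelihood on it
changes every branch length and is essentially never accepted). The
fixed-topology engine also collapses identical site patterns (exact, with
pattern weights). Each chain runs from a single seeded generator; the
chain id offsets the seed, and equal seeds give bitwise-identical traces.

Convergence is reported as the maximum clade-frequency difference between
two chains (threshold 0.3) plus relative differences of scalar means.

## Cross-validation

Learning/test splits are uniform without replacement: fixed counts (e.g.
10,000/2,000) or fractions (90/10; on 66,593 sites that is 59,934/6,659).
The score of a model is ln[(1/S) Σ_s L(test | θ_s)] over retained posterior
samples via running log-sum-exp (the mean-of-logs alternative is behind a
flag). CAT samples mix their components by occupancy weight at prediction
time; the new-component mass is omitted, which affects all compared models
alike. Models are compared by paired per-replicate differences, reported
as mean ± sample SD (not standard error).

## Synthetic benchmarks

The generator draws birth-death chronograms conditioned on tip count and
root age (inverse-CDF kernel sampling plus uniform lineage splitting),
rates under any of the three clocks with an optional fold-elevation of a
designated subtree, and amino-acid alignments simulated root-to-tips with
discrete-gamma site rates and optional per-site profiles. Missing data are
applied as whole taxon-by-gene blocks until the global target is met —
mirroring how transcriptome incompleteness manifests — and no taxon is
ever blanked entirely.

Two presets are pinned:

* **tiny** — 8 taxa, 5 genes × 200 sites, LN clock (μ_r = 0.002,
  σ² = 0.001), Poisson model with a single rate class (age/rate recovery
  does not need among-site rate variation, and a single class keeps the
  recovery studies fast), two soft calibrations bracketing the two oldest
  non-root clades at ±15%, birth rate 0.01/Mya. The root age is drawn from
  an exponential with mean 500 Mya — the same law used as the root prior in
  recovery runs — so that interval-coverage studies are well-calibrated:
  the truth is a draw from the model's own prior.
* **paper-shape** — a fixed 63-taxon deuterostome-wide backbone
  (18 tunicates, 34 vertebrates, 1 cephalochordate, 10 outgroup taxa),
  20 genes × 100 sites under LG+Γ₄, 20% block missing data, the packaged
  13-calibration fixture attached to the matching clades, ages drawn
  hierarchically inside the calibration plateaus with the root near
  540 Mya, and a 6.25-fold rate elevation of the tunicate subtree — the
  emulated effect size for rate-contrast analyses.

Benchmarks regenerate bit-identically from (preset, seed).

What passing these benchmarks shows: the samplers target their stated
posteriors, the estimators recover parameters under the generating model,
and model selection ranks the generating model first. What it does not
show: robustness to alignment error, model misspecification beyond the
tested families, orthology mistakes, or compositional heterogeneity of
real transcriptome data — the generator produces none of these.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` rerun these studies at sizes
chosen to finish on a single CPU:

1. **Likelihood oracle** — pruning vs exhaustive internal-state
   enumeration on 4–5-taxon, ≤5-site cases under Poisson, LG+Γ₄, GTR+Γ₄
   and one-component CAT (tolerance 1e-10).
2. **Prior recovery** — a prior-only dating chain on 6 taxa; the root-age
   marginal is tested against Exponential(540) and non-root internal ages
   by probability-integral transform against the birth-death kernel (KS,
   ~10⁴ samples thinned to near-independence; the KS test assumes i.i.d.
   draws, hence the heavy thinning).
3. **Coverage** — 20 tiny-preset replicates, LN dating with
   hyperparameters treated as known; 95% CI coverage of true node ages is
   tested by a one-sided binomial test against under-coverage (the
   calibration windows sit around the truth and can only make intervals
   conservative).
4. **Substitution-model CV** — data simulated under a fixed general
   reversible matrix (the LG table) with Γ₄ on 6 taxa; GTR vs Poisson at
   2,000 training / 500 test sites, 10 replicates.
5. **Clock CV** — LN-simulated rates (σ² = 0.002, μ_r = 0.0008) on a fixed
   balanced 8-taxon chronogram of two 400-Mya-deep sister clades, with a
   6.25-fold elevation of one clade (the between-group contrast) and
   alternating 4× fast / 4× slow terminal lineages within both clades (the
   within-group contrast); 90/10 splits, 5 replicates; both relaxed clocks
   must outscore the strict clock. Two design points matter here. First,
   divergences stay at the informative scale (base root-to-tip paths ≈ 0.3
   substitutions/site): a saturated fast clade leaves no mid-depth signal
   for any clock model to disagree about. Second, a smooth between-clade
   contrast alone is nearly ultrametric-fittable — a strict clock with
   free node ages reproduces almost all tip-to-tip distances by rescaling
   node ages — so the discriminating signal is the within-clade
   alternation: sister tips with very different terminal rates violate the
   ultrametric three-point condition against every distant taxon, which no
   assignment of node ages can absorb.
6. **Jackknife bookkeeping** — 100 replicates of 130-of-258 genes;
   jackknife support is 100 exactly for clades present in every replicate
   consensus.
7. **Descriptive statistics** — node-to-tip path-length medians, the
   tunicate/vertebrate rate contrast (ratio of group means, two-tailed
   Welch t test) and pairwise sequence identities on the paper-shape
   benchmark, recomputed deterministically.

## Known limitations

* Topology inference is practical at tens of taxa and thousands of sites;
  the CAT samplers are intended for small-to-moderate matrices (no
  data-parallel likelihood).
* "Cycle" counts are internal to this package's move schedule and not
  comparable to other software's cycle definitions.
* No tip dating, no fossilised birth-death process, no codon or nucleotide
  models, no data recoding.
* The predictive CV score for CAT ignores prospective new components; with
  realistic concentrations the omitted mass is negligible and identical
  across compared models.
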
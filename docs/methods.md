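# Methods

This note documents the models, the numerical choices and the open
design decisions behind `minet`, and what the synthetic benchmark does
and does not establish.

## Statistical model of the pipeline

The pipeline treats miRNA expression X (n samples × J miRNAs) as the
explanatory side and gene expression Y (n × K genes) as the response
side, twice over: once pair-by-pair (phase 2) and once jointly under
structured sparsity (phase 5).

**Pairwise cis eQTL model.** For each cis pair, y = a + βx + ε with
Gaussian ε; β is tested with the exact two-sided t statistic on n − 2
degrees of freedom. No covariates are included. "cis" means the
minimal distance between the two genomic intervals is ≤ 1 Mb,
inclusive at the boundary and strand-agnostic; overlapping features
have distance 0. BH-FDR is applied once, jointly across every tested
cis pair (the convention of single-analysis cis scans), and the seed
set is FDR < 0.01. p-values that underflow to exactly 0 under extreme
signal are clamped to the smallest positive double before the BH step,
whose domain is (0, 1].

**Quantile normalization.** Between-sample: each column is mapped to
the across-column mean of order statistics. Ties receive the mean of
the reference values over the tied rank span, which keeps the map rank
preserving and makes it idempotent on tie-free data (to 1e-10; with
ties the per-column tie pattern perturbs the reference on the second
pass, as in the common implementations of this dialect). Samples are
intersected and completeness-filtered *before* normalization, since
the order-statistic reference is only meaningful on a common sample
set.

**Permutation null for PPI seeds.** The statistic per seed gene is its
number of direct connections to other seeds. The null conserves
topology: the edge structure is kept verbatim and node labels are
permuted within exact-degree bins; a bin holding a single node is
merged with the nearest-degree bin so no node is trivially fixed (at
the price of only approximate degree conservation inside merged bins).
p = (1 + #{permuted statistic ≥ observed}) / (1 + P) with P = 1000 by
default — the add-one estimator, so p ∈ [1/(P+1), 1] and the test is
valid (super-uniform under the null). Correction across seeds is BH.
Expansion keeps every PPI edge incident to a seed with corrected
p ≤ 0.05, as a single ranked round (ranked by the incident seed's
significance); iterative multi-round growth was deliberately not made
the default since one expansion round is the documented behaviour of
the workflow this package operationalizes.

Degree-conditioned nulls are conservative by construction for modules
whose members dominate their own degree class: if the planted/true
module inflates its members' degrees beyond what the background
carries, the permutation can only map seeds onto seeds and power
collapses. This is a property of the test, not a bug; the synthetic
PPI defaults (below) are chosen so the background shares the module's
degree range.

**MtLasso2G.** The joint model minimizes

    ||Y − XB||²_F + λ||B||₁
      + γ₁ Σ_{(m,l)∈E_gene}  w_ml Σ_j |b_jm − sign(r_ml) b_jl|
      + γ₂ Σ_{(f,g)∈E_miRNA} w_fg Σ_k |b_fk − sign(r_fg) b_gk|

over B (J × K). E_gene and E_miRNA are Pearson co-expression graphs
with edges at |r| ≥ 0.7 (configurable; the construction of these
graphs is otherwise an open choice) and w = |r|. The signed fusion
pushes coefficients of positively correlated features toward equality
and of negatively correlated features toward equal magnitude with
opposite sign. Columns of X and Y are z-scored internally;
coefficients are reported on the standardized scale.

## Solver

Both fusion terms are linear maps of B followed by an entrywise ℓ1
norm (difference operators D₁: K→E₁ acting on the right, D₂: J→E₂ on
the left), so they are Nesterov-smoothed with the Huber function of
width μ (default 1e-3): quadratic inside ±μ, linear outside, gradient
clip(z/μ, −1, 1). The ℓ1 term is kept exact through its prox
(soft-thresholding at λ/L). The step size is 1/L with

    L = 2·σ²max(X) + γ₁·σ²max(D₁)/μ + γ₂·σ²max(D₂)/μ,

spectral norms computed densely (problem sizes are desk scale). FISTA
momentum is combined with a monotone restart: if an accepted step
would increase the recorded surrogate objective (exact RSS + exact ℓ1
+ smoothed fusion), momentum is reset and the step retaken from the
best iterate, so the recorded trace is non-increasing by construction;
a second increase from a cold restart indicates numerical
stationarity and stops the solver. Convergence is declared at relative
surrogate change < 1e-8 (default) or max_iter = 2000.

The smoothing bias is O(μ) in the objective; the reductions are exact
in the limit and verified in the tests: γ = λ = 0 matches per-column
least squares to 1e-4 normalized Frobenius error, γ = 0 matches
coordinate-descent lasso to 1e-3 per coefficient, and a single strong
fusion edge (γ → 1e4) fuses the two coupled columns to 1e-3.

**Hyperparameters.** λ, γ₁, γ₂ default to joint data-driven selection:
5-fold cross-validated mean squared prediction error over the grid
λ ∈ {0.5, 0.3, 0.2, 0.1}·λmax (λmax = 2·max|XᵀY|, the smallest λ with
an all-zero solution at γ = 0) crossed with γ = {0.02, 0.1, 0.5}·λ
(γ₁ = γ₂ during the search). The one-SE rule resolves statistically
indistinguishable candidates toward parsimony — largest λ first,
smallest γ second. The direction of that tie-break matters: CV
prediction error is nearly flat between the sparse solution and one
that smears a causal coefficient across its correlated block-mates
(correlated predictors substitute for one another at little predictive
cost), and only the parsimonious end of the plateau identifies the
support.

**eQTL extraction.** Entries with |b| > 0.1·max|b| (default,
`nonzero_rel`; or an explicit absolute `nonzero_eps`) are reported as
multitask eQTLs. A machine-epsilon cutoff is deliberately not the
default: the smoothed fusion terms and lasso over-selection under
correlated designs leave a halo of small but genuinely nonzero
coefficients on co-expression neighbours of true effects. Pilot
simulation under the default synthetic conditions places that halo
below ~0.15·max|b| while planted effects stay above ~0.35·max|b|; the
0.1 default is the standard thresholded-lasso post-step sitting
between the two scales. On real data with effects spanning orders of
magnitude this cutoff trades weak true effects for precision — lower
`nonzero_rel` (or set `nonzero_eps=0.0`) to see everything the solver
kept.

**Association subnetworks.** "Perturbed" features/labels are those in
at least one extracted eQTL. The gene-side subnetwork is the
correlation edges *among* perturbed genes (both endpoints); the
miRNA-side subnetwork keeps every correlation edge *touching* a
perturbed miRNA. The asymmetry feeds the integration rules: the miRNA
merge rule may introduce a correlated partner as a new node, while the
gene and multitask-eQTL rules only ever connect existing members.

## Integration

The integrated network is a multigraph: parallel edges of different
types between one node pair are all retained (an eQTL and a target
interaction between the same miRNA and gene are distinct evidence).
Deduplication is on (a, b, edge_type). Merging runs miRNA correlations
first — newly added miRNAs can then anchor multitask eQTL edges — and
the two both-endpoint rules afterwards; those two are pure filters
over a fixed node set and commute. Endpoint-type discipline
(miRNA→gene for eqtl/target/mtlasso_eqtl, gene–gene for ppi/gene_corr,
miRNA–miRNA for mirna_corr) is asserted after every merge.

## Synthetic data: what it emulates, what it does not

The generator emulates the post-normalization shape of a paired
tumor-cohort dataset at desk scale (defaults 60 mature miRNAs as 30
hairpins × 2 arms, 300 genes, 200 samples; the cohort it stands in for
is roughly 3× the miRNAs, 45× the genes and 2.4× the samples):

* **Expression.** Gaussian marginals — the pipeline operates after
  quantile normalization, so count-level modelling would add realism
  the downstream stages never see. Co-expression blocks are generated
  by a shared latent factor per block (x = √ρ·f + √(1−ρ)·ε), giving
  exchangeable within-block correlation ρ = 0.8 — comfortably above
  the 0.7 graph threshold so the fusion graphs are populated.
* **Planted effects.** 20 miRNA→gene pairs, standardized effect 1.0
  with ±10% jitter against noise SD 0.5. Effects are graph-smooth by
  construction: a perturbed gene block shares one causal miRNA and the
  sign of its effect, which is the structure the fusion penalty
  rewards; causal miRNAs' block-mates are null, which is the structure
  the miRNA fusion can wrongly smear (and the hyperparameter selection
  must resist).
* **Coordinates.** BED, 0-based half-open; one chromosome per miRNA
  block, anchors 10 Mb apart. Exactly round(cis_fraction·n_true) true
  pairs fall inside the 1 Mb window (gap 10–900 kb); the rest sit 2–5
  Mb away. Null genes are split half inside, half outside random
  miRNA windows so the cis scan tests genuine null pairs.
* **Target database.** The planted pairs plus an equal number of
  decoy records; 25% of names (by default) have the arm suffix
  stripped to exercise −3p/−5p disambiguation.
* **PPI.** Barabási–Albert preferential attachment (heavy-tailed
  degrees) over the gene universe plus a planted clique among the
  true-pair genes. The default density (3000 edges, mean degree ~20,
  the ballpark of aggregate PPI resources) is a deliberate choice:
  with a sparse background the clique-inflated seed degrees would
  dominate their own degree class and the degree-conditioned
  permutation test would be structurally powerless (see above).

Not emulated: read-level sequencing noise, isoform quantification,
batch effects, library-size artifacts, non-Gaussian marginals,
trans-acting effects, and target-database false positives beyond the
uniform decoys. Passing tests therefore establish the correctness and
calibration of the machinery under the stated generative model, not
performance on real cohorts.

All generator randomness flows from one integer seed; identical
configurations produce byte-identical files.

## Numerical and degenerate-input choices

* Constant features: detected exactly (min == max). They are excluded
  from correlation graphs and skipped in pairwise scans with a
  warning; a constant predictor in a single fit is an error.
* BH domain: p ∈ (0, 1] enforced; underflowed p = 0 values are clamped
  to 5e-324 by the caller before correction.
* Perfect pairwise fits report p = 0 with t = ±∞ by convention.
* Quantile-normalization ties: mean of the reference values over the
  tied span (see above).
* Permutation p-values: add-one estimator, never 0.
* Extraction ties and ordering: eQTLs sorted by |coefficient|
  descending with a stable sort; expansion edges ranked by
  (p_corrected, p_perm, gene_id) of the incident seed, then neighbour
  ID, so all outputs are deterministic.

## Problem sizes in the shipped configuration

The packaged study conditions (`configs/synthetic.yaml`) run the
workflow at 60 × 300 × 200 with 1000 PPI permutations and the full CV
grid — about 13 s end to end on one CPU — and the test suite's
calibration checks use 100–500 replicated small instances per
property. These sizes were chosen so the whole suite stays
desk-interactive while every statistical claim is still measured from
replicated sampling rather than a single draw.

## Known limitations

* The fused objective is convex but not strongly so; with duplicated
  features the argmin is not unique and only the objective value, not
  B itself, is stable — the tests compare against oracles only in
  well-posed settings.
* The smoothed solver's halo (see extraction) means "the set of
  nonzero coefficients" is threshold-relative; report thresholds, not
  raw support sizes, when comparing runs.
* The degree-binned permutation null is conservative for seed sets
  that dominate their degree classes, and the merged singleton bins
  conserve degree only approximately.
* BH across permutation p-values with heavy ties is conservative as
  well; corrected seed significance should be read as a ranking, not
  an exact error rate.
* cis distance is interval-to-interval; analyses anchored at TSSs
  will count a handful of boundary pairs differently.
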
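# Methods

## Scope and model overview

synernet links three evidence streams — clinical outcomes, a PBMC
transcriptome, and a urinary NMR metabolome — to bioactive compounds
through a typed directed biological network. Each stream is reduced to a
set of differential markers; markers curated to a phenotype become the
sinks of a bounded shortest-path search from the compounds; the retained
subnetwork is summarized (per-compound targets, per-target connectivity)
and annotated with enriched metabolic pathways to form a
component–target–pathway (CTP) network.

## Clinical comparison

The response analysed per outcome is the percent relative change
`100·(week4 − baseline)/baseline`, undefined at zero baseline (an error,
not a NaN). Arms are compared by one-way ANCOVA: an OLS fit of
`Δ% ~ 1 + arm + baseline` with treatment-coded arm dummies. Adjusted LS
means are the fitted values at the grand mean of the baseline covariate;
when baselines are balanced across arms these reduce to raw arm means,
which the tests assert. The group p-value is the partial F test of the arm
dummies (residual df = N − arms − 1). The covariate is the same-outcome
baseline: with a relative-change response, baseline adjustment is the
standard reading of "adjusted LS means", and the simulation tests confirm
it recovers planted effects without bias. Categorical baseline tables use
Pearson chi-square with no continuity correction — the choice is fixed by
the published alcohol-consumption table, whose printed p (0.6262) matches
the uncorrected statistic exactly; the published gender p does not
reproduce under any chi-square variant (a sparse-table exact test was
likely used) and is deliberately not asserted. The log-transform gate uses
bias-corrected sample skewness with default threshold |skew| > 1; the
threshold is a convention, configurable per call.

No multiplicity correction is applied across outcomes, matching
per-outcome reporting practice; no repeated-measures or mixed modelling is
attempted (complete-case analysis only).

## Differential expression

Fold change is the ratio of arithmetic group means on the linear scale
(treatment/reference, reference = lexicographically first group label);
the test is Welch's t on log2 values, the standard unequal-variance choice
at this scale. Cutoffs are inclusive (≥ 1.3-fold) and applied to |log2 FC|
so up- and down-regulation are symmetric; relabelling groups maps FC to
1/FC and leaves p unchanged (property-tested). Zero-variance genes with
equal means get p = 1 rather than erroring, so a degenerate row cannot
abort a screen. Raw p < 0.05 with no FDR correction mirrors the screening
design this stage reproduces; the downstream network stage is where
error control (FDR < 0.01) is applied.

## OPLS-DA, Q², VIP

The estimator follows the classical single-response orthogonal projection
scheme: at each of `n_orth` rounds the candidate predictive weight
`w ∝ Xᵀy` is computed, the orthogonal weight `w_o ∝ p − (wᵀp)w` is
extracted from the loading `p`, and the component `t_o p_oᵀ` is removed
from X; the final predictive component is a one-component PLS fit on the
filtered matrix. With `n_orth = 0` the model equals one-component PLS,
asserted against scikit-learn's PLSRegression as an independent oracle.
X is autoscaled (unit variance) by default, the convention for
metabolomics concentration tables; y is the centred −1/+1 class vector.
Defaults are one predictive + one orthogonal component and 7-fold
cross-validation, the common defaults of commercial chemometrics software.

Q² uses stratified k-fold CV: folds are drawn per class from a seeded
permutation so no fold can lose a whole group (a configuration that would
otherwise silently produce a one-class training set). Every fold refits
scaling and deflation from the training samples only. Q² ≤ R²Y is asserted
on separated data, where the optimism inequality holds in practice; it is
not a theorem for arbitrary data and is not asserted under the null.
Under the null (no group difference) the median Q² over 200 simulations is
non-positive, the accepted signature of an uninformative discriminant
model.

With one predictive component, `VIP_j = √p·|w_j|/‖w‖`, so the mean of
squared VIPs is exactly 1 — asserted to 1e−8 for every fitted model.
The marker tiers are: discriminant (VIP ≥ 1.0) and significant
(discriminant ∧ Welch p < 0.05). Note that under the null the significant
fraction of the discriminant tier exceeds the nominal α because VIP
selection and small p are positively correlated on the same data; the test
suite therefore bounds this fraction rather than asserting it equals α.

## Pathway analysis and enrichment

Over-representation is the hypergeometric upper tail
`P(X ≥ k)` with population = universe size, successes = pathway members in
the universe, draws = hit-set size — equivalent to the one-sided Fisher
exact test. Benjamini–Hochberg q-values are computed across tested
pathways; pathways with no members in the universe are excluded with a
warning rather than an error. The metabolome stage reports an additional
topological impact: the sum of relative betweenness centralities (each
node's betweenness divided by the graph total) of hit metabolites in the
pathway's graph, which is 1 when the hits carry all centrality (e.g. the
hub of a star) and 0 without a supplied graph. The enrichment universe for
the network stage defaults to all protein and metabolite nodes of the
parent network.

## Network extraction

Shortest-path search is directed compound → … → marker by default with an
undirected fallback flag, bounded at 3 hops (compound → target →
intermediate → marker covers the curated relations); all tied shortest
paths per pair are kept, verified against a brute-force DFS enumeration on
graphs of ≤ 50 nodes. "Targets" of a compound are its direct
protein/metabolite successors inside the retained subgraph, matching how
curated compound–target lists pair compounds with immediate targets.
Succinate is admitted as a metabolite-kind target. The marker→phenotype
layer is always read from a curated table, never inferred. CTP assembly
takes compound–target edges from the subnetwork and target–pathway edges
from curated links and/or membership of targets in enriched pathways;
isolated pathway nodes are dropped.

The curated vascular fixture transcribes the published six-compound /
15-target / six-pathway subnetwork; the corrupted symbol "NO53" is
normalized to NOS3 at fixture build time (the surrounding text
consistently uses NOS3 for endothelial nitric-oxide synthase). The fixture
network adds six decoy constituents wired only to decoy proteins; these
are synthetic stand-ins (so the extraction step has compounds to discard),
not curated content.

## Synthetic data: what it emulates and what it does not

Expression noise is Gaussian on log2 (lognormal linear), so planted genes
have exactly the stated expected fold change; metabolite concentrations
are lognormal with multiplicative group shifts, keeping them positive;
clinical follow-ups are `baseline·(1 + effect/100)` plus additive Gaussian
noise, so the expected relative change equals the planted effect. Default
problem sizes (1000 genes, 10 samples/group at 2-fold; 30-metabolite
panel, 12/group; 3 arms around 20/arm) are deliberately desk-scale:
simulations complete in seconds while leaving planted effects near the
detection boundary of the weakest ones. The generators do not emulate
probe-level microarray artifacts, NMR spectral overlap or binning,
inter-metabolite correlation structure, dropout/missingness, or
measurement drift — so passing recovery tests demonstrates correctness of
the estimators, not robustness to those real-data pathologies. The raw
trial data behind the original study are not deposited, so published fit
statistics from those data (e.g. a specific R²Y/Q² pair, exact DE gene
counts) are not reproduction targets; the tests instead assert recovery of
planted structure under the stated synthetic conditions.

## Numerical choices and degenerate inputs

- Fold-change boundary uses a 1e−12 slack so an exact 1.3-fold gene passes
  despite floating-point log rounding.
- OPLS deflation stops early if the orthogonal weight norm falls below
  1e−12 (no orthogonal variation left); requesting more components than
  the data support is therefore safe.
- Constant metabolite columns abort autoscaling with the column named;
  zero-variance genes abort z-scoring with the gene named.
- Tie-breaks: result tables sort by ascending p with a stable mergesort;
  node/edge exports sort lexicographically, making outputs byte-stable
  across runs.
- Clinical generator draws are keyed to arm position, not label, so
  relabelling arms permutes labels without changing values.

## Known limitations

Only two-group designs are supported in the omics stages; OPLS-DA is
single-response. The ANCOVA assumes a common baseline slope across arms
(no interaction term). Pathway impact requires user-supplied pathway
graphs; no pathway topology database ships with the package. The network
stage does not attempt to reconstruct any external association database —
analyses run on user-supplied edge lists, the synthetic generator, or the
curated fixture.
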
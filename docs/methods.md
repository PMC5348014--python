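# Methods

`rewirenet` models signal rewiring between a drug-sensitive (parental)
and a matched drug-resistant cancer cell line.  The input is one gene
expression matrix per cell line with samples in four conditions —
parental basal (PB), parental treatment (PT), resistant basal (RB),
resistant treatment (RT) — plus a protein–protein interaction (PPI)
network, a cancer-gene list, pathway gene sets (GMT) and a manually
curated signaling-link network.  The output is a set of *aberrant* gene
pairs whose probability of being connected differs between the two
conditions, pathway enrichment calls for those pairs, and V-structure
motifs linking rewired dependencies to gene dysregulation.

## Gene–gene relationship networks (GGR)

For each condition a network GGR = (S, R) is built.

**Seed genes S.** Differentially expressed (DE) genes come from a
two-tailed pooled-variance t-test of all parental against all resistant
samples with Bonferroni correction (corrected p ≤ α; α is per-run
configuration).  The pooled test follows the study design of matched
cell lines with equal group variances; degenerate zero-variance genes
get p = 1 when the group means agree and p = 0 otherwise — a convention,
since the test statistic is undefined there.  DE genes are combined with
the cancer-gene list (restricted to measured genes) and, later, with the
linker genes discovered below: S = DE ∪ CGC ∪ Linker.

**Edges R.** Pearson correlations are computed across the condition's
samples for all pairs of DE ∪ CGC genes.  Constant-expression genes get
correlation 0 (undefined PCC), which keeps them out of the cut.  The top
20% of |PCC| (exactly ceil(0.2 · C(n,2)) pairs; ties broken by
lexicographic pair order) become *direct* edges.  This ceiling rule
reproduces the cell-line counting arithmetic exactly: 704 genes give
247,456 pairs and 49,492 direct edges; 698 genes give 243,253 and
48,651.

Pairs below the cut are probed for *indirect* relationships: a length-2
PPI path i–L–j is scored by the geometric mean of |PCC(i,L)| and
|PCC(L,j)| and tested against an exhaustive empirical null in which L is
replaced by every eligible gene (all PPI genes with expression except i,
j and any gene already on a length-2 path between them).  The empirical
p-value is the fraction of null statistics ≥ the observed one (the
observed value is not added to the null); paths with p ≤ 0.05 are
significant.  A pair with at least one significant path becomes an
*indirect* edge, its middle genes become linkers, and the two PPI edges
of each significant path are added to R with provenance `ppi`.  No
multiple-testing correction is applied across path tests (a raw
empirical cutoff), and only paths of length exactly 2 are considered —
longer paths would make the search combinatorial without adding
interpretable linkers.

**Harmonization.** The final seed set is the intersection S_R ∩ S_P;
both edge sets are restricted to it and every unordered pair of the
final set becomes a dyad with binary indicators (u_R, u_P).

## The hierarchical p1 model

Each dyad (i, j) is an independent Bernoulli edge with

    log Pr(Y_ij1 = 1) = λ_ij + θ + α_i + α_j ,
    log Pr(Y_ij0 = 1) = λ_ij ,

so the edge probability is the logistic function of
η = θ + α_i + α_j and λ_ij = −log(1 + e^η) is never stored.  θ is a
global density parameter (one per condition by default; a shared-θ
switch exists because the formulation leaves this open) and α_i is gene
i's propensity to form edges.  The hierarchy is

    θ_c ~ N(0, τ_c⁻¹),  τ_c ~ Gamma(a₀ = 0.001, b₀ = 0.001),
    (α_i^R, α_i^P) ~ N₂(0, Σ),  Σ⁻¹ ~ Wishart(I₂, 2).

The bivariate prior on the per-gene propensity pair is the only coupling
between the two condition networks; its posterior covariance measures
how strongly connectivity is preserved across conditions.

**Sampling.** A Metropolis-within-Gibbs sweep updates θ_c and each
(α_i^R, α_i^P) pair by Gaussian random-walk Metropolis (the logistic
likelihood is not conjugate), then draws τ_c from its conjugate
Gamma(a₀ + ½, b₀ + θ_c²/2) full conditional and Σ⁻¹ from its conjugate
Wishart(2 + n, (I + Σᵢ αᵢαᵢᵀ)⁻¹) full conditional; both conjugacies are
verified in the tests against direct density evaluation.  Proposal
scales adapt every 50 sweeps during burn-in toward ≈ 0.44 acceptance
and then freeze, so the post-burn-in chain is a valid fixed-kernel
Markov chain.  Initialization: θ_c at the logit of the observed network
density, α = 0, Σ = I.  Defaults are 15,000 sweeps with a 10,000-sweep
burn-in and no thinning; a run on ~1,300 dyads takes under a minute on
one CPU.  Acceptance rates outside [0.05, 0.95] trigger a warning
rather than an error.

**Posterior edge probabilities.** After each post-burn-in sweep one
network per condition is drawn with independent Bernoulli edges at the
current probabilities; the reported posterior of a dyad is the fraction
of sampled networks containing it, with Monte-Carlo standard error
√(p(1−p)/S).  This posterior-predictive frequency converges to the
chain mean of the analytic edge probability (tested within binomial MC
error).

## Aberrant-pair selection

Posteriors are divided by their per-condition maximum over all dyads
(the two networks' posteriors live on different scales), giving
normalized values in [0, 1] and reciprocal odds

    odds_R = norm_p_R / norm_p_P ,  odds_P = 1 / odds_R .

Dyads with a zero posterior in the denominator are excluded from the
odds ranking (counted and logged) rather than mapped to infinity.
Selection is two-stage per condition: keep the top 20% of the odds
distribution, then among those the top 50% of the normalized
posteriors; "top X%" always means the ceil(X·n) largest values with
lexicographic tie-breaking, which makes selection deterministic and
order-invariant and reproduces the published aberrant totals exactly
(80,372 at 897 genes; 76,476 at 875).  Survivors in the resistant
direction are *red* (gained in resistance), in the parental direction
*green* (lost).  A dyad qualifying for both colors — only possible when
both odds thresholds are ≤ 1 — gets the color of its larger odds, ties
to red.  A diagnostic table sorts colored pairs by signed posterior
(green negated) and smooths their |PCC| with a centered 25-point moving
average, truncated at the ends; a smoothed-correlation trend mirroring
the posterior curve indicates the model tracks signal already present
in the correlations.

## Pathway enrichment

Pathway databases provide gene sets only; the true pairwise
relationships inside a pathway are the curated signaling links with
both endpoints in the gene set (directions and signs dropped).  With
N the size of the universe (union of all per-pathway link sets and all
aberrant pairs), M a pathway's links, K the pooled red+green aberrant
pairs and x = |M ∩ K|, the enrichment p-value is the hypergeometric
upper tail Pr(X ≥ x), computed with a numerically stable tail routine
and verified against exhaustive enumeration for all N ≤ 12.
Benjamini–Hochberg correction is applied within each database (one
family per database, matching per-database reporting); q < 0.05 flags a
pathway as dysregulated.  Pathways without curated links keep p = 1 and
stay in their family.  An alternative reading of the universe — all
within-pathway gene pairs instead of curated links — is conceivable but
the curated-link universe is used because enriched pairs are counted
among known links.

## V-structures and dysregulation

A V-structure is one green and one red edge sharing a *crossing gene*.
Crossing genes are those incident to at least one edge of each color;
the motifs are the Cartesian products of green and red edges at each
crossing gene, so the count is exactly Σ_k deg_green(k)·deg_red(k).
Against each pathway collection a motif is typed with precedence
III > II > I: Type-III if one pathway contains all three genes, Type-II
if two different pathways hold the green and red pair with the crossing
gene in both (cross-talk through the crossing gene), Type-I if all
three genes are annotated but neither configuration holds, otherwise
unclassified.  The precedence makes the per-type counts disjoint; genes
belong to many pathways, so without it most motifs would multi-type.  A
motif is literature-supported when both its edges are curated links.

A gene is *dysregulated* when its log2 fold-change versus the parental
baseline flips sign: FC_PT and both FC_RB, FC_RT strictly opposite.
Fold-changes use replicate-mean expression; input is assumed
linear-scale (log2 of a ratio of means), with a config switch to mean
differences for log-scale input.  No magnitude threshold is applied —
any strict flip counts — and a gene with a non-positive condition mean
is untestable.  The architecture summary splits genes with aberrant
degree ≥ 2 into a both-colors group (crossing genes) and a single-color
group and reports the dysregulation rate of each.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with every planted feature recorded as ground truth:

* **Samples**: 3 replicates × 2 treatment levels × 2 conditions,
  linear-scale values around baseline 8 with unit noise.
* **Stable block**: genes with graded loadings (0.15 up to 0.7) on a
  factor shared by both conditions — a co-expression continuum whose
  ranking is stable across conditions, as in real data.
* **Rewired modules**: two "bypass" modules correlated (ρ = 0.95) only
  in resistant samples and two "targeted" modules only in parental
  samples.  The twelve planted rewired anchor pairs sit inside these
  modules, because the p1 model reads rewiring off coordinated changes
  in connection propensity: an isolated rewired edge leaves no degree
  signature and is undetectable by this model class even in principle.
  Module satellites keep a weak off-condition loading (ρ = 0.45),
  mimicking a bypass program that pre-exists at low coherence; this
  also keeps module genes from becoming probability-floor outliers
  whose odds would crowd out every other dyad.
* **Crossing genes**: four genes each belonging to one red and one
  green module (the two colorings split the genes differently so
  failures decorrelate), with the dysregulation mean-shift pattern
  (+δ under parental treatment, −δ in both resistant conditions,
  δ = 0.8; the parental loading is raised slightly to offset the
  variance the shift adds).
* **Linker triples** (i, L, j): L correlates with both ends (ρ = 0.95
  through two private factors), i and j are uncorrelated, and the PPI
  network carries exactly the i–L and L–j edges.
* **DE genes**: a constant shift in all resistant samples, which
  changes the mean without touching within-condition correlations.
* **Pathways**: one enriched pathway holding all module genes and all
  within-module pairs as curated links, plus decoy pathways whose links
  avoid the planted pair space.

What passing end-to-end tests show — and what they do not: the planted
anchor pairs are colored at well above the background rate, the planted
pathway ranks first by q, and the planted crossing genes re-emerge as
V-structure apexes.  They do not show that the *specific* planted edge
at a crossing gene is recovered: because edge posteriors are functions
of node propensities only, a gene active in both conditions pushes all
its edges' odds toward 1, and which module partner passes the cut is
essentially noise.  Recovery of the apex, not the exact partner, is the
level of resolution this model class supports.  The generator makes no
attempt to mimic microarray noise (probe effects, batches), so the
tests say nothing about robustness to such artefacts.

## Numerical and testing choices

* Softplus terms use `logaddexp`, so Pr(Y₁) + Pr(Y₀) = 1 holds to
  machine precision at any η.
* All randomness flows through one seeded NumPy generator per run;
  outputs are bit-for-bit reproducible given the seed and sorted
  lexicographically by gene pair.
* Test problem sizes: conjugacy on 2-gene grids, parameter recovery at
  60 genes with 4,000 sweeps (θ within 3 posterior sd, Spearman between
  true and posterior-mean propensities ≥ 0.7), end-to-end runs on the
  default 120-gene scenario with 3,000 sweeps and five seeds — the
  posterior-predictive frequencies are stable at those lengths for this
  dyad count.  `scripts/acceptance.py` runs the full 15,000-sweep
  default once per scenario seed.

## Known limitations

* The p1 model is a degree model: it cannot represent community
  structure, so in networks with strong hub blocks the within-module
  posteriors of small modules are shrunk toward their genes' global
  connectivity.
* Max-normalization of posteriors makes the odds scale sensitive to the
  single most probable dyad per condition.
* The empirical path test is exhaustive but unadjusted across pairs;
  with few samples its null is wide.
* Six samples per condition make sample correlations noisy; direct-edge
  membership near the cut is unstable, which propagates into
  degree-contrast noise in the fit.
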
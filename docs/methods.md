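# Methods

## Scope and data model

The package operates downstream of denoising: its substrate is a validated
integer count matrix (ASVs × samples), a QIIME-style taxonomy (up to seven
ranks, unassigned ranks marked), and per-sample water chemistry. Upstream
read processing, taxonomy assignment and function prediction are out of
scope; the pipeline produces the inputs such tools consume (rarefied tables,
abundant/rare sub-community tables, keystone lists).

## Preprocessing

**Lineage exclusion.** ASVs annotated as chloroplast or mitochondria, and
ASVs with no domain-level assignment, are removed before any analysis.
Matching is a case-insensitive substring test over the assigned rank labels;
the sentinel term `unknown` selects domain-unassigned ASVs (including ASVs
absent from the taxonomy altogether). Exclusion runs before rarefaction, so
the common depth is spent on taxa that stay in the analysis; the operation
is idempotent and order-preserving.

**Rarefaction** draws, for each sample independently, `depth` reads without
replacement from the observed reads — a multivariate hypergeometric draw
(`numpy.random.Generator.multivariate_hypergeometric`). Consequences used by
the tests: every rarefied column sums exactly to the depth, no count
exceeds its original value, the marginal expectation of each count is
`depth · k/N`, and a fixed seed reproduces the table exactly. The seed is a
required argument. Samples shallower than the requested depth raise an
error naming the sample.

**Relative abundance** is computed after exclusion and rarefaction;
downstream classification and correlation work on these proportions.

## Alpha diversity

Shannon entropy uses the natural log and "Simpson" means the Gini–Simpson
index 1 − Σp² — the dominant conventions in amplicon tooling, stated here
because both have competing variants. Chao1 is
S_obs + F₁²/(2F₂) when doubletons exist and the bias-corrected
S_obs + F₁(F₁−1)/2 when F₂ = 0. ACE follows Chao & Lee with the
conventional rare/abundant cutoff at 10 (exposed as a parameter):
S_abund + S_rare/C + (F₁/C)·γ², C = 1 − F₁/N_rare, with γ² truncated at
zero; degenerate rare groups (C ≤ 0, i.e. all rare taxa are singletons, or
fewer than two rare reads) fall back to Chao1, and a sample with no rare
taxa returns S_obs. Good's coverage is 1 − F₁/N. These estimators are
implemented in-package because the exact branch behaviour above is part of
the contract; the test suite cross-checks them against scikit-bio on random
vectors.

## Abundance partitioning

Classification uses only each ASV's minimum m and maximum M relative
abundance across samples, against a rare threshold of 0.01 % (10⁻⁴) and an
abundant threshold of 1 % (10⁻²), in a fixed order: AAT if m ≥ 1 %; else
ART if M < 0.01 %; else CRAT if M ≥ 1 % and m < 0.01 %; else CAT if
M ≥ 1 %; else CRT if m < 0.01 %; else MT. Decisions embedded in that tree,
each a genuine choice:

* "≥ 1 %" is inclusive and "< 0.01 %" exclusive, so an ASV at exactly
  0.01 % everywhere is MT;
* a zero count is read as "below 0.01 %" in that sample, which is the only
  reading under which CAT (never below 0.01 %) excludes taxa with absences;
* the always-rare test precedes the conditionally-rare test, resolving the
  literal overlap between the two definitions.

Contribution accounting reports, per category and per coarse group, the ASV
count and the mean over samples of the summed member proportions (in %);
the three group contributions sum to 100 % by construction.

## Co-occurrence network

Taxa present (count > 0) in strictly more than 50 % of samples enter the
network stage. All-pairs Spearman correlation is computed as the Pearson
correlation of average ranks; the two-sided p-value uses the
t-approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df (p = 0 at |ρ| = 1).
Constant taxa have undefined ρ and simply acquire no edges. One shared
routine serves both the network and the environment screens, so the
tie-handling and p-value conventions cannot drift apart; scipy's
`spearmanr` and a hand-rolled rank-then-Pearson oracle verify it to 1e-12.

Edges require |ρ| > 0.6 **and** p < 0.05, both strict — a pair at exactly
ρ = 0.6 is not connected. Edge sign (positive/negative) is metadata; module
detection and Zi/Pi treat the graph as undirected, unweighted and unsigned.
No multiple-testing correction is applied to edge p-values by default,
matching the common practice for these descriptive networks; at n = 34 the
joint predicate's null rejection rate is ≈ 2·10⁻⁴ per pair, which the null
simulation test confirms.

Modules come from Louvain modularity maximization
(`networkx.algorithms.community.louvain_communities`), deterministic for a
given seed; module labels are assigned by descending size (ties broken by
smallest member id) so outputs are stable. For node i in module s:
Zi is the z-score of its within-module degree among module s's members
(population standard deviation; Zi = 0 for singleton or zero-spread
modules) and Pi = 1 − Σₛ (k_is/k_i)². Roles use Zi = 2.5 and Pi = 0.62
with strict inequalities for the non-peripheral classes, so a node exactly
on a threshold falls to the peripheral side; keystones are all
non-peripheral nodes. Within-module degrees always sum to the total degree,
and Pi ≤ 1 − 1/M for M modules — both property-tested.

## Trophic state and screens

Two trophic state formulations are implemented because the field uses both
and published station data rarely state which variant produced a reported
index. Carlson: TSI(SD) = 60 − 14.41 ln SD, TSI(Chl) = 9.81 ln Chl + 30.6,
TSI(TP) = 14.42 ln(1000·TP) + 4.15, composite = mean of available
components. The default `tli_composite` is the Chinese comprehensive TLI:
component indices for Chl-a, TP, TN, SD and the permanganate index
(formulas in `rarenet.envscreen`), weighted by the squared chlorophyll
correlations (r = 1, 0.84, 0.82, −0.83, 0.83). Missing components are
dropped per sample and the weights renormalised. Units: Chl-a in µg/L,
nutrients in mg/L, SD in m; non-positive inputs to a log raise an error
naming the sample and variable.

Screens correlate features (diversity indices, rank-aggregated taxa, or
keystone ASV proportions) against the metadata with TSI appended, through
the shared Spearman routine, starring p < 0.05 (*), p < 0.01 (**) and
p < 0.001 (***) with no multiple-testing correction (the raw-star
convention of correlation heatmaps in this literature). Pairs with fewer
than five complete observations or a constant vector are reported as
not-computed rather than dropped. Indicator calls list the taxa with any
starred TSI correlation, with direction, invariant to row order.

## Synthetic data: what it emulates and what it does not

`simulate_community` builds per-sample intensities
exp(baseline + loading·factor + noise): baselines are N(0, σ=2), giving the
heavy-tailed lognormal abundance spread in which rare taxa vastly outnumber
abundant ones; module members share a latent N(0,1) sample factor
(pairwise factor correlation 0.3 by default); connector taxa load on the
scaled sum of all factors; counts are a single multinomial draw per sample
at the configured depth. Category-forced taxa are planted by fixing their
expected proportions directly (e.g. always ≥ 2.5 % for an always-abundant
taxon, ≤ 10⁻⁶ for an always-rare one) so the planted label is the only
possible classification outcome under sampling noise — these margins are
what the 100 %-recovery test exercises. Metadata variables are monotone
transforms (normal CDF into realistic limnological ranges) of their linked
factor plus Gaussian noise; TN (0.5–0.7 mg/L) and TP (0.02–0.04 mg/L) are
linked to the first two module factors by default, with the other variables
independent noise in range.

Default study conditions: 34 samples, 5,000 taxa, 50,000 reads per sample,
four 30-taxon modules, loading 1.0, taxon noise 0.3. The sample count
matches the surveyed design; the taxon count and depth are desk-scale
choices that preserve the qualitative regime (thousands of taxa, coverage
near 1, a long rare tail) rather than the survey's full 10⁵-ASV scale.

`planted_network` emits a proportion matrix plus the generative block
structure. A large unstructured background pool (~95 % of total intensity)
is included deliberately: without it, the per-sample closure (dividing by
the sample total) couples every planted taxon to the module factors and
destroys the planted correlation structure — a compositional artefact worth
remembering when interpreting real correlation networks too. With
correlated factors (0.3), a connector taxon's population correlation with
module members is ≈ 0.69, above the edge threshold, while cross-module
member pairs stay near 0.3, below it.

Graph-level generators (`planted_partition_graph`, `planted_role_graph`)
plant modules, hubs and connectors directly in adjacency space: four
30-node blocks, within-block edge probability 0.6 (0.3 for the role graph)
and 0.02 between; one hub per module wired to 80 % of its module; extra
connector nodes wired to 5 random nodes in each module, whose analytic
participation coefficient is 1 − 4·(1/4)² = 0.75.

What the generator does **not** emulate: sequencing error and chimeras,
overdispersion beyond the multinomial (a Dirichlet layer could be added,
but the plain multinomial keeps the null calibration analytically
transparent), phylogenetic signal in the taxonomy (labels are drawn
randomly from a fixed pool of realistic lineages), spatial autocorrelation
among samples, and genuinely compositional negative dependence at low
richness. Passing the recovery tests therefore demonstrates correctness of
the pipeline's inference machinery under its stated model, not robustness
to every artefact of real amplicon data.

## Numerical choices and degenerate inputs

* Spearman needs ≥ 4 paired observations; screens additionally require 5.
* ρ is clipped to [−1, 1] against floating-point drift before the p-value.
* Zero-variance vectors: undefined correlation, logged as no-edge /
  not-computed, never an exception.
* Empty keystone sets, empty screens and zero-row tables flow through;
  zero-sum samples and over-deep rarefaction raise errors naming the
  sample.
* Module labels, node tables and edge lists are sorted deterministically;
  the end-to-end pipeline is byte-reproducible for a fixed seed.

## Problem sizes

The shipped tests and the acceptance script run the community pipeline at
34 samples × 5,000 taxa × 50,000 reads, recovery simulations at 120-node
planted graphs over 20 seeds, and calibration at 500 replicates of n = 34 —
sizes chosen so the full suite completes in well under a minute while
keeping every estimate's Monte-Carlo error far below the asserted margins.
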
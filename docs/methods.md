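# Methods

This note records the modelling conventions, reconstructed formulas, and
design choices behind `seednet`, and what the synthetic-data tests do and do
not establish about real data.

## Module construction

The module is the two-step closure of the seed list: seeds, their direct
interaction partners, and all interactions among the retained proteins.
Protein IDs are case-sensitive opaque strings; edges are stored with
lexicographically ordered endpoints, undirected, unweighted, without
self-loops or duplicates. A seed absent from the interaction universe stays
in the module as an isolated vertex (with a warning) so that seed counts are
preserved under resampling nulls.

Connectivity is reported as a boolean single-component check. Degree-one
claims such as "every pair of proteins is linked" are not meaningful for a
sparse module; what matters statistically is whether the module is one
component and how its measures compare to matched random graphs.

## Centrality conventions

Random G(n, m) graphs can be disconnected, so every measure must be defined
on disconnected graphs and applied identically to observed and null
networks:

* closeness: per connected component, (number of reachable vertices) /
  (sum of distances to them); isolated vertex → 0;
* betweenness: raw unordered-pair counts (a normalized variant is a flag);
* eccentricity: maximum distance within the component; isolated vertex → 0;
* clustering coefficient: standard local transitivity, 0 for degree < 2;
* density: 2m / n(n−1).

Null-replicate statistics are vertex means over the whole graph, isolated
vertices included. That choice (rather than dropping isolated vertices) is
an assumption; it biases null closeness/eccentricity means downward
slightly, in the conservative direction for "observed exceeds null" tests.

## Discrete power-law fit

The tail model is p(x) = x^(−α)/ζ(α, x_min) on integers x ≥ x_min. α is
estimated by maximizing the tail log-likelihood (dense grid plus one
parabolic refinement — accurate to ~1e-3, far below the sampling error
(α−1)/√n_tail); x_min by minimizing the KS distance between tail empirical
and fitted CDFs, ties broken toward the smaller x_min (larger tail).

Candidate thresholds that would keep fewer than max(10, 2% of n)
observations are excluded from the scan. Unconstrained scans can land on a
handful of deep-tail points that fit any law by luck; that choice inflates
neither error under the true model (the tests recover α = 2.5 to ±0.04 at
n = 5000 with x_min found at its true value) but it is essential for the
power of the goodness-of-fit test against curved alternatives. The fraction
is configurable, and a pinned `x_min` bypasses the scan.

Goodness of fit uses the semi-parametric bootstrap: each replicate draws
the body (x < x_min) empirically and the tail from the fitted law, is
refitted from scratch under the same scan constraints, and the p-value is
the fraction of replicate KS distances at least as large as observed.
1000 replicates by default; the bootstrap seed is mandatory in the CLI.
Sampling uses an inverse-CDF table truncated where the residual tail mass
falls below ~1e-9 (cap 10^6), which is negligible for the exponents that
arise here. The power of the test depends on the alternative: a geometric
with mean ≈ 4 (success probability 0.25, the mean-degree scale of these
networks) is rejected at n = 5000, whereas very long-tailed geometrics are
locally power-law-like over their last decade and may not be.

## Null models and empirical p-values

Two ensembles: G(n, m) matched on vertex and edge counts, and seed
resampling (the same number of seeds drawn uniformly without replacement
from the universe, module rebuilt; replicate sizes vary by construction).
The default desk-scale replicate count is 1000 — large enough to resolve
p < 0.05 and p < 0.001 in kind; the original analysis used 100,000 for
finer resolution. One-sided empirical p is the tie-inclusive count of
replicates at least as extreme over N; a zero count reports "< 1/N";
two-sided is 2·min(one-sided) capped at 1.

## Term specificity and enrichment

Ancestors and offspring are distinct-set counts over both is-a and part-of
edges (relation filtering is a flag); the DAG has a single root. Two
specificity formulas are reconstructions pinned to the published worked
examples (the printed equations were not machine-readable):

* offspring score ln((A+1)/(n_offspring+1)), with A the root's offspring
  count (default 23877). The +1 convention gives a zero root score and
  reproduces the anchor value 8.982 for two offspring exactly. The printed
  table is itself inconsistent at the fourth decimal for single-offspring
  terms (9.389 printed where any constant consistent with the two-offspring
  row gives 9.388), so agreement there is to ~1.5e-3, not exact.
* GO proportion n_anc/(n_anc + n_off) in [0, 1]; undefined when both
  counts are zero.

Information content is −log₂(annotation count / total annotated), in bits;
base 2 is pinned by inverting the published values onto integer counts
(e.g. 11.034 bits ⇔ 7 of 14673). Annotation counts are taken after upward
propagation (a protein annotated to a term counts for all its ancestors);
pre-propagation counting is the other defensible reading, but propagation
matches the "root has IC 0" anchor with partial annotation coverage.

Enrichment: EASE score, the one-sided Fisher exact p after removing one
protein from the study-overlap cell — equivalently the hypergeometric tail
P(X ≥ k−1); terms with fewer than 2 study hits are skipped (k ≤ 1 gives
p = 1 anyway). Raw p-values are thresholded at 0.05 by default, matching
the original analysis; a Benjamini–Hochberg flag exists but defaults off.
A term is "most specific" within a result set when none of its offspring is
in the set.

## Similarity matrices

* Jaccard J_ij = |N_i ∩ N_j|/|N_i ∪ N_j| over direct-neighbor sets, unit
  diagonal by definition, 0 for pairs of isolated proteins.
* Wang semantic similarity: S-values computed by memoized recursion over
  the ancestor closure; S_t(t) = 1 and S_t(a) = max over in-scope children
  c of w(relation)·S_t(c), with weights 0.8 (is-a) and 0.6 (part-of) — the
  method's published defaults, not overridden here. Term similarity is
  Σ(S₁+S₂ over common ancestors)/(SV₁+SV₂); protein similarity is the
  best-match average over annotation sets. Unannotated proteins get
  similarity 0 with a warning.
* Combination: the exact published combination of J and GS is not
  recoverable; the default is the elementwise mean, which preserves
  symmetry, the unit diagonal, and the [0, 1] range. Product and max are
  available, and the chosen scheme is recorded in the output metadata so
  any convention is reproducible.

## Label propagation

With D the diagonal row-sum matrix of W, unlabeled scores solve
(D_UU − W_UU) f_U = W_UL y_L — the harmonic solution, which obeys the
maximum principle (scores stay inside the labeled range). Unlabeled
proteins with no similarity path to any label are reported as
unpredictable (NaN) rather than raising; scores are clipped to [0, 1]
against numerical drift.

The sequential variant ranks unlabeled proteins by labeled connectivity
(count of labeled proteins with nonzero similarity, ties by ID), splits
them into k regions (default: one per protein), and solves region by
region with each fitted region joining the labeled side. Two details are
deliberate reconstructions, isolated behind `PropagationConfig`:

* regions feed forward their raw fitted scores; the penalty
  1/(1 + l·region_index) (l = 2 by default) shrinks only the *reported*
  score toward the neutral 0.5. Shrinkage encodes reporting confidence;
  feeding shrunk scores forward would penalize distance twice. Shrinkage
  never moves a score across 0.5, so predicted directions are unaffected —
  only the abstention calls are.
* calls use threshold 0.5 with a symmetric ±0.05 abstention band, so only
  confident directions are called; k = 1 reduces exactly to a single
  harmonic pass.

If either direction has fewer than two labels, its calls are suppressed
with a warning — one observation is not evidence enough to extrapolate a
whole direction.

## Abstract mining

Sentences are split on ./!/? followed by whitespace and a capital, with an
abbreviation list (e.g., i.e., et al., fig., …) and single-initial guard.
Aliases match case-insensitively at token boundaries, longest alias first,
so "CAT" never matches inside "indicate". Change words match as word-prefix
stems ("elevat" hits "elevated"/"elevates"). When a sentence carries several
change words, each protein mention pairs with the *nearest* one, so
contrasting clauses ("X was reduced while Y was elevated") yield opposite
directions instead of a cross product.

A protein is labeled when ≥ 2 distinct PMIDs (citations, not sentences)
support one direction and none support the other; conflicted proteins are
excluded and reported. Negation ("not elevated") is not modelled — mined
output is a review queue, mirroring the manual-check step of the original
workflow; the shipped change-word dictionary is a small editable stand-in,
not a reproduction of any published word list.

## Pathway clustering

Cohen's κ is computed per pathway pair from the 2×2 membership contingency
over the union of all member proteins; independence gives κ = 0, identical
sets κ = 1, complementary sets κ < 0. Clustering is average linkage on
1 − κ (negative κ maps above 1). The published analysis cut its dendrogram
at 2.5 on an unstated scale — κ ≤ 1, so that cutoff cannot be a κ
threshold; here the cut height is fully configurable (CLI default 0.9 on
the 1 − κ scale) and the heat-map export orders rows by dendrogram leaves.
Mapping clusters to named functional components is curation, supported via
user-supplied labels, never inferred.

## Synthetic data

One scenario object generates every input deterministically from its seed:

* network: preferential attachment (4 edges/vertex by default), optionally
  two communities joined by a configurable fraction of cross edges
  (default 0.1); seeds drawn degree-weighted, mimicking well-studied
  disease proteins. The power-law exponent of the tail is checked by the
  fitter, not guaranteed by construction.
* ontology: a branching-3, depth-4 is-a tree plus part-of edges to
  shallower layers at rate 0.2; proteins annotated to 3 random leaves.
* labels/corpus: 8 UP labels in one community, 8 DOWN in the other, each
  backed by 2 distinct-PMID abstracts containing one planted
  alias+change-word sentence; plain-text abstracts by default, with a
  PubMed-XML fixture exercising the XML reader.
* pathways: 10 sets in 2 blocks, within-block core overlap 0.8 versus 0.05
  across.

These generators reproduce the statistical *structure* the pipeline assumes
— scale-free degrees, planted label homophily, block-structured pathway
overlap, unambiguous mention sentences. They do not emulate real-data
nuisances: interaction false positives/negatives, annotation bias toward
well-studied proteins, negated or hedged literature statements, or pathway
databases' nested redundancy. Passing tests therefore validate the
algorithms' correctness and power under their stated assumptions, not
end-to-end accuracy on live databases.

## Problem sizes and numerics

Tests and examples run at desk scale: modules of 60–600 proteins, 1000
null replicates, 1000 bootstrap replicates at n = 5000, chosen so the full
suite completes in minutes on one CPU while leaving every statistical
check with adequate resolution. Linear systems are solved densely
(`numpy.linalg.solve`, least-squares fallback on singularity); empirical
and bootstrap p-values are tie-inclusive; all RNG flows through
`numpy.random.default_rng` seeds, and re-running any stage with the same
seed is byte-identical.
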
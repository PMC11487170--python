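# Methods

This note documents the statistical procedures, the synthetic data
model, the default parameters and the numerical choices made where the
design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Non-negative factorization

A TPM matrix X (genes × samples) is decomposed as X ≈ A·P with A, P ≥ 0
by minimising the Frobenius loss.  The fitter runs the standard
multiplicative updates (Lee–Seung for the Frobenius objective, which
makes the error non-increasing per iteration) from a random
non-negative start, with convergence declared when the relative error
change falls below `tol` (default 1e-6) or after `max_iter` (default
2000) iterations.  Several independently seeded restarts are fitted
(default 3) and the lowest-error restart kept, ties broken by restart
index; the winner is refined by a few alternating exact-NNLS passes
(default 3 rounds).  The polish matters qualitatively, not just
numerically: multiplicative updates approach zero only asymptotically,
whereas NNLS reaches exact zeros, which sharpens sample-specific
structure and marker contrasts.  The scale degeneracy is fixed by
rescaling each row of P to unit maximum and absorbing the inverse into
A, which leaves A·P unchanged.

TPM input is used directly, without log transform — the factorization
consumes the same quantity the quantification step emits — and a
`log1p` preprocessing step is deliberately not applied by default.

Determinism: every stochastic choice (restart inits, gene partitions,
permutation nulls, the synthetic generator) derives its generator from
`numpy.random.SeedSequence` seeded by the user-supplied seed plus a
fixed tag, so identical inputs and seeds reproduce outputs bit for bit.

### Consensus mode

`nmf_consensus` partitions the genes into `n_sets` seeded random groups,
factorizes each group at the same k, pools the `n_sets·k` sample-weight
vectors, clusters them into k consensus patterns by average-linkage
agglomeration on 1 − Pearson distance (constant vectors are assigned
maximal distance), averages each cluster, rescales rows to unit maximum
and finally re-solves every gene's amplitudes against the consensus P
by NNLS.  `n_sets = 1` returns the plain fit unchanged.  Cluster order
is fixed by first appearance, keeping the output deterministic.

## Pattern classification and pattern-count selection

For each pattern the sample-weight vector w is summarised by:

* eta² for three groupings — tissue, state, and tissue × state cell —
  each computed as between-group over total sum of squares.  The cell
  grouping is the finest, so its eta² bounds the other two from above.
* dominance = max(w) / Σw (reported; in [0, 1]).
* sibling support = the largest weight among the dominating sample's
  tissue × state group-mates, divided by the top weight.
* Pearson correlation of w with library size, when annotations carry it.

The decision cascade is: **technical** if |depth correlation| ≥ τ_depth
(default 0.8); else **sample-specific** if the dominating sample's group
has ≥ 2 samples, sibling support < τ_dom (default 0.5) and the cell
eta² is below a guard value (default 0.75); else **tissue** / **state**
if exactly that main effect reaches τ_eta (default 0.5);
**tissue_state** if the cell grouping reaches τ_eta; otherwise
**unclassified**.  All statistics are invariant to sample order and to
positive rescaling of w.

Two choices deserve comment.  First, sample specificity is judged by
whether a pattern *separates a sample from its own replicates* (low
sibling support), not by a threshold on max/Σ: in fitted factorizations
a genuinely single-sample pattern still carries a small positive weight
floor on the other samples, which caps max/Σ near 0.3–0.45 for datasets
with ~27 samples, while replicate separation discriminates cleanly.
Second, the eta² guard protects noisy but genuinely cell-specific
patterns (high cell eta², shaky replicate ordering) from the
sample-specific call; genuinely single-sample patterns rarely exceed
cell eta² ≈ 0.5 because one sample can drag only its own cell mean.

`select_pattern_count` returns the largest scanned k at which every
pattern shows tissue and/or state specificity and none is
sample-specific; a pattern with no metadata specificity (unclassified)
also disqualifies its k.  Technical patterns do not disqualify — they
are removed afterwards by `drop_technical_patterns`, without refitting
the remaining patterns.  After dropping, the stored Frobenius error
still refers to the full-k fit unless the training matrix is passed for
recomputation.

### Pattern markers

Each column of A is scaled to unit maximum; gene g is assigned to the
pattern j minimising the Euclidean distance between g's scaled row and
the unit indicator e_j (ties to the lowest pattern index), and genes are
ranked within a pattern by ascending distance.  This is the "all"
regime of the scaled-amplitude marker statistic; the thresholded "cut"
variant is not implemented.  All-zero amplitude rows are reported
separately as unassigned.

## Projection and group tests

Cross-dataset transfer first aligns the source amplitude matrix and the
target expression matrix on one-to-one ortholog pairs (map order is
preserved; pairs missing from either side are dropped and counted).
Orientation is taken from the caller or inferred from which side of the
map the source gene ids match; matching both sides is an error.  Each
target sample's profile y is then regressed on the aligned gene weights
by unconstrained ordinary least squares — no intercept, no
non-negativity — after subtracting each gene's mean across target
samples (`center=True` by default; the weights themselves are never
centered).  Scores therefore take both signs.  Rank deficiency of the
aligned weight matrix aborts with the collinear pattern pair named.

Group comparisons use the two-sided two-sample Student's t-test with
pooled variance (df = n_a + n_b − 2); Welch's correction is available
behind a flag.  Two samples per group are required.  Two degenerate
cases are pinned down: identical constant groups give t = 0, p = 1, and
zero pooled variance with different means gives an infinite t with the
p-value clamped to the smallest positive float so that p stays in
(0, 1].  Raw p-values are reported (no correction across group tests),
with a BH option available downstream of the caller.

## Gene-set enrichment

Genes are ordered by descending pattern weight (ties broken
lexicographically; an optional ortholog map translates identifiers, with
unmapped genes dropped and counted).  The enrichment score of a set is
the maximum of the weighted running sum — a member at rank i adds
w_i^exponent / Σ_members w^exponent, a non-member subtracts
1/(N − N_members) — floored at zero, the positive-only regime
appropriate for non-negative weights; ES ∈ [0, 1], invariant to
rescaling all weights.  The exponent defaults to 1 (classic weighted
scheme).  Because pattern weights carry no sample labels, the null is a
gene-label permutation: `n_perm` (default 1000) random same-size
subsets drawn without replacement, shared across sets of equal size
within a call, with p = (1 + #{null ES ≥ observed}) / (1 + n_perm) —
bounded in [1/(n_perm+1), 1] — and NES = ES / mean(null ES).  BH
adjustment is applied across the sets tested for one pattern.  If every
member weight is zero the hit increments fall back to equal steps.

## Synthetic data model

The generator emulates a two-species, multi-tissue torpor study:
3 tissues × {euthermia, torpor, IBA} × 3 replicates per species by
default, with

    X = (A_true · P_true) ⊙ noise ⊙ module ⊙ depth.

* **Baselines.**  Per-gene baselines are lognormal(3, 0.5) (TPM-like
  medians ~20, spread about one decade — the regime of expressed genes
  after the usual abundance filtering; a much heavier tail would let a
  handful of housekeeping-scale transcripts dominate the Frobenius
  loss).  Ortholog-paired genes share one ancestral baseline draw.
  Baseline expression rides inside the tissue pattern columns of A_true
  (each sample has exactly one tissue), so the planted matrix has rank
  exactly k_true and no phantom "baseline component" appears at
  k_true + 1.
* **Planted programs.**  Default k_true = 6 per species: three shared
  tissue programs, shared torpor and IBA state programs, and one private
  tissue × torpor program per species — a *different* program in each
  species (different cell, own marker genes, absent from the other
  species).  Each program owns a disjoint block of ortholog genes
  (default 50 markers at 2000 genes, 2.5%; scaled runs keep the same
  density) whose baselines are drawn lognormal(3.5, 0.5) and which
  receive amplitude `effect_size` × baseline (default 2).  Sample
  weights are 0/1 condition indicators plus uniform(0, 0.1) jitter.
* **Noise.**  I.i.d. multiplicative lognormal(0, noise_sd) (default
  0.1) keeps values non-negative, matching the TPM-level consumption of
  the pipeline; count-level negative-binomial simulation is out of
  scope.
* **Sample modules.**  Each sample additionally multiplies a random 10%
  subset of sub-top-decile genes by one shared factor of random sign
  and uniform(0, 0.8) log-magnitude.  This term models coherent
  individual-animal variability (each library is a different animal)
  and is what over-factorized fits lock onto as sample-specific
  patterns; with purely i.i.d. noise that phenomenon never materialises.
  The magnitude bound is calibrated so the strongest module in a
  27-sample dataset stays below every planted program's energy (fits at
  k ≤ k_true remain clean) while exceeding the leading i.i.d.-noise
  component (the k_true+1 and k_true+2 slots capture outlier samples).
* **Depth.**  A per-sample lognormal(0, depth_factor_sd) factor
  (default 0.1) scales whole columns; annotation `library_size` is the
  realised column sum, so depth-driven patterns are detectable by
  correlation.  Because planted biology itself moves column sums by a
  few percent, the correlation between column sums and depth factors
  saturates slightly below 1 even at low noise.

Everything is fully determined by the scenario seed.  What passing
tests on these data do *not* show: robustness to count-level
overdispersion, isoform-level structure, partial (non-one-to-one)
orthology, unbalanced designs, or phylogenetically calibrated
divergence between the species — the two species differ only in their
private programs and non-ortholog gene complement.

## Problem sizes used in validation

Repeated-simulation checks run at desk scale, chosen once: 800 genes
per species (20 markers per pattern, preserving the 2.5% default
density) for the pattern-count-selection and marker-recovery studies;
the full 2000-gene default for the transfer power study (200
simulations; the per-run cost is dominated by a single least-squares
solve); 400-gene rankings and n_perm = 500–1000 for the enrichment null
and recovery studies.  Factorization scans use 6 restarts; marker
recovery uses 4.

## Known limitations

* The k-selection rule inherits the qualitative character of visual
  heatmap inspection: its thresholds (τ_dom, τ_eta, the eta² guard,
  τ_depth) are declared defaults, configurable per dataset, not
  universal constants.
* Technical patterns are dropped, not refit; the remaining patterns are
  exactly the fitted ones.
* Projection assumes the aligned weight matrix has full column rank;
  heavily collinear patterns must be merged or dropped upstream.
* The enrichment module reports set-level statistics only (no
  leading-edge gene lists) and uses the simple permutation estimator,
  so p-values are bounded below by 1/(n_perm + 1).
* Cross-species comparison uses one-to-one orthologs only; gene family
  expansions contribute no signal.
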
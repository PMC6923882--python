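# Methods

## Problem

Given a bulk expression matrix (FPKM-scale, genes × samples) over three
tissue groups — healthy normal, normal-adjacent-to-tumor (NAT), and
tumor — the package (i) ranks genes by how differently they are
expressed between groups, (ii) selects a small marker panel by average
rank, (iii) assigns each marker concrete expression-level boundaries
separating the three groups, and (iv) evaluates the panel by
cross-validated tumor-vs-rest classification.

## Kernel MMD scoring

The differential-expression score is the unbiased estimate of the
squared maximum mean discrepancy between the two groups' expression
distributions.  For samples X = {x₁..x_m} and Y = {y₁..y_n} of one
gene and kernel k,

    MMD²_u = 1/(m(m−1)) Σ_{i≠j} k(x_i,x_j) + 1/(n(n−1)) Σ_{i≠j} k(y_i,y_j)
           − 2/(mn) Σ_{i,j} k(x_i,y_j),

a U-statistic whose expectation is exactly MMD²(p, q): it needs no
distributional assumption on the expression values (the point of using
it over a t-test) and can be slightly negative under the null, which we
report as-is rather than clamping — clamping would bias the null mean.
The kernel is Gaussian, k(a,b) = exp(−(a−b)²/2σ²); inputs are
univariate (one gene at a time) so ‖·‖ is the absolute difference.

**Bandwidth.**  σ is resolved per gene by the median heuristic: the
median of the nonzero pairwise absolute differences of the pooled
two-group values.  Zero differences are excluded because FPKM vectors
are frequently tied at zero and a collapsed bandwidth would make every
kernel value degenerate.  A fixed global σ is available
(`KernelConfig(bandwidth_policy="fixed", sigma=...)`) for
reproducibility studies.

**Scale.**  The raw U-statistic is bounded above by 2.  Some two-sample
testing libraries report m·MMD²_u instead; both are exposed
(`scale_mode="raw"|"m_scaled"`).  Group sizes are shared by all genes
within a comparison, so the choice rescales scores without changing any
ranking; the default is raw.

## Baselines, ranking and selection

Two conventional scorers are provided for comparison: the two-sample
t-test (pooled variance by default, Welch behind a flag; two constant
groups yield p = 1 if equal and p = 0 if unequal, documented conventions
instead of NaN) and the fold change |log2(E1/E2)| of group means, with
an optional pseudocount for zero-mean genes (default 0, hard error on a
zero mean, since the definition has none).

Within each comparison genes get fractional ranks (rank 1 strongest;
ties share the mean of the spanned positions so rank sums stay at
G(G+1)/2, keeping average ranks comparable across comparisons).  Two
aggregation presets exist: `tumor_focused` averages the normal-vs-tumor
and NAT-vs-tumor ranks (the clinically relevant contrasts for tumor
detection) and `all_pairs` averages all three.  The top-k genes by
average rank, ties broken by lexicographic id, form the marker panel.

## Expression boundaries by information gain

For a labelled value set D the class entropy is Ent(D) = −Σ p_k log2 p_k
(0·log 0 := 0) and a split point x has gain
Gain(D,x) = Ent(D) − Σ_v |Dᵛ|/|D|·Ent(Dᵛ) over the two induced subsets
{e ≤ x} and {e > x}.  Candidate splits are the midpoints between
consecutive *distinct* sorted values (duplicates collapse, so no split
ever equals a data value); the boundary is the candidate with maximal
gain, the exhaustive scan being O(#distinct · n).  Ties go to the
smallest threshold for determinism.  On cleanly separated classes this
recovers the midpoint of the gap, so the traditional gap-edge rule is a
special case.

Three groups are handled as two adjacent binary problems: groups are
ordered by ascending median expression of the gene (the data decide the
orientation — marker panels contain both tumor-low and tumor-high
genes), then low-vs-middle gives threshold t1 and middle-vs-high gives
t2, and the classes occupy e ≤ t1 / t1 < e < t2 / e ≥ t2.  A joint
exhaustive optimization of both thresholds would also be possible but
is not the default; when noise makes t1 ≥ t2 the result is flagged
non-monotone rather than silently reordered.

## Panel evaluation

Stratified 10-fold cross-validation of tumor-vs-rest classification
(normal and NAT pooled as negatives) with a seeded 100-tree random
forest.  Metrics per fold and as fold means: recall, F1, accuracy and
MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)).  Pooled-count
metrics over the summed confusion table are reported alongside, since
fold means and pooled counts differ slightly under imbalance; the
report labels both.  Zero denominators yield 0 with a degeneracy flag.
Note that genes are selected on the full data before CV, as is usual in
marker screening; the metrics therefore measure panel separability, not
unbiased generalization.

## Synthetic cohorts

`simulate_expression` draws a three-group cohort with known truth.
Null genes share one distribution across groups.  DE genes get
group-specific locations in a configurable ordering; the shift between
adjacent groups is `effect_sizes × within_sd`.  The default law is
lognormal (log-values normal, sd `within_sd`, per-gene baseline
log-location ~ N(1, 1)), giving the right-skewed strictly positive
values characteristic of FPKM; effects act on the log scale and the
true thresholds recorded in the truth object are the geometric
midpoints between adjacent group medians.  A zero-truncated normal law
is available for tests needing exact raw-scale control of separations.
A single seed drives everything through per-gene `SeedSequence`
substreams, so extending the gene list leaves earlier genes untouched.

`default_paper_shape()` fixes the desk-scale study design: 500 genes,
5% DE at a 2-within-sd adjacent shift, groups of 75 normal / 12 NAT /
108 tumor — a fifth of a realistic lung cohort's size, keeping its
signature imbalance (NAT much rarest).  These sizes keep every test and
the reproduction script comfortably fast while leaving the group-size
ratios, and hence the stratification behaviour, realistic.

What the simulator does *not* model: library-size or batch effects,
count noise, correlated genes, outlier samples.  Passing tests
therefore demonstrate the correctness and power of the estimators under
clean location-shift alternatives, not performance on real cohorts.

## Numerical and design choices

- Left child of a split is {e ≤ x}; immaterial numerically (splits
  never hit data values) but fixed for serialization.
- MMD inputs require ≥ 2 samples per group (the m(m−1) denominators);
  violations raise with the gene and group named.
- Raw FPKM values are scored by default; `log_transform`
  (log2(v+offset)) is opt-in, since per-gene median-heuristic MMD and
  rank aggregation are already scale-adaptive.
- Pipeline artifacts are deterministic functions of the config: reruns
  with an identical config are byte-identical, and the manifest echoes
  the full configuration.

## Limitations

- Boundary quality is only as good as the panel: the search always
  returns *some* threshold, even for genes with heavily overlapping
  groups; the reported gain (and the non-monotone flag) must be
  consulted.
- No multiple-testing control is applied to the t-test baseline —
  scores are used only for ranking.
- The MMD score's absolute magnitude depends on the bandwidth policy
  and scale mode; only within-comparison rankings should be compared
  across runs with different kernel settings.
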
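# Methods

## Scoring model

A response is a short free text produced to a prompt. Scoring embeds it in a
fixed word-vector space (any whitespace-delimited GloVe-format text file):
tokens are lower-cased, split on runs of non-alphanumeric characters
(hyphens and apostrophes separate; underscores are word-internal so that
identifier-style vocabularies survive tokenization), stoplisted against a
small bundled English function-word list (overridable by file), and looked up
case-insensitively with a raw-form fallback. The response vector is the
weighted arithmetic mean Σ w(t)·v(t) / Σ w(t) over surviving in-vocabulary
tokens. Because the mean is normalized, rescaling all weights by a constant
changes nothing, and the uniform default table makes weighting a no-op.
Out-of-vocabulary tokens are dropped and counted, never imputed.

A response with no surviving tokens has an **undefined** vector — an explicit
state, never a zero vector (a zero vector has no direction and would fabricate
extreme cosine distances). Undefined vectors propagate: any pair or
prompt-distance touching one is skipped, not zero-filled. Fluency still counts
such responses, so they inflate the mean's divisor; the drop counts are logged
so this is auditable.

Flexibility pairs are strictly consecutive (1–2, 2–3, …, n−1–n), preserving
generation order; n responses yield n−1 pairs. The pair score is the cosine
distance 1 − cos θ, clipped to [0, 2] against floating-point overshoot; the
angle in degrees is exposed alongside for interpretability, and an
`angle-degrees` metric option scores on that scale instead.

### Aggregation and the fluency confound

Sum scores grow mechanically with the number of responses. The mean divides
the pair-distance sum by **fluency n** — the convention of the scoring
procedure this package implements — rather than by the pair count n−1.
Dividing by n deflates the mean by a factor (n−1)/n, so the expectation of
the mean is not exactly fluency-free; the `mean_divisor="pairs"` option gives
the exactly stable n−1 variant, and the simulation tests exercise both (the
fluency-divisor drift is small relative to the sum's growth). Appending a
response identical to the last one adds a zero-distance pair: the sum is
unchanged and the mean strictly decreases — the confound-correction property,
asserted directly in the tests.

Originality is the distance from the prompt vector to each response, with the
same sum/mean/max aggregation (mean always divides by fluency). Battery
summaries report per-participant mean and maximum fluency across items.
Undefined aggregates are emitted as empty cells, never zeros, since a zero is
meaningful (identical adjacent ideas).

## Psychometrics

Correlations use scipy (average ranks for ties); confidence intervals use the
Fisher transform with standard error 1/√(n−3). The two-correlation comparison
is the independent-samples z = (atanh r₂ − atanh r₁)/√(1/(n₁−3) + 1/(n₂−3));
Steiger's dependent-sample variant is provided but not the default. The
Pearson point estimate is defined from 3 complete pairs, its Fisher interval
from 4 (below that the interval is NaN). Missing data are handled
complete-case per analysis, with the retained n reported.

Reliability: Cronbach's α = k/(k−1)(1 − Σσᵢ²/σ_total²) (also available
directly from a covariance matrix, where the compound-symmetry closed form
kρ̄/(1+(k−1)ρ̄) is checked exactly); ω = (Σλ)²/((Σλ)² + Σθ);
H = 1/(1 + 1/Σ(λ²/(1−λ²))). Under homogeneous loadings with θ = 1 − λ²,
ω = H exactly — a frozen identity test.

### CFA

Plain maximum likelihood: minimize F = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p
over free loadings (one factor per variable, no cross-loadings), free factor
correlations (box-bounded in (−0.999, 0.999)), residual variances (≥ 1e−6),
and the residual covariances the model spec allows (only between variables on
different factors). Identification fixes every factor variance to 1.
Optimization is L-BFGS-B with analytic gradients via
∂F = tr(Σ⁻¹(Σ−S)Σ⁻¹ ∂Σ); start values are 0.5 for loadings and residuals, 0
for covariances; convergence tolerance 1e−10 on the discrepancy, with the
convergence flag reported honestly (no fallback). χ² = (n−1)·F_min and
df = p(p+1)/2 − free parameters. The reported solution is standardized by the
implied standard deviations; `standardize=True` fits on the correlation
matrix, under which χ² is invariant to variable order and affine rescaling
(tested). Robust (Satorra–Bentler) corrections are out of scope, so published
chi-squares from robust estimators are comparison points, not exact targets —
except RMSEA arithmetic, which is exact given printed χ²/df/n.

Fit indices: RMSEA = √(max(χ²−df, 0)/(df(n−1))) (the n−1 convention
reproduces published values from printed chi-squares), with a 90% CI from the
noncentral-χ² noncentrality search; CFI and TLI against the closed-form
independence baseline (F_b = −ln|R|, so χ²_b = −(n−1)ln|R|, df_b = p(p−1)/2);
SRMR as the RMS of correlation-scale residuals including the diagonal. When
χ² ≤ df (plus a 1e−8 slack for optimizer noise at a perfect fit) RMSEA is 0
and CFI is 1; a saturated model reports RMSEA 0 by convention with a note.

## Synthetic data

The ideation generator emulates the structure of timed verbal DT data: per
participant × item, a fluency drawn uniformly (default 3–12, matching the
single-digit per-item counts typical of 2–5-minute tasks), then a random walk
over the planted clusters of a toy embedding space — stay in-cluster with
probability 1 − switch_probability, else jump to a uniformly chosen *other*
cluster, so the realized switch rate equals the parameter exactly in
expectation. Default geometry: 5 clusters × 20 tokens in 50 dimensions with
spread 0.2; cluster centroids are orthonormal whenever the dimension allows,
guaranteeing within-cluster cosine similarity exceeds between-cluster
similarity. Responses are single toy tokens (so cluster membership is exactly
known), with a two-token option to exercise multiword averaging. All
randomness flows from one seed through named sub-streams (fluency, walk,
token, noise), so adding a stream never shifts the others.

What this does **not** emulate: real responses are multiword free text with
out-of-vocabulary words, typos, and graded rather than planted category
structure, and real fluency correlates with ability. Passing tests therefore
demonstrate the arithmetic and ordering properties of the scores, not their
validity on human data — that is what the correlation/reliability/CFA toolkit
is for.

The factor-model generator draws multivariate normal data from
Σ = ΛΦΛᵀ + Θ with unit indicator variances (θᵢᵢ = 1 − communality) and
optional planted cross-factor residual covariances; positive definiteness is
checked before the Cholesky draw.

## Problem sizes and numerical choices

Simulation-backed checks use sizes at which Monte-Carlo error is well inside
the asserted tolerances while the whole suite runs in seconds: 100–200
participants for flexibility monotonicity, n = 2000 for reliability recovery
(±0.03), n = 5000 for one-factor loading recovery (±0.05), n = 2000 for the
30-indicator three-factor recovery (factor correlations ±0.1), n = 20000 for
covariance convergence (max element error < 0.05). Distance arithmetic is
checked against a brute-force dot-product oracle at 1e−12; closed-form
reliability identities at 1e−10.

## Limitations

- Scoring quality is bounded by the supplied embedding space; the package
  treats it as user input and records its provenance rather than fixing a
  corpus. Published worked-example angles (44°/86°) are reproducible only
  under the original service's pretrained space, hence the optional
  integration test.
- Flexibility from consecutive pairs cannot detect a return to an earlier
  category (no clustering over the whole response set), which can overstate
  flexibility; category-level methods are out of scope.
- The CFA is plain ML: with strongly non-normal indicators its chi-square is
  inflated relative to robust estimators.
- No multiple-testing correction is applied; confidence intervals are
  reported instead.
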
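# semflex

Automated scoring of **flexibility** in verbal divergent-thinking (DT) tasks,
plus the psychometric toolkit used to validate such scores.

In DT tasks (e.g. the Alternate Uses Task: "list unusual uses for a bottle"),
*fluency* counts the ideas a participant produces, *originality* measures how
far each idea is from the prompt, and *flexibility* measures shifting between
semantic categories during ideation. Hand-scoring flexibility requires trained
raters and arbitrary category systems. `semflex` instead embeds each free-text
response in a word-vector space and scores flexibility as the **semantic
distance between consecutive responses**: responses 1–2 form the first pair,
2–3 the second, and so on, preserving generation order.

## The scores

Each response is represented as the weighted mean of its word vectors after
stoplisting, v(r) = Σᵗ w(t)·v(t) / Σᵗ w(t). For consecutive responses
r₁, …, rₙ to one prompt, the pair distances are

    dᵢ = 1 − cos(v(rᵢ), v(rᵢ₊₁)),   i = 1 … n−1,

and the per-item scores are

- **fluency** = n (count of responses),
- **flex_sum** = Σ dᵢ, **flex_max** = max dᵢ, **flex_mean** = Σ dᵢ / n
  (division by fluency corrects the mechanical growth of the sum with n; a
  pair-count divisor n−1 is available via `mean_divisor="pairs"`),
- **originality**: the same sum/mean/max over prompt→response distances.

The validation half of the package implements Spearman/Pearson correlations
with Fisher r-to-z confidence intervals, the independent-samples Fisher z
comparison of two correlations, Cronbach's α, McDonald's ω, Hancock's
coefficient H, and maximum-likelihood confirmatory factor analysis (unit
factor variances, optional cross-factor residual covariances) with RMSEA
(plus noncentrality CI), CFI, TLI and SRMR.

## Worked example

Three responses whose vectors are planted at consecutive cosine distances
0.2 and 0.4:

```python
import math, numpy as np
from semflex import EmbeddingModel, ResponseRecord, score_item

t2 = math.acos(0.8); t3 = t2 + math.acos(0.6)
model = EmbeddingModel(
    vectors={t: np.array([math.cos(a), math.sin(a)])
             for t, a in [("r1", 0.0), ("r2", t2), ("r3", t3)]},
    dimension=2, source_tag="planted",
)
recs = [ResponseRecord("p1", "r1", i + 1, t) for i, t in enumerate(["r1", "r2", "r3"])]
s = score_item(recs, model, stoplist=())
print(s.fluency, round(s.flex_sum, 6), round(s.flex_mean, 6), round(s.flex_max, 6))
```

prints

```
3 0.6 0.2 0.4
```

— fluency 3; the pair distances 0.2 + 0.4 sum to 0.6; the mean divides the
sum by fluency (0.6 / 3 = 0.2); the max is the largest single jump (0.4).

The same pipeline runs from the shell on CSV response tables
(`semflex score --toy-config ... --responses ... --out-item ... --out-battery ...`),
and `semflex simulate` / `semflex psych` generate seeded fixture data and run
reliability/CFA/correlation reports on score matrices.

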
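# Methods

This document specifies the statistical models, the synthetic-data
generators, the numerical choices, and the known limitations of the
`stagemap` package. Notation: `G` genes, `S` samples, `k` ordered stages,
`N` genes in the reference universe, `m` genes in a signature, `K`
permutations.

## 1. Staged cohort model and signature derivation

### Generator

`simulate_expression_cohort` draws a `G × S` log2-scale expression matrix.
Defaults: `G = 1000`, five stages of 20 samples each
(`normal → low → medium → high → AML`-style ordered labels), 50 planted
increasing and 50 planted decreasing genes, per-stage step `Δ = 1.0`,
residual noise `σ = 0.25`, baseline level `8.0`.

- Each gene gets a baseline `b_g ~ N(8, 1)`.
- A planted increasing gene adds `+Δ·j` at stage index `j = 0 … k−1`;
  decreasing genes add `−Δ·j`. Null genes add nothing.
- i.i.d. `N(0, σ²)` noise is added to every cell. `σ = 0` is allowed and
  yields exact stage means, used by the exact-recovery checks.
- Planted positions are a seeded random subset of the gene index, so planted
  and null genes are interleaved.

This emulates the *shape* of a staged disease cohort (monotone expression
drift across ordered severity groups) and nothing else: no gene–gene
correlation, no batch structure, no heteroscedasticity, equal group sizes by
default (unequal sizes are supported by the analysis code).

### Analysis

1. **Per-gene ANOVA.** One-way fixed-effects ANOVA across the `k` groups,
   vectorized over genes: `F = (SSB/(k−1)) / (SSW/(S−k))`, p from the
   `F(k−1, S−k)` survival function. Degenerate cases follow an explicit
   policy: if both sums of squares are zero (a constant gene) then `F = 0,
   p = 1`; if only `SSW = 0` then `F = ∞, p = 0`, which is what makes
   noise-free recovery exact. "Zero" is an absolute floor scaled to the data:
   a sum of squares below `n·(64·ε·(1 + |grand mean|))²` (ε = double-precision
   machine epsilon) is treated as 0, so catastrophic cancellation in the
   subtraction-based sums cannot manufacture tiny positive `SSW`.
2. **FDR.** Benjamini–Hochberg step-up q-values via
   `statsmodels.stats.multitest.multipletests(method="fdr_bh")`. The test
   suite checks it against an independently hand-written step-up
   implementation to 1e-12.
3. **Monotone filter.** Stage means are computed per gene; the `k−1`
   adjacent-stage differences (`fc1 … fc4` for five stages) must all be
   strictly positive (increasing genes) or all strictly negative. Combined
   with `q ≤ 0.05`, this is the gene-selection rule. Survivors are ordered by
   ascending p, then descending absolute total span (sum of the adjacent fold
   changes), then gene id — a total, reproducible order.
4. **Signatures.** At depth `d`, the top `d` increasing genes receive signed
   ranks `+d, +d−1, …, +1` (strongest first) and the top `d` decreasing
   genes `−d, …, −1`. Default depths `10, 20, 30, 40, 50` give nested
   signatures of length 20–100. A depth that exceeds the available genes in
   either direction is skipped with a logged warning rather than padded.

## 2. Reference profiles and connectivity scoring

### Reference model

A reference instance (one perturbagen treatment) is a complete signed-rank
profile over the universe: ranks are a signed permutation of `1 … N`, with
`±N` the largest absolute effect. `build_reference_profile` converts a vector
of per-gene statistics into this form by sorting on (descending absolute
value, then gene id) — the gene-id tie-break makes the ranking total — with
the sign taken from the statistic (exact zeros rank last with positive sign).

`simulate_refset` draws latent per-gene effects i.i.d. `N(0, 1)` per
instance (default 100 instances over a 1000-gene universe) and converts them
to profiles. A *planted inverter* for a signature with ranks `q_i` adds
`−α·sign(q_i)` (default `α = 3`) to the latent effect of each signature gene
before ranking; a *planted mimic* adds `+α·sign(q_i)`. Planted instances
therefore differ from nulls only through the signature genes, which is the
signal the mapper is supposed to detect. The generator emulates rank
structure only; it does not model compound replicate correlation, batch, or
cell-line effects (a `cell_line` label is carried through but is purely
descriptive).

### Score

For signature `(g_i, q_i)` and profile `r(·)`:

- raw score `Σ_i q_i · r(g_i)`;
- `max_score = Σ_k |q|_(k) · (N − k + 1)` with `|q|` sorted descending — the
  largest raw score any profile could give this signature;
- normalized score `c = raw / max_score ∈ [−1, 1]`.

Both `q_i` and `r` are integers, and all products are far below 2⁵³, so the
float64 arithmetic is exact and ties in the permutation null are counted
exactly.

### Permutation null and threshold

The null randomizes *gene identity*: a random signature keeps the observed
signed-rank multiset `{q_i}` (values in a random order) on `m` distinct genes
drawn uniformly from the universe. `K = 10 000` such signatures are drawn per
observed signature and shared across all instances of the reference set —
the null distribution depends only on the rank multiset and the universe, not
on the instance — and the two-sided p-value is
`(#{|c_rand| ≥ |c_obs|} + 1)/(K + 1)`, never zero.

The significance cutoff admits a configured number of expected false
positives per analysis (default 1): `p_cut = fpr / N_comparisons`. For 3730
comparisons this is `1/3730 ≈ 0.00027` (`−log10 = 3.572`). A perturbagen is
a **hit** when it has significant connections of the required sign for at
least `min_signatures = 2` distinct signatures; repurposing candidates use
the negative direction (signature inversion).

Implementation notes:

- The engine processes random signatures in chunks of 2048. Distinct gene
  sampling uses an argpartition of i.i.d. uniform keys per row (equivalent to
  sampling without replacement); rank orders use `rng.permuted`. Scores for a
  chunk are one dense scatter plus a single matrix product `Q Rᵀ` against all
  instances, so one shared draw prices every instance.
- Child seeds: each signature's generator is
  `SeedSequence(master, spawn_key=(crc32(signature_id),))`, so results are
  independent of the order in which signatures are scored, and re-running a
  single signature reproduces its p-values exactly.
- `connect_all` output is sorted by (p, signature id, instance id) with a
  stable sort — byte-reproducible for a fixed master seed.

## 3. Dose response, median effect, and combination index

### Generator

`simulate_dose_response` produces plate-reader-style rows
(drug, dose, replicate, RLU). Defaults: `Dm = 2.0` (dose units), slope
`m = 1.5`, doses `0.25–8` in doublings plus dose-0 vehicle wells, 3
replicates, multiplicative noise with coefficient of variation 5% around a
base signal of 10 000 RLU. True viability is `1 − fa(D)` with
`fa(D) = (D/Dm)^m / (1 + (D/Dm)^m)`.

`simulate_combination_grid` builds a 5×5 dose grid for two drugs. Boundary
rows (one dose zero) follow each single agent's exact median-effect curve.
An interior point at doses `(d1, d2)` gets the fraction affected `fa` that
solves `d1/Dx1(fa) + d2/Dx2(fa) = interaction` (found by `brentq`), so the
downstream exclusive combination index equals `interaction` identically:
`interaction = 1` is Loewe additivity, `< 1` synergy, `> 1` antagonism. The
generator emulates Loewe-consistent interaction surfaces only — not
receptor-level mechanisms, reader saturation, or edge effects.

### Analysis

1. **Normalization.** Per condition, viability% `= 100 · mean(RLU) /
   mean(vehicle RLU)`; `fa = 1 − viability/100`. Conditions with `fa ≤ 0` or
   `fa ≥ 1` are flagged non-informative (the linearization is undefined
   there) and excluded from fits, with the count reported.
2. **Median-effect fit.** Ordinary least squares of `log10(fa/(1−fa))` on
   `log10 D` (`numpy.polyfit`): slope is `m`, `Dm = 10^(−intercept/slope)`.
   Fewer than two informative distinct doses raises `FitError`; a
   non-positive slope yields a flagged fit with `Dm = NaN` rather than a
   nonsensical potency.
3. **Combination index.** `Dx(fa) = Dm · (fa/(1−fa))^(1/m)`;
   `CI = d1/Dx1 + d2/Dx2` (mutually exclusive model; the nonexclusive option
   adds the cross term `(d1·d2)/(Dx1·Dx2)`). Classification uses a ±0.1 band
   around 1. Interior points whose observed `fa` is non-informative get
   `CI = NaN` and class "undefined".

## 4. Pipeline orchestration

`run_pipeline` executes the stages
`cohort → derive → refset → connect → hits → combo → synergy` from a flat
TOML configuration (`RunConfig`); each stage can be toggled, and disabled
stages fall back to reading their inputs from the output directory. Stage
seeds are derived from the single master seed and kept below 2³¹. Every
artifact (TSVs, signature files, the reference-set directory) is listed in
`manifest.json` with its SHA-256 checksum; identical configurations produce
identical checksums. Unknown configuration keys raise `ConfigurationError`
naming the key; a stage failure raises `RuntimeError` naming the stage.

## 5. Default problem sizes

All problem sizes in this package — 1000 genes, 5 stages × 20 samples,
50+50 planted genes, 100 reference instances, `K = 10 000`, depths 10–50 —
are package defaults chosen so that the full pipeline and the acceptance
checks run in seconds to minutes on one CPU while leaving the planted signal
comfortably detectable (a planted inverter at `α = 3` scores ≈ −0.95 with
`p = 1/(K+1)` in all five signatures at these sizes). Every size is a
parameter; nothing in the code depends on these particular values.

## 6. Limitations

- Generators are deliberately minimal: independent Gaussian noise, no
  gene–gene correlation, no batch/plate effects, no missing data. They
  validate the *analysis machinery*, not biological realism.
- The ANOVA is fixed-effects with a common variance assumption; no
  trend-specific test (e.g. Jonckheere–Terpstra) is offered — monotonicity is
  enforced as a strict post-hoc filter on stage means, so weak monotone genes
  whose sample means wiggle are dropped (at the default noise level this
  costs nothing; at high noise the filter is conservative).
- Permutation p-values are Monte-Carlo estimates with resolution `1/(K+1)`;
  at the default threshold `1/N_comparisons`, `K` must comfortably exceed
  `N_comparisons` for the call to be meaningful (the defaults satisfy this
  hundredfold).
- The nested signatures are strongly correlated by construction, so the
  `≥ 2 signatures` hit rule is a robustness heuristic, not an independent
  replication; borderline null compounds that clear the threshold once tend
  to clear it for adjacent depths too.
- The median-effect fit is the classical linearization, which weights
  extreme `fa` values heavily; it reproduces the standard method rather than
  a statistically optimal nonlinear fit, and fits with fewer than ~3
  informative doses or `r² < 0.9` are flagged rather than rejected.
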
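# Methods

## Model and procedure

`wsea` tests whether a gene set is enriched for expression change in a
two-class (case/control) experiment. The pipeline is

1. quantile-normalize the linear-scale intensity matrix,
2. per gene: fold change `FC = mean(case) / mean(control)` and a
   two-tailed pooled-variance Student's t-test p-value, with a
   significance call at `alpha` (default 0.01),
3. optionally collapse probe-level statistics to genes (mean fold
   change, minimum p-value; probes without a gene mapping are dropped
   and counted),
4. one of four enrichment tests per gene set,
5. Benjamini–Hochberg FDR (reported, never used for filtering) and a
   deterministic rank.

### The four tests

Let `N` be the number of genes measured, `m` the number significant at
`alpha`, `n` the number of set members measured, and `k` context-dependent.

- **hypergeometric** — `k` = significant member count; p = strict tail
  `P(X > k)` of Hypergeometric(N, m, n). Note the strict inequality:
  the observed count is excluded, which makes the test slightly
  anti-conservative relative to the conventional `P(X ≥ k)`; we keep
  the strict form deliberately as the package's defining convention.
- **chi2** — the 2×2 table with *overlapping* columns
  (genes-on-array, significant-genes): `n11 = n, n12 = k, n21 = N − n,
  n22 = m − k`, uncorrected statistic, 1 df upper tail. Because the
  columns overlap (significant genes are also genes on the array), this
  is *not* the classical independence table; its statistic is deflated
  by roughly `(1 − m/N)` relative to the classical one and is therefore
  only χ²₁-calibrated when `m ≪ N`. This is a property of the method,
  not a bug; see "Calibration" below.
- **weighted_hypergeometric** — gene scores `g_i = |log2 FC_i|^a` are
  rounded half-away-from-zero; per set, `k = Σ round(g_i)` and
  `Q = round(max g_i)`. The pseudo population has `N·Q` gene copies,
  `S = Σ_array round(g_i)` of them significant (capped at the population
  size, with a logged flag if the cap binds), and the set draws `n·Q`
  copies; p = `P(X > k)`. A set whose largest score rounds to 0 cannot
  form a pseudo pathway and is reported degenerate with p = 1.
- **weighted_chi2** — no discretization: the significant-genes column
  of the 2×2 table is replaced by the unrounded `k` and the array total
  `S`, i.e. `n11 = n, n12 = k, n21 = N − n, n22 = S − k`. Using `S − k`
  (not `S`) in the not-in-pathway cell preserves the table's
  row-exclusive semantics; a flag (`exclusive_not_in_pathway=False`)
  exposes the alternative reading for sensitivity analysis.

The pseudo-population arithmetic is pinned by an exact reduction: with
per-gene scores replaced by the 0/1 significance indicator, the weighted
hypergeometric p-values coincide with the classical ones to 1e-12 (the
reduction cannot hold for a set with no significant member, which is
degenerate by the Q = 0 rule while the classical test still returns
`P(X > 0)`; the property suite avoids that corner by construction).

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `a` (power) | 1.0 | exponent on `|log2 FC|`; larger values concentrate weight on extreme genes. `a = 0` is an edge configuration scoring every changed gene 1 (with `0^0 := 0` so fold-change-1 genes never contribute). |
| `alpha` | 0.01 | gene-level significance threshold; enters the unweighted tests only. |
| `top_k` | 10 | reporting cutoff for ranked lists and the cross-dataset recurrence analysis. |
| fold-change orientation | case/control | the weighted tests use `|log2 FC|`, so orientation cannot change them (tested); it flips the sign of reported log fold changes only. |

Ranking is p ascending with ties broken by larger pathway score, then
set identifier — output files are byte-reproducible.

## Synthetic data: what it emulates and what it does not

`simulate_dataset` draws log-normal intensities: per-gene baseline
log2 level ~ U(5, 10), within-group normal noise of sd 0.5 (log2 scale),
random gene sets, and planted class shifts on selected sets. Defaults:
1000 genes, 5 samples per class, 20 pathways of 10–30 genes, planted
shift magnitude 2.0 log2 units. Effect modes:

- `significant-shift`: shift at background noise — members are both
  high-FC and individually significant;
- `high-FC-nonsignificant`: the same shift with within-group sd 2.5,
  chosen so the 5v5 t-test has noncentrality ≈ 1.3 against a 1%-level
  critical value of ≈ 3.36 (8 df) — large fold change, few significant
  calls. This is the regime that motivates weighting;
- `bidirectional`: half the members up, half down — net pathway
  expression is flat but every member has high `|log2 FC|`.

The generator does **not** emulate probe-level noise, background
correction, array-specific artifacts, correlated genes, or overlapping
pathway structure. A green test on synthetic data therefore establishes
the statistics' internal correctness and the qualitative
weighted-vs-unweighted contrast, not performance on real microarray
noise or on correlated gene sets.

## Calibration and its limits

Both null-distribution claims behind the tests are asymptotic:

- the strict-tail hypergeometric p-value is discrete; for a small set
  the null p-value distribution has atoms of mass `P(X = k)` and is far
  from uniform (and anti-conservative, since the strict tail excludes
  the observed count);
- the overlapping-column chi-squared table is χ²₁ only when `m ≪ N`.

The calibration suite therefore runs the null where both hold: 20000
genes, set sizes 4000–6000 (sd of the member count ≈ 13, so the discrete
support is fine), enrichment alpha 0.1, 1000 set tests across 4 seeds;
a Kolmogorov–Smirnov test against Uniform(0,1) is required to exceed
p = 0.01 for both unweighted methods. In realistic small-set regimes the
p-values are *not* uniform; ranks (the package's primary reporting
device) are unaffected by the common distortion within a dataset, which
is why reporting is rank-based with FDR included only for completeness.

## Numerical choices

- Rounding of gene scores: half away from zero (`floor(x + 0.5)` on the
  non-negative scores), not banker's rounding.
- Hypergeometric tails via `scipy.stats.hypergeom.sf` (log-space stable
  for large pseudo populations); chi-squared tails via
  `scipy.stats.chi2.sf`; BH step-up via statsmodels.
- Quantile normalization: reference = row means of column-sorted values;
  ties within a column receive the mean of the reference values their
  ranks span. Idempotent (exactly, for tie-free columns).
- t-test degeneracies: both groups constant and equal → p = 1; constant
  but different → p = 0; zero control mean → error (fold change
  undefined).
- Set members absent from the array are excluded from `n` and all
  scores; a set with empty intersection is "untestable" (p = 1, flagged).
- `S_discrete` can exceed the pseudo population when many scores round
  up; it is capped with a `successes_capped` flag.

## Design choices made where the design was open

- Pooled-variance (not Welch) t-test, matching the classical Student
  test; fixtures use equal group sizes where this matters least.
- Per-set `Q` (the maximum member score), not a global maximum.
- Probes mapping to multiple genes are rejected outright rather than
  duplicated or arbitrated.
- The cross-dataset analysis exposes both the plain top-10 rule and a
  p-cutoff-then-top-10 variant (`p_cutoff`), since either convention is
  defensible; neither is hard-wired.

## Known limitations

- Pathway topology is ignored; a gene's effect cannot cancel against a
  downstream partner's.
- p-values for small sets are discrete and anti-conservative (strict
  tail); interpret ranks, not absolute p-values, and treat FDR values
  as advisory.
- The weighted chi-squared table inherits the overlapping-column
  construction; its absolute p-values are conservative when scores are
  a large fraction of the array total.
- No moderated variance estimation; with very few samples the t-test is
  noisy and the high-FC regime detection correspondingly seed-dependent.
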
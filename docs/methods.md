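# Methods

## The model

`netdriver` infers the *regulatory activity* of network drivers —
transcription factors (TF), signalling proteins (SIG) and miRNAs — from
the expression of their target genes (their *regulon*) rather than from
their own transcript abundance. For driver *i* with regulon
*T(i)* and per-feature standardized log2 expression *E(j, n)* of target
*j* in sample *n*, the activity score is

```
AS(i, n) = ( Σ_{j ∈ T(i)} sign(i,j) · MI(i,j) · E(j, n) ) / |T(i)|
```

* `MI(i,j)` is the mutual information between the driver's and the
  target's expression profiles (nats, always ≥ 0);
* `sign(i,j)` is the regulatory sign of the edge: −1 for all miRNA
  edges (miRNAs repress their targets in mammals), the curated sign for
  TF/SIG edges, and the sign of the edge correlation when no curated
  sign is given;
* the sum is normalized by the regulon size, so duplicating a regulon
  leaves the score unchanged and scores are comparable across drivers.

The sign convention makes the score read like an activity: when a
repressor's targets drop uniformly, its score *rises*. A miRNA whose
activity increases after a knockdown therefore shows a positive
activity difference even if its own expression never moves — the
"hidden driver" situation this package exists to detect.

### Why activity instead of expression

A hub-TF knockdown reshapes the regulatory state of the cell in ways
that transcript abundance does not capture: a miRNA can gain or lose
repressive potency through target availability, RISC loading or UTR
remodeling while its own level stays flat. Testing the *regulon* pools
evidence over many targets, which both detects such drivers and gains
power roughly with the regulon size.

## Pipeline stages and the choices behind them

1. **Depth normalization** (per assay): `value = log2((count + 1) ·
   meanDepth / depth(sample))`, with depth = column sum of raw counts.
   Normalization is applied per assay *before* the mRNA and miRNA
   matrices are merged; a joint scaling factor would be dominated by
   the mRNA library depth and distort the miRNA features.
2. **Merge**: row-concatenation over shared sample labels (cell line ×
   condition × replicate). Feature namespaces must be disjoint.
3. **Low-expression filter**: a feature is dropped iff it sits at or
   below the 5th percentile of its sample (linear-interpolation
   percentile, computed per sample over all features) in ≥ 90% of
   samples. Thresholds are computed once on the input matrix; passing
   them back in makes the filter idempotent.
4. **Batch adjustment**: parametric empirical-Bayes location/scale
   adjustment (ComBat; batch = cell line) with the knockdown/control
   condition preserved in the standardization design. The
   implementation delegates to `scanpy.pp.combat`; the preserved
   condition is passed as a numeric 0/1 covariate because a categorical
   covariate makes the design matrix collinear with the batch one-hot
   block. A `center` mode (per-feature, per-batch centering of
   condition-residuals) is available as a transparent fallback; it is
   exact in balanced designs, where it preserves every feature's global
   mean to machine precision — the EB mode only does so approximately,
   since shrunken location estimates do not cancel exactly.
5. **Edge scoring**: Spearman correlation per edge over the **four
   (cell line × condition) group means** of the merged matrix, because
   the mRNA and miRNA profiles are not sample-paired; a
   `paired_correlations` switch uses the 16 per-sample columns instead.
   Scoring (and MI weighting) deliberately uses the normalized,
   filtered matrix *before* batch adjustment: between-cell-line
   covariation is precisely the biological signal that identifies
   functional edges, and removing it would leave the 4-point
   correlations dominated by the condition contrast that the
   differential test later consumes — an avoidable double-dipping that
   measurably inflates the null differential-activity rate.
6. **miRNA edge pruning**: miRNA→target edges with correlation ≥ 0 (or
   unscorable) are removed; zero is not negative, so rho = 0 edges go.
   TF/SIG edges are kept regardless of correlation sign (their curated
   sign takes precedence; see Open choices below).
7. **MI weighting**: Gaussian-copula estimator,
   `r = 2·sin(π·ρ_s/6)`, `MI = −½·ln(1 − min(r², 1 − 1e−6))`. It is
   deterministic, binless, monotone-invariant and exact for Gaussian
   margins; the clamp keeps perfectly monotone pairs finite
   (≈ 6.9078 nats). An equal-width binned plug-in estimator is
   available behind `mi_estimator="binned"` for sensitivity checks.
8. **Differential tests**: per-feature OLS of the (expression or
   activity) profile on condition, with empirical-Bayes variance
   shrinkage (moderated t). The prior (d0, s0²) is moment-matched on
   log variances via digamma/trigamma identities; the trigamma inverse
   is solved by damped Newton iteration. `d0 = 0` recovers the
   classical pooled-variance t exactly; if the observed variances have
   literally zero spread the prior is taken as that common variance
   (so shrinkage is a no-op) rather than the moment-matched scale,
   which assumes sampling spread that is absent. p-values are
   two-sided; `z` is the signed normal quantile of p; BH controls FDR.
   Calls: DE significant iff adj p ≤ 0.05 **and** |log2FC| ≥ 1 (both
   inclusive); DA significant iff adj p ≤ 0.05 (no effect cut —
   activity units are not fold changes).
9. **Driver summary**: per driver, counts of regulon targets with
   expression |z| ≥ 1.64 (≈ two-sided p ≤ 0.10), split by direction.
10. **Enrichment**: targets of DA-significant miRNA drivers against
    the network's own gene universe. One-sided Fisher exact
    (hypergeometric tail) p; whole-count odds ratio
    `OR = overlap·background / (hallmark·input)` with
    `background = N − (overlap + hallmark + input)`; combined score
    `−ln(p)·OR`. The whole-count OR subtracts the overlap twice and is
    biased *downward* relative to the cross-product OR of the 2×2
    table in small universes (it can sit below 1 where the 2×2 OR
    signals enrichment, never the reverse); the cross-product form is
    available via `or_mode="standard"`.

## The synthetic-data generator

The generator emulates a hub-TF knockdown study: 2 cell lines × 2
conditions × 4 biological replicates = 16 samples per assay, a hub TF
regulating ~30% of the other TFs and miRNAs, every TF/miRNA regulating
4–30 target genes, and negative-binomial counts at 0.8–1.2 M reads per
library.

Planted structure, all recorded in `GroundTruth`:

* **hub knockdown**: −2.5 log2 on the hub, propagated one hop to its
  direct targets at attenuation 0.5 (signed);
* **hidden drivers**: 10 of the 40 miRNAs (chosen outside the hub's
  regulon) whose own expression is untouched while their targets shift
  by `edge sign × 1.0` log2 under knockdown — i.e. down, since miRNA
  edges are repressive;
* optional spike-ins, off by default: miRNAs with shifted own
  expression, and plain DE genes (used, e.g., to test that batch
  adjustment preserves a known +2 log2 condition effect).

Nuisance structure: per-(cell line, feature) location offsets
(sd 1.0) and lognormal noise-scale multipliers (sd 0.3); per-sample
biological noise (sd 0.2, log2); NB dispersion 0.1; uniform library
depths. Targets additionally track their regulators' cell-line offsets
(`regulatory_coupling = 0.4`, signed, one hop). This coupling is the
steady-state covariation a real regulatory network shows — cell lines
with more of a miRNA have less of its targets — and it is what makes
correlation-based edge pruning meaningful: without it the generator
would offer pruning nothing but noise, and edge selection on noise
measurably mis-calibrates the downstream activity test.

Parameters that matter most (defaults in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_mirna`, `hidden_driver_fraction` | 40, 0.25 | 10 hidden drivers among 40 miRNAs |
| `hidden_activity_shift` | 1.0 | log2 shift planted on hidden drivers' targets |
| `hub_kd_log2_shift` | −2.5 | knockdown depth of the hub transcript |
| `targets_per_driver` | (4, 30) | regulon sizes, uniform |
| `batch_location_sd`, `batch_scale_sd` | 1.0, 0.3 | cell-line offsets |
| `regulatory_coupling` | 0.4 | log2 target response per log2 regulator offset |
| `nb_dispersion` | 0.1 | NB overdispersion (var = μ + 0.1 μ²) |
| `depth_range` | (8e5, 1.2e6) | library sizes per sample |

What the generator does **not** emulate: raw reads, isoform structure,
UTR remodeling, ceRNA competition, cooperative miRNA binding,
sample-paired assay noise (the two assays share only cell-line-level
structure, as in an unpaired design). Passing recovery tests on this
generator therefore shows that the statistical chain works when the
network is right and repression is additive on the log2 scale — not
that the method is robust to network misspecification.

## Numerical and degenerate-case conventions

* Constant vectors: Spearman is undefined (NaN, edge treated as
  unscored and pruned if miRNA); MI is 0 with a warning; standardized
  expression of a constant feature is 0, not ±inf.
* p-values are floored at 1e−300 before the z transform, so z stays
  finite.
* Enrichment: negative whole-count background is floored at 0 with a
  warning; 0/0 odds ratios are 0 with a warning.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configs give byte-identical
  outputs, including written TSVs.
* Problem sizes used in the shipped checks: oracle equivalence at
  20 drivers × 100 targets × 16 samples; calibration and recovery at
  the default study size (2000 genes, 16 samples per assay) over 10–20
  generator seeds — sizes at which the full chain runs in a few
  seconds per study on one core.

## Open choices and limitations

* **Edge correlations on 4 points are fragile.** With two cell lines
  the group-mean Spearman has four observations; a hidden driver whose
  two cell-line offsets happen to be close contributes almost no
  coupling signal, and the shared condition pattern of its targets can
  then flip the sign of *all* its edge correlations at once, pruning
  the entire regulon. On the default study this costs roughly one
  hidden driver on an unlucky seed (10-seed mean AUROC ≈ 0.93–0.95
  rather than 1.0). More cell lines, or `paired_correlations` when the
  design supports it, soften this.
* TF/SIG edges whose correlation contradicts their curated sign are
  kept with the curated sign; there is no principled way to arbitrate
  from two cell lines.
* The moderated model assumes roughly Gaussian noise on the log2 scale
  and a common variance prior across features; activity scores of
  different drivers are correlated (shared targets), so BH controls
  FDR only in the usual PRDS-approximate sense.
* A driver whose regulon is entirely filtered or pruned disappears
  from the activity matrix; downstream consumers treat it as
  "not testable", and recovery metrics in the shipped checks rank it
  last rather than dropping it.
* The `center` batch mode is location-only; heteroscedastic batches
  need the EB mode.
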
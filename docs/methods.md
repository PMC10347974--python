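# Methods

`synscreen` analyzes checkerboard drug-combination viability screens of the
kind run on patient-derived tumor cultures: two drugs titrated against each
other in a 6×6 matrix (three-fold dilutions from a top dose anchored near
each drug's IC50), an ATP-luminescence viability readout normalized to
vehicle (DMSO) controls, and technical duplicates. This note records the
models, the numerical choices, and what the synthetic-data tests do and do
not establish.

## Monotherapy model

Each drug/culture pair is summarized by a four-parameter Hill (4PL) curve

    v(d) = einf + (e0 − einf) / (1 + (d / ec50)^h)

with viability `v` as a fraction of control, dose `d` in µM, plateau
`e0` (bounded to [0.7, 1.2] — the zero-dose response cannot stray far from
the control it was normalized to), floor `einf ∈ [0, 1]`, potency `ec50`
(bounded to [min dose/100, max dose×100]) and slope `h ∈ [0.1, 10]`.
Replicates enter the least-squares fit jointly rather than as means, so the
residual structure is preserved. The optimizer (`scipy.optimize.curve_fit`,
trust-region reflective, analytic Jacobian, `maxfev=200`) is restarted from
three log-spaced `ec50` values (geometric mid, min, max of the tested
doses) to avoid local minima; `ec50` itself is fitted on the log10 scale.

A response whose per-dose means span less than 0.1 viability is flat:
`ec50` and `h` are reported as NaN with `identifiable=False` rather than as
arbitrary numbers. Fits in which the optimizer drifts to a rising curve
(`einf > e0`) are likewise declared unidentifiable.

The **absolute IC50** — the dose where viability crosses 50% of control,
not the curve midpoint — is the screening quantity:

    IC50 = ec50 · ((e0 − 0.5) / (0.5 − einf))^(1/h),

undefined ("not reached") when `einf ≥ 0.5`. The screen-entry filter keeps
a drug when its absolute IC50 is reached within the tested range on at
least a configurable fraction of cultures (default: all of them — the
strictest reading of "lack of drug sensitivity"); a combination survives
only if both partners do.

## Matrices

The screened 6×6 block is stored as a 7×7 surface with explicit zero-dose
edges: row/column 0 hold the monotherapies and well (0,0) the control, so
every reference model is computed from the same plate. Missing wells are
masked (NaN) and skipped with explicit well counts — never imputed — and a
design more than 20% empty is rejected. An untreated (0,0) well whose
replicate mean leaves [0.9, 1.1] triggers a warning (an error in strict
mode): a breach usually means broken normalization, but duplicate-level
technical noise crosses the band by chance in a fraction of a percent of
honest matrices, so the default does not destroy data.

## Reference models and scores

Expected combination viability under no interaction:

* **Bliss independence** — `va · vb` (multiplicative survival);
* **HSA** — `min(va, vb)` (the better single agent);
* **Loewe additivity** — the viability `v` solving
  `da/A(v) + db/B(v) = 1`, where `A`, `B` invert the two Hill curves.
  The root is bracketed on `(max(einf), min(e0))` and solved with Brent's
  method. `f(v)` is monotone increasing on that interval, so the root is
  unique; when even the bracket floor leaves `f ≥ 0` the requested effect
  lies below what either curve can reach (Emax floor) and the well falls
  back to the HSA expectation, with the fallback count reported per matrix;
* **Chou–Talalay** — combination index in the mutually non-exclusive form
  `CI = da/Da + db/Db + da·db/(Da·Db)` with the median-effect parameters
  taken from the Hill fits (`Dm = ec50`, `m = h`) and
  `Dx = Dm·(fa/(1−fa))^(1/m)`. Observed viability is converted to an
  affected fraction on the mean response scale of the two fits,
  `fa = (ē0 − v)/(ē0 − ē∞)`, and clamped to [0.005, 0.995] so the index
  stays bounded at extreme effects.

Per well the score is `(expected − observed) × 100` percentage points
(`(1 − CI) × 100` for Chou–Talalay); the observed value is the mean of the
technical replicates. A combination on a culture is summarized by the sum
over the 36 combination wells — signed (synergy and antagonism allowed to
cancel), plus synergy-only and antagonism-only partial sums — together
with the **minimum viability** over combination wells, the tumoricidal
readout. Positive totals mean synergy. Monotherapy viabilities above 1
(outgrowth) are clamped to 1 before entering Bliss/HSA expectations:
exceeding the control carries no additional protection under either
reference.

## Consolidation

Summed scores from different models and the minimum viability live on
incommensurable scales, so each metric is z-scaled — mean 0, sample SD 1
(n−1 denominator) — over all combination × culture entries (at least two
values required; the sample SD needs no more). Missing entries stay
missing through scaling and are median-imputed (with a reported count)
only at the clustering step.

Clustering operates on one feature vector per combination: the per-metric
median z over cultures, four features for the primary analysis (Loewe,
HSA, Bliss signed sums + minimum viability). Gaussian mixtures are fitted
by EM for k = 1..min(9, C−1) across four covariance families (diagonal,
full, tied, spherical; 10 restarts, fixed seed) and the model with the
lowest BIC wins. Two validity constraints apply before comparison:

* components must be supported by at least d+1 hard-assigned points under
  a full covariance (fewer points give a singular matrix) and at least 2
  otherwise — without this, BIC chases likelihood spikes in which a
  component collapses onto one or two observations;
* a single-component solution provides no contrast and therefore never
  produces a synergy call.

The validation analysis runs K-means (same k as the selected mixture,
fixed seed) on the synergy-only variant of the panel (positive partial
sums of Loewe, HSA, Bliss, Chou–Talalay, plus minimum viability).

**Consistent synergy selection.** In each partition, the
"synergy with viability loss" cluster is read off the cluster
characterization: pooled median z over the synergy metrics above 0 and
median minimum-viability z below 0. Mixture components are density pieces,
not clusters — when BIC resolves the synergistic region into several
components, all components with that profile are merged before comparison.
The selected set is the intersection of the GMM members and the K-means
members of the respective synergy clusters; if either analysis has no such
cluster the selection is empty.

Replicate concordance is Pearson's r with its two-sided p (Spearman as an
option) on paired replicate score vectors.

## Longitudinal calls

Endpoint matrices from the long-term (18-day, repeated exposure) assay are
scored by the identical Loewe engine. No external threshold exists for
"longitudinal synergy", so calls are made against a permutation null: well
values of the replicate-mean matrix are shuffled across plate positions
(edges included, control fixed) and each shuffled matrix is rescored from
scratch — edges refitted, expectation surface rebuilt. Holding the
expectation surface fixed instead would be degenerate: the summed score is
invariant under any rearrangement of the combination block. Because
observed and shuffled matrices pass through the identical scoring path,
the observed score is exchangeable with the null scores under an
exchangeable-noise null, making the test exact at its nominal level
(measured: ~5% rejections at the 95th-percentile threshold).

Two details keep this affordable and honest at once. A monotone-trend gate
(Spearman correlation of each edge's means against dose rank ≤ −0.5)
decides whether a Hill fit is even meaningful; matrices failing it — as
almost all shuffled matrices do — are scored against the HSA expectation.
The gate is part of the statistic and applies identically to observed and
shuffled matrices. A combination is called synergistic when its observed
score exceeds the null's 95th percentile in at least one culture (both the
quantile and the ≥1-culture rule are configurable).

## Synthetic screens

The generator draws per-drug, per-culture Hill parameters
(`e0 = 1` exactly — the zero-dose plateau after DMSO normalization is 1 by
construction; `einf ~ U(0, 0.3)`; `ec50` log-uniform over 0.01–1 µM;
`h ~ U(0.8, 2.5)`), anchors each drug's 6-point three-fold ladder at its
true absolute IC50 (10 µM top dose when 50% viability is never reached),
and builds combination wells as the Bliss product `va·vb`. A designated
subset of combinations receives an interaction excess `delta` scaled by a
unimodal weight that peaks mid-grid and fades toward the dose extremes, so
the zero-dose edges remain honest monotherapies; a uniform weight and a
Loewe-consistent dose-shift mode (effective dose inflated by partner
occupancy) are alternatives. Truncated Gaussian noise (clip to [0, 1.2])
is added per replicate, and raw RLU plate maps with 16 DMSO control wells
are emitted so the normalization path is exercised end to end. Everything
is driven by one seed and regenerates bit-identically.

Default study conditions: 40 combinations × 10 cultures, 10 synergistic,
`delta = 0.15`, noise SD 0.05, technical duplicates. Under these
conditions the full pipeline recovers the injected subset with sensitivity
and specificity ≥ 0.9 over 20 seeds, and screens with no injected
interaction yield an empty selection in ≥ 90% of seeds (the BIC then
prefers a single component).

What the generator does **not** emulate: biological replicate variation
between passages, plate-position (edge) effects, dispensing errors,
heteroscedastic luminescence noise, drug-specific solubility ceilings, and
correlations between cultures' sensitivities. Passing recovery tests
therefore demonstrate that the analysis chain is correct and calibrated
under its own assumptions, not that real screens meet those assumptions.

## Cohort summaries

Driver-event frequencies are computed from a long-format
patient × gene × event table against per-gene driving-event rules
(amplification/mutation for oncogenes, deep deletion for tumor
suppressors; IDH1 R132H and gene fusions excluded by default). Percentages
are rounded half-up to integers, matching the reporting convention. The
43-combination screen panel (drugs, targets, external prediction scores
with "Not calculated" preserved as a sentinel) ships as a packaged TSV
fixture; the prediction model that produced the scores is consumed as
data, not reimplemented.

## Problem sizes

The test suite and the acceptance script size their simulations to run on
a single CPU: 20 screens of 400 matrices each for the recovery and null
calibration checks, 200 noisy curves for Hill recovery, 300 simulations ×
199 permutations for the type-I calibration, and 100 random Hill pairs
against a 10⁵-point grid scan for the Loewe solver oracle.

## Known limitations

* The Loewe fallback at unreachable effect levels (HSA capping) makes deep
  wells slightly conservative for highly asymmetric drug pairs.
* Chou–Talalay parameters inherit the 4PL fit; a separate median-effect
  regression on log(fa/fu) would weight extreme-effect wells differently.
* The permutation null destroys dose structure entirely; it tests "more
  synergy than any arrangement of these values", which is conservative for
  weak but well-organized synergy.
* Biological replicate reproducibility has no criterion here; only
  technical-replicate concordance is quantified.
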
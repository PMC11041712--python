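# Methods

## Behavioral phenotyping

A test-phase record holds six per-object exploration times and the index of
the novel object. The phenotype criterion compares the novel-object time to
the five familiar times: a subject is **Unimpaired** iff
`New > mean(Familiar) + k · SD(Familiar)` with `k = 1.5` by default. Two
conventions were genuinely open and are resolved as follows:

* **SD flavor.** The criterion's SD is the *sample* SD (denominator n−1),
  the usual behavioral-statistics convention for five observations; a
  `sd_mode="population"` switch exposes the n-denominator alternative.
* **Ties.** Unimpaired requires *strict* exceedance; `New` exactly equal to
  the threshold (inevitable when all familiar times are equal, so SD = 0)
  is labelled Impaired. The strict reading makes the two branches of the
  criterion exhaustive.

Cohort percentages are rounded to one decimal, half away from zero (so
16/29 → 55.2%, 13/29 → 44.8%), matching how such tallies are conventionally
printed. The 210 s study cap (35 s × 6 objects) is enforced by the data
generator and checked by a validator that warns on user data exceeding it;
user data are never silently truncated.

Omnibus statistics are the ones reported for this design: a pooled-variance
unpaired t-test (df = nA + nB − 2; t = 0, p = 1 by convention when the
pooled variance is zero with equal means), a one-way repeated-measures
ANOVA (df = (K−1, (K−1)(N−1)), uncorrected — no sphericity adjustment),
and a split-plot mixed ANOVA with between df (G−1, N−G) and within /
interaction error df (K−1)(N−G). The interaction numerator df is the
general (K−1)(G−1); with two groups it reduces to K−1. Both ANOVAs are
direct sums-of-squares decompositions (weighted group means for unbalanced
designs) and are cross-checked in the tests against pingouin's independent
implementation to 1e−10.

## Two-channel microarray pipeline

Input is probe-level two-channel fluorescence with quality flags, read
either from GenePix-style tab-delimited tables (`F532` = green = Hy3,
`F635` = red = Hy5; flag codes ≥ 0 → ok, −50 → marginal, ≤ −75 → absent) or
a simplified CSV dialect. Channel semantics are fixed so that **Hy3 carries
the Impaired pool** and Hy5 the Unimpaired pool; the reported
`log2_ratio = log2(Hy3/Hy5)` is therefore positive when a miRNA is higher
in the Impaired group. The mapping is a parameter of the experiment, not of
the code: swapping channels negates every ratio and exchanges up/down
calls exactly (a tested invariant).

Stages, in order:

1. **Flag filter** — only `ok` spots survive.
2. **Normalization** — per-slide median of the raw log2 ratios over the
   slide's endogenous-control probes is subtracted from every probe.
   "Endogenous-control normalization" admits several readings;
   median-centring on controls was chosen because it is robust, needs no
   distributional assumption, and absorbs any constant multiplicative dye
   bias on either channel (also a tested invariant). Probes with a zero
   intensity in either channel cannot be log-transformed and are dropped
   with a warning, never imputed. With normalization disabled, raw ratios
   pass through.
3. **Intensity window** — the mean log2 intensity `(log2 Hy3 + log2 Hy5)/2`
   must lie strictly inside (8, 14), excluding the noise floor and
   saturation. "Log intensity" is read as log2 of fluorescence.
4. **Replicate averaging** — arithmetic mean and sample SD (n−1; with two
   technical replicates the SD equals |difference|/√2) of the surviving
   log2 ratios per miRNA.
5. **Calling** — up if mean > +0.7, down if < −0.7, else unchanged (strict
   inequalities); tallies partition the considered set.

The published description contains two selection rules — |log2 FC| > 0.5
with SD 0.4 ("retention") and the ±0.7 call — whose interplay is not fully
specified. This package treats the **considered universe** as every miRNA
surviving stages 1–3 and applies the ±0.7 call to all of them; the
retention rule is computed as its own stage and recorded per miRNA as
`passed_retention`. This is the only reading under which the up + down +
unchanged tallies partition the considered set, and under which a planted
upregulated miRNA with tight replicates can be detected at all. The SD
comparator itself is ambiguous (`SD > 0.4` as printed, versus the common
reproducibility reading `SD < 0.4`); both are implemented
(`sd_mode="as_printed"` default, `"reproducibility"` alternate) and neither
is asserted to be the original intent.

## qPCR relative quantification

For each sample pool, `ΔCt = mean Ct(target) − mean Ct(reference)` with
replicate SDs combined in quadrature; `ΔΔCt` subtracts the calibrator
sample's ΔCt, and the fold change is `2^−ΔΔCt`. The calibrator's own fold
change is exactly 1 by construction. Error bars propagate the ΔCt SD
through the exponential:

    upper = 2^−(ΔΔCt − SD) − 2^−ΔΔCt
    lower = 2^−ΔΔCt − 2^−(ΔΔCt + SD)

which is asymmetric — upper > lower for every SD > 0 — reproducing the
characteristic pattern of published 2^−ΔΔCt tables. How the original error
bars were computed is not stated anywhere authoritative; this standard
propagation is an interpretation, documented as such. The SD covers
technical replicates only (the design pools animals, so there is no
biological-replicate variance to propagate). No outlier rejection is
applied by default; an optional validator warns when a replicate set spans
more than a configurable number of cycles.

## Integration and network statistics

Platform pairs match miRNAs by name; unmatched miRNAs are dropped with a
warning, never imputed. The Pearson correlation uses `scipy.stats.pearsonr`
(two-sided p via the t transform, n−2 df) and requires ≥ 3 pairs with
non-zero variance. Candidate selection keeps calls with mean log2 FC above
+0.5, ranked descending with lexicographic tie-break for deterministic
output.

Target consensus: a gene qualifies when predicted by at least two of the
three algorithms — TaPmiR counting only when its binding probability is
strictly above 0.95 — or when it carries validation evidence. Validated
genes enter the network node set like any other consensus gene. The
interaction graph is simple and undirected; edge confidence scores, if
present, are ignored by the degree statistics. Average degree is 2E/N over
*all* nodes, counting isolated targets, which is the whole-target-set
convention (101 nodes / 71 edges → 1.41).

## Synthetic data generators

The generators define the study conditions under which the pipeline is
validated; their defaults are fixed once.

* **Cohort** (`CohortSpec`): 29 subjects, impaired fraction 13/29, study
  cap 210 s. Per-object exploration times are log-normal (median 20 s,
  log-scale SD 0.3) — non-negative and right-skewed like real exploration
  bouts. Latently unimpaired subjects get a ×3 novelty boost on the novel
  object; impaired subjects get boost 1. Over-cap study records are
  proportionally rescaled to the cap, mimicking the timed cutoff without
  changing n. At these settings the criterion recovers ≥ 90% of latent
  labels; the residual errors are the criterion's intrinsic false-positive
  rate (one of five iid familiar draws occasionally clears mean + 1.5 SD)
  and boost draws that land inside the familiar range.
* **Array** (`ArraySpec`): 179 miRNAs, 38 planted upregulated at log2 FC
  +1.2, 10 zero-FC control probes, 2 replicate slides, log2-scale noise SD
  0.1, baselines uniform in (9, 13) so everything sits inside the intensity
  window. Channel intensities are `2^(baseline ± fc/2 + noise)`, with an
  optional per-slide multiplicative Hy5 dye bias that normalization must
  absorb.
* **qPCR** (`QpcrSpec`): Ct = base − latent_expression + noise, triplicates
  with 0.2-cycle noise; the reference assay (U6) has zero latent difference
  and its own base Ct. Default latent differences are the log2 values of
  the five validated assays' fold changes, so recovery can be judged on a
  realistic scale.

Each generator consumes one integer seed, split into independent
sub-streams via `numpy.random.SeedSequence`; identical spec + seed gives
identical output.

**What passing tests do and do not show.** The generators model measurement
noise as iid Gaussian on the log2/Ct scale, probes as independent, and the
novelty effect as a clean multiplicative boost. Real slides have spatially
correlated artefacts, intensity-dependent dye bias and probe
cross-hybridization; real exploration has session-level correlations and
habituation drift. Recovery results therefore demonstrate correctness of
the computational chain under its stated noise model, not robustness to
every artefact of real data.

## Problem sizes and numerics

The test suite and the acceptance script run the pipeline at the study's
own scale (29 subjects, 179 miRNAs × 2 slides, 5 assays × 3 Ct replicates),
plus property sweeps of 100 random slides and 10⁴ random error-propagation
draws; everything completes in seconds on one CPU. Strict inequalities are
used at every published threshold (criterion exceedance, intensity window,
±0.7 call, TaPmiR 0.95), so boundary values fall on the conservative side.
Degenerate inputs are errors, not silent results: zero total exploration,
zero pooled variance with unequal means, slides without usable controls,
missing reference or calibrator entries, empty graphs.

## Known limitations

* The exact published microarray fold-change values and raw inputs are not
  deposited, so the published cross-platform correlation (computed on real
  data) cannot be recomputed; the package reports correlations on data it
  can generate.
* No efficiency-corrected (Pfaffl) qPCR model, no loess/print-tip array
  normalization, no moderated differential-expression statistics, no
  post-hoc multiple-comparison tests — all outside this pipeline's scope.
* The split-plot ANOVA reports uncorrected df; sphericity corrections are
  deliberately not applied.
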
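# Methods

This note records the models implemented by `exonuse`, the numerical
conventions behind them, what the synthetic-data generator does and
does not emulate, and the design choices made where the procedure was
genuinely open.

## Data model and preprocessing

Input is a probe-level intensity table (probe → probeset → transcript
annotation; one column per sample) plus a sample sheet with
`treatment ∈ {untreated, vehicle, kainate}` and `time_h ∈ {0, 1, 4, 8}`.
The canonical design has 4 untreated controls and 3 vehicle plus 3
kainate replicates at each of 1, 4 and 8 h (22 arrays). Missing
intensities are rejected, never imputed: the presence filter below
operates on detection calls and silent imputation would corrupt it.

Preprocessing follows the robust multichip average in three stages:

1. **Background** (linear input only): optional per-sample percentile
   shift (default quantile 0.01, floor 2^-10). The convolution
   background model of classic RMA is deliberately not fitted — the
   splice statistics downstream depend on relative probe behaviour
   within genes, which the convolution correction leaves essentially
   unchanged, and no background parameters were available to match.
   Log2-scale input (the generator default) skips this stage.
2. **Quantile normalization**: every sample is mapped onto the common
   distribution of row-wise means of column-sorted values. Ties share
   the mean of the quantile slots they would occupy, making the map
   well defined and permutation-equivariant. With untied data the
   column multisets agree exactly (tested at 1e-12).
3. **Median polish**: Tukey's row/column median sweeps (rows first,
   tol 0.01, max 10 iterations — the conventional defaults; the source
   procedure names neither). The decomposition
   `chip + probe + residual = input` is exact by construction; chip
   effects (overall + per-sample) are the summarized expression.
   Summarization runs once per probeset and once per transcript; the
   transcript-level residual matrices feed the FIRMA scorer.

The transcript-level expression filter retains transcripts whose mean
log2 expression across samples lies strictly above the median of those
means. The summary statistic per transcript (mean across samples) is a
design choice: the source procedure says only "expression values above
the median".

## Time-dependent ANOSVA

Per gene, probe log2 intensities are modelled as
`y_peth = mu + alpha_e + beta_t + delta_h + gamma_eth + eps`, i.e. a
probeset main effect, treatment and time main effects, and a
probeset×treatment×time interaction. Under the pooled design — all
controls (untreated and vehicle, any collection time) treated as one
condition at time 0, treated samples only at 1/4/8 h — `beta_t` and
`delta_h` are confounded; the model is therefore fitted with a single
4-level condition factor {control, KA1, KA4, KA8} spanning the same
column space. That makes the design a saturated probeset×condition
layout, so OLS fitted values are cell means and each interaction
coefficient is the double difference
`(e,c) − (e,ref) − (ref,c) + (ref,ref)`; the implementation computes
them in closed form (an explicit design-matrix `lstsq` route serves as
the independent oracle in the tests). Reference levels are the 5′-most
probeset and the control condition. The residual variance is pooled
within cells with df = N − 4E.

Before fitting, the presence cascade drops (i) cross-hybridizing
probes, (ii) probesets not "present" in at least half the samples of
any treatment group, (iii) transcripts without a group in which at
least half their probesets are present, and (iv) transcripts left with
fewer than 3 probesets. Presence is an annotation-free surrogate for
detection-above-background: a probeset is present in a sample when its
mean log2 intensity exceeds the `present_quantile` (default 0.25)
quantile of all probeset means in that sample. The quantile is
monotone, deterministic and exposed as a parameter.

Each interaction coefficient gets a marginal two-sided t-test against
the pooled residual variance. Within a gene the p-values are
Holm-adjusted and their minimum is the gene-level p (a valid gene-level
test); across genes the minima are Benjamini–Hochberg adjusted and
genes called at q ≤ 0.05. Marginal coefficient tests (not sequential
ANOVA sums of squares) are a design choice. Genes with an empty
probeset×condition cell or nonpositive residual df are skipped and
reported in a skip ledger. A single-timepoint variant restricts to
control + kainate-at-t with a two-level condition factor; on simulated
data its calls are (almost always) a subset of the time-dependent
calls.

**Calibration caveat.** The model has no probe term: constant probe
affinities sit in the residual. They cancel exactly in every
interaction contrast (the same probes appear in both cells of each
difference) but inflate the estimated residual variance, so with
realistic affinity spread the t-tests are conservative — p-values shift
right, never left. Null calibration (uniform p-values, ≤0.5% global
null call rate) is therefore verified in the regime that satisfies the
model's iid-error assumption (probe-affinity SD 0); with affinity
SD 1.0 the tests only become more conservative, which lowers, never
inflates, the realized false-discovery proportion.

## FIRMA scoring and the empirical FDR

Only transcripts whose summarized log expression exceeds the global
median in at least half the samples are scored. For probeset *e* and
sample *s*, `F[e,s]` is the median of the probes' transcript-fit
residuals divided by a robust scale of the gene's whole residual
matrix: MAD × 1.4826, floored at 1e-8 (the floor only matters for
exactly-zero residual matrices). The F formula itself is a
reconstruction from the robust-multichip-analysis lineage the
procedure cites; the source text never prints it.

The all-sample score of a probeset is the maximum over condition groups
of the within-group minimum of its F row. Two scores are computed
against two group layouts with identical topology: the *sample*
distribution `F_s` over {untreated, KA-1h, KA-4h, KA-8h}, where
activity-dependent splicing would appear, and the *background*
distribution `F_0` over {untreated, vehicle-1h, vehicle-4h,
vehicle-8h}, where none is expected. Untreated controls participate in
both. The background grouping is mirrored by design so both scores
share a null distribution; the source names only the sample-side
groups.

The plug-in empirical FDR thresholds both score lists at each
probeset's sample score τ = `F_s[e]`:
`p_s = #{F_s ≥ τ}/N`, `p_0 = #{F_0 ≥ τ}/N`, `FDR = p_0/p_s`, ties
counted inclusively; `p_s ≥ 1/N` by construction so the ratio is always
defined. Probesets with FDR ≤ 0.10 are called. All probesets compete in
one pooled genome-wide ranking. An alternative reading of the
procedure — pairing the two lists by rank rather than thresholding —
cannot be excluded from the source text; the threshold-counting form
implemented here is the conventional plug-in estimator and matches the
worked examples frozen in the tests.

## Moderated-t differential expression and kinetic classes

Per timepoint t ∈ {1,4,8} h, a two-group model (kainate_t vs vehicle_t;
log2fc = mean difference, pooled variance with df = n₁ + n₂ − 2) is fit
per transcript. Residual variances are shrunk toward a scaled-F prior
`s_g² ~ s0² F(df_g, d0)` whose parameters are estimated by moments on
log variances via the digamma/trigamma identities (trigamma inversion
by bracketed root finding). The moderated variance is the df-weighted
blend and the moderated t uses df_g + d0 degrees of freedom. Two
degenerate regimes are defined explicitly: d0 = ∞ (no excess spread)
sets every moderated variance to the mean observed variance, making
moderation a fixed point for identical variances; a forced d0 = 0
reproduces the ordinary two-sample t exactly. Robustified (winsorized)
prior estimation is not implemented.

P-values are BH-adjusted within timepoint. The significance pattern
maps onto four kinetic classes: significant-up at 1 h → immediate
early; significant-down at 1 h → immediate down; otherwise a
significant later timepoint decides delayed up/down, conflicts resolved
by the larger |log2fc|. The class taxonomy is rule-based rather than
clustered, for determinism and testability. Defaults α = 0.05,
`lfc_min` = 0; both exposed.

**Known limitation.** When a large fraction of the transcriptome moves
in one direction, quantile normalization's majority-invariance
assumption fails and unaffected genes acquire small systematic fold
changes (≈0.1–0.4 log2 at a 50% DE fraction in simulation). Because
the moderated variances on summarized data are tiny, such shifts can
reach significance at `lfc_min` = 0; a modest fold-change floor
(e.g. 0.5) removes them. At the generator's default 10% DE fraction
the effect is negligible and class recovery exceeds 90%.

## Synthetic data generator

The generator emulates the canonical 22-sample design with
gene → probeset → probe hierarchy: 4–12 probesets per transcript, 4
probes per probeset, baselines uniform on 6–12 log2, probe affinities
N(0, 1.0) centered within probeset, iid N(0, 0.25) noise, 10% of
transcripts with gene-level induction of 2.0 log2 following one of the
four kinetic classes (immediate classes: full effect at 1 h, half at
4 h, none at 8 h; delayed classes: none at 1 h, full at 4 and 8 h —
invented shapes matching the class names), and 10% of transcripts with
one probeset shifted +1.5 log2 in the kainate conditions only. A small
fraction of probesets can be forced to a background baseline (2 log2
below the 1st percentile of gene baselines) and probes flagged
cross-hybridizing. Unit assignment uses exact counts drawn by seeded
permutation, so realized fractions equal configured ones and the whole
dataset is a pure function of the seed. Where the emulated study
reports no magnitude (noise, affinity spread, effect sizes), the
defaults are one-time calibration choices at values typical for
log-scale array data, not claims about any deposited dataset.

Not emulated: probe sequence/GC affinity structure, scanner saturation,
spatial artifacts, correlated (non-iid) noise, partial-exon probesets
and multi-exon splice patterns (available via configuration but not the
default). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not
performance on real arrays, where probe-level error is heavier-tailed
and annotation is imperfect.

## Evaluation conventions and problem sizes

Realized false-discovery proportion is FP/max(calls, 1) against the
generator truth, and power is TP/positives. Error control is exercised
on ten replicate simulations of 2000 transcripts each (the canonical
design; 10% spliced at +1.5 log2; noise SD 0.25; affinity SD 1.0):
mean FDP of ANOSVA gene calls at q ≤ 0.05 and of FIRMA probeset calls
at FDR ≤ 0.10. Splice-unit *recovery* (≥90% at effect 3.0, noise
SD 0.2) is measured among the units each detector admits through the
expression filters: the FIRMA retention rule excludes roughly half the
transcriptome by construction (above-global-median is a relative
criterion) and the presence quantile roughly a quarter, so recovery
against all generated positives is bounded well below 1 regardless of
effect size. Smaller simulations (150–500 transcripts) back the
distributional and invariance tests; all problem sizes are fixed in the
test suite and chosen to keep the full run in the minutes range on a
single core.

## Numerical conventions

- TSV throughout, UTF-8, `.` decimal, floats at ≥10 significant digits
  (`%.10g`) so round-trips are lossless at 1e-9.
- Ties: top-SD transcript selection breaks ties by transcript id;
  argmin interaction terms break ties by probeset order then condition
  order; empirical-FDR counts are inclusive.
- PCA components fix their sign so the first nonzero loading is
  positive, making outputs run-to-run identical.
- Degenerate inputs: zero residual variance in a gene yields p = 0 for
  nonzero interactions and p = 1 otherwise (logged); single-sample
  quantile normalization warns and passes through; empty filter results
  warn and propagate as empty tables, never exceptions.
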
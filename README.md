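# exonuse

Detection of condition-dependent **alternative exon usage** from
exon-microarray probe intensities, built for time-course designs in
which a treatment (here labelled *kainate*, after the seizure model the
design emulates) is profiled at 1, 4 and 8 h against vehicle-treated
and untreated controls.

The package is aimed at transcriptomics analysts who have probe-level
exon-array intensity tables (probe → probeset/exon → transcript) and
want reproducible splice-variation calls without vendor tooling: it
chains RMA-style preprocessing, moderated-t differential expression
with kinetic classification, and two complementary splice detectors,
and ships a seeded synthetic-data generator with ground truth so every
stage is testable offline.

## The statistics at the core

**Time-dependent ANOSVA.** Each gene's probe log2 intensities are
modelled as

```
y_peth = mu + alpha_e + beta_t + delta_h + gamma_eth + eps_peth
```

with probeset main effects `alpha_e`, treatment (`beta_t`) and time
(`delta_h`) main effects, and a probeset x treatment x time interaction
`gamma_eth`. A nonzero interaction means one exon departs from the
gene's overall regulation — the signature of differential exon usage.
Because controls are pooled at time 0 and treated samples exist only at
1/4/8 h, `beta` and `delta` are confounded and the model is fitted with
a single 4-level condition factor spanning the same column space. Each
interaction coefficient gets a marginal t-test against the gene's
pooled residual variance; the minimum Holm-adjusted interaction p is
the gene-level p, Benjamini–Hochberg adjusted across genes
(FDR 0.05).

**FIRMA all-sample scoring.** After median-polish summarization, the
per-sample score of probeset *e* is the median of its probes' residuals
standardized by the gene's robust residual scale (MAD x 1.4826). Scores
collapse into an *all-sample score* — the maximum over condition groups
of the within-group minimum — so a high score demands consistent
deviation in every sample of at least one group. Two scores are
computed per probeset: `F_s` over the kainate + untreated groups and
`F_0` over the vehicle + untreated groups, and the empirical FDR
thresholds both lists at each probeset's sample score:

```
p_s = #{F_s >= tau}/N    p_0 = #{F_0 >= tau}/N    FDR = p_0 / p_s
```

with calls at FDR <= 0.10.

**Moderated-t DE with kinetic classes.** Per timepoint, kainate vs
vehicle fold changes are tested with empirical-Bayes variance shrinkage
(scaled-F prior fitted by moments on log variances) and mapped onto
four kinetic classes: immediate early, delayed up, delayed down,
immediate down.

## Worked example

```python
from exonuse import (GeneratorConfig, generate_dataset, quantile_normalize,
                     summarize, TimeDependentAnosva, FirmaModel,
                     KineticDEModel, evaluate_calls)

cfg = GeneratorConfig(n_transcripts=300, seed=1)   # canonical 22-sample design
ds, truth = generate_dataset(cfg)
dsn = quantile_normalize(ds)
summary = summarize(dsn)

anosva = TimeDependentAnosva(dsn).fit(fdr=0.05)
print(anosva.summary())
```

```
ANOSVA (time-dependent) interaction test
  genes tested  : 244
  genes skipped : 0
  FDR cutoff    : 0.05
  genes called  : 12
```

244 of 300 transcripts survive the presence filter (cross-hybridizing
probes removed; probesets detected in at least half the samples of some
treatment group; at least 3 probesets per transcript); 12 genes are
called spliced. Against the generator truth all 12 are genuinely
spliced:

```python
print(evaluate_calls(anosva.called, truth, "gene"))
# EvaluationMetrics(n_called=12, n_true_positive=12, n_false_positive=0,
#                   realized_fdp=0.0, power=0.4)
```

(power is 0.4 against *all* simulated spliced genes because the
presence and expression filters exclude low-expressed transcripts up
front). The top of the gene table names the offending exon and
condition:

```
transcript_id   p_gene top_probeset_id top_condition  n_probesets  n_terms   q_gene  call
      tx00198 0.000004    tx00198_ps02           KA4            7       18 0.000949  True
      tx00288 0.000011    tx00288_ps04           KA4            4        9 0.000949  True
```

The DE stage with a 0.5 log2 fold-change floor recovers the simulated
kinetic classes exactly (30 DE genes generated):

```python
print(KineticDEModel(summary.transcript_expr, dsn.design).fit(lfc_min=0.5).summary())
```

```
Kinetic differential expression (kainate vs vehicle per timepoint)
  transcripts tested : 300
  alpha (BH q)       : 0.05
  prior at 1 h      : d0=22.9, s0^2=0.002906
  prior at 4 h      : d0=60, s0^2=0.003087
  prior at 8 h      : d0=15.4, s0^2=0.00284
  not_significant   : 270
  immediate_early   : 8
  delayed_up        : 8
  immediate_down    : 7
  delayed_down      : 7
```

A shell workflow is available through the `exonuse` CLI
(`simulate`, `validate`, `preprocess`, `qc`, `de`, `anosva`, `firma`,
`run`, `report --gene <id>`), all stages writing plain TSV tables plus
a JSON run manifest; re-running with the same inputs and seed
reproduces every output byte-for-byte.

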
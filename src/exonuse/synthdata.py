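"""Seeded generator of exon-array probe intensities with known truth.

The generator emulates the kainate seizure time-course design: 4
untreated controls, 3 vehicle and 3 kainate replicates at each of 1, 4
and 8 h, a gene→probeset→probe annotation hierarchy with ~4 probes per
probeset, additive probe affinities, gene-level induction following four
kinetic classes, and probeset-restricted splice effects confined to the
kainate conditions.  Every stochastic choice flows from one integer
seed, and fractional assignments (DE, spliced, absent, cross-hybridizing
units) use exact counts drawn by seeded permutation so the realized
fractions equal the configured ones.

Intensities are generated on the log2 scale; ``to_linear`` exports the
2**y view for exercising the linear-scale input path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import ExonArrayDataset, SampleDesign, design_frame

KINETIC_CLASSES = ("immediate_early", "delayed_up", "delayed_down", "immediate_down")


@dataclass(frozen=True)
class GeneratorConfig:
    n_transcripts: int = 200
    probesets_per_transcript: tuple[int, int] = (4, 12)
    probes_per_probeset: int = 4
    baseline_mu: tuple[float, float] = (6.0, 12.0)
    probe_affinity_sd: float = 1.0
    noise_sd: float = 0.25
    frac_de: float = 0.10
    de_effect: float = 2.0
    de_class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    frac_spliced: float = 0.10
    splice_effect: float = 1.5
    splice_conditions: tuple[str, ...] = ("KA1", "KA4", "KA8")
    frac_absent_probesets: float = 0.05
    frac_crosshyb: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_de", "frac_spliced", "frac_absent_probesets", "frac_crosshyb"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.noise_sd < 0 or self.probe_affinity_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        lo, hi = self.probesets_per_transcript
        if lo < 1 or hi < lo:
            raise ValueError("invalid probesets_per_transcript range")
        if abs(sum(self.de_class_mix) - 1.0) > 1e-9:
            raise ValueError("de_class_mix must sum to 1")
        if any(c not in ("KA1", "KA4", "KA8") for c in self.splice_conditions):
            raise ValueError("splice_conditions must be kainate conditions")


@dataclass
class SyntheticTruth:
    """Ground truth: per transcript the DE class and time profile and
    whether it carries a spliced probeset; per probeset the splice
    effect and affected conditions; per probe the cross-hyb flag."""

    transcripts: pd.DataFrame  # transcript_id, de_class, de_1h, de_4h, de_8h, spliced
    probesets: pd.DataFrame    # probeset_id, transcript_id, spliced, splice_effect, splice_conditions, absent
    probes: pd.DataFrame       # probe_id, cross_hybridizing

    @property
    def spliced_transcripts(self) -> set[str]:
        t = self.probesets
        return set(t.loc[t["spliced"], "transcript_id"])

    @property
    def spliced_probesets(self) -> set[str]:
        t = self.probesets
        return set(t.loc[t["spliced"], "probeset_id"])

    @property
    def de_transcripts(self) -> set[str]:
        t = self.transcripts
        return set(t.loc[t["de_class"] != "none", "transcript_id"])


@dataclass
class EvaluationMetrics:
    n_called: int
    n_true_positive: int
    n_false_positive: int
    realized_fdp: float
    power: float


def kinetic_profile(de_class: str, effect: float) -> tuple[float, float, float]:
    """Log2 effect at 1/4/8 h for each kinetic class.

    Immediate classes peak at 1 h, halve by 4 h and vanish by 8 h;
    delayed classes are silent at 1 h and fully on at 4 and 8 h.
    """
    if de_class == "immediate_early":
        return (effect, effect / 2.0, 0.0)
    if de_class == "delayed_up":
        return (0.0, effect, effect)
    if de_class == "immediate_down":
        return (-effect, -effect / 2.0, 0.0)
    if de_class == "delayed_down":
        return (0.0, -effect, -effect)
    return (0.0, 0.0, 0.0)


def generate_design() -> list[SampleDesign]:
    """The canonical 22-sample design: 4 untreated controls plus 3
    vehicle and 3 kainate replicates at each of 1, 4 and 8 h."""
    out = [SampleDesign(f"cntrl_{r}", "untreated", 0, r) for r in range(1, 5)]
    for t in (1, 4, 8):
        out += [SampleDesign(f"veh_{t}h_{r}", "vehicle", t, r) for r in range(1, 4)]
    for t in (1, 4, 8):
        out += [SampleDesign(f"ka_{t}h_{r}", "kainate", t, r) for r in range(1, 4)]
    return out


def _exact_count_mask(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(frac * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.permutation(n)[:k]] = True
    return mask


def generate_dataset(cfg: GeneratorConfig) -> tuple[ExonArrayDataset, SyntheticTruth]:
    """Simulate a probe×sample log2 intensity matrix and its truth.

    y[p, s] = baseline_g + a_p + de_g(cond(s)) + splice_e(cond(s)) + ε
    with ε ~ N(0, noise_sd) and probe affinities a_p ~ N(0,
    probe_affinity_sd) centered within each probeset.  Absent probesets
    sit at a constant background baseline 2 log2 units below the 1st
    percentile of gene baselines, untouched by DE or splice effects.
    Identical seeds give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    designs = generate_design()
    ddf = design_frame(designs)
    conditions = np.array([d.condition for d in designs])
    n_samples = len(designs)

    ntx = cfg.n_transcripts
    lo, hi = cfg.probesets_per_transcript
    n_ps_per_tx = rng.integers(lo, hi + 1, size=ntx)
    baselines = rng.uniform(*cfg.baseline_mu, size=ntx)

    de_mask = _exact_count_mask(ntx, cfg.frac_de, rng)
    # deterministic class mix over the DE transcripts
    de_classes = np.full(ntx, "none", dtype=object)
    de_idx = np.flatnonzero(de_mask)
    if len(de_idx):
        counts = np.floor(np.asarray(cfg.de_class_mix) * len(de_idx)).astype(int)
        while counts.sum() < len(de_idx):
            counts[int(np.argmin(counts))] += 1
        labels = np.repeat(KINETIC_CLASSES, counts)
        de_classes[de_idx] = rng.permutation(labels)
    spliced_mask = _exact_count_mask(ntx, cfg.frac_spliced, rng)

    total_ps = int(n_ps_per_tx.sum())
    absent_mask_flat = _exact_count_mask(total_ps, cfg.frac_absent_probesets, rng)
    background = np.percentile(baselines, 1) - 2.0

    ann_rows = []
    y_rows = []
    tx_rows = []
    ps_rows = []
    cond_levels = ("control", "KA1", "KA4", "KA8")
    cond_index = {c: i for i, c in enumerate(cond_levels)}
    cond_of_sample = np.array([cond_index[c] for c in conditions])

    ps_cursor = 0
    for g in range(ntx):
        tid = f"tx{g + 1:05d}"
        n_ps = int(n_ps_per_tx[g])
        profile = kinetic_profile(str(de_classes[g]), cfg.de_effect)
        de_by_cond = np.array([0.0, *profile])
        absent = absent_mask_flat[ps_cursor:ps_cursor + n_ps].copy()
        ps_cursor += n_ps
        spliced_ps = -1
        if spliced_mask[g]:
            candidates = np.flatnonzero(~absent)
            if len(candidates):
                spliced_ps = int(rng.choice(candidates))
            else:
                spliced_mask[g] = False
        splice_by_cond = np.zeros(4)
        for c in cfg.splice_conditions:
            splice_by_cond[cond_index[c]] = cfg.splice_effect

        tx_rows.append(
            (tid, str(de_classes[g]), profile[0], profile[1], profile[2],
             spliced_ps >= 0)
        )
        for e in range(n_ps):
            pid = f"{tid}_ps{e + 1:02d}"
            ps_rows.append(
                (
                    pid, tid, e == spliced_ps,
                    cfg.splice_effect if e == spliced_ps else 0.0,
                    ",".join(cfg.splice_conditions) if e == spliced_ps else "",
                    bool(absent[e]),
                )
            )
            affin = rng.normal(0.0, cfg.probe_affinity_sd, size=cfg.probes_per_probeset)
            affin -= affin.mean()
            base = background if absent[e] else baselines[g]
            mean_by_cond = base + (0.0 if absent[e] else 1.0) * (
                de_by_cond + (splice_by_cond if e == spliced_ps else 0.0)
            )
            mu = mean_by_cond[cond_of_sample]  # per sample
            eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.probes_per_probeset, n_samples))
            y_rows.append(mu[None, :] + affin[:, None] + eps)
            for k in range(cfg.probes_per_probeset):
                ann_rows.append((f"{pid}_p{k + 1}", pid, tid, e, False))

    ann = pd.DataFrame(
        ann_rows,
        columns=["probe_id", "probeset_id", "transcript_id", "probeset_order",
                 "cross_hybridizing"],
    )
    crosshyb = _exact_count_mask(len(ann), cfg.frac_crosshyb, rng)
    ann["cross_hybridizing"] = crosshyb
    Y = np.vstack(y_rows)
    inten = pd.DataFrame(Y, index=ann["probe_id"].to_numpy(),
                         columns=ddf["sample_id"].to_numpy())
    ds = ExonArrayDataset(annotation=ann, design=ddf, intensities=inten, scale="log2")
    truth = SyntheticTruth(
        transcripts=pd.DataFrame(
            tx_rows, columns=["transcript_id", "de_class", "de_1h", "de_4h", "de_8h", "spliced"]
        ),
        probesets=pd.DataFrame(
            ps_rows,
            columns=["probeset_id", "transcript_id", "spliced", "splice_effect",
                     "splice_conditions", "absent"],
        ),
        probes=ann[["probe_id", "cross_hybridizing"]].copy(),
    )
    return ds, truth


def to_linear(ds: ExonArrayDataset) -> ExonArrayDataset:
    """Export the 2**y linear-scale view of a log2 dataset."""
    if ds.scale != "log2":
        raise ValueError("to_linear expects a log2 dataset")
    return ExonArrayDataset(ds.annotation, ds.design, 2.0 ** ds.intensities, scale="linear")


def evaluate_calls(
    calls: set[str], truth: SyntheticTruth, level: str = "gene"
) -> EvaluationMetrics:
    """Confusion counts for a call set against the splice truth.

    Gene-level truth: the transcript carries at least one spliced
    probeset.  Probeset-level truth: the probeset's spliced flag.
    """
    if level == "gene":
        universe = set(truth.transcripts["transcript_id"])
        positives = truth.spliced_transcripts
    elif level == "probeset":
        universe = set(truth.probesets["probeset_id"])
        positives = truth.spliced_probesets
    else:
        raise ValueError(f"unknown level {level!r}")
    unknown = set(calls) - universe
    if unknown:
        raise ValueError(f"calls not present in truth: {sorted(unknown)[:5]}")
    tp = len(calls & positives)
    fp = len(calls) - tp
    return EvaluationMetrics(
        n_called=len(calls),
        n_true_positive=tp,
        n_false_positive=fp,
        realized_fdp=fp / max(len(calls), 1),
        power=tp / len(positives) if positives else 0.0,
    )


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat probeset-level truth table for the ``simulate`` CLI output."""
    tx = truth.transcripts.set_index("transcript_id")
    out = truth.probesets.copy()
    out["de_class"] = tx["de_class"].reindex(out["transcript_id"]).to_numpy()
    return out


def config_with(cfg: GeneratorConfig, **kwargs) -> GeneratorConfig:
    return replace(cfg, **kwargs)
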
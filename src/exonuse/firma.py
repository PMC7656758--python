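"""FIRMA probeset scoring and the empirical sample-vs-background FDR.

FIRMA asks whether one probeset's probes systematically deviate from the
gene's fitted additive (median polish) model.  The per-sample score of
probeset e is the median of its probes' residuals, standardized by a
robust scale of the gene's whole residual matrix (MAD × 1.4826).  Scores
are then collapsed into an "all-sample" score: the maximum over
condition groups of the within-group minimum, so a high score demands
uniformly elevated residuals in every sample of at least one group.

Two all-sample scores are computed per probeset against two group
layouts with identical topology:

* sample distribution F^s — groups {untreated controls, KA-1h, KA-4h,
  KA-8h}: where activity-dependent splicing would show;
* background distribution F^0 — groups {untreated controls, vehicle-1h,
  vehicle-4h, vehicle-8h}: no activity-induced splicing expected.

The plug-in empirical FDR thresholds both score lists at each probeset's
sample score τ = F^s_e:

    p^s_e = #{F^s >= τ}/N,   p^0_e = #{F^0 >= τ}/N,   FDR_e = p^0_e/p^s_e

and probesets with FDR ≤ 10% are called differentially spliced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ExonArrayDataset  # noqa: F401  (type referenced in docs)
from .preprocess import ExpressionSummary

log = logging.getLogger(__name__)

MAD_CONSTANT = 1.4826
SCALE_FLOOR = 1e-8


@dataclass
class FirmaScores:
    """Per-probeset per-sample F scores (probesets × samples)."""

    F: pd.DataFrame
    transcript_of: pd.Series  # probeset_id -> transcript_id


def firma_retained(summary: ExpressionSummary) -> set[str]:
    """Transcripts whose log expression exceeds the global median in at
    least half of the samples."""
    X = summary.transcript_expr.to_numpy(dtype=float)
    med = float(np.median(X))
    above = (X > med).sum(axis=1)
    keep = above * 2 >= X.shape[1]
    return set(summary.transcript_expr.index[keep])


def firma_scores(
    summary: ExpressionSummary, retained: set[str] | None = None
) -> FirmaScores:
    """MAD-standardized median residual per probeset and sample.

    ``retained`` defaults to :func:`firma_retained`; transcripts without
    residual matrices are skipped with a log record.
    """
    if retained is None:
        retained = firma_retained(summary)
    rows: list[np.ndarray] = []
    idx: list[str] = []
    tx: list[str] = []
    samples = summary.transcript_expr.columns
    ps_of_tx = summary.probeset_transcript
    for tid in sorted(retained):
        resid = summary.residuals.get(tid)
        if resid is None:
            log.info("firma_scores: transcript %s missing residuals; skipped", tid)
            continue
        R = resid.to_numpy(dtype=float)
        scale = MAD_CONSTANT * float(np.median(np.abs(R - np.median(R))))
        scale = max(scale, SCALE_FLOOR)
        probes = resid.index.to_numpy()
        ps_ids = ps_of_tx.index[ps_of_tx == tid]
        probe_ps = summary.probe_probeset.reindex(probes).to_numpy()
        for ps in ps_ids:
            mask = probe_ps == ps
            if not mask.any():
                continue
            rows.append(np.median(R[mask], axis=0) / scale)
            idx.append(ps)
            tx.append(tid)
    F = pd.DataFrame(rows, index=idx, columns=samples)
    return FirmaScores(F=F, transcript_of=pd.Series(tx, index=idx))


def all_sample_score(F_row: np.ndarray, groups: list[np.ndarray]) -> float:
    """Max over condition groups of the within-group minimum score."""
    if any(len(g) == 0 for g in groups):
        raise ValueError("all_sample_score: empty condition group")
    return float(max(np.min(np.asarray(F_row)[g]) for g in groups))


def _distribution_groups(design: pd.DataFrame) -> tuple[list[np.ndarray], list[np.ndarray]]:
    treatment = design["treatment"].to_numpy()
    time_h = design["time_h"].to_numpy()
    untreated = np.flatnonzero(treatment == "untreated")
    sample_groups = [untreated] + [
        np.flatnonzero((treatment == "kainate") & (time_h == t)) for t in (1, 4, 8)
    ]
    background_groups = [untreated] + [
        np.flatnonzero((treatment == "vehicle") & (time_h == t)) for t in (1, 4, 8)
    ]
    return sample_groups, background_groups


def build_distributions(
    scores: FirmaScores, design: pd.DataFrame
) -> pd.DataFrame:
    """All-sample scores for the sample (F_s) and background (F_0)
    distributions, sorted by decreasing F_s."""
    sample_groups, background_groups = _distribution_groups(design)
    missing = [i for i, g in enumerate(sample_groups + background_groups) if len(g) == 0]
    if missing:
        raise ValueError(
            "build_distributions: design lacks required condition groups "
            "(untreated, kainate and vehicle at 1/4/8 h)"
        )
    Fnp = scores.F.to_numpy(dtype=float)
    F_s = np.array([all_sample_score(row, sample_groups) for row in Fnp])
    F_0 = np.array([all_sample_score(row, background_groups) for row in Fnp])
    out = pd.DataFrame(
        {
            "probeset_id": scores.F.index,
            "transcript_id": scores.transcript_of.reindex(scores.F.index).to_numpy(),
            "F_s": F_s,
            "F_0": F_0,
        }
    )
    return out.sort_values(["F_s", "probeset_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def empirical_fdr(F_s: np.ndarray, F_0: np.ndarray) -> pd.DataFrame:
    """Plug-in FDR: threshold both lists at each probeset's F_s.

    p_s >= 1/N by construction (every probeset's own score meets its own
    threshold), so the ratio never divides by zero.
    """
    F_s = np.asarray(F_s, dtype=float)
    F_0 = np.asarray(F_0, dtype=float)
    if F_s.shape != F_0.shape or F_s.ndim != 1 or F_s.size < 1:
        raise ValueError("empirical_fdr needs two equal-length nonempty vectors")
    N = F_s.size
    ss = np.sort(F_s)
    s0 = np.sort(F_0)
    # count >= tau via searchsorted on the sorted arrays
    p_s = (N - np.searchsorted(ss, F_s, side="left")) / N
    p_0 = (N - np.searchsorted(s0, F_s, side="left")) / N
    return pd.DataFrame({"p_s": p_s, "p_0": p_0, "fdr": p_0 / p_s})


def call_spliced(results: pd.DataFrame, cutoff: float = 0.10) -> pd.DataFrame:
    """Threshold the empirical FDR; output sorted by descending F_s."""
    out = results.copy()
    out["call"] = out["fdr"] <= cutoff
    return out.sort_values(["F_s", "probeset_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


@dataclass
class FirmaResults:
    """Probeset-level splice calls with their score provenance.

    ``table`` has one row per scored probeset (F_s, F_0, p_s, p_0, fdr,
    call); ``scores`` is the full probeset×sample F matrix.
    """

    table: pd.DataFrame
    scores: FirmaScores
    cutoff: float = 0.10

    @property
    def called(self) -> set[str]:
        return set(self.table.loc[self.table["call"], "probeset_id"])

    def heatmap_table(self, floor: float = 2.0 ** -10) -> pd.DataFrame:
        """log2-scale F matrix of the called probesets (scores clipped at
        ``floor`` before the transform, mirroring the log-scale heatmap
        display convention)."""
        called = self.table.loc[self.table["call"], "probeset_id"]
        sub = self.scores.F.loc[called]
        return np.log2(sub.clip(lower=floor))

    def summary(self) -> str:
        return "\n".join(
            [
                "FIRMA all-sample splice scoring",
                f"  probesets scored : {len(self.table)}",
                f"  FDR cutoff       : {self.cutoff}",
                f"  probesets called : {len(self.called)}",
            ]
        )


class FirmaModel:
    """FIRMA scoring model over an expression summary.

    Parameters
    ----------
    summary : ExpressionSummary
        Output of :func:`exonuse.preprocess.summarize` (transcript-level
        residual matrices are required).
    design : DataFrame
        Sample sheet frame; must contain untreated, vehicle and kainate
        samples at the canonical timepoints.
    retained : set of str, optional
        Transcript restriction; defaults to expression above the global
        median in at least half the samples.
    """

    def __init__(
        self,
        summary: ExpressionSummary,
        design: pd.DataFrame,
        retained: set[str] | None = None,
    ):
        self.summary = summary
        self.design = design
        self.retained = retained

    def fit(self, cutoff: float = 0.10) -> FirmaResults:
        scores = firma_scores(self.summary, self.retained)
        if len(scores.F) == 0:
            table = pd.DataFrame(
                columns=["probeset_id", "transcript_id", "F_s", "F_0",
                         "p_s", "p_0", "fdr", "call"]
            )
            return FirmaResults(table=table, scores=scores, cutoff=cutoff)
        dist = build_distributions(scores, self.design)
        fdr = empirical_fdr(dist["F_s"].to_numpy(), dist["F_0"].to_numpy())
        table = call_spliced(pd.concat([dist, fdr], axis=1), cutoff=cutoff)
        return FirmaResults(table=table, scores=scores, cutoff=cutoff)
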
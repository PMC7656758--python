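"""RMA-style preprocessing for exon arrays.

Three stages mirror the robust multichip average: an optional percentile
shift as background handling, quantile normalization so every array
shares one empirical intensity distribution, and Tukey median polish to
summarize probes to probeset- and transcript-level log2 expression.  The
transcript-level polish additionally yields the per-probe residual
matrices that the FIRMA scorer consumes, plus the median-expression
transcript filter and the per-exon log2-ratio profiles used for
gene-level reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ExonArrayDataset, TIMEPOINTS

log = logging.getLogger(__name__)

#: floor applied after the percentile shift, in linear units
BACKGROUND_FLOOR = 2.0 ** -10


@dataclass
class ExpressionSummary:
    """Probeset- and transcript-level log2 expression with polish leftovers.

    ``residuals[tid]`` and ``probe_effects[tid]`` come from one additive
    (median polish) fit of all the transcript's probes; chip effect +
    probe effect + residual reconstructs the normalized log2 intensity
    exactly.
    """

    probeset_expr: pd.DataFrame
    transcript_expr: pd.DataFrame
    residuals: dict[str, pd.DataFrame] = field(default_factory=dict)
    probe_effects: dict[str, pd.Series] = field(default_factory=dict)
    probeset_transcript: pd.Series | None = None  # probeset_id -> transcript_id
    probeset_order: pd.Series | None = None  # probeset_id -> 5'->3' rank
    probe_probeset: pd.Series | None = None  # probe_id -> probeset_id


def background_correct(
    ds: ExonArrayDataset, method: str = "none", q: float = 0.01
) -> ExonArrayDataset:
    """Subtract a per-sample low percentile from linear intensities.

    ``method="shift"`` subtracts each sample's q-th percentile (linear
    interpolation) and floors at ``BACKGROUND_FLOOR``; ``"none"`` passes
    through.  A full convolution background model is deliberately not
    fitted — the downstream splice statistics are invariant to it.
    """
    if ds.scale != "linear":
        raise ValueError("background_correct expects linear-scale intensities")
    if method == "none":
        return ds
    if method != "shift":
        raise ValueError(f"unknown background method {method!r}")
    X = ds.intensities.to_numpy(dtype=float)
    shifted = X - np.quantile(X, q, axis=0, keepdims=True)
    shifted = np.maximum(shifted, BACKGROUND_FLOOR)
    out = pd.DataFrame(shifted, index=ds.intensities.index, columns=ds.intensities.columns)
    return ExonArrayDataset(ds.annotation, ds.design, out, scale="linear")


def quantile_normalize(ds: ExonArrayDataset) -> ExonArrayDataset:
    """Force every sample onto the common (mean-of-sorted) distribution.

    Linear input is log2-transformed first.  Ties within a column share
    the mean of the quantile values their ranks would have received, so
    the map is well defined and permutation-equivariant.
    """
    X = ds.intensities.to_numpy(dtype=float)
    if ds.scale == "linear":
        X = np.log2(X)
    if X.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning log2 input")
        out = pd.DataFrame(X, index=ds.intensities.index, columns=ds.intensities.columns)
        return ExonArrayDataset(ds.annotation, ds.design, out, scale="log2")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = np.empty(n)
        col[order[:, j]] = ref
        # ties: average the reference values assigned to equal inputs
        vals = X[:, j]
        uniq, inv, counts = np.unique(vals, return_inverse=True, return_counts=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col)
            col = (sums / counts)[inv]
        out[:, j] = col
    outdf = pd.DataFrame(out, index=ds.intensities.index, columns=ds.intensities.columns)
    return ExonArrayDataset(ds.annotation, ds.design, outdf, scale="log2")


def median_polish_fit(
    log2_probes: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a probes×samples log2 matrix.

    Returns ``(chip_effects, probe_effects, residuals)`` where
    ``chip_effects`` (overall + per-sample effect) are the summarized
    expression values.  The decomposition is exact by construction:
    ``chip[s] + probe[p] + residual[p, s]`` equals the input cellwise.
    Iteration stops when no cell changes by more than ``tol``.
    """
    x = np.asarray(log2_probes, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("median_polish_fit needs a 2-D matrix with >=1 probe")
    if x.shape[1] < 2:
        raise ValueError("median_polish_fit needs >=2 samples")
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(max_iter):
        before = resid.copy()
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        shift = np.median(col)
        overall += shift
        col -= shift
        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        shift = np.median(row)
        overall += shift
        row -= shift
        if np.max(np.abs(resid - before)) <= tol:
            break
    chip = overall + col
    return chip, row, resid


def summarize(ds: ExonArrayDataset) -> ExpressionSummary:
    """Median-polish every probeset and transcript of a normalized dataset.

    One polish per probeset gives probeset-level expression; one polish
    per transcript over all its probes gives transcript expression and
    the residual matrices kept for FIRMA scoring.  Transcript processing
    order does not affect any output.
    """
    if ds.scale != "log2":
        raise ValueError("summarize expects a quantile-normalized log2 dataset")
    ann = ds.annotation
    X = ds.intensities.to_numpy(dtype=float)
    samples = list(ds.intensities.columns)
    probe_pos = {p: i for i, p in enumerate(ds.intensities.index)}
    rows_ps: list[np.ndarray] = []
    idx_ps: list[str] = []
    rows_tx: list[np.ndarray] = []
    idx_tx: list[str] = []
    residuals: dict[str, pd.DataFrame] = {}
    probe_effects: dict[str, pd.Series] = {}

    for tid, tann in ann.groupby("transcript_id", sort=True):
        if len(tann) == 0:  # pragma: no cover - defensive
            log.info("transcript %s has no probes after filtering; skipped", tid)
            continue
        for ps, pann in tann.groupby("probeset_id", sort=True):
            rows = [probe_pos[p] for p in pann["probe_id"]]
            chip, _, _ = median_polish_fit(X[rows])
            rows_ps.append(chip)
            idx_ps.append(ps)
        rows = [probe_pos[p] for p in tann["probe_id"]]
        chip, probe_eff, resid = median_polish_fit(X[rows])
        rows_tx.append(chip)
        idx_tx.append(tid)
        residuals[tid] = pd.DataFrame(
            resid, index=tann["probe_id"].to_numpy(), columns=samples
        )
        probe_effects[tid] = pd.Series(probe_eff, index=tann["probe_id"].to_numpy())

    ps_map = ann.drop_duplicates("probeset_id").set_index("probeset_id")
    return ExpressionSummary(
        probeset_expr=pd.DataFrame(rows_ps, index=idx_ps, columns=samples),
        transcript_expr=pd.DataFrame(rows_tx, index=idx_tx, columns=samples),
        residuals=residuals,
        probe_effects=probe_effects,
        probeset_transcript=ps_map["transcript_id"],
        probeset_order=ps_map["probeset_order"],
        probe_probeset=ann.set_index("probe_id")["probeset_id"],
    )


def median_expression_filter(summary: ExpressionSummary) -> set[str]:
    """Transcripts whose mean log2 expression sits strictly above the
    median of all transcripts' means."""
    if len(summary.transcript_expr) < 2:
        raise ValueError("median_expression_filter needs >=2 transcripts")
    means = summary.transcript_expr.mean(axis=1)
    med = float(np.median(means.to_numpy()))
    retained = set(means.index[means > med])
    if not retained:
        warnings.warn("median_expression_filter retained no transcripts")
    return retained


def exon_profiles(
    summary: ExpressionSummary,
    design: pd.DataFrame,
    retained: set[str] | None = None,
) -> pd.DataFrame:
    """Per-exon log2 ratios: mean(kainate at t) − mean(all controls).

    Untreated and vehicle samples are pooled as the reference.  Returns a
    long table (transcript_id, probeset_id, probeset_order, ratio_1h,
    ratio_4h, ratio_8h) with probesets in 5'→3' order; a timepoint with
    no kainate samples yields NaN in its column.
    """
    expr = summary.probeset_expr
    treatment = design["treatment"].to_numpy()
    time_h = design["time_h"].to_numpy()
    ctrl_cols = np.flatnonzero(treatment != "kainate")
    ctrl_mean = expr.iloc[:, ctrl_cols].mean(axis=1)
    ratios = {}
    for t in TIMEPOINTS:
        ka_cols = np.flatnonzero((treatment == "kainate") & (time_h == t))
        if len(ka_cols) == 0:
            ratios[f"ratio_{t}h"] = pd.Series(np.nan, index=expr.index)
        else:
            ratios[f"ratio_{t}h"] = expr.iloc[:, ka_cols].mean(axis=1) - ctrl_mean
    out = pd.DataFrame(ratios)
    out.insert(0, "probeset_id", out.index)
    out.insert(0, "transcript_id", summary.probeset_transcript.reindex(out.index).to_numpy())
    out.insert(2, "probeset_order", summary.probeset_order.reindex(out.index).to_numpy())
    if retained is not None:
        out = out[out["transcript_id"].isin(retained)]
    out = out.sort_values(["transcript_id", "probeset_order"]).reset_index(drop=True)
    return out
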
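"""Sample-level quality control: correlation of the most variable
transcripts and a principal-component overview of the samples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class QCReport:
    correlation: pd.DataFrame
    pc_scores: pd.DataFrame
    pc_variance_fraction: np.ndarray


def top_sd_correlation(transcript_expr: pd.DataFrame, top_n: int = 1000) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples over the ``top_n``
    transcripts with the highest across-sample standard deviation.

    Ties in the SD ranking are broken by transcript_id so the selected
    set is deterministic.  A sample with zero variance over the selected
    rows gets NaN correlations.
    """
    if transcript_expr.shape[1] < 2:
        raise ValueError("top_sd_correlation needs >=2 samples")
    if top_n < 2:
        raise ValueError("top_n must be >=2")
    sd = transcript_expr.std(axis=1, ddof=1)
    # descending SD, ties broken by transcript_id ascending
    order = np.lexsort((sd.index.to_numpy(), -sd.to_numpy()))
    chosen = sd.index[order][: min(top_n, len(sd))]
    sub = transcript_expr.loc[chosen].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    return pd.DataFrame(corr, index=transcript_expr.columns, columns=transcript_expr.columns)


def pca_scores(expr_subset: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance fractions from an SVD of the centered
    sample×transcript matrix.

    Components are ordered by explained variance; each component's sign
    is fixed so its first nonzero transcript loading is positive.
    """
    if expr_subset.shape[1] < 2:
        raise ValueError("pca_scores needs >=2 samples")
    # samples as observations, transcripts as variables
    M = expr_subset.to_numpy(dtype=float).T
    M = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    for k in range(Vt.shape[0]):
        nz = np.flatnonzero(np.abs(Vt[k]) > 1e-12)
        if len(nz) and Vt[k, nz[0]] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * S
    var = S ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=expr_subset.columns, columns=cols), frac


def qc_report(transcript_expr: pd.DataFrame, top_n: int = 1000,
              pca_subset: pd.DataFrame | None = None) -> QCReport:
    """Run both QC views; PCA defaults to the same expression matrix but
    accepts a restricted transcript set (e.g. the DE-significant genes)."""
    corr = top_sd_correlation(transcript_expr, top_n=top_n)
    scores, frac = pca_scores(pca_subset if pca_subset is not None else transcript_expr)
    return QCReport(correlation=corr, pc_scores=scores, pc_variance_fraction=frac)
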
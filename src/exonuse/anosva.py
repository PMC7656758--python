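"""Time-dependent ANOSVA: probe-level interaction tests for
differential exon usage over a treatment time course.

Each gene's probe log2 intensities are modelled as

    y_peth = mu + alpha_e + beta_t + delta_h + gamma_eth + eps_peth

with probeset main effects alpha_e, treatment and time main effects, and
a probeset×treatment×time interaction gamma_eth whose nonzero entries
signal exon-level departures from the gene's overall regulation.  Under
the pooled design — all control samples (untreated and vehicle,
regardless of collection time) treated as one condition at time 0, and
kainate samples observed only at 1/4/8 h — beta_t and delta_h are
confounded, so the model is fitted with a single 4-level condition
factor {control, KA1, KA4, KA8} spanning the same column space.  The
design is then a saturated probeset×condition layout, so the OLS
coefficients are cell-mean contrasts and are computed in closed form;
an independent ``lstsq`` route exists in the test suite.

Each interaction coefficient gets a marginal t-test against the gene's
pooled residual variance; the within-gene minimum of Holm-adjusted
interaction p-values is the gene-level p, which is Benjamini–Hochberg
adjusted across genes and thresholded at FDR 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CONDITIONS, ExonArrayDataset
from .gene_de import adjust_bh, adjust_holm

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# presence filtering

def probeset_presence(
    ds: ExonArrayDataset, present_quantile: float = 0.25
) -> pd.DataFrame:
    """Boolean probeset×sample presence matrix.

    A probeset is "present" in a sample when its mean log2 probe
    intensity exceeds the ``present_quantile`` quantile of all probeset
    means in that sample — a monotone, annotation-free surrogate for
    detection-above-background calls.
    """
    means = ds.intensities.groupby(ds.annotation.set_index("probe_id")["probeset_id"]).mean()
    thresh = np.quantile(means.to_numpy(), present_quantile, axis=0)
    return means.gt(thresh, axis=1)


def _treatment_groups(design: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sample-index groups used by the presence rule: pooled controls
    plus the kainate timepoints."""
    treatment = design["treatment"].to_numpy()
    time_h = design["time_h"].to_numpy()
    groups = {"control": np.flatnonzero(treatment != "kainate")}
    for t in (1, 4, 8):
        groups[f"KA{t}"] = np.flatnonzero((treatment == "kainate") & (time_h == t))
    return {k: v for k, v in groups.items() if len(v)}


def presence_filter(
    ds: ExonArrayDataset,
    present_quantile: float = 0.25,
    return_report: bool = False,
):
    """The pre-test filter cascade.

    (i) drop cross-hybridizing probes; (ii) keep probesets present in at
    least half the samples of at least one treatment group (pooled
    controls, KA-1h, KA-4h, KA-8h); (iii) keep transcripts for which, in
    some group, at least half their probesets pass rule (ii); (iv) drop
    transcripts left with fewer than 3 probesets.
    """
    ann = ds.annotation
    clean = ds.subset_probes(ann.loc[~ann["cross_hybridizing"], "probe_id"])
    if clean.n_probes == 0:
        log.warning("presence_filter: no probes left after cross-hyb removal")
        return (clean, pd.DataFrame()) if return_report else clean

    present = probeset_presence(clean, present_quantile)
    groups = _treatment_groups(clean.design)
    pres_np = present.to_numpy()
    # probeset present-in-group: >= half the group's samples
    in_group = {
        g: pres_np[:, idx].sum(axis=1) * 2 >= len(idx) for g, idx in groups.items()
    }
    ps_keep = np.logical_or.reduce(list(in_group.values()))
    ps_keep_s = pd.Series(ps_keep, index=present.index)

    ps_ann = clean.annotation.drop_duplicates("probeset_id").set_index("probeset_id")
    tx_of_ps = ps_ann["transcript_id"]
    # transcript-wise rule (iii): in some group, >= half its probesets present
    tx_keep: dict[str, bool] = {}
    ingroup_df = pd.DataFrame(in_group, index=present.index)
    for tid, ps_ids in tx_of_ps.groupby(tx_of_ps):
        sub = ingroup_df.loc[ps_ids.index]
        n_ps = len(sub)
        tx_keep[tid] = bool((sub.sum(axis=0) * 2 >= n_ps).any())

    keep_ps = set(ps_keep_s.index[ps_keep_s])
    keep_tx = {t for t, k in tx_keep.items() if k}
    ann2 = clean.annotation
    mask = ann2["probeset_id"].isin(keep_ps) & ann2["transcript_id"].isin(keep_tx)
    surviving = ann2.loc[mask]
    # rule (iv): >=3 surviving probesets per transcript
    counts = surviving.groupby("transcript_id")["probeset_id"].nunique()
    final_tx = set(counts.index[counts >= 3])
    out = clean.subset_probes(surviving.loc[surviving["transcript_id"].isin(final_tx), "probe_id"])
    if out.n_probes == 0:
        log.warning("presence_filter: empty dataset after filtering")
    if return_report:
        report = pd.DataFrame(
            {
                "probeset_id": present.index,
                "transcript_id": tx_of_ps.reindex(present.index).to_numpy(),
                "present_any_group": ps_keep,
            }
        )
        return out, report
    return out


# ---------------------------------------------------------------------------
# per-gene fit

@dataclass
class AnosvaFit:
    """Reference-coded OLS fit of one gene's probeset×condition model.

    Reference levels (first probeset in 5'→3' order, control condition)
    carry coefficient 0; ``gamma``/``se`` are (probesets−1)×(conditions−1)
    frames of interaction estimates and standard errors.
    """

    transcript_id: str
    mu: float
    alpha: pd.Series
    beta_delta: pd.Series
    gamma: pd.DataFrame
    se: pd.DataFrame
    sigma_sq: float
    df_resid: int
    cell_means: pd.DataFrame
    n_obs: int


def fit_gene(
    y: np.ndarray,
    probeset_of_probe: np.ndarray,
    condition_of_sample: np.ndarray,
    probeset_levels: list[str],
    condition_levels: list[str],
    transcript_id: str = "",
) -> AnosvaFit:
    """Closed-form OLS of the saturated probeset×condition model.

    ``y`` is the probes×samples log2 matrix; levels list the reference
    level first.  Because the model is saturated, fitted values are the
    cell means and each interaction coefficient is the double difference
    (e, c) − (e, ref) − (ref, c) + (ref, ref); the residual variance is
    pooled within cells with df = N − (#probesets × #conditions).
    """
    E, C = len(probeset_levels), len(condition_levels)
    y = np.asarray(y, dtype=float)
    row_idx = {e: i for i, e in enumerate(probeset_levels)}
    col_idx = {c: j for j, c in enumerate(condition_levels)}
    ri = np.array([row_idx[e] for e in probeset_of_probe])
    ci = np.array([col_idx[c] for c in condition_of_sample])
    # one-hot aggregation: cell sums and counts via two small matmuls
    P = np.zeros((E, y.shape[0]))
    P[ri, np.arange(y.shape[0])] = 1.0
    Q = np.zeros((y.shape[1], C))
    Q[np.arange(y.shape[1]), ci] = 1.0
    counts = (P @ np.ones(y.shape) @ Q).round().astype(int)
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"gene {transcript_id}: empty cell (probeset {probeset_levels[i]}, "
            f"condition {condition_levels[j]})"
        )
    sums = P @ y @ Q
    means = sums / counts
    sq = P @ (y * y) @ Q
    sse = float((sq - counts * means ** 2).sum())
    n = int(counts.sum())
    df = n - E * C
    if df <= 0:
        raise ValueError(f"gene {transcript_id}: nonpositive residual df ({df})")
    sigma_sq = sse / df

    mu = means[0, 0]
    alpha = pd.Series(means[1:, 0] - mu, index=probeset_levels[1:])
    beta_delta = pd.Series(means[0, 1:] - mu, index=condition_levels[1:])
    gamma = means[1:, 1:] - means[1:, :1] - means[:1, 1:] + mu
    inv_n = 1.0 / counts
    var = sigma_sq * (inv_n[1:, 1:] + inv_n[1:, :1] + inv_n[:1, 1:] + inv_n[0, 0])
    return AnosvaFit(
        transcript_id=transcript_id,
        mu=float(mu),
        alpha=alpha,
        beta_delta=beta_delta,
        gamma=pd.DataFrame(gamma, index=probeset_levels[1:], columns=condition_levels[1:]),
        se=pd.DataFrame(np.sqrt(var), index=probeset_levels[1:], columns=condition_levels[1:]),
        sigma_sq=float(sigma_sq),
        df_resid=int(df),
        cell_means=pd.DataFrame(means, index=probeset_levels, columns=condition_levels),
        n_obs=n,
    )


def interaction_pvalues(fit: AnosvaFit) -> pd.DataFrame:
    """Two-sided p per interaction coefficient from t = gamma/se with the
    fit's residual df.

    A degenerate zero residual variance yields p = 0 for nonzero gamma
    and p = 1 otherwise.
    """
    g = fit.gamma.to_numpy()
    se = fit.se.to_numpy()
    if fit.sigma_sq <= 0:
        log.info("gene %s: zero residual variance", fit.transcript_id)
        p = np.where(np.abs(g) > 0, 0.0, 1.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = g / se
        p = 2.0 * stats.t.sf(np.abs(tstat), fit.df_resid)
    rows = []
    for i, e in enumerate(fit.gamma.index):
        for j, c in enumerate(fit.gamma.columns):
            rows.append((fit.transcript_id, e, c, g[i, j], se[i, j], float(p[i, j])))
    return pd.DataFrame(
        rows, columns=["transcript_id", "probeset_id", "condition", "gamma", "se", "p"]
    )


def gene_level_call(
    terms_by_gene: dict[str, pd.DataFrame], fdr: float = 0.05
) -> pd.DataFrame:
    """Holm within gene, min as gene-level p, BH across genes, call at fdr.

    The reported top probeset/condition is the raw-p argmin, ties broken
    by probeset then condition order as the term tables are ordered.
    """
    if not terms_by_gene:
        raise ValueError("gene_level_call needs at least one gene")
    rows = []
    for tid, terms in terms_by_gene.items():
        holm = adjust_holm(terms["p"].to_numpy())
        k = int(np.argmin(terms["p"].to_numpy()))
        rows.append(
            (
                tid,
                float(holm.min()),
                terms["probeset_id"].iloc[k],
                terms["condition"].iloc[k],
                terms["probeset_id"].nunique() + 1,
                len(terms),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["transcript_id", "p_gene", "top_probeset_id", "top_condition",
                 "n_probesets", "n_terms"],
    )
    out["q_gene"] = adjust_bh(out["p_gene"].to_numpy())
    out["call"] = out["q_gene"] <= fdr
    return out.sort_values(["p_gene", "transcript_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results

@dataclass
class AnosvaResults:
    """Gene-level splice calls plus the per-term ledger.

    ``table``: one row per tested gene (p_gene, q_gene, call, argmin
    term); ``terms``: one row per interaction coefficient with its Holm-
    adjusted p; ``skipped``: genes dropped with the reason.
    """

    table: pd.DataFrame
    terms: pd.DataFrame
    skipped: pd.DataFrame
    fdr: float = 0.05
    timepoint: int | None = None

    @property
    def called(self) -> set[str]:
        return set(self.table.loc[self.table["call"], "transcript_id"])

    def summary(self) -> str:
        label = (
            "time-dependent" if self.timepoint is None
            else f"single timepoint {self.timepoint} h"
        )
        return "\n".join(
            [
                f"ANOSVA ({label}) interaction test",
                f"  genes tested  : {len(self.table)}",
                f"  genes skipped : {len(self.skipped)}",
                f"  FDR cutoff    : {self.fdr}",
                f"  genes called  : {len(self.called)}",
            ]
        )


class TimeDependentAnosva:
    """Interaction-test model over a presence-filtered dataset.

    Parameters
    ----------
    ds : ExonArrayDataset
        Normalized log2 probe-level dataset.
    present_quantile : float
        Quantile defining the presence surrogate (see
        :func:`probeset_presence`).
    timepoint : int, optional
        If given, restricts to control + kainate-at-t samples with a
        two-level condition factor (the original single-timepoint test);
        otherwise the full 4-level condition factor is used.
    apply_filter : bool
        Skip the presence filter when the caller already applied it.
    """

    def __init__(
        self,
        ds: ExonArrayDataset,
        present_quantile: float = 0.25,
        timepoint: int | None = None,
        apply_filter: bool = True,
    ):
        self.present_quantile = present_quantile
        self.timepoint = timepoint
        self.dataset = presence_filter(ds, present_quantile) if apply_filter else ds

    def _conditions(self) -> tuple[ExonArrayDataset, list[str]]:
        ds = self.dataset
        if self.timepoint is None:
            return ds, list(CONDITIONS)
        cond = ds.conditions().to_numpy()
        keep = (cond == "control") | (cond == f"KA{self.timepoint}")
        sub = ExonArrayDataset(
            annotation=ds.annotation,
            design=ds.design.loc[keep].reset_index(drop=True),
            intensities=ds.intensities.loc[:, keep],
            scale=ds.scale,
        )
        return sub, ["control", f"KA{self.timepoint}"]

    def fit(self, fdr: float = 0.05) -> AnosvaResults:
        ds, cond_levels = self._conditions()
        cond = ds.conditions().to_numpy()
        X = ds.intensities.to_numpy(dtype=float)
        probe_pos = {p: i for i, p in enumerate(ds.intensities.index)}
        terms_by_gene: dict[str, pd.DataFrame] = {}
        term_frames: list[pd.DataFrame] = []
        skipped: list[tuple[str, str]] = []
        for tid, tann in ds.annotation.groupby("transcript_id", sort=True):
            ps_levels = list(
                tann.drop_duplicates("probeset_id")
                .sort_values("probeset_order")["probeset_id"]
            )
            rows = [probe_pos[p] for p in tann["probe_id"]]
            y = X[rows]
            ps_of_probe = tann["probeset_id"].to_numpy()
            try:
                fit = fit_gene(y, ps_of_probe, cond, ps_levels, cond_levels, tid)
            except ValueError as exc:
                skipped.append((tid, str(exc)))
                continue
            terms = interaction_pvalues(fit)
            terms["holm_p"] = adjust_holm(terms["p"].to_numpy())
            terms_by_gene[tid] = terms
            term_frames.append(terms)
        if not terms_by_gene:
            table = pd.DataFrame(
                columns=["transcript_id", "p_gene", "top_probeset_id", "top_condition",
                         "n_probesets", "n_terms", "q_gene", "call"]
            )
            terms_all = pd.DataFrame(
                columns=["transcript_id", "probeset_id", "condition", "gamma", "se",
                         "p", "holm_p"]
            )
        else:
            table = gene_level_call(terms_by_gene, fdr=fdr)
            terms_all = pd.concat(term_frames, ignore_index=True)
        return AnosvaResults(
            table=table,
            terms=terms_all,
            skipped=pd.DataFrame(skipped, columns=["transcript_id", "reason"]),
            fdr=fdr,
            timepoint=self.timepoint,
        )


def anosva_single_timepoint(
    ds: ExonArrayDataset, t: int, fdr: float = 0.05, present_quantile: float = 0.25
) -> AnosvaResults:
    """The original per-timepoint test: control vs kainate-at-t only."""
    return TimeDependentAnosva(
        ds, present_quantile=present_quantile, timepoint=t
    ).fit(fdr=fdr)
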
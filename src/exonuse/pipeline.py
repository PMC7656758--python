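"""End-to-end orchestration: load → preprocess → QC → DE → ANOSVA →
FIRMA, writing every interface table plus a run manifest.

Every stage is deterministic given its inputs; the only stochastic step
is the synthetic generator, keyed off the single config seed, so
re-running with identical inputs and configuration reproduces all
outputs byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anosva import TimeDependentAnosva
from .dataio import (
    ExonArrayDataset,
    design_frame,
    load_probe_table,
    load_sample_sheet,
    validate_dataset,
    write_table,
)
from .firma import FirmaModel
from .gene_de import KineticDEModel
from .preprocess import (
    background_correct,
    exon_profiles,
    median_expression_filter,
    quantile_normalize,
    summarize,
)
from .qc import qc_report

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit status 2 in the CLI)."""


class DataError(ValueError):
    """Input data failed validation (exit status 3 in the CLI)."""


@dataclass
class PipelineConfig:
    probe_table: str | None = None
    sample_sheet: str | None = None
    out_dir: str = "exonuse_out"
    scale: str = "log2"
    background: str = "none"      # for linear input: none | shift
    present_quantile: float = 0.25
    anosva_fdr: float = 0.05
    firma_cutoff: float = 0.10
    de_alpha: float = 0.05
    de_lfc_min: float = 0.0
    top_sd_n: int = 1000
    seed: int = 0
    run_qc: bool = True
    run_de: bool = True
    run_anosva: bool = True
    run_firma: bool = True

    def validate(self) -> None:
        for name in ("anosva_fdr", "firma_cutoff", "de_alpha", "present_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0,1), got {v}")
        if self.top_sd_n < 2:
            raise ConfigError("top_sd_n must be >= 2")
        if self.scale not in ("linear", "log2"):
            raise ConfigError(f"scale must be linear or log2, got {self.scale!r}")


def run_pipeline(
    cfg: PipelineConfig, dataset: ExonArrayDataset | None = None
) -> dict:
    """Execute the configured stages and return the run manifest.

    ``dataset`` may be passed directly (e.g. from the synthetic
    generator); otherwise ``cfg.probe_table``/``cfg.sample_sheet`` are
    loaded from disk.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(cfg),
        "stages": {},
        "outputs": [],
        "complete": False,
    }

    def _stage(name: str):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts
            }

        return done

    def _write(name: str, df: pd.DataFrame):
        path = write_table(df, out / name)
        manifest["outputs"].append(name)
        return path

    done = _stage("load")
    if dataset is None:
        if not cfg.probe_table or not cfg.sample_sheet:
            raise ConfigError("probe_table and sample_sheet are required")
        designs = load_sample_sheet(cfg.sample_sheet)
        dataset = load_probe_table(cfg.probe_table, scale=cfg.scale, design=designs)
    report = validate_dataset(dataset)
    if not report.ok:
        raise DataError(f"dataset validation failed: {report.violations}")
    done(n_probes=report.n_probes, n_probesets=report.n_probesets,
         n_transcripts=report.n_transcripts, n_samples=report.n_samples)

    done = _stage("preprocess")
    ds = dataset
    if ds.scale == "linear":
        ds = background_correct(ds, method=cfg.background)
    ds = quantile_normalize(ds)
    summary = summarize(ds)
    retained = median_expression_filter(summary)
    profiles = exon_profiles(summary, ds.design, retained)
    _write("probeset_expr.tsv", summary.probeset_expr.rename_axis("probeset_id").reset_index())
    _write("transcript_expr.tsv", summary.transcript_expr.rename_axis("transcript_id").reset_index())
    _write("retained_transcripts.tsv", pd.DataFrame({"transcript_id": sorted(retained)}))
    _write("exon_profiles.tsv", profiles)
    done(n_retained=len(retained))

    de_res = None
    if cfg.run_de:
        done = _stage("gene_de")
        de_res = KineticDEModel(summary.transcript_expr, ds.design).fit(
            alpha=cfg.de_alpha, lfc_min=cfg.de_lfc_min
        )
        _write("de_results.tsv", de_res.to_frame())
        done(n_significant=len(de_res.significant))

    if cfg.run_qc:
        done = _stage("qc")
        sig = de_res.significant if de_res is not None else None
        subset = (
            summary.transcript_expr.loc[sorted(sig)]
            if sig else summary.transcript_expr
        )
        qc = qc_report(summary.transcript_expr, top_n=cfg.top_sd_n, pca_subset=subset)
        _write("qc_correlation.tsv", qc.correlation.rename_axis("sample_id").reset_index())
        pca = qc.pc_scores.rename_axis("sample_id").reset_index()
        var_row = pd.DataFrame(
            [["__variance_fraction__", *qc.pc_variance_fraction]], columns=pca.columns
        )
        _write("qc_pca.tsv", pd.concat([pca, var_row], ignore_index=True))
        done()

    if cfg.run_anosva:
        done = _stage("anosva")
        anosva_res = TimeDependentAnosva(ds, present_quantile=cfg.present_quantile).fit(
            fdr=cfg.anosva_fdr
        )
        _write("anosva_results.tsv", anosva_res.table)
        _write("anosva_terms.tsv", anosva_res.terms)
        _write("anosva_skipped.tsv", anosva_res.skipped)
        done(n_tested=len(anosva_res.table), n_called=len(anosva_res.called),
             n_skipped=len(anosva_res.skipped))

    if cfg.run_firma:
        done = _stage("firma")
        firma_res = FirmaModel(summary, ds.design).fit(cutoff=cfg.firma_cutoff)
        table = firma_res.table.copy()
        order = summary.probeset_order
        table.insert(2, "exon_order", order.reindex(table["probeset_id"]).to_numpy())
        F = firma_res.scores.F.reindex(table["probeset_id"])
        for col in F.columns:
            table[f"F_{col}"] = F[col].to_numpy()
        _write("firma_results.tsv", table)
        heat = firma_res.heatmap_table()
        _write("firma_heatmap.tsv", heat.rename_axis("probeset_id").reset_index())
        done(n_scored=len(table), n_called=len(firma_res.called))

    manifest["complete"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def report_gene(
    transcript_id: str,
    ds_normalized: ExonArrayDataset,
    summary,
    profiles: pd.DataFrame,
    anosva_table: pd.DataFrame | None = None,
    firma_table: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Three tabular views of one gene — probe-level intensities,
    probeset-level expression and per-exon log2 ratios — plus its splice
    test rows."""
    ann = ds_normalized.annotation
    mask = ann["transcript_id"] == transcript_id
    if not mask.any():
        raise KeyError(f"unknown transcript {transcript_id!r}")
    probes = ann.loc[mask]
    probe_view = probes.merge(
        ds_normalized.intensities.rename_axis("probe_id").reset_index(), on="probe_id"
    )
    ps_ids = probes["probeset_id"].unique()
    probeset_view = (
        summary.probeset_expr.loc[[p for p in ps_ids if p in summary.probeset_expr.index]]
        .rename_axis("probeset_id")
        .reset_index()
    )
    ratio_view = profiles.loc[profiles["transcript_id"] == transcript_id].copy()
    out = {
        "probes": probe_view,
        "probesets": probeset_view,
        "ratios": ratio_view,
    }
    if anosva_table is not None:
        out["anosva"] = anosva_table.loc[
            anosva_table["transcript_id"] == transcript_id
        ].copy()
    if firma_table is not None:
        out["firma"] = firma_table.loc[
            firma_table["transcript_id"] == transcript_id
        ].copy()
    return out
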
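import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonuse.anosva import (
    TimeDependentAnosva,
    anosva_single_timepoint,
    fit_gene,
    gene_level_call,
    interaction_pvalues,
    presence_filter,
)
from exonuse.dataio import CONDITIONS
from exonuse.preprocess import quantile_normalize
from exonuse.synthdata import GeneratorConfig, generate_dataset


def _gene(E=3, probes=4, conditions=("control",) * 10 + ("KA1",) * 3 + ("KA4",) * 3 + ("KA8",) * 3):
    """Helper layout: E probesets x `probes` probes, canonical-ish samples."""
    cond = np.array(conditions)
    ps = np.repeat([f"ps{i}" for i in range(E)], probes)
    levels = [f"ps{i}" for i in range(E)]
    return ps, cond, levels


def _ols_oracle(y, ps_of_probe, cond_of_sample, ps_levels, cond_levels):
    """Independent reference-coded OLS via explicit design matrix."""
    rows = []
    obs = []
    for i, e in enumerate(ps_of_probe):
        for j, c in enumerate(cond_of_sample):
            obs.append(y[i, j])
            x = [1.0]
            x += [1.0 if e == lev else 0.0 for lev in ps_levels[1:]]
            x += [1.0 if c == lev else 0.0 for lev in cond_levels[1:]]
            for pe in ps_levels[1:]:
                for cc in cond_levels[1:]:
                    x.append(1.0 if (e == pe and c == cc) else 0.0)
            rows.append(x)
    X = np.array(rows)
    yv = np.array(obs)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df = len(yv) - X.shape[1]
    sigma_sq = (resid ** 2).sum() / df
    cov = sigma_sq * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    k0 = 1 + (len(ps_levels) - 1) + (len(cond_levels) - 1)
    gamma = beta[k0:]
    gamma_se = se[k0:]
    p = 2 * stats.t.sf(np.abs(gamma / gamma_se), df)
    return gamma, gamma_se, p, sigma_sq, df


class TestPresenceFilter:
    def test_two_probeset_transcript_removed(self):
        cfg = GeneratorConfig(n_transcripts=20, seed=1, probesets_per_transcript=(4, 6),
                              frac_absent_probesets=0.0, frac_crosshyb=0.0)
        ds, _ = generate_dataset(cfg)
        ann = ds.annotation
        tid = ann["transcript_id"].iloc[0]
        keep_ps = sorted(ann.loc[ann["transcript_id"] == tid, "probeset_id"].unique())[:2]
        drop = ann[(ann["transcript_id"] == tid) & ~ann["probeset_id"].isin(keep_ps)]
        trimmed = ds.subset_probes(
            [p for p in ann["probe_id"] if p not in set(drop["probe_id"])]
        )
        out = presence_filter(trimmed)
        assert tid not in set(out.annotation["transcript_id"])

    def test_cross_hybridizing_probes_dropped(self):
        cfg = GeneratorConfig(n_transcripts=20, seed=2, frac_crosshyb=0.2,
                              frac_absent_probesets=0.0)
        ds, truth = generate_dataset(cfg)
        out = presence_filter(ds)
        xh = set(truth.probes.loc[truth.probes["cross_hybridizing"], "probe_id"])
        assert xh.isdisjoint(set(out.annotation["probe_id"]))

    def test_absent_probesets_exactly_removed(self):
        cfg = GeneratorConfig(n_transcripts=300, seed=3, frac_de=0.0, frac_spliced=0.0,
                              frac_absent_probesets=0.10, frac_crosshyb=0.0,
                              baseline_mu=(8.0, 12.0))
        ds, truth = generate_dataset(cfg)
        _, report = presence_filter(ds, present_quantile=0.10, return_report=True)
        removed = set(report.loc[~report["present_any_group"], "probeset_id"])
        absent = set(truth.probesets.loc[truth.probesets["absent"], "probeset_id"])
        assert removed == absent


class TestFitGene:
    def test_parallel_probesets_zero_interaction(self):
        ps, cond, levels = _gene(E=3)
        shift = {"control": 0.0, "KA1": 1.0, "KA4": 2.0, "KA8": 0.5}
        y = np.array([[5.0 + shift[c] for c in cond] for _ in ps])
        fit = fit_gene(y, ps, cond, levels, list(CONDITIONS))
        np.testing.assert_allclose(fit.gamma.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.sigma_sq, 0.0, atol=1e-12)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(7)
        ps, cond, levels = _gene(E=4)
        y = rng.normal(8, 1, size=(len(ps), len(cond)))
        fit = fit_gene(y, ps, cond, levels, list(CONDITIONS))
        gamma, se, p, sigma_sq, df = _ols_oracle(y, ps, cond, levels, list(CONDITIONS))
        np.testing.assert_allclose(fit.gamma.to_numpy().ravel(), gamma, atol=1e-9)
        np.testing.assert_allclose(fit.se.to_numpy().ravel(), se, atol=1e-9)
        np.testing.assert_allclose(fit.sigma_sq, sigma_sq, atol=1e-10)
        assert fit.df_resid == df
        terms = interaction_pvalues(fit)
        np.testing.assert_allclose(terms["p"].to_numpy(), p, atol=1e-9)

    def test_injected_interaction_is_top_term(self):
        rng = np.random.default_rng(8)
        ps, cond, levels = _gene(E=3)
        y = rng.normal(8, 0.2, size=(len(ps), len(cond)))
        target = (ps == "ps1")[:, None] & (cond == "KA4")[None, :]
        y = y + 3.0 * target
        fit = fit_gene(y, ps, cond, levels, list(CONDITIONS))
        terms = interaction_pvalues(fit)
        top = terms.iloc[terms["p"].argmin()]
        assert (top["probeset_id"], top["condition"]) == ("ps1", "KA4")
        assert abs(top["gamma"]) == terms["gamma"].abs().max()

    def test_reconstruction_from_coefficients(self):
        rng = np.random.default_rng(9)
        ps, cond, levels = _gene(E=3)
        y = rng.normal(size=(len(ps), len(cond)))
        fit = fit_gene(y, ps, cond, levels, list(CONDITIONS))
        # mu + alpha + beta_delta + gamma reconstructs every cell mean
        for e in levels:
            for c in CONDITIONS:
                val = fit.mu
                if e != levels[0]:
                    val += fit.alpha[e]
                if c != "control":
                    val += fit.beta_delta[c]
                if e != levels[0] and c != "control":
                    val += fit.gamma.loc[e, c]
                np.testing.assert_allclose(val, fit.cell_means.loc[e, c], atol=1e-10)

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(10)
        ps, cond, levels = _gene(E=3)
        y = rng.normal(size=(len(ps), len(cond)))
        fit1 = fit_gene(y, ps, cond, levels, list(CONDITIONS))
        perm = rng.permutation(len(cond))
        fit2 = fit_gene(y[:, perm], ps, cond[perm], levels, list(CONDITIONS))
        pd.testing.assert_frame_equal(fit1.gamma, fit2.gamma)

    def test_empty_cell_rejected(self):
        ps, cond, levels = _gene(E=3)
        cond = np.where(cond == "KA8", "KA4", cond)  # no KA8 samples
        y = np.zeros((len(ps), len(cond)))
        with pytest.raises(ValueError, match="KA8"):
            fit_gene(y, ps, cond, levels, list(CONDITIONS))


class TestInteractionPvalues:
    def test_zero_gamma_gives_p_one(self):
        ps, cond, levels = _gene(E=3)
        rng = np.random.default_rng(11)
        noise = rng.normal(0, 0.5, size=(len(ps), len(cond)))
        # symmetrize so cell means are exactly equal: use pure noise fit then zero gammas
        y = np.zeros((len(ps), len(cond))) + noise - noise  # exact zeros
        y += rng.normal(size=(1, len(cond)))  # condition shifts only
        fit = fit_gene(y, ps, cond, levels, list(CONDITIONS))
        terms = interaction_pvalues(fit)
        np.testing.assert_allclose(terms["gamma"], 0.0, atol=1e-12)
        # degenerate zero-variance fit: zero gamma reports p = 1
        np.testing.assert_allclose(terms["p"], 1.0)

    def test_null_pvalues_uniform(self):
        cfg = GeneratorConfig(
            n_transcripts=500, seed=7, frac_de=0.0, frac_spliced=0.0,
            frac_absent_probesets=0.0, frac_crosshyb=0.0,
            probe_affinity_sd=0.0, noise_sd=0.25,
        )
        ds, _ = generate_dataset(cfg)
        res = TimeDependentAnosva(quantile_normalize(ds)).fit()
        p = res.terms["p"].to_numpy()
        assert len(p) > 5000
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestGeneLevelCall:
    def test_holm_hand_example(self):
        terms = pd.DataFrame(
            {
                "transcript_id": ["g1", "g1"],
                "probeset_id": ["ps1", "ps2"],
                "condition": ["KA1", "KA4"],
                "gamma": [1.0, 0.5],
                "se": [0.1, 0.1],
                "p": [0.01, 0.04],
            }
        )
        out = gene_level_call({"g1": terms}, fdr=0.05)
        np.testing.assert_allclose(out["p_gene"].iloc[0], 0.02)

    def test_single_gene_single_term(self):
        terms = pd.DataFrame(
            {
                "transcript_id": ["g1"], "probeset_id": ["ps1"],
                "condition": ["KA1"], "gamma": [0.1], "se": [0.2], "p": [0.5],
            }
        )
        out = gene_level_call({"g1": terms}, fdr=0.05)
        assert out["p_gene"].iloc[0] == 0.5
        assert out["q_gene"].iloc[0] == 0.5
        assert not out["call"].iloc[0]

    def test_argmin_term_reported(self):
        rng = np.random.default_rng(12)
        cfg = GeneratorConfig(
            n_transcripts=50, seed=13, frac_de=0.0, frac_spliced=0.2,
            splice_effect=3.0, noise_sd=0.2, frac_absent_probesets=0.0,
            frac_crosshyb=0.0, splice_conditions=("KA4",),
        )
        ds, truth = generate_dataset(cfg)
        res = TimeDependentAnosva(quantile_normalize(ds)).fit()
        called = res.table[res.table["call"]]
        spliced_ps = truth.spliced_probesets
        # for called genes the argmin term should usually be the spliced probeset
        hit = called["top_probeset_id"].isin(spliced_ps)
        assert hit.mean() >= 0.8
        assert (called["top_condition"] == "KA4").mean() >= 0.8


class TestSingleTimepoint:
    def test_effect_at_4h_called_at_4_not_1(self):
        cfg = GeneratorConfig(
            n_transcripts=100, seed=21, frac_de=0.0, frac_spliced=0.10,
            splice_effect=3.0, noise_sd=0.2, splice_conditions=("KA4",),
            frac_absent_probesets=0.0, frac_crosshyb=0.0,
        )
        ds, truth = generate_dataset(cfg)
        dsn = quantile_normalize(ds)
        td = TimeDependentAnosva(dsn).fit()
        at4 = anosva_single_timepoint(dsn, 4)
        at1 = anosva_single_timepoint(dsn, 1)
        spliced = truth.spliced_transcripts & set(td.table["transcript_id"])
        assert spliced  # effect present and testable
        assert spliced <= td.called
        assert spliced <= at4.called
        assert not (spliced & at1.called)

    def test_single_timepoint_calls_subset_of_time_dependent(self):
        ok = 0
        for seed in range(1, 11):
            cfg = GeneratorConfig(
                n_transcripts=150, seed=seed, frac_de=0.0, frac_spliced=0.10,
                splice_effect=3.0, noise_sd=0.2,
                frac_absent_probesets=0.0, frac_crosshyb=0.0,
            )
            ds, _ = generate_dataset(cfg)
            dsn = quantile_normalize(ds)
            td_calls = TimeDependentAnosva(dsn).fit().called
            single = set()
            for t in (1, 4, 8):
                single |= anosva_single_timepoint(dsn, t).called
            ok += single <= td_calls
        assert ok >= 9


class TestPowerMonotonicity:
    def test_power_nondecreasing_in_effect(self):
        power = []
        for effect in (0.5, 1.0, 2.0):
            hits, total = 0, 0
            for seed in (1, 2, 3):
                cfg = GeneratorConfig(
                    n_transcripts=150, seed=seed, frac_de=0.0, frac_spliced=0.10,
                    splice_effect=effect, noise_sd=0.25,
                    frac_absent_probesets=0.0, frac_crosshyb=0.0,
                )
                ds, truth = generate_dataset(cfg)
                res = TimeDependentAnosva(quantile_normalize(ds)).fit()
                tested = set(res.table["transcript_id"])
                pos = truth.spliced_transcripts & tested
                hits += len(res.called & pos)
                total += len(pos)
            power.append(hits / total)
        assert power[0] <= power[1] + 1e-12 <= power[2] + 2e-12
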
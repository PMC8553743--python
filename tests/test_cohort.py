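"""Synthetic cohort, annotation and connectivity generator behavior."""

import numpy as np
import pandas as pd
import pytest

from hicrit import (
    EffectSpec,
    make_node_annotation,
    simulate_connectomes,
    simulate_subjects,
    simulate_timeseries,
)
from hicrit.cohort import REGION_GROUPS, SUBJECT_COLUMNS


class TestSimulateSubjects:
    def test_cohort_marginals_match_configured_values(self):
        df = simulate_subjects(10_000, seed=1)
        assert abs(df["pswq"].mean() - 48.2) < 0.5
        assert abs(df["pswq"].std(ddof=1) - 14.6) < 0.5
        # moment-matched marginals: sample moments within 3 SE of configuration
        n = len(df)
        for col, mean, sd in [
            ("age", 61.8, 8.2), ("education", 16.0, 2.3), ("pss", 13.0, 7.0),
            ("rsq", 37.0, 12.9), ("neo_ffi", 19.2, 9.9),
            ("madrs", 7.4, 7.9), ("hars", 7.4, 5.7), ("cirs_g", 3.7, 3.5),
        ]:
            se_mean = sd / np.sqrt(n)
            # integer rounding perturbs moments by < 0.3/sqrt(12) here
            assert abs(df[col].mean() - mean) < 3 * se_mean + 0.1, col
            assert abs(df[col].std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * n) + 0.1, col
        assert abs((df["sex"] == "F").mean() - 0.62) < 3 * np.sqrt(0.62 * 0.38 / n)
        assert df["race"].value_counts().idxmax() == "W"

    def test_scores_respect_instrument_ranges(self):
        df = simulate_subjects(5_000, seed=3)
        assert df["pswq"].between(16, 80).all()
        assert (df["madrs"] >= 0).all() and (df["hars"] >= 0).all()
        assert (df["cirs_g"] >= 0).all()
        assert not df.isna().any().any()

    def test_empty_cohort_keeps_header(self):
        df = simulate_subjects(0, seed=0)
        assert list(df.columns) == SUBJECT_COLUMNS
        assert len(df) == 0

    def test_fixed_seed_reproduces_identical_tables(self):
        a = simulate_subjects(50, seed=7)
        b = simulate_subjects(50, seed=7)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = simulate_subjects(50, seed=8)
        assert a.to_csv(index=False) != c.to_csv(index=False)

    @pytest.mark.parametrize(
        "n,config",
        [
            (-1, None),
            (10, {"sex": {"p": [0.7, 0.7]}}),
            (10, {"pswq": {"sd": -1.0}}),
        ],
    )
    def test_invalid_inputs_raise(self, n, config):
        with pytest.raises(ValueError):
            simulate_subjects(n, seed=0, config=config)

    def test_psychometric_copula_induces_correlation(self):
        cfg = {
            "psychometric_corr": {
                "vars": ["pswq", "rsq"],
                "matrix": [[1.0, 0.6], [0.6, 1.0]],
            }
        }
        df = simulate_subjects(8_000, seed=9, config=cfg)
        r = np.corrcoef(df["pswq"], df["rsq"])[0, 1]
        assert 0.45 < r < 0.7
        # marginals survive the copula
        assert abs(df["pswq"].mean() - 48.2) < 0.6


class TestNodeAnnotation:
    def test_default_connectome_dimensions(self, annotation212):
        assert len(annotation212) == 212
        counts = annotation212["network"].value_counts()
        assert counts["DMN"] == 79 and counts["ASN"] == 78 and counts["LECN"] == 55
        assert set(annotation212["region_group"]).issubset(set(REGION_GROUPS))
        assert annotation212["node_id"].tolist() == list(range(212))

    def test_minimal_annotation(self):
        df = make_node_annotation({"networks": {"DMN": 1, "ASN": 1, "LECN": 1}})
        assert len(df) == 3
        assert set(df["network"]) == {"DMN", "ASN", "LECN"}

    def test_annotation_is_seed_deterministic(self):
        a = make_node_annotation(seed=4)
        b = make_node_annotation(seed=4)
        assert a.equals(b)

    def test_unknown_network_rejected(self):
        with pytest.raises(ValueError, match="network"):
            make_node_annotation({"networks": {"XYZ": 5}})
        with pytest.raises(ValueError):
            make_node_annotation({"networks": {"DMN": 0}})


class TestSimulateConnectomes:
    def test_noise_free_panel_is_constant_at_baseline(self, cohort77, small_annotation):
        spec = EffectSpec(planted={}, baseline_z=0.4, noise_sd=0.0)
        panel = simulate_connectomes(cohort77, small_annotation, spec, seed=0)
        assert np.allclose(panel.values, 0.4)

    def test_planted_slope_recovered_by_ols(self, small_annotation):
        # oracle: closed-form simple OLS of the planted edge on standardized worry
        subjects = simulate_subjects(2_000, seed=21)
        spec = EffectSpec(planted={10: 0.3}, noise_sd=0.3)
        panel = simulate_connectomes(subjects, small_annotation, spec, seed=22)
        w = subjects["pswq"].to_numpy(float)
        x = (w - w.mean()) / w.std(ddof=1)
        y = panel.values[:, 10]
        xc = x - x.mean()
        slope = (xc @ y) / (xc @ xc)
        resid = y - y.mean() - slope * xc
        se = np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc))
        assert abs(slope - 0.3) < 1.96 * se

    def test_same_seed_reproduces_panel(self, cohort77, small_annotation):
        spec = EffectSpec(planted={3: 0.2})
        a = simulate_connectomes(cohort77, small_annotation, spec, seed=5)
        b = simulate_connectomes(cohort77, small_annotation, spec, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_out_of_range_planted_edge_rejected(self, cohort77, small_annotation):
        spec = EffectSpec(planted={10**6: 0.2})
        with pytest.raises(ValueError, match="out of range"):
            simulate_connectomes(cohort77, small_annotation, spec, seed=0)

    def test_covariate_effect_enters_edges(self, cohort77, small_annotation):
        spec = EffectSpec(planted={}, covariate_effects={"age": 0.5}, noise_sd=1e-9)
        panel = simulate_connectomes(cohort77, small_annotation, spec, seed=0)
        age = cohort77["age"].to_numpy(float)
        r = np.corrcoef(age, panel.values[:, 0])[0, 1]
        assert r > 0.99


class TestSimulateTimeseries:
    def test_independent_nodes_give_near_zero_correlations(self):
        subjects = simulate_subjects(1, seed=0)
        ann = make_node_annotation({"networks": {"DMN": 2, "ASN": 1, "LECN": 1}})
        spec = EffectSpec(planted={}, baseline_z=0.0, noise_sd=0.0)
        ts = simulate_timeseries(subjects, ann, spec, T=5_000, seed=1)
        corr = np.corrcoef(ts.series[0], rowvar=False)
        off = corr[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_pairwise_target_correlation_recovered(self):
        subjects = simulate_subjects(1, seed=0)
        ann = make_node_annotation({"networks": {"DMN": 1, "ASN": 1, "LECN": 1}})
        ann = ann.iloc[:2].copy()
        spec = EffectSpec(planted={}, baseline_z=np.arctanh(0.5), noise_sd=0.0)
        ts = simulate_timeseries(subjects, ann, spec, T=20_000, band=None, seed=2)
        r = np.corrcoef(ts.series[0], rowvar=False)[0, 1]
        # Fisher-scale standard error 1/sqrt(T-3) ~ 0.007
        assert abs(r - 0.5) < 0.02

    def test_scan_defaults(self):
        subjects = simulate_subjects(2, seed=0)
        ann = make_node_annotation({"networks": {"DMN": 2, "ASN": 2, "LECN": 1}})
        spec = EffectSpec(planted={}, baseline_z=0.1, noise_sd=0.05)
        ts = simulate_timeseries(subjects, ann, spec, seed=3)
        assert ts.T == 360 and ts.tr == 1.0 and ts.band == (0.008, 0.15)

    def test_invalid_band_rejected(self):
        subjects = simulate_subjects(1, seed=0)
        ann = make_node_annotation({"networks": {"DMN": 1, "ASN": 1, "LECN": 1}})
        spec = EffectSpec(planted={})
        with pytest.raises(ValueError, match="band"):
            simulate_timeseries(subjects, ann, spec, T=100, tr=1.0, band=(0.3, 0.9), seed=0)

    def test_fisher_estimates_concentrate_around_target(self):
        # white-noise case: atanh(r_hat) within 3/sqrt(T-3) of atanh(rho)
        # in essentially all replicates
        subjects = simulate_subjects(1, seed=0)
        ann = make_node_annotation({"networks": {"DMN": 1, "ASN": 1, "LECN": 1}}).iloc[:2]
        rho, T = 0.4, 500
        spec = EffectSpec(planted={}, baseline_z=np.arctanh(rho), noise_sd=0.0)
        hits = 0
        reps = 100
        for k in range(reps):
            ts = simulate_timeseries(subjects, ann, spec, T=T, band=None, seed=1000 + k)
            r = np.corrcoef(ts.series[0], rowvar=False)[0, 1]
            hits += abs(np.arctanh(r) - np.arctanh(rho)) < 3 / np.sqrt(T - 3)
        assert hits >= 0.98 * reps


def test_null_generator_yields_uniform_downstream_pvalues(cohort77):
    """No planted edges -> per-edge worry p-values are uniform (KS, multiple seeds)."""
    from scipy import stats

    from hicrit import build_design_matrix, fit_edge_regressions
    from hicrit.cohort import plant_random_edges

    design = build_design_matrix(cohort77)
    for seed in (31, 32, 33):
        spec = plant_random_edges(1_081, 0, 0.0, seed=seed, noise_sd=0.3)
        ann = make_node_annotation({"networks": {"DMN": 16, "ASN": 16, "LECN": 15}})
        panel = simulate_connectomes(cohort77, ann, spec, seed=seed)
        res = fit_edge_regressions(panel, design)
        assert stats.kstest(res.p, "uniform").pvalue > 0.01


def test_planted_beta_recovered_unbiasedly(small_annotation):
    """Mean estimate over replicates within 2 Monte-Carlo SEs of the planted slope."""
    from hicrit import build_design_matrix, fit_edge_regressions

    subjects = simulate_subjects(120, seed=40)
    design = build_design_matrix(subjects)
    sd_w = subjects["pswq"].std(ddof=1)
    spec = EffectSpec(planted={7: 0.25}, noise_sd=0.3)
    estimates = []
    for rep in range(200):
        panel = simulate_connectomes(subjects, small_annotation, spec, seed=500 + rep)
        res = fit_edge_regressions(panel, design)
        estimates.append(res.beta[7] * sd_w)  # per-SD scale of the planted slope
    estimates = np.asarray(estimates)
    mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - 0.25) < 2 * mc_se
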
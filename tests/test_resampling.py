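import numpy as np
import pandas as pd
import pytest

from ctdetect import (
    DuplexCountTable,
    SampleRecord,
    ScenarioConfig,
    ResamplingPlan,
    ValidationError,
    binomial_model_check,
    downsample_panel,
    downscale_fraction,
    exact_detection_probability,
    make_panel,
    simulate_cohort,
)


def _saturated_table(panel, n_samples=4, t=20):
    """Every site mutant in every sample (f = 1 cohort)."""
    rows = [
        {"sample_id": f"s{i}", "site_id": sid, "t": t, "n": t}
        for i in range(n_samples)
        for sid in panel.site_ids
    ]
    return DuplexCountTable(pd.DataFrame(rows), panel=panel)


def _zero_table(panel, n_samples=4, t=20):
    rows = [
        {"sample_id": f"s{i}", "site_id": sid, "t": t, "n": 0}
        for i in range(n_samples)
        for sid in panel.site_ids
    ]
    return DuplexCountTable(pd.DataFrame(rows), panel=panel)


def _meta(table):
    return [SampleRecord(s, "control", burden_flux=1e6) for s in table.sample_ids]


class TestResamplingPlan:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"panel_sizes": []},
            {"panel_sizes": [0]},
            {"thresholds": []},
            {"thresholds": [-1]},
            {"fractions": [1.5]},
            {"n_replicates": 1},
            {"se_mode": "wrong"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValidationError):
            ResamplingPlan(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        plan = ResamplingPlan(panel_sizes=[5, 10], thresholds=[2, 3], fractions=[1e-4], seed=3)
        p = tmp_path / "plan.yaml"
        p.write_text(yaml.safe_dump({"resampling": plan.to_dict()}))
        assert ResamplingPlan.from_yaml(p) == plan


class TestDownsamplePanel:
    def test_saturated_cohort_full_panel(self):
        panel = make_panel(8)
        table = _saturated_table(panel)
        plan = ResamplingPlan(panel_sizes=[8], thresholds=[1, 2, 5], n_replicates=20, seed=0)
        grid = downsample_panel(table, _meta(table), plan)
        assert (grid["mean"] == 1.0).all()
        assert (grid["se"] == 0.0).all()
        assert (grid["fraction"] == "observed").all()

    def test_all_zero_table(self):
        panel = make_panel(8)
        table = _zero_table(panel)
        plan = ResamplingPlan(panel_sizes=[2, 5, 8], thresholds=[1, 2], n_replicates=20, seed=0)
        grid = downsample_panel(table, _meta(table), plan)
        assert (grid["mean"] == 0.0).all()
        assert (grid["se"] == 0.0).all()

    def test_panel_size_exceeding_full_rejected(self):
        panel = make_panel(4)
        table = _saturated_table(panel)
        plan = ResamplingPlan(panel_sizes=[5], thresholds=[1], n_replicates=5)
        with pytest.raises(ValidationError, match="exceeds"):
            downsample_panel(table, _meta(table), plan)

    def test_empty_table_rejected(self, toy_panel):
        table = DuplexCountTable(
            pd.DataFrame(columns=["sample_id", "site_id", "t", "n"]), panel=toy_panel
        )
        plan = ResamplingPlan(panel_sizes=[1], thresholds=[1], n_replicates=5)
        with pytest.raises(ValidationError, match="empty"):
            downsample_panel(table, [], plan)

    def test_mean_nondecreasing_in_panel_size(self):
        cfg = ScenarioConfig(
            panel_size=200, n_samples_per_arm=10, true_fraction_grid=[2e-4],
            mean_depth=100, priming_fold=1.0, seed=5,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[10, 50, 200], thresholds=[2], n_replicates=60, seed=1)
        grid = downsample_panel(table, records, plan)
        for arm, g in grid.groupby("arm"):
            means = g.sort_values("panel_size")["mean"].tolist()
            assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))

    def test_brute_force_average_small_panel(self):
        """Bootstrap mean at full panel size converges to the expectation over
        resampled site multisets (independent brute-force average)."""
        rng = np.random.default_rng(3)
        panel = make_panel(6)
        rows = []
        for i in range(5):
            t = rng.integers(5, 30, size=6)
            n = (rng.random(6) < 0.4) * rng.integers(1, 4, size=6)
            for j, sid in enumerate(panel.site_ids):
                rows.append({"sample_id": f"s{i}", "site_id": sid, "t": int(t[j]), "n": int(n[j])})
        table = DuplexCountTable(pd.DataFrame(rows), panel=panel)
        meta = _meta(table)
        thr = 2
        plan = ResamplingPlan(panel_sizes=[6], thresholds=[thr], n_replicates=4000, seed=11)
        grid = downsample_panel(table, meta, plan)
        got = grid["mean"].iloc[0]

        # independent oracle: plain loop over fresh multiset draws
        _, _, _, nmat = table.to_matrices()
        oracle_rng = np.random.default_rng(999)
        vals = []
        for _ in range(4000):
            idx = oracle_rng.integers(0, 6, size=6)
            vals.append((((nmat[:, idx] >= 1).sum(axis=1)) >= thr).mean())
        assert got == pytest.approx(np.mean(vals), abs=0.02)

    def test_without_replacement_full_panel_is_deterministic(self):
        cfg = ScenarioConfig(
            panel_size=30, n_samples_per_arm=5, true_fraction_grid=[5e-3],
            mean_depth=100, priming_fold=1.0, seed=2,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(
            panel_sizes=[30], thresholds=[2], n_replicates=10, seed=0, with_replacement=False
        )
        grid = downsample_panel(table, records, plan)
        # without replacement at full size every replicate sees the whole panel
        assert (grid["se"] == 0.0).all()

    def test_determinism_given_seed(self):
        cfg = ScenarioConfig(
            panel_size=40, n_samples_per_arm=4, true_fraction_grid=[1e-3],
            mean_depth=80, seed=6,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[10, 40], thresholds=[2, 4], n_replicates=30, seed=77)
        g1 = downsample_panel(table, records, plan)
        g2 = downsample_panel(table, records, plan)
        pd.testing.assert_frame_equal(g1, g2)

    def test_collapse_duplicates_lowers_counts(self):
        panel = make_panel(5)
        table = _saturated_table(panel, n_samples=2)
        meta = _meta(table)
        base = ResamplingPlan(panel_sizes=[5], thresholds=[5], n_replicates=50, seed=1)
        collapsed = ResamplingPlan(
            panel_sizes=[5], thresholds=[5], n_replicates=50, seed=1, collapse_duplicates=True
        )
        g_base = downsample_panel(table, meta, base)
        g_coll = downsample_panel(table, meta, collapsed)
        # with duplicates counted, 5 draws always yield 5 hits; collapsed usually fewer
        assert g_base["mean"].iloc[0] == 1.0
        assert g_coll["mean"].iloc[0] < 1.0


class TestDownscaleFraction:
    def test_f_target_zero(self):
        cfg = ScenarioConfig(
            panel_size=20, n_samples_per_arm=3, true_fraction_grid=[1e-2],
            mean_depth=100, seed=0,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[20], thresholds=[1, 2], fractions=[0.0],
                              n_replicates=10, seed=0)
        grid = downscale_fraction(table, records, plan)
        assert (grid["mean"] == 0.0).all()
        assert (grid["se"] == 0.0).all()

    def test_requires_fractions(self):
        cfg = ScenarioConfig(panel_size=5, n_samples_per_arm=2, mean_depth=50, seed=0)
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[5], thresholds=[2], n_replicates=5)
        with pytest.raises(ValidationError, match="fractions"):
            downscale_fraction(table, records, plan)

    def test_upscaling_warns(self):
        cfg = ScenarioConfig(
            panel_size=20, n_samples_per_arm=2, true_fraction_grid=[1e-4],
            mean_depth=50, seed=0,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[20], thresholds=[2], fractions=[0.5],
                              n_replicates=5, seed=0)
        with pytest.warns(UserWarning, match="up-scaling"):
            downscale_fraction(table, records, plan)

    def test_self_consistency_with_direct_simulation(self):
        """Down-scaling to the cohort's own true fraction reproduces the
        directly simulated sensitivity within Monte-Carlo error."""
        f = 2e-3
        cfg = ScenarioConfig(
            panel_size=150, n_samples_per_arm=30, true_fraction_grid=[f],
            mean_depth=30, depth_dispersion=0.3, priming_fold=1.0, seed=17,
        )
        table, records = simulate_cohort(cfg)
        samples, _, t, n = table.to_matrices()
        thr = 2
        direct = (((n >= 1).sum(axis=1)) >= thr).mean()
        plan = ResamplingPlan(panel_sizes=[150], thresholds=[thr], fractions=[f],
                              n_replicates=200, seed=4)
        grid = downscale_fraction(table, records, plan)
        m = len(samples)
        tol = 4 * np.sqrt(0.25 / m) + 4 * np.sqrt(0.25 / m) / np.sqrt(200)
        for _, row in grid.iterrows():
            assert abs(row["mean"] - direct) < tol

    def test_mean_matches_exact_oracle(self):
        """Replicate mean converges to the average exact detection probability
        over the cohort's fixed depth vectors."""
        cfg = ScenarioConfig(
            panel_size=25, n_samples_per_arm=12, true_fraction_grid=[1e-2],
            mean_depth=60, priming_fold=1.0, seed=8,
        )
        table, records = simulate_cohort(cfg)
        _, _, t, _ = table.to_matrices()
        f_target, thr = 3e-3, 2
        exact = np.mean([exact_detection_probability(ti, f_target, thr) for ti in t])
        plan = ResamplingPlan(panel_sizes=[25], thresholds=[thr], fractions=[f_target],
                              n_replicates=400, seed=12, with_replacement=False)
        grid = downscale_fraction(table, records, plan)
        got = grid["mean"].mean()  # both arms behave identically at priming_fold=1
        se = np.sqrt(exact * (1 - exact) / (len(t) * 400))
        assert abs(got - exact) < max(5 * se, 0.01)

    def test_se_magnitude_matches_binomial_proportion(self):
        cfg = ScenarioConfig(
            panel_size=40, n_samples_per_arm=25, true_fraction_grid=[5e-3],
            mean_depth=50, priming_fold=1.0, seed=19,
        )
        table, records = simulate_cohort(cfg)
        f_target, thr, m = 2e-3, 2, 25
        plan = ResamplingPlan(panel_sizes=[40], thresholds=[thr], fractions=[f_target],
                              n_replicates=300, seed=5, with_replacement=False)
        grid = downscale_fraction(table, records, plan)
        for _, row in grid.iterrows():
            s = row["mean"]
            if 0.05 < s < 0.95:
                analytic = np.sqrt(s * (1 - s) / m)
                assert analytic / 2 < row["se"] < analytic * 2

    def test_determinism(self):
        cfg = ScenarioConfig(
            panel_size=15, n_samples_per_arm=3, true_fraction_grid=[1e-2],
            mean_depth=50, seed=0,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[5, 15], thresholds=[2], fractions=[1e-3, 5e-3],
                              n_replicates=25, seed=42)
        g1 = downscale_fraction(table, records, plan)
        g2 = downscale_fraction(table, records, plan)
        pd.testing.assert_frame_equal(g1, g2)

    def test_monotone_in_fraction(self):
        cfg = ScenarioConfig(
            panel_size=50, n_samples_per_arm=10, true_fraction_grid=[1e-2],
            mean_depth=100, priming_fold=1.0, seed=3,
        )
        table, records = simulate_cohort(cfg)
        plan = ResamplingPlan(panel_sizes=[50], thresholds=[2],
                              fractions=[1e-5, 1e-4, 1e-3, 1e-2], n_replicates=80, seed=2)
        grid = downscale_fraction(table, records, plan)
        for arm, g in grid.groupby("arm"):
            means = g.sort_values("fraction")["mean"].tolist()
            assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))


class TestBinomialModelCheck:
    def test_null_calibration(self):
        """Data generated by the binomial model: p-values roughly uniform,
        rejection rate near nominal alpha."""
        cfg = ScenarioConfig(
            panel_size=100, n_samples_per_arm=30, true_fraction_grid=[5e-3],
            mean_depth=200, depth_dispersion=0.3, priming_fold=1.0, seed=100,
        )
        table, _ = simulate_cohort(cfg)
        report = binomial_model_check(table, n_sim=150, seed=1)
        assert len(report) == 60
        alpha = 0.05
        rate = (report["p_value"] < alpha).mean()
        # 60 samples, binomial(60, 0.05): allow up to ~4x nominal
        assert rate <= 0.2
        assert report["p_value"].mean() == pytest.approx(0.5, abs=0.2)

    def test_hotspot_contamination_detected(self):
        rng = np.random.default_rng(0)
        panel = make_panel(100)
        t = np.full(100, 500)
        n = rng.binomial(t, 1e-4)
        n[0] = rng.binomial(500, 0.5)  # one contaminated hot-spot site
        rows = [
            {"sample_id": "hot", "site_id": sid, "t": int(t[j]), "n": int(n[j])}
            for j, sid in enumerate(panel.site_ids)
        ]
        table = DuplexCountTable(pd.DataFrame(rows), panel=panel)
        report = binomial_model_check(table, n_sim=200, seed=2)
        assert report["p_value"].iloc[0] < 0.01

    def test_empty_sample_skipped_with_note(self, toy_panel):
        rows = [
            {"sample_id": "empty", "site_id": sid, "t": 0, "n": 0} for sid in toy_panel.site_ids
        ]
        table = DuplexCountTable(pd.DataFrame(rows), panel=toy_panel)
        with pytest.warns(UserWarning, match="skipped"):
            report = binomial_model_check(table, n_sim=10, seed=0)
        assert report["note"].iloc[0].startswith("skipped")
        assert np.isnan(report["p_value"].iloc[0])
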
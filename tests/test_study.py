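"""Replicate engine: seeding, summaries, Monte-Carlo SEs and the power grid."""

import numpy as np
import pandas as pd
import pytest

from hetmr import (
    ConfigurationError,
    SimConfig,
    StudyScenario,
    child_seed,
    power_curve,
    run_replicates,
    shared_scenario,
    summarize,
)

TRUTH = {"beta1": -200.0, "beta0": -100.0, "diff": -100.0}


def small_scenario(**overrides):
    base = dict(
        base=shared_scenario(1000, 0),
        sample_sizes=(500, 1000),
        n_reps=3,
        methods=("rgmee", "method2"),
        master_seed=7,
    )
    base.update(overrides)
    return StudyScenario(**base)


class TestScenarioValidation:
    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError, match="n_reps"):
            small_scenario(n_reps=1)

    def test_non_increasing_sizes_rejected(self):
        with pytest.raises(ConfigurationError, match="sample_sizes"):
            small_scenario(sample_sizes=(1000, 1000))

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError, match="methods"):
            small_scenario(methods=("method3",))

    def test_truth_reflects_base_config(self):
        scn = small_scenario(base=SimConfig(n=10, seed=0, beta1=-180.0, beta0=-60.0))
        assert scn.truth == {"beta1": -180.0, "beta0": -60.0, "diff": -120.0}

    def test_from_file_round_trip(self, tmp_path):
        import yaml

        cfg = shared_scenario(100, 1).to_dict()
        cfg["study"] = dict(
            sample_sizes=[500, 1000], n_reps=4, methods=["rgmee"], master_seed=3
        )
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(cfg))
        scn = StudyScenario.from_file(path)
        assert scn.sample_sizes == (500, 1000)
        assert scn.n_reps == 4
        assert scn.methods == ("rgmee",)
        assert scn.base.n == 100  # generator n is overridden per grid point anyway


class TestChildSeeds:
    def test_deterministic_and_bounded(self):
        seeds = {child_seed(1, n, r) for n in (100, 200) for r in range(50)}
        assert len(seeds) == 100  # no collisions on this grid
        assert all(0 <= s < 2**31 for s in seeds)
        assert child_seed(1, 100, 0) == child_seed(1, 100, 0)

    def test_independent_of_grid_ordering(self):
        """A replicate's seed depends only on (master_seed, n, replicate)."""
        assert child_seed(5, 1000, 2) != child_seed(5, 2000, 2)
        assert child_seed(5, 1000, 2) != child_seed(6, 1000, 2)


class TestRunReplicates:
    def test_repeated_runs_identical(self):
        scn = small_scenario()
        a, b = run_replicates(scn), run_replicates(scn)
        pd.testing.assert_frame_equal(a, b)

    def test_long_table_keys(self):
        table = run_replicates(small_scenario())
        # rgmee yields 1 parameter, method2 yields 3, per (n, replicate)
        assert len(table) == 2 * 3 * (1 + 3)
        assert table["error"].isna().all()
        assert set(table["parameter"]) == {"beta1", "beta0", "diff"}

    def test_summaries_match_independent_groupby(self):
        """Spreadsheet-style re-aggregation reproduces summarize exactly."""
        scn = small_scenario(n_reps=20, sample_sizes=(800,), methods=("rgmee",))
        table = run_replicates(scn)
        summary = summarize(table, TRUTH)
        est = table["estimate"]
        assert summary.loc[0, "mean_estimate"] == pytest.approx(est.mean())
        assert summary.loc[0, "bias"] == pytest.approx(est.mean() - TRUTH["diff"])
        assert summary.loc[0, "empirical_sd"] == pytest.approx(est.std(ddof=1))
        assert summary.loc[0, "power"] == pytest.approx((table["p_value"] < 0.05).mean())
        cover = ((table["ci_low"] <= -100.0) & (-100.0 <= table["ci_high"])).mean()
        assert summary.loc[0, "coverage"] == pytest.approx(cover)


class TestSummarize:
    @staticmethod
    def synthetic_replicates(n_reps=10_000, power=0.5):
        rng = np.random.default_rng(0)
        p = np.where(rng.random(n_reps) < power, 0.01, 0.5)
        return pd.DataFrame(
            dict(
                method="rgmee",
                parameter="diff",
                n=1000,
                replicate=np.arange(n_reps),
                estimate=-100.0,
                se=1.0,
                ci_low=-102.0,
                ci_high=-98.0,
                p_value=p,
                error=None,
            )
        )

    def test_power_mcse_closed_form(self):
        table = self.synthetic_replicates()
        summary = summarize(table, TRUTH)
        power = summary.loc[0, "power"]
        assert summary.loc[0, "mcse_power"] == pytest.approx(
            np.sqrt(power * (1 - power) / 10_000)
        )
        # at power ~0.5 with 10,000 replicates the MCSE is ~0.005
        assert summary.loc[0, "mcse_power"] == pytest.approx(0.005, abs=2e-4)

    def test_degenerate_full_coverage(self):
        table = self.synthetic_replicates(n_reps=50)
        summary = summarize(table, TRUTH)  # every CI contains -100
        assert summary.loc[0, "coverage"] == 1.0
        assert summary.loc[0, "mcse_coverage"] == 0.0

    def test_missing_truth_component_rejected(self):
        table = self.synthetic_replicates(n_reps=5)
        with pytest.raises(ConfigurationError, match="diff"):
            summarize(table, {"beta1": -200.0})

    def test_failures_counted_and_flagged(self):
        table = self.synthetic_replicates(n_reps=50)
        failures = pd.DataFrame(
            dict(
                method="rgmee",
                parameter=[None],
                n=1000,
                replicate=[50],
                estimate=np.nan,
                se=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                p_value=np.nan,
                error="cell (S=1, G=1) is empty",
            )
        )
        summary = summarize(pd.concat([table, failures], ignore_index=True), TRUTH)
        assert summary.loc[0, "n_failed"] == 1
        assert bool(summary.loc[0, "flag_invalid"])  # 1/51 > 1%
        assert summary.loc[0, "n_reps_used"] == 50


class TestPowerCurve:
    def test_null_difference_rejects_at_nominal_rate(self):
        """With no moderated effect the 5% test fires at its size."""
        table = power_curve(
            shared_scenario(1000, 0),
            diffs=[0.0],
            sample_sizes=[2000],
            n_reps=200,
            methods=("rgmee",),
            master_seed=11,
        )
        power = float(table.loc[0, "power"])
        mcse = float(table.loc[0, "mcse_power"])
        assert abs(power - 0.05) <= max(1.96 * mcse, 0.035)

    def test_power_grows_with_true_difference(self):
        table = power_curve(
            shared_scenario(1000, 0),
            diffs=[-100.0, 0.0],
            sample_sizes=[2000],
            n_reps=60,
            methods=("rgmee",),
            master_seed=3,
        )
        by_diff = table.set_index("diff")["power"]
        assert by_diff[-100.0] > by_diff[0.0] + 0.3

    def test_methods_without_difference_rejected(self):
        with pytest.raises(ConfigurationError):
            power_curve(
                shared_scenario(1000, 0), [-15.0], [1000], 10, methods=("standard_mr",)
            )


class TestSamplingBehaviour:
    def test_empirical_sd_shrinks_as_root_n(self):
        """Across the size grid the replicate SD scales ~ 1/sqrt(n)."""
        scn = StudyScenario(
            base=shared_scenario(1000, 0),
            sample_sizes=(2000, 8000, 32_000),
            n_reps=300,
            methods=("rgmee",),
            master_seed=21,
        )
        summary = summarize(run_replicates(scn), TRUTH).sort_values("n")
        slope = np.polyfit(np.log(summary["n"]), np.log(summary["empirical_sd"]), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_methods_agree_when_both_assumption_sets_hold(self):
        """With every violation off the two procedures target the same
        parameters; replicate means agree within combined Monte-Carlo error."""
        scn = StudyScenario(
            base=shared_scenario(1000, 0),
            sample_sizes=(20_000,),
            n_reps=200,
            methods=("method1", "method2"),
            master_seed=22,
        )
        summary = summarize(run_replicates(scn), TRUTH)
        for parameter in ("beta1", "beta0", "diff"):
            sub = summary[summary["parameter"] == parameter].set_index("method")
            gap = sub.loc["method1", "mean_estimate"] - sub.loc["method2", "mean_estimate"]
            mcse = np.hypot(sub.loc["method1", "mcse_bias"], sub.loc["method2", "mcse_bias"])
            assert abs(gap) < 3 * mcse, parameter

    def test_power_ordering_reverses_between_parameters(self):
        """The RGMEE-based procedure detects the moderated difference more
        readily, while the joint procedure is more powerful for beta1.
        Methods run on the same replicate cohorts, so the orderings are
        assessed as paired rejection contrasts."""
        scn = StudyScenario(
            base=shared_scenario(1000, 0),
            sample_sizes=(3000,),
            n_reps=2000,
            methods=("method1", "method2"),
            master_seed=23,
        )
        table = run_replicates(scn)

        def paired_gap(parameter, better, worse):
            sub = table[table["parameter"] == parameter]
            reject = (
                sub.assign(reject=(sub["p_value"] < 0.05).astype(float))
                .pivot(index="replicate", columns="method", values="reject")
            )
            d = reject[better] - reject[worse]
            return d.mean(), d.std(ddof=1) / np.sqrt(len(d))

        d_gap, d_mcse = paired_gap("diff", "method2", "method1")
        assert d_gap > 3 * d_mcse
        b1_gap, b1_mcse = paired_gap("beta1", "method1", "method2")
        assert b1_gap > 3 * b1_mcse


class TestFigures:
    def test_summary_and_power_figures_render(self, tmp_path):
        scn = small_scenario(n_reps=4, sample_sizes=(400, 800), methods=("rgmee",))
        summary = summarize(run_replicates(scn), TRUTH)
        from hetmr.study import plot_power_curve, plot_summary

        fig = plot_summary(summary, metric="coverage")
        fig.savefig(tmp_path / "coverage.png")
        power = power_curve(
            shared_scenario(1000, 0), [-100.0], [400], 4, ("rgmee",), master_seed=1
        )
        fig2 = plot_power_curve(power)
        fig2.savefig(tmp_path / "power.png")
        assert (tmp_path / "coverage.png").stat().st_size > 0
        assert (tmp_path / "power.png").stat().st_size > 0
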
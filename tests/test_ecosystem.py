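"""Inventory-plot pipeline: filtering, averaging, correlations, trimming."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saplingniche import (
    PlotGeneratorConfig,
    attach_predicted_height,
    average_repeated,
    correlate,
    fig_battery,
    filter_conifer_plots,
    gen_fia_plots,
    trim_95,
)
from saplingniche.ecosystem import battery_to_frame, recode_productivity


def brute_force_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


class TestFilter:
    def test_hand_count(self):
        plots = pd.DataFrame(
            {"conifer_fraction": [0.9, 0.7, 0.69, 1.0, 0.5]}
        )
        assert len(filter_conifer_plots(plots)) == 3  # 0.70 inclusive

    @pytest.mark.parametrize(
        "threshold,expected", [(0.0, 5), (1.0, 1)]
    )
    def test_threshold_extremes(self, threshold, expected):
        plots = pd.DataFrame(
            {"conifer_fraction": [0.9, 0.7, 0.69, 1.0, 0.5]}
        )
        assert len(filter_conifer_plots(plots, threshold)) == expected


class TestAverageRepeated:
    def test_two_samplings_averaged(self):
        plots = pd.DataFrame(
            {
                "plot_id": ["a", "a", "b"],
                "biomass": [10.0, 20.0, 7.0],
                "tree_diversity": [2, 4, 1],
            }
        )
        out = average_repeated(plots)
        assert len(out) == 2
        row = out[out.plot_id == "a"].iloc[0]
        assert row.biomass == pytest.approx(15.0)
        assert row.tree_diversity == pytest.approx(3.0)
        assert row.n_samplings == 2

    def test_three_samplings_hand_mean(self):
        plots = pd.DataFrame(
            {"plot_id": ["x"] * 3, "biomass": [1.0, 2.0, 6.0]}
        )
        assert average_repeated(plots)["biomass"].iloc[0] == pytest.approx(3.0)

    def test_unique_plots_pass_through(self):
        plots = pd.DataFrame(
            {"plot_id": ["a", "b"], "biomass": [1.0, 2.0]}
        )
        out = average_repeated(plots)
        assert out["biomass"].tolist() == [1.0, 2.0]
        assert (out["n_samplings"] == 1).all()

    def test_conflicting_labels_rejected(self):
        plots = pd.DataFrame(
            {
                "plot_id": ["a", "a"],
                "biomass": [1.0, 2.0],
                "owner": ["x", "y"],
            }
        )
        with pytest.raises(ValueError, match="owner"):
            average_repeated(plots)

    def test_averaging_never_resurrects_filtered_plots(self, truth_model):
        plots = gen_fia_plots(
            PlotGeneratorConfig(n_plots=400, seed=9), truth_model
        )
        kept = filter_conifer_plots(plots)
        merged = average_repeated(kept)
        assert set(merged.plot_id) == set(kept.plot_id)
        assert (merged.conifer_fraction >= 0.70).all()


class TestAttachPredictedHeight:
    def test_identical_climates_identical_heights(self, truth_model):
        plots = gen_fia_plots(
            PlotGeneratorConfig(n_plots=2, seed=0), truth_model
        )
        plots = pd.concat([plots, plots.iloc[[0]]], ignore_index=True)
        out = attach_predicted_height(plots, truth_model)
        assert out.predicted_height.iloc[0] == out.predicted_height.iloc[2]

    def test_age_zero_override(self, truth_model):
        plots = gen_fia_plots(
            PlotGeneratorConfig(n_plots=5, seed=0), truth_model
        )
        out = attach_predicted_height(plots, truth_model, age=0.0)
        assert (out.predicted_height == 0).all()

    def test_matches_scalar_prediction(self, truth_model):
        from saplingniche import ClimateVector, predict_height

        plots = gen_fia_plots(
            PlotGeneratorConfig(n_plots=3, seed=1), truth_model
        )
        out = attach_predicted_height(plots, truth_model, age=8.0)
        row = out.iloc[0]
        cv = ClimateVector.from_original(
            eref=row.eref, dd5=row.dd5, dd_18=row.dd_18, mat=row.mat
        )
        assert row.predicted_height == pytest.approx(
            predict_height(truth_model, 8.0, cv)
        )


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10
        assert res.slope == pytest.approx(2.0)
        assert res.significant

    def test_hand_value(self):
        res = correlate([1, 2, 3, 4], [1, 2, 3, 5])
        assert res.r == pytest.approx(6.5 / np.sqrt(5 * 8.75), rel=1e-12)
        assert res.r == pytest.approx(0.9827, abs=1e-4)
        assert res.df == (1, 2)

    def test_matches_brute_force_and_f_identity(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            res = correlate(x, y)
            assert res.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
            # F = t^2 of the slope; p consistent with the F(1, n-2) tail
            p_from_f = stats.f.sf(res.f_stat, 1, n - 2)
            assert res.p == pytest.approx(p_from_f, rel=1e-8)

    def test_null_simulation_p_roughly_uniform(self):
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            ps.append(correlate(x, y).p)
        ps = np.asarray(ps)
        assert abs(np.mean(ps < 0.5) - 0.5) < 0.12
        assert np.mean(ps < 0.05) < 0.15

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTrim95:
    def test_normal_retention_rate(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20000)
        y = rng.standard_normal(20000)
        kept = trim_95(x, y)
        # (P(|z|<2))^2 ~ 0.911 under independence
        assert 0.89 < len(kept) / 20000 < 0.93

    def test_constant_coordinate_retains_all(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.zeros(4)
        assert len(trim_95(x, y)) == 4

    def test_gross_outlier_excluded(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        x[0] = 10 * x.std()
        assert 0 not in trim_95(x, y)

    def test_unimodal_retention_invariant(self):
        rng = np.random.default_rng(7)
        x = rng.normal(3.0, 2.0, 3000)
        y = 0.5 * x + rng.normal(0, 1.0, 3000)
        frac = len(trim_95(x, y)) / 3000
        assert 0.85 < frac <= 1.0


@pytest.fixture(scope="module")
def prepared(truth_model):
    plots = gen_fia_plots(
        PlotGeneratorConfig(n_plots=6000, seed=21), truth_model
    )
    plots = filter_conifer_plots(plots)
    plots = average_repeated(plots)
    return attach_predicted_height(plots, truth_model)


class TestBattery:
    def test_six_pairs_full_and_trimmed(self, prepared):
        results = fig_battery(prepared)
        assert len(results) == 12
        assert sum(r.trimmed for r in results) == 6

    def test_signs_match_default_couplings(self, prepared):
        results = {(r.x_name, r.y_name): r for r in fig_battery(prepared) if not r.trimmed}
        assert results[("productivity", "predicted_height")].r > 0
        assert results[("biomass", "predicted_height")].r > 0
        assert results[("productivity", "tree_diversity")].r > 0
        assert results[("biomass", "tree_diversity")].r > 0
        assert results[("species_diversity", "predicted_height")].r > 0
        assert results[("tree_diversity", "predicted_height")].r < 0.05

    def test_zero_coupling_mostly_insignificant(self, truth_model):
        zero = {k: 0.0 for k in (
            "productivity", "biomass", "tree_diversity",
            "species_diversity", "tree_diversity_productivity",
            "tree_diversity_biomass", "productivity_biomass",
        )}
        sig_counts = []
        for seed in range(5):
            plots = gen_fia_plots(
                PlotGeneratorConfig(
                    n_plots=300, coupling_strengths=zero, seed=seed
                ),
                truth_model,
            )
            plots = attach_predicted_height(
                filter_conifer_plots(plots), truth_model
            )
            full = [r for r in fig_battery(plots) if not r.trimmed]
            sig_counts.append(sum(r.significant for r in full))
        assert np.median(sig_counts) <= 1

    def test_duplicated_table_same_r_doubled_df(self, prepared):
        small = prepared.iloc[:500]
        doubled = pd.concat(
            [small, small.assign(plot_id=small.plot_id + "_dup")],
            ignore_index=True,
        )
        r1 = [r for r in fig_battery(small) if not r.trimmed]
        r2 = [r for r in fig_battery(doubled) if not r.trimmed]
        for a, b in zip(r1, r2):
            assert b.r == pytest.approx(a.r, abs=1e-12)
            assert b.df[1] == 2 * a.df[1] + 2  # (2n - 2) vs (n - 2)

    def test_frame_suppresses_insignificant_lines(self, prepared):
        frame = battery_to_frame(fig_battery(prepared))
        bad = frame[~frame.significant]
        assert bad["slope"].isna().all()

    def test_productivity_recode_is_monotone_inversion(self):
        mids = recode_productivity([1, 2, 3, 4, 5, 6, 7])
        assert (np.diff(mids) < 0).all()
        assert mids[0] == 250.0
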
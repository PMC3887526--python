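"""Design enumeration, subsampling, metrics, smoothing, and budget arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

import barseqtools as bt
from barseqtools.core import DesignSpec
from barseqtools.counts import collapse_tags_and_technical
from barseqtools.design_eval import (
    design_efficiency,
    enumerate_replicate_subsets,
    evaluate_subsample,
    gold_standard,
    make_fraction_grid,
    power_by_effect_size,
    run_design_evaluation,
    subsample_counts,
)
from barseqtools.splines import natural_spline_knots, smooth_natural_spline

FULL = DesignSpec(2, 4, 2)


class TestEnumeration:
    @pytest.mark.parametrize(
        "target,expected",
        [
            ("2x4x2", 1),
            ("2x4x1", 2),
            ("2x3x2", 4),
            ("2x3x1", 8),
            ("2x2x2", 6),
            ("2x2x1", 12),
        ],
    )
    def test_combination_counts(self, target, expected):
        combos = enumerate_replicate_subsets(FULL, DesignSpec.parse(target))
        assert len(combos) == expected
        assert len(set(combos)) == expected

    def test_full_design_is_identity(self):
        (combo,) = enumerate_replicate_subsets(FULL, FULL)
        assert combo.bio_reps == (1, 2, 3, 4)
        assert combo.tech_reps == (1, 2)

    def test_target_exceeding_full_fails(self):
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_replicate_subsets(FULL, DesignSpec(2, 5, 2))


class TestFractionGrid:
    def test_default_grid_matches_quarter_percent_steps(self):
        grid = make_fraction_grid()
        assert len(grid) == 400
        assert grid[0] == 0.0025
        assert grid[-1] == 1.0
        assert np.all(np.diff(grid) > 0)
        assert np.abs(np.diff(grid) - 0.0025).max() < 1e-15


class TestSubsample:
    def test_identity_and_zero(self):
        df = pd.DataFrame(np.arange(12).reshape(3, 4))
        rng = np.random.default_rng(0)
        assert subsample_counts(df, 1.0, rng).equals(df)
        assert (subsample_counts(df, 0.0, rng) == 0).all().all()
        with pytest.raises(ValueError):
            subsample_counts(df, 1.5, rng)

    def test_binomial_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": [10_000] * 1000})
        draws = subsample_counts(df, 0.3, rng)["x"].to_numpy()
        se = np.sqrt(10_000 * 0.3 * 0.7 / 1000)
        assert abs(draws.mean() - 3000) < 3 * se
        assert abs(draws.var(ddof=1) - 2100) < 0.15 * 2100
        assert (draws <= 10_000).all()

    def test_thinning_composes(self):
        # subsample(subsample(X, p), q) ~ subsample(X, pq): match moments
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": [5000] * 2000})
        two_step = subsample_counts(subsample_counts(df, 0.6, rng), 0.5, rng)["x"]
        one_step = subsample_counts(df, 0.3, rng)["x"]
        assert abs(two_step.mean() - one_step.mean()) < 4 * np.sqrt(2 * 5000 * 0.3 / 2000)
        assert abs(two_step.var() / one_step.var() - 1) < 0.15


@pytest.fixture(scope="module")
def gold_and_matrix(medium_counts):
    _, _, matrix = medium_counts
    return gold_standard(matrix), collapse_tags_and_technical(matrix)


class TestMetrics:
    def test_self_comparison_is_perfect(self, gold_and_matrix):
        gold, collapsed = gold_and_matrix
        point = evaluate_subsample(collapsed, gold)
        assert point["power"] == 1.0
        assert point["empirical_fdr"] == 0.0
        assert point["mse_logfc"] == 0.0
        assert point["n_significant"] == len(gold.significant)

    def test_effect_size_strata_are_nested_and_ordered(self, gold_and_matrix):
        gold, collapsed = gold_and_matrix
        assert gold.strata["2"] <= gold.strata["1.5"] <= gold.strata["all"]
        # recovery by stratum from a strongly thinned sample: larger effects
        # are easier to recover
        thin = subsample_counts(collapsed, 0.05, np.random.default_rng(4))
        from barseqtools.design_eval import _fit_pipeline

        res = _fit_pipeline(thin, "treatment", 0.05)
        strata = power_by_effect_size(set(res.significant(0.05)), gold)
        assert strata["2"] >= strata["all"] - 1e-12

    def test_empty_stratum_reports_missing(self, gold_and_matrix):
        gold, _ = gold_and_matrix
        gold2 = bt.GoldStandard(gold.table, fold_thresholds=(1.5, 2.0, 64.0))
        strata = power_by_effect_size(set(), gold2)
        assert strata["64"] is None


class TestSplines:
    def test_constant_and_line_reproduced(self):
        x = np.linspace(0, 1, 50)
        assert np.abs(smooth_natural_spline(x, np.full(50, 3.3), 8) - 3.3).max() < 1e-10
        y = 2.0 * x - 1.0
        assert np.abs(smooth_natural_spline(x, y, 8) - y).max() < 1e-10

    def test_matches_constrained_truncated_power_oracle(self):
        # independent construction: full cubic truncated-power basis with
        # explicit natural constraints (zero 2nd/3rd derivative outside the
        # boundary knots), solved on the constraint null space
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(size=50))
        y = np.sin(6 * x) + rng.normal(scale=0.2, size=50)
        df = 6
        knots = natural_spline_knots(x, df)
        inner, lo, hi = knots[1:-1], knots[0], knots[-1]

        def tp_basis(t):
            t = np.asarray(t, float)
            cols = [np.ones_like(t), t, t**2, t**3]
            cols += [np.clip(t - k, 0, None) ** 3 for k in knots]
            return np.column_stack(cols)

        # constraints: f''(lo)=f'''(lo)=0 and f''(hi)=f'''(hi)=0 (evaluate
        # just outside the boundary knots where all truncations are active
        # or inactive)
        def d2_row(t):
            row = [0.0, 0.0, 2.0, 6.0 * t]
            row += [6.0 * max(t - k, 0.0) for k in knots]
            return row

        def d3_row(t):
            row = [0.0, 0.0, 0.0, 6.0]
            row += [6.0 * (1.0 if t > k else 0.0) for k in knots]
            return row

        eps = 1e-9
        C = np.array(
            [d2_row(lo - eps), d3_row(lo - eps), d2_row(hi + eps), d3_row(hi + eps)]
        )
        Z = null_space(C)
        B = tp_basis(x) @ Z
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        grid = np.linspace(x.min(), x.max(), 40)
        oracle = (tp_basis(grid) @ Z) @ coef

        got = smooth_natural_spline(x, y, df, grid)
        assert np.abs(got - oracle).max() < 1e-8

    def test_too_few_points_fail(self):
        with pytest.raises(ValueError):
            smooth_natural_spline(np.arange(5.0), np.arange(5.0), 6)


class TestRunEvaluation:
    def test_degenerate_grid_reproduces_gold(self, medium_counts):
        _, _, matrix = medium_counts
        ev = run_design_evaluation(matrix, ["2x4x2"], grid=np.array([1.0]), seed=0)
        row = ev.points.iloc[0]
        assert row["power"] == 1.0 and row["mse_logfc"] == 0.0
        assert row["n_significant"] == len(ev.gold.significant)

    def test_points_are_reproducible_per_seed(self, medium_counts):
        _, _, matrix = medium_counts
        grid = np.array([0.1, 0.4])
        ev1 = run_design_evaluation(matrix, ["2x3x2"], grid=grid, seed=3,
                                    max_combinations=2)
        ev2 = run_design_evaluation(matrix, ["2x3x2"], grid=grid, seed=3,
                                    max_combinations=2)
        pd.testing.assert_frame_equal(ev1.points, ev2.points)
        ev3 = run_design_evaluation(matrix, ["2x3x2"], grid=grid, seed=4,
                                    max_combinations=2)
        assert not ev3.points["power"].equals(ev1.points["power"])


def test_design_efficiency_arithmetic():
    eff = design_efficiency()
    assert eff["reads_per_mutant_per_condition"] == 1397
    assert eff["reads_per_mutant_per_library"] == 349
    assert eff["conditions_per_lane_by_indices"] == 30
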
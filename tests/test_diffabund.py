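"""Normalization, dispersion estimation, the exact NB test, and q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom, binom

import barseqtools as bt
from barseqtools.diffabund import (
    NBExactModel,
    NBFit,
    _doubletail_pvalues,
    equalize_library_sizes,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    exact_nb_test,
    storey_qvalues,
    tmm_factors,
)

GROUPS_44 = ["A"] * 4 + ["B"] * 4


def nb_frame(rng, n, mu, phi, n_samples=8, lfc=None):
    lam = np.broadcast_to(np.asarray(mu, float)[:, None], (n, n_samples)).copy()
    if lfc is not None:
        lam[:, n_samples // 2 :] *= 2.0 ** np.asarray(lfc)[:, None]
    if phi > 0:
        lam = lam * rng.gamma(1 / phi, phi, size=lam.shape)
    y = rng.poisson(lam)
    return pd.DataFrame(y, columns=[f"s{i}" for i in range(n_samples)])


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(tmm_factors(df), 1.0)

    def test_pure_depth_difference_is_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=200)
        df = pd.DataFrame({"a": base, "b": 2 * base})
        f = tmm_factors(df)
        assert np.allclose(f, 1.0, atol=1e-12)  # doubling is pure library size
        # normalized means agree exactly
        eff = df.sum(0) * f
        assert np.allclose(df["a"] / eff["a"], df["b"] / eff["b"])

    def test_matches_direct_trimmed_mean_formula(self):
        rng = np.random.default_rng(1)
        y = rng.negative_binomial(10, 0.1, size=(300, 2)).astype(float) + 1
        df = pd.DataFrame(y, columns=["a", "b"])
        f = tmm_factors(df, reference_column="a")
        # independent straightforward implementation of the doubly trimmed
        # weighted mean of M-values for column b against reference a
        na, nb = y[:, 0].sum(), y[:, 1].sum()
        pa, pb = y[:, 0] / na, y[:, 1] / nb
        M = np.log2(pb / pa)
        A = 0.5 * np.log2(pb * pa)
        w = (nb - y[:, 1]) / (nb * y[:, 1]) + (na - y[:, 0]) / (na * y[:, 0])
        n = len(M)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (
            (rM >= np.floor(0.3 * n) + 1)
            & (rM <= n - np.floor(0.3 * n))
            & (rA >= np.floor(0.05 * n) + 1)
            & (rA <= n - np.floor(0.05 * n))
        )
        fb = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected = np.array([1.0, fb])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.to_numpy(), expected, rtol=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson(100, size=(100, 5)), columns=list("abcde"))
        f = tmm_factors(df)
        assert abs(np.log(f).mean()) < 1e-12

    def test_all_zero_column_fails(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(df)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        df = nb_frame(rng, 2000, rng.lognormal(5, 0.8, 2000), phi=0.0)
        assert estimate_common_dispersion(df, GROUPS_44) <= 0.01

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(4)
        df = nb_frame(rng, 2000, rng.lognormal(5, 0.8, 2000), phi=0.1)
        assert 0.07 <= estimate_common_dispersion(df, GROUPS_44) <= 0.13

    def test_constant_replicates_hit_lower_boundary(self):
        df = pd.DataFrame(
            np.tile(np.arange(10, 60, 10)[:, None], (1, 4)), columns=list("abcd")
        )
        phi = estimate_common_dispersion(df, ["A", "A", "B", "B"])
        assert phi <= 1e-6

    def test_requires_replication(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError, match="replicate"):
            estimate_common_dispersion(df, ["A", "B"])

    def test_infinite_prior_collapses_to_common(self):
        rng = np.random.default_rng(5)
        df = nb_frame(rng, 200, rng.lognormal(5, 0.5, 200), phi=0.1)
        common = estimate_common_dispersion(df, GROUPS_44)
        tag = estimate_tagwise_dispersion(df, GROUPS_44, common, prior_df=1e9)
        assert np.allclose(tag, common)

    def test_zero_prior_tracks_per_mutant_variance(self):
        rng = np.random.default_rng(6)
        df = nb_frame(rng, 300, np.full(300, 200.0), phi=0.05)
        # inflate within-group variance of one mutant far beyond the rest
        df.iloc[0] = [40, 400, 30, 500, 35, 450, 28, 380]
        common = estimate_common_dispersion(df, GROUPS_44)
        tag0 = estimate_tagwise_dispersion(df, GROUPS_44, common, prior_df=0.0)
        assert tag0.iloc[0] > common

    def test_shrinkage_reduces_spread(self):
        rng = np.random.default_rng(7)
        df = nb_frame(rng, 500, rng.lognormal(5, 0.5, 500), phi=0.1)
        common = estimate_common_dispersion(df, GROUPS_44)
        spread0 = np.log(
            estimate_tagwise_dispersion(df, GROUPS_44, common, prior_df=0.0)
        ).std()
        spread10 = np.log(
            estimate_tagwise_dispersion(df, GROUPS_44, common, prior_df=10.0)
        ).std()
        assert spread10 < spread0


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def oracle_doubletail(t, obs, n1, n2, phi, slack=1e-12):
    """Brute-force enumeration of the conditional distribution: the split of
    the total between groups is beta-binomial (binomial in the Poisson
    limit); sum every outcome probability <= the observed one."""
    k = np.arange(t + 1)
    if phi < 1e-7:
        pmf = binom.pmf(k, t, n1 / (n1 + n2))
    else:
        pmf = betabinom.pmf(k, t, n1 / phi, n2 / phi)
    return min(1.0, pmf[pmf <= pmf[obs] * (1 + slack)].sum())


class TestExactTest:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for phi in (0.0, 0.05, 0.2, 1.0):
            for (n1, n2) in ((2, 2), (4, 4), (2, 3)):
                t = rng.integers(1, 200, size=25)
                obs = np.array([rng.integers(0, x + 1) for x in t])
                got = _doubletail_pvalues(t, obs, n1, n2, np.full(len(t), phi))
                want = [oracle_doubletail(x, o, n1, n2, phi) for x, o in zip(t, obs)]
                assert np.allclose(got, want, atol=1e-10)

    def test_balanced_split_is_null(self):
        df = pd.DataFrame([[50, 60, 55, 55]], columns=list("abcd"))
        fit = NBFit(
            pd.Series(1e6, index=list("abcd")),
            pd.Series(1.0, index=list("abcd")),
            phi_common=0.1,
        )
        res = exact_nb_test(df, ["A", "A", "B", "B"], fit)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(res["logFC"].iloc[0]) < 1e-12

    def test_depth_scaling_decreases_pvalue(self):
        # the read-depth sensitivity at the heart of the NB approach:
        # scaling a truly-different mutant's counts up makes it more, not
        # equally, significant
        cols = list("abcd")
        fit = NBFit(
            pd.Series(1e6, index=cols), pd.Series(1.0, index=cols), phi_common=0.01
        )
        base = np.array([[20, 24, 40, 44]])
        p_prev = 1.0
        for k in (1, 4, 16):
            df = pd.DataFrame(base * k, columns=cols)
            p = exact_nb_test(df, ["A", "A", "B", "B"], fit)["pvalue"].iloc[0]
            assert p < p_prev
            p_prev = p

    def test_requires_two_groups(self):
        df = pd.DataFrame([[1, 2, 3]], columns=list("abc"))
        fit = NBFit(pd.Series(1.0, index=list("abc")), pd.Series(1.0, index=list("abc")), 0.1)
        with pytest.raises(ValueError, match="two groups"):
            exact_nb_test(df, ["A", "B", "C"], fit)

    def test_equal_library_pseudocounts_are_raw_counts(self):
        df = pd.DataFrame([[10, 20, 30, 40], [5, 5, 5, 5]], columns=list("abcd"))
        pseudo, n_star = equalize_library_sizes(
            df, pd.Series(100.0, index=list("abcd")), ["A", "A", "B", "B"], 0.1
        )
        assert np.allclose(pseudo.to_numpy(), df.to_numpy())
        assert n_star == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

class TestStoreyQ:
    def test_all_ones(self):
        assert np.allclose(storey_qvalues(np.ones(50)), 1.0)

    def test_pi0_one_reproduces_bh(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        q = storey_qvalues(p, pi0=1.0)
        # direct BH computation
        order = np.argsort(p)
        bh = p[order] * len(p) / np.arange(1, len(p) + 1)
        bh = np.minimum.accumulate(bh[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(bh, 1)
        assert np.allclose(q, expected)

    def test_pi0_near_one_on_uniform_null(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=5000)
        q = storey_qvalues(p)
        # q = pi0 * BH; recover the implied pi0 from the largest ratio
        bh = storey_qvalues(p, pi0=1.0)
        pi0 = np.max(q / np.maximum(bh, 1e-12))
        assert 0.9 <= pi0 <= 1.0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=300) ** 2
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


# ---------------------------------------------------------------------------
# model-level behaviour
# ---------------------------------------------------------------------------

class TestModel:
    def test_logfc_recovery_slope(self, medium_counts):
        params, effects, matrix = medium_counts
        collapsed = bt.collapse_tags_and_technical(matrix)
        res = NBExactModel(collapsed, "treatment").fit()
        truth = pd.Series(effects.log2fc, index=effects.mutant_ids)
        totals = collapsed.counts.sum(axis=1)
        keep = totals[totals > 1000].index
        x, y = truth.loc[keep], res.table.loc[keep, "logFC"]
        slope = np.polyfit(x, y, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_summary_mentions_key_quantities(self, medium_counts):
        _, _, matrix = medium_counts
        res = NBExactModel(bt.collapse_tags_and_technical(matrix), "treatment").fit()
        text = res.summary()
        assert "dispersion" in text and "significant" in text
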
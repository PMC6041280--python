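"""Statistical layer vs independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorequiv.exceptions import UndefinedCorrelationError
from motorequiv.landmarks import LandmarkTable
from motorequiv.stats import (
    compare_tools,
    correlation_power,
    effector_correlation_matrix,
    holm_adjust,
    pearson_r,
    posthoc_paired_t_holm,
    r_to_p,
    rm_anova,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())


def brute_holm(p, alpha=0.05):
    """Literal step-down execution of Holm's rule."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject


def brute_bonferroni(p, alpha=0.05):
    return np.asarray(p) <= alpha / len(p)


def brute_rm_anova_F(mat):
    """Sum-of-squares decomposition of a subjects x conditions matrix."""
    mat = np.asarray(mat, float)
    n, k = mat.shape
    grand = mat.mean()
    cond_means = mat.mean(axis=0)
    subj_means = mat.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = mat - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


# ---------------------------------------------------------------------------


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert pearson_r(x, y) == pytest.approx(brute_pearson(x, y), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestRToP:
    def test_null_value(self):
        assert r_to_p(0.0, 10) == pytest.approx(1.0)

    def test_t_distribution_oracle(self):
        """r = 0.68, n = 10: p from the Student density at
        t = 0.68 sqrt(8)/sqrt(1 - 0.4624)."""
        from scipy.integrate import quad
        from scipy.stats import t as tdist

        t_stat = 0.68 * np.sqrt(8) / np.sqrt(1 - 0.68**2)
        tail, _ = quad(lambda u: tdist.pdf(u, 8), t_stat, np.inf)
        assert r_to_p(0.68, 10) == pytest.approx(2 * tail, rel=1e-6)
        assert r_to_p(0.68, 10) == pytest.approx(0.0305, abs=5e-4)

    def test_monotone_in_magnitude(self):
        assert r_to_p(0.9, 10) < r_to_p(0.8, 10)

    def test_boundary(self):
        assert r_to_p(1.0, 10) == 0.0


class TestHolm:
    def test_hand_executed_example(self):
        """0.011 > 0.05/5 stops the chain after the first rejection."""
        p = [0.001, 0.011, 0.02, 0.03, 0.04, 0.2]
        np.testing.assert_array_equal(
            holm_adjust(p), [True, False, False, False, False, False]
        )

    def test_all_tiny_all_significant(self):
        assert holm_adjust([0.001] * 6).all()

    def test_bracketed_by_bonferroni_and_unadjusted(self):
        """On 1000 random p-vectors: Bonferroni ⊆ Holm ⊆ unadjusted, and
        Holm equals the literal step-down rule."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            holm = holm_adjust(p)
            np.testing.assert_array_equal(holm, brute_holm(p))
            bonf = brute_bonferroni(p)
            raw = p <= 0.05
            assert (holm | ~bonf).all()  # bonferroni rejections subset
            assert (raw | ~holm).all()  # holm subset of unadjusted

    def test_permutation_invariance(self):
        p = np.array([0.001, 0.04, 0.011, 0.2, 0.02, 0.03])
        perm = np.random.default_rng(3).permutation(6)
        np.testing.assert_array_equal(holm_adjust(p)[perm], holm_adjust(p[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([])


class TestCorrelationPower:
    def test_size_of_test_at_null(self):
        assert correlation_power(0.0, 10) == pytest.approx(0.05, abs=1e-9)

    def test_fisher_z_value_at_r08_n10(self):
        """Direct evaluation: Phi(sqrt(7) atanh(0.8) - 1.96) ~ 0.83."""
        from scipy.stats import norm

        direct = norm.cdf(np.sqrt(7) * np.arctanh(0.8) - norm.ppf(0.975)) + \
            norm.cdf(-np.sqrt(7) * np.arctanh(0.8) - norm.ppf(0.975))
        p = correlation_power(0.80, 10)
        assert p == pytest.approx(direct, rel=1e-12)
        assert p > 0.80

    def test_strictly_increasing_in_rho(self):
        rhos = np.linspace(0.05, 0.95, 19)
        powers = [correlation_power(r, 10) for r in rhos]
        assert all(b > a for a, b in zip(powers, powers[1:]))


class TestRmAnova:
    def test_df_structure(self):
        mat = np.random.default_rng(0).normal(size=(10, 4))
        res = rm_anova(mat)
        assert (res.df_num, res.df_den) == (3, 27)

    def test_zero_condition_variance_gives_zero_F(self):
        base = np.random.default_rng(1).normal(size=(8, 1))
        res = rm_anova(np.repeat(base, 4, axis=1))
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_100_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 12)
            k = rng.integers(2, 6)
            mat = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = rm_anova(mat)
            assert res.F == pytest.approx(brute_rm_anova_F(mat), rel=1e-8)
            assert (res.df_num, res.df_den) == (k - 1, (k - 1) * (n - 1))

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        mat = np.random.default_rng(5).normal(size=(10, 4))
        long = pd.DataFrame(mat).reset_index(names="subj").melt(
            id_vars="subj", var_name="cond", value_name="y"
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        res = rm_anova(mat)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


class TestPairedPosthoc:
    def test_identical_conditions_not_significant(self):
        base = np.random.default_rng(2).normal(size=(8, 1))
        results = posthoc_paired_t_holm(np.repeat(base, 4, axis=1))
        assert all(r.degenerate for r in results)
        assert not any(r.holm_significant for r in results)

    def test_shifted_condition_detected(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(12, 4))
        mat[:, 0] += 50.0
        results = posthoc_paired_t_holm(mat)
        for r in results:
            involves_shifted = "c0" in r.pair
            assert r.holm_significant == involves_shifted

    def test_equals_one_sample_t_on_differences(self):
        from scipy.stats import ttest_1samp

        rng = np.random.default_rng(4)
        mat = rng.normal(size=(9, 3))
        results = posthoc_paired_t_holm(mat)
        cols = {f"c{i}": i for i in range(3)}
        for r in results:
            d = mat[:, cols[r.pair[0]]] - mat[:, cols[r.pair[1]]]
            t_ref, p_ref = ttest_1samp(d, 0.0)
            assert r.t == pytest.approx(float(t_ref), rel=1e-10)
            assert r.p == pytest.approx(float(p_ref), rel=1e-10)


def _toy_table(n=10, seed=0, n_tools=3):
    """Preserved-structure synthetic landmark table (no kinematics)."""
    rng = np.random.default_rng(seed)
    rows = []
    tools = ["hammer", "brush", "roller"][:n_tools]
    for tool in tools:
        base = rng.normal(10, 3, size=n) + 5 * tools.index(tool)
        for eff_i, eff in enumerate(
            ["right_foot", "right_elbow", "left_hand", "right_hand"]
        ):
            vals = base * (1 + 0.05 * eff_i) + rng.normal(0, 0.2, size=n)
            for p_i, v in enumerate(vals):
                rows.append({
                    "participant": f"P{p_i:02d}", "tool": tool,
                    "effector": eff, "parameter": "cycle_duration",
                    "value": v,
                })
    return LandmarkTable(pd.DataFrame(rows))


class TestEffectorCorrelationMatrix:
    def test_preserved_structure_high_r(self):
        m = effector_correlation_matrix(_toy_table(seed=1), "hammer",
                                        "cycle_duration")
        assert len(m.entries) == 6
        assert (m.r_values > 0.5).all()

    def test_affine_pair_r_equals_one(self):
        table = _toy_table(seed=2)
        df = table.data
        hammer = df["tool"] == "hammer"
        lh = df[hammer & (df["effector"] == "left_hand")].set_index(
            "participant")["value"]
        mask = hammer & (df["effector"] == "right_hand")
        df.loc[mask, "value"] = (
            2.0 * df.loc[mask, "participant"].map(lh) + 7.0
        ).to_numpy()
        m = effector_correlation_matrix(LandmarkTable(df), "hammer",
                                        "cycle_duration")
        pair_r = [e.r for e in m.entries
                  if set(e.pair) == {"left_hand", "right_hand"}][0]
        assert pair_r == pytest.approx(1.0)

    def test_flags_consistent_with_holm(self):
        m = effector_correlation_matrix(_toy_table(seed=3), "brush",
                                        "cycle_duration")
        np.testing.assert_array_equal(m.significant, brute_holm(m.p_values))

    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_uniform_affine_rescaling(self, scale, shift):
        table = _toy_table(seed=4, n_tools=1)
        m0 = effector_correlation_matrix(table, "hammer", "cycle_duration")
        df = table.data.copy()
        df["value"] = df["value"] * scale + shift
        m1 = effector_correlation_matrix(LandmarkTable(df), "hammer",
                                         "cycle_duration")
        np.testing.assert_allclose(m1.r_values, m0.r_values, rtol=1e-9)


class TestCompareTools:
    def test_df_structure_3_tools_10_participants(self):
        res = compare_tools(_toy_table(n=10, seed=5), "cycle_duration")
        assert (res.df_num, res.df_den) == (2, 27)

    def test_identical_tools_zero_F(self):
        table = _toy_table(n=8, seed=6)
        df = table.data
        hammer = df[df["tool"] == "hammer"].set_index(
            ["participant", "effector"])["value"]
        for tool in ("brush", "roller"):
            mask = df["tool"] == tool
            df.loc[mask, "value"] = df.loc[mask].set_index(
                ["participant", "effector"]).index.map(hammer).to_numpy()
        res = compare_tools(LandmarkTable(df), "cycle_duration", posthoc=False)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_between_groups_ss(self):
        table = _toy_table(n=10, seed=8)
        res = compare_tools(table, "cycle_duration", posthoc=False)
        groups = [
            table.values_matrix(t, "cycle_duration").mean(axis=1).to_numpy()
            for t in table.tools
        ]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert res.F == pytest.approx(F, rel=1e-10)
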
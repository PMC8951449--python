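"""Edgewise group statistics, FDR control, duration models, cohort balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cstcnet as c
from tests.conftest import group_indices


def matrix_from_edges(edges, kind="static_z"):
    """Symmetric 20x20 matrix with given upper-triangle entries."""
    m = np.zeros((20, 20))
    iu = np.triu_indices(20, k=1)
    m[iu] = edges
    return c.ConnectivityMatrix(m + m.T, kind=kind)


def null_cohort(rng, n, scale=0.065):
    return [matrix_from_edges(rng.normal(0, scale, 190)) for _ in range(n)]


class TestEdgewiseTTest:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        group = null_cohort(rng, 5)
        res = c.edgewise_ttest(group, list(group))
        assert np.allclose(res.table.statistic.dropna(), 0.0)
        assert not res.table.significant.any()

    def test_hand_computed_pooled_t(self):
        """One edge with A=[1,2,3], B=[2,3,4]: pooled t = -1.2247, df=4."""
        a = [matrix_from_edges(np.r_[v, np.zeros(189)]) for v in (1.0, 2.0, 3.0)]
        b = [matrix_from_edges(np.r_[v, np.zeros(189)]) for v in (2.0, 3.0, 4.0)]
        res = c.edgewise_ttest(a, b)
        t0 = res.table.statistic.iloc[0]
        assert t0 == pytest.approx(-np.sqrt(3 / 2), abs=1e-10)
        assert res.table.p.iloc[0] == pytest.approx(2 * sps.t.sf(np.sqrt(1.5), 4), abs=1e-12)

    def test_zero_variance_edges_excluded_from_family(self):
        a = [matrix_from_edges(np.r_[1.0, np.zeros(189)]) for _ in range(3)]
        b = [matrix_from_edges(np.r_[2.0, np.zeros(189)]) for _ in range(3)]
        res = c.edgewise_ttest(a, b)
        assert np.isnan(res.table.p).all()  # every edge constant within groups
        assert not res.table.significant.any()

    def test_planted_mean_shifts_detected_with_bounded_false_positives(self):
        """Four edges shifted by 0.3 at n=30/group: all four detected,
        false positives among the 186 null edges within the q=0.05
        binomial bound."""
        rng = np.random.default_rng(1)
        planted = [0, 50, 100, 150]
        a, b = [], []
        for _ in range(30):
            ea = rng.normal(0, 0.065, 190)
            eb = rng.normal(0, 0.065, 190)
            eb[planted] += 0.3
            a.append(matrix_from_edges(ea))
            b.append(matrix_from_edges(eb))
        res = c.edgewise_ttest(a, b)
        sig = res.table.significant.to_numpy()
        assert sig[planted].all()
        false_pos = sig.sum() - 4
        assert false_pos <= 3  # P(X>3 | Bin(186, ~0.0025)) is negligible

    def test_mixed_kinds_rejected(self):
        rng = np.random.default_rng(2)
        a = null_cohort(rng, 3)
        b = [matrix_from_edges(rng.normal(0, 1, 190), kind="dfc_sd_z") for _ in range(3)]
        with pytest.raises(ValueError, match="kind"):
            c.edgewise_ttest(a, b)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(3)
        a, b = null_cohort(rng, 6), null_cohort(rng, 6)
        res1 = c.edgewise_ttest(a, b)
        transposed = [
            c.ConnectivityMatrix(m.values.T, kind=m.kind) for m in a
        ]
        res2 = c.edgewise_ttest(transposed, b)
        pd.testing.assert_frame_equal(res1.table, res2.table)


class TestBhFdr:
    def test_hand_step_up_example(self):
        """p = [0.01, 0.02, 0.03, 0.5]: BH thresholds k*0.05/4 reject the
        first three."""
        q = c.bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)
        assert (q[:3] < 0.05).all() and q[3] >= 0.05

    def test_all_ones_no_rejection(self):
        q = c.bh_fdr(np.ones(10))
        np.testing.assert_array_equal(q, np.ones(10))

    def test_single_p_unchanged(self):
        assert c.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            c.bh_fdr([0.5, 1.2])

    def test_fdr_controlled_on_null_simulations(self):
        """Fully null edge families: empirical false-discovery proportion
        stays within Monte-Carlo error of the nominal 0.05."""
        rng = np.random.default_rng(4)
        n_rep, n_edges = 500, 190
        fdp = []
        for _ in range(n_rep):
            p = rng.uniform(size=n_edges)
            q = c.bh_fdr(p)
            rejected = (q < 0.05).sum()
            fdp.append(rejected / max(rejected, 1) if rejected else 0.0)
        mc_se = np.std(fdp) / np.sqrt(n_rep)
        assert np.mean(fdp) <= 0.05 + 2 * mc_se + 1e-9


class TestDurationCorrelation:
    def test_exactly_linear_edge_gives_r_one(self):
        durations = np.array([1.0, 3.0, 5.0, 9.0, 12.0])
        mats = [matrix_from_edges(np.r_[0.1 * d, np.zeros(189)]) for d in durations]
        res = c.edgewise_duration_correlation(mats, durations)
        assert res.table.statistic.iloc[0] == pytest.approx(1.0)
        assert res.table.p.iloc[0] < 1e-12

    def test_planted_negative_slope_recovered(self):
        rng = np.random.default_rng(5)
        durations = rng.uniform(0.5, 25, 60)
        mats = []
        for d in durations:
            e = rng.normal(0, 0.1, 190)
            e[7] += -0.02 * d
            mats.append(matrix_from_edges(e))
        res = c.edgewise_duration_correlation(mats, durations)
        row = res.table.iloc[7]
        assert row.statistic < 0 and row.significant

    def test_null_edges_reject_at_nominal_rate(self):
        rng = np.random.default_rng(6)
        rates = []
        for _ in range(50):
            durations = rng.uniform(0.5, 25, 40)
            mats = [matrix_from_edges(rng.normal(0, 0.1, 190)) for _ in durations]
            res = c.edgewise_duration_correlation(mats, durations)
            rates.append((res.table.p < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)

    def test_constant_durations_rejected(self):
        mats = null_cohort(np.random.default_rng(7), 6)
        with pytest.raises(ValueError, match="constant"):
            c.edgewise_duration_correlation(mats, np.full(6, 5.0))


class TestInteractionModel:
    @staticmethod
    def build(slopes, n_per_group=10, noise=0.0, seed=8):
        rng = np.random.default_rng(seed)
        mats, groups, durations = [], [], []
        for g, slope in slopes.items():
            for _ in range(n_per_group):
                d = rng.uniform(1, 20)
                e = np.zeros(190)
                e[0] = slope * d + rng.normal(0, noise)
                e[1:] = rng.normal(0, max(noise, 1e-3), 189)
                mats.append(matrix_from_edges(e))
                groups.append(g)
                durations.append(d)
        return mats, np.array(groups), np.array(durations)

    def test_equal_slopes_give_zero_interaction(self):
        mats, groups, durations = self.build({"GE": 0.5, "FE": 0.5})
        res = c.interaction_model(mats, groups, durations)
        assert res.table.statistic.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_slopes_give_minus_one(self):
        """GE slope +0.5, FE slope -0.5 noiselessly: b3 = -1.0 under
        GE=0/FE=1 coding."""
        mats, groups, durations = self.build({"GE": 0.5, "FE": -0.5})
        res = c.interaction_model(mats, groups, durations)
        assert res.table.statistic.iloc[0] == pytest.approx(-1.0, abs=1e-10)
        assert "GE=0, FE=1" in res.notes

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        mats, groups, durations = self.build({"GE": 0.3, "FE": -0.1}, noise=0.05)
        res = c.interaction_model(mats, groups, durations)
        y = np.array([m.edge_vector()[0] for m in mats])
        g = (groups == "FE").astype(float)
        x = sm.add_constant(np.column_stack([g, durations, g * durations]))
        fit = sm.OLS(y, x).fit()
        assert res.table.statistic.iloc[0] == pytest.approx(fit.params[3], abs=1e-10)
        assert res.table.t.iloc[0] == pytest.approx(fit.tvalues[3], abs=1e-8)

    def test_noisy_opposite_slopes_significant_after_fdr(self):
        mats, groups, durations = self.build(
            {"GE": 0.01, "FE": -0.01}, n_per_group=57, noise=0.05, seed=9
        )
        res = c.interaction_model(mats, groups, durations)
        assert res.table.significant.iloc[0]

    def test_one_group_rejected(self):
        mats, groups, durations = self.build({"GE": 0.5})
        with pytest.raises(ValueError, match="two groups"):
            c.interaction_model(mats, groups, durations)


class TestCohortBalance:
    @staticmethod
    def phen(n=114, females=39, age_jitter=None):
        rows = []
        rng = np.random.default_rng(10)
        for g in ("HC", "GE", "FE"):
            ages = np.linspace(20, 40, n)
            if age_jitter:
                ages = ages + rng.normal(0, age_jitter, n)
            for k in range(n):
                rows.append(
                    {
                        "id": f"{g}{k}",
                        "group": g,
                        "sex": "F" if k < females else "M",
                        "age": ages[k],
                        "duration_years": np.nan if g == "HC" else rng.uniform(1, 15),
                        "seizure_freq_per_month": np.nan if g == "HC" else rng.uniform(0.5, 4),
                    }
                )
        return pd.DataFrame(rows)

    def test_matched_sex_counts_give_zero_chi_square(self):
        """Three groups each 75 male / 39 female: Pearson chi-square is
        exactly 0 (p = 1)."""
        balance = c.cohort_balance(self.phen())
        assert balance.sex_chi2 == pytest.approx(0.0, abs=1e-12)
        assert balance.sex_p == pytest.approx(1.0)

    def test_identical_ages_give_zero_f(self):
        balance = c.cohort_balance(self.phen())
        assert balance.age_f == pytest.approx(0.0, abs=1e-12)

    def test_anova_matches_sums_of_squares_oracle(self):
        phen = self.phen(n=30, age_jitter=3.0)
        balance = c.cohort_balance(phen)
        groups = [phen.loc[phen.group == g, "age"].to_numpy() for g in ("HC", "GE", "FE")]
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = 3, sum(len(g) for g in groups)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert balance.age_f == pytest.approx(f_oracle, abs=1e-10)

    def test_duration_t_matches_scipy(self):
        phen = self.phen(n=20, age_jitter=1.0)
        balance = c.cohort_balance(phen)
        ge = phen.loc[phen.group == "GE", "duration_years"]
        fe = phen.loc[phen.group == "FE", "duration_years"]
        t, p = sps.ttest_ind(ge, fe, equal_var=True)
        assert balance.duration_t == pytest.approx(t, abs=1e-12)
        assert balance.duration_p == pytest.approx(p, abs=1e-12)


class TestGeneratorLevelStats:
    def test_planted_static_deltas_detected_in_cohort(self, roi_cohort):
        """GE vs HC on static networks: the two planted thalamic edges
        survive FDR."""
        cohort, static, dyn_sd = roi_cohort
        ge = [static[i] for i in group_indices(cohort, "GE")]
        hc = [static[i] for i in group_indices(cohort, "HC")]
        res = c.edgewise_ttest(ge, hc)
        sig = {
            frozenset((r.edge_i, r.edge_j))
            for r in res.significant_edges.itertuples()
        }
        assert frozenset(("cortex-motor", "thalamus-motor")) in sig
        assert frozenset(("cortex-somatosensory", "thalamus-somatosensory")) in sig

    def test_planted_dynamic_effect_detected(self, roi_cohort):
        cohort, static, dyn_sd = roi_cohort
        ge = [dyn_sd[i] for i in group_indices(cohort, "GE")]
        fe = [dyn_sd[i] for i in group_indices(cohort, "FE")]
        res = c.edgewise_ttest(ge, fe)
        assert res.table.significant.any()
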
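"""Inference wrappers: Shapiro-Wilk, mixed ANOVA, Holm-Sidak, t, d, Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bandstates import (
    cohens_d,
    cohens_d_from_stats,
    holm_sidak,
    mann_whitney_u,
    mixed_anova,
    shapiro_wilk,
    two_group_t,
    two_group_t_from_stats,
)
from bandstates.stats import auto_two_group_test


class TestShapiroWilk:
    def test_normal_quantiles_fit_well(self):
        x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, _p = shapiro_wilk(x)
        assert w > 0.99
        assert w <= 1.0

    def test_bimodal_rejected(self):
        x = np.concatenate([np.full(25, -10.0), np.full(25, 10.0)])
        x += np.linspace(-0.01, 0.01, 50)  # break exact ties
        _w, p = shapiro_wilk(x)
        assert p < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))


class TestMixedAnova:
    @staticmethod
    def _toy(values):
        # 2 groups x 2 subjects x 4 states
        rows = []
        for gi, g in enumerate(("HC", "MD")):
            for si in range(2):
                for ci, c in enumerate("ABCD"):
                    rows.append(
                        {"subject_id": f"{g}{si}", "group": g, "state": c,
                         "value": values[gi, si, ci]}
                    )
        return pd.DataFrame(rows)

    def test_planted_interaction_matches_hand_anova(self):
        # additive group and state effects plus a pure interaction term
        base = np.zeros((2, 2, 4))
        interaction = np.array([[1.0, -1.0, 0.0, 0.0], [-1.0, 1.0, 0.0, 0.0]])
        for gi in range(2):
            base[gi, :, :] += interaction[gi]
        base += np.array([[[0.0]], [[2.0]]])  # group main effect
        df = self._toy(base)
        aov = mixed_anova(df)
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        # hand-computed split-plot SS: n_per_cell=2 subjects, SS_int = 2*sum(cell_dev^2)
        assert inter["SS"] == pytest.approx(2 * np.sum(interaction**2))
        # no residual noise: subject-level error is zero, F blows up or is huge
        assert inter["F"] > 1e10 or np.isnan(inter["F"])

    def test_identical_values_degenerate(self):
        df = self._toy(np.ones((2, 2, 4)))
        aov = mixed_anova(df)
        f = aov["F"].to_numpy(dtype=float)
        assert np.all(np.isnan(f) | (np.abs(f) < 1e-9))

    def test_within_permutation_symmetry(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((2, 2, 4))
        aov1 = mixed_anova(self._toy(vals))
        aov2 = mixed_anova(self._toy(vals[:, :, [2, 0, 3, 1]]))
        np.testing.assert_allclose(
            aov1["F"].to_numpy(float), aov2["F"].to_numpy(float), rtol=1e-9
        )

    def test_missing_cells_rejected(self):
        df = self._toy(np.random.default_rng(1).standard_normal((2, 2, 4)))
        with pytest.raises(ValueError):
            mixed_anova(df.drop(df.index[0]))


class TestHolmSidak:
    def test_single_p_unchanged(self):
        adj, _ = holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_hand_computed_stepdown(self):
        adj, _ = holm_sidak([0.01, 0.04, 0.03])
        # sorted (0.01, 0.03, 0.04): 1-(1-p)^(m-i+1), monotone-enforced
        assert adj[0] == pytest.approx(1 - 0.99**3)
        assert adj[2] == pytest.approx(1 - 0.97**2)
        assert adj[1] == pytest.approx(max(1 - 0.96, 1 - 0.97**2))

    def test_zero_p_stay_zero(self):
        adj, rej = holm_sidak([0.0, 0.0, 0.0])
        assert np.allclose(adj, 0.0)
        assert rej.all()

    def test_matches_definitional_procedure_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            m = int(rng.integers(1, 21))
            p = rng.uniform(size=m)
            adj, _ = holm_sidak(p)
            # independent step-down construction
            order = np.argsort(p)
            expected = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                val = 1.0 - (1.0 - p[idx]) ** (m - rank)
                running = max(running, val)
                expected[idx] = running
            np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=12)
        adj, _ = holm_sidak(p)
        assert np.all(adj >= p - 1e-15)


class TestTwoGroupT:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = two_group_t(x, x, variant="pooled")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_printed_summary_stats_give_printed_t(self):
        res = two_group_t_from_stats(31, 0.383, 0.104, 19, 0.162, 0.040, variant="pooled")
        assert res.statistic == pytest.approx(8.89, abs=0.10)
        assert res.df == 48

    def test_matches_reference_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.standard_normal(8) + 0.5
            y = rng.standard_normal(6)
            res = two_group_t(x, y, variant="welch")
            # independent formula evaluation
            v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
            t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
            p = 2 * sps.t.sf(abs(t), df)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_welch_reduces_to_pooled_when_balanced(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        y = (y - y.mean()) / y.std(ddof=1) * x.std(ddof=1) + y.mean()  # equal sd
        w = two_group_t(x, y, variant="welch")
        p = two_group_t(x, y, variant="pooled")
        assert w.statistic == pytest.approx(p.statistic, abs=1e-12)

    def test_auto_variant_uses_levene(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40) * 8.0
        assert auto_two_group_test(x, y).test == "t_welch"
        z = rng.standard_normal(40)
        assert auto_two_group_test(x, z).test == "t_pooled"


class TestCohensD:
    def test_equal_means_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x + 0.0) == pytest.approx(0.0)

    def test_printed_summary_stats(self):
        d = cohens_d_from_stats(31, 0.383, 0.104, 19, 0.162, 0.040)
        assert d == pytest.approx(2.59, abs=0.03)

    def test_scale_equivariance(self):
        d1 = cohens_d_from_stats(10, 1.0, 0.5, 10, 0.0, 0.5)
        d2 = cohens_d_from_stats(10, 1.0, 1.0, 10, 0.0, 1.0)
        assert d1 == pytest.approx(2 * d2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(5), np.ones(5))


class TestMannWhitney:
    def test_complete_dominance(self):
        u, _p = mann_whitney_u([1.0, 2.0], [0.0])
        assert u == 2.0

    def test_tie_convention(self):
        u, _p = mann_whitney_u([5.0], [5.0])
        assert u == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.integers(0, 8, size=6).astype(float)
            y = rng.integers(0, 8, size=5).astype(float)
            u, _p = mann_whitney_u(x, y)
            brute = sum(
                1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y
            )
            assert u == pytest.approx(brute)

    def test_orientation_complement(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal(9), rng.standard_normal(7)
        u1, _ = mann_whitney_u(x, y)
        u2, _ = mann_whitney_u(y, x)
        assert u1 + u2 == pytest.approx(63.0)
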
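import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from txprot.core import Contrast, ValidationError
from txprot.diffexpr import (
    EbayesPrior,
    bh_adjust,
    estimate_prior,
    fit_gene_models,
    moderated_t,
    run_differential,
)
from tests.conftest import protein_matrix


@pytest.fixture()
def two_group(toy_protein_design):
    samples = toy_protein_design.samples()  # vehicle r1-3 then agonist r1-3

    def build(vehicle_vals, agonist_vals, n_features=1):
        values = np.tile(
            np.asarray(vehicle_vals + agonist_vals, dtype=float),
            (n_features, 1),
        )
        return protein_matrix(values, samples)

    return build


CONTRAST = Contrast("agonist", "vehicle", "early")


class TestFitGeneModels:
    def test_hand_computation(self, two_group, toy_protein_design):
        mat = two_group([2.0, 2.0, 2.0], [4.0, 4.0, 4.0])
        fit = fit_gene_models(mat, toy_protein_design, CONTRAST)
        assert fit["coef"].iloc[0] == pytest.approx(2.0)
        assert fit["s2"].iloc[0] == pytest.approx(0.0)
        assert fit["df"].iloc[0] == 4
        assert fit["stdev_unscaled"].iloc[0] == pytest.approx(
            np.sqrt(2.0 / 3.0)
        )

    def test_identical_groups_zero_coef(self, two_group, toy_protein_design):
        mat = two_group([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        fit = fit_gene_models(mat, toy_protein_design, CONTRAST)
        assert fit["coef"].iloc[0] == pytest.approx(0.0)

    def test_missing_condition_rejected(self, two_group, toy_protein_design):
        mat = two_group([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        bad = Contrast("agonist_antagonist", "vehicle", "early")
        with pytest.raises(ValidationError):
            fit_gene_models(mat, toy_protein_design, bad)

    def test_pooled_variance(self, two_group, toy_protein_design):
        mat = two_group([1.0, 2.0, 3.0], [4.0, 6.0, 8.0])
        fit = fit_gene_models(mat, toy_protein_design, CONTRAST)
        expected = (
            2 * np.var([1, 2, 3], ddof=1) + 2 * np.var([4, 6, 8], ddof=1)
        ) / 4
        assert fit["s2"].iloc[0] == pytest.approx(expected)


class TestEstimatePrior:
    def test_degenerate_equal_variances(self):
        prior = estimate_prior(np.full(100, 0.05), np.full(100, 4.0))
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.05)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        d0_true, s0_true = 4.0, 0.05
        s2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        big_df = np.full(5000, 1e6)  # draws are prior samples, no extra noise
        prior = estimate_prior(s2, big_df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_full_hierarchy_recovery(self):
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 4.0, 0.05, 4
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        prior = estimate_prior(s2, np.full(5000, float(df)))
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_boundary_infinite_d0(self):
        # variance of log s2 far below the sampling term -> d0 = inf
        rng = np.random.default_rng(2)
        s2 = 0.05 * np.exp(rng.normal(0, 0.001, 200))
        prior = estimate_prior(s2, np.full(200, 4.0))
        assert np.isinf(prior.d0)

    def test_too_few_variances(self):
        with pytest.raises(ValidationError):
            estimate_prior(np.full(5, 0.1), np.full(5, 4.0))


class TestModeratedT:
    def test_zero_coef(self):
        prior = EbayesPrior(d0=4.0, s0_sq=0.05)
        t, p, _ = moderated_t([0.0], [0.8], [0.1], [4.0], prior)
        assert t[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_infinite_d0_flat_variance(self):
        prior = EbayesPrior(d0=np.inf, s0_sq=0.07)
        rng = np.random.default_rng(3)
        s2 = rng.uniform(0.01, 1.0, 50)
        t, _, _ = moderated_t(
            np.ones(50), np.full(50, 0.8), s2, np.full(50, 4.0), prior
        )
        assert np.allclose(t, 1.0 / (0.8 * np.sqrt(0.07)))

    def test_d0_zero_equals_classical_t(self):
        rng = np.random.default_rng(4)
        prior = EbayesPrior(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 1, 5)
            coef = a.mean() - b.mean()
            s2 = (
                ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            ) / (len(a) + len(b) - 2)
            su = np.sqrt(1 / len(a) + 1 / len(b))
            t_mod, p_mod, _ = moderated_t(
                [coef], [su], [s2], [len(a) + len(b) - 2.0], prior
            )
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert t_mod[0] == pytest.approx(t_ref, abs=1e-10)
            assert p_mod[0] == pytest.approx(p_ref, abs=1e-10)

    def test_shrinkage_monotonicity(self):
        # a low-variance feature's |t| shrinks as d0 grows
        coef, su, s2, df = 1.0, 0.8, 0.001, 4.0
        s0 = 0.5  # prior variance well above the feature's own
        ts = [
            abs(
                moderated_t([coef], [su], [s2], [df],
                            EbayesPrior(d0=d0, s0_sq=s0))[0][0]
            )
            for d0 in (0.5, 2.0, 8.0, 32.0)
        ]
        assert all(a > b for a, b in zip(ts, ts[1:]))


class TestBhAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @staticmethod
    def _oracle(p):
        """Definition-level step-up: q_i = min over k with p_(k) >= p_i of
        m * p_(k) / k, capped at 1."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        sp = p[order]
        q = np.empty(m)
        for i in range(m):
            q[i] = min(min(m * sp[k] / (k + 1) for k in range(i, m)), 1.0)
        out = np.empty(m)
        out[order] = q
        return out

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_statsmodels_equivalence(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(50)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        perm = rng.permutation(200)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_fdr_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(500)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestRunDifferential:
    def test_planted_effect_dominates(self, toy_protein_design):
        rng = np.random.default_rng(10)
        samples = toy_protein_design.samples()
        values = rng.normal(20, 0.05, size=(200, 6))
        values[0, 3:] += 2.0  # strong planted shift in agonist group
        mat = protein_matrix(values, samples)
        tables = run_differential(mat, toy_protein_design, [CONTRAST])
        table = tables[CONTRAST.name]
        assert table["fdr"].idxmin() == "p0"

    def test_empty_contrast_list(self, small_sim):
        assert run_differential(
            small_sim["protein"], small_sim["design"], []
        ) == {}

    def test_fdr_column_valid(self, toy_protein_design):
        rng = np.random.default_rng(11)
        mat = protein_matrix(
            rng.normal(20, 1, size=(300, 6)), toy_protein_design.samples()
        )
        table = run_differential(
            mat, toy_protein_design, [CONTRAST]
        )[CONTRAST.name]
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
        assert (table["fdr"] >= table["p"] - 1e-12).all()
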
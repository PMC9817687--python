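import numpy as np
import pandas as pd
import pytest

from txprot.core import ExpressionMatrix, GeneLengths, ValidationError
from txprot.preprocess import (
    count_theoretical_peptides,
    counts_to_tpm,
    filter_detected_proteins,
    filter_expressed_genes,
    ibaq_transform,
    impute_missing,
    median_normalize,
)
from tests.conftest import protein_matrix


def counts_matrix(values, feature_ids=None, sample_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    feature_ids = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), "counts"
    )


class TestCountsToTpm:
    def test_hand_calculation(self):
        counts = counts_matrix([[10], [20]])
        lengths = GeneLengths(pd.Series([1000.0, 2000.0], index=["g0", "g1"]))
        tpm = counts_to_tpm(counts, lengths)
        assert np.allclose(tpm.values.to_numpy().ravel(), [500000, 500000])

    def test_all_zero_sample_warns(self):
        counts = counts_matrix([[0], [0]])
        lengths = GeneLengths(pd.Series([1000.0, 2000.0], index=["g0", "g1"]))
        with pytest.warns(UserWarning):
            tpm = counts_to_tpm(counts, lengths)
        assert (tpm.values.to_numpy() == 0).all()

    def test_single_gene_is_million(self):
        counts = counts_matrix([[7]])
        lengths = GeneLengths(pd.Series([543.0], index=["g0"]))
        tpm = counts_to_tpm(counts, lengths)
        assert tpm.values.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_million(self, small_sim):
        tpm = counts_to_tpm(small_sim["rna"], small_sim["lengths"])
        sums = tpm.values.sum(axis=0).to_numpy()
        assert np.allclose(sums, 1e6, rtol=1e-6)


class TestFilterExpressedGenes:
    def _tpm(self, rows):
        values = np.asarray(rows, dtype=float)
        return ExpressionMatrix(
            pd.DataFrame(
                values,
                index=[f"g{i + 1}" for i in range(values.shape[0])],
                columns=[f"s{i}" for i in range(values.shape[1])],
            ),
            "tpm",
        )

    def test_hand_count(self):
        tpm = self._tpm(
            [[1.2, 1.5, 0.9, 2.0], [0.5, 0.8, 1.1, 0.2], [1.0, 1.0, 1.0, 0.0]]
        )
        assert filter_expressed_genes(tpm) == ["g1", "g3"]

    def test_all_zero_empty(self):
        tpm = self._tpm([[0, 0, 0, 0], [0, 0, 0, 0]])
        assert filter_expressed_genes(tpm) == []

    def test_zero_threshold_keeps_all(self):
        tpm = self._tpm([[0, 0, 0, 0], [5, 0, 0, 0]])
        assert filter_expressed_genes(tpm, min_tpm=0) == ["g1", "g2"]

    def test_min_samples_exceeds_n(self):
        tpm = self._tpm([[1, 1]])
        with pytest.raises(ValidationError):
            filter_expressed_genes(tpm, min_samples=3)

    def test_idempotent(self, small_sim):
        tpm = counts_to_tpm(small_sim["rna"], small_sim["lengths"])
        once = filter_expressed_genes(tpm)
        twice = filter_expressed_genes(tpm.subset_features(once))
        assert once == twice


class TestFilterDetectedProteins:
    def test_one_complete_group_kept(self, toy_protein_design):
        samples = toy_protein_design.samples()
        values = np.full((1, 6), 20.0)
        values[0, 3:] = np.nan  # agonist replicates all missing
        mat = protein_matrix(values, samples)
        assert filter_detected_proteins(mat, toy_protein_design) == ["p0"]

    def test_no_complete_group_dropped(self, toy_protein_design):
        samples = toy_protein_design.samples()
        values = np.full((1, 6), 20.0)
        values[0, 0] = np.nan
        values[0, 3] = np.nan  # one missing per condition
        mat = protein_matrix(values, samples)
        assert filter_detected_proteins(mat, toy_protein_design) == []

    def test_toy_mask_rule(self, toy_protein_design):
        # condition 1 complete, condition 2 has a hole -> kept
        samples = toy_protein_design.samples()
        values = np.array([[20.0, 21.0, 20.5, np.nan, 19.0, 20.0]])
        mat = protein_matrix(values, samples)
        assert filter_detected_proteins(mat, toy_protein_design) == ["p0"]

    def test_unknown_sample_rejected(self, toy_protein_design):
        mat = protein_matrix(np.ones((1, 2)), ["x1", "x2"])
        with pytest.raises(ValidationError):
            filter_detected_proteins(mat, toy_protein_design)

    def test_idempotent(self, small_sim):
        prot, design = small_sim["protein"], small_sim["design"]
        once = filter_detected_proteins(prot, design)
        twice = filter_detected_proteins(
            prot.subset_features(once), design
        )
        assert once == twice


class TestImputeMissing:
    def _matrix_with_hole(self):
        rng = np.random.default_rng(0)
        values = rng.normal(20, 2, size=(120, 2))
        values[0, 0] = np.nan
        return protein_matrix(values, ["s1", "s2"])

    def test_identity_when_complete(self):
        mat = protein_matrix(np.random.default_rng(1).normal(20, 2, (50, 2)),
                             ["s1", "s2"])
        out, mask = impute_missing(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)
        assert not mask.to_numpy().any()

    def test_imputed_mean_matches_lower_tail(self):
        # observed values 1..100; sub-decile values 1..10 have mean 5.5;
        # one extra all-NaN-in-s1 feature provides the missing cell
        col = np.arange(1.0, 101.0)
        values = np.column_stack([np.append(col, np.nan),
                                  np.append(col, 50.0)])
        mat = protein_matrix(values, ["s1", "s2"])
        draws = []
        for seed in range(1000):
            out, _ = impute_missing(mat, rng=np.random.default_rng(seed))
            draws.append(out.values.iloc[-1, 0])
        assert abs(np.mean(draws) - 5.5) < 1.0

    def test_deterministic_with_seed(self):
        mat = self._matrix_with_hole()
        a, _ = impute_missing(mat, rng=np.random.default_rng(7))
        b, _ = impute_missing(mat, rng=np.random.default_rng(7))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_observed_cells_untouched_and_mask_complete(self):
        mat = self._matrix_with_hole()
        out, mask = impute_missing(mat, rng=np.random.default_rng(3))
        obs = (~mat.values.isna()).to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[obs], mat.values.to_numpy()[obs]
        )
        assert mask.to_numpy().sum() == mat.n_missing
        assert not out.values.isna().any().any()

    def test_too_few_observed_rejected(self):
        values = np.full((10, 2), 20.0)
        values[0, 0] = np.nan
        mat = protein_matrix(values, ["s1", "s2"])
        with pytest.raises(ValidationError):
            impute_missing(mat)


class TestMedianNormalize:
    def test_equal_medians_identity(self):
        values = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        mat = protein_matrix(values, ["s1", "s2"])
        out = median_normalize(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_two_sample_shifts(self):
        values = np.array([[9.0, 11.0], [10.0, 12.0], [11.0, 13.0]])
        mat = protein_matrix(values, ["s1", "s2"])
        out = median_normalize(mat)
        # medians 10 and 12, target 11 -> shifts +1 and -1
        assert np.allclose(out.values["s1"], values[:, 0] + 1)
        assert np.allclose(out.values["s2"], values[:, 1] - 1)

    def test_constant_matrix_unchanged(self):
        mat = protein_matrix(np.full((5, 3), 8.0), ["a", "b", "c"])
        out = median_normalize(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_missing_cells_untouched(self):
        values = np.array([[9.0, 11.0], [10.0, 12.0], [np.nan, 13.0]])
        mat = protein_matrix(values, ["s1", "s2"])
        out = median_normalize(mat)
        assert np.isnan(out.values.iloc[2, 0])


class TestTrypticDigest:
    def test_two_observable_fragments(self):
        assert count_theoretical_peptides("AAAAAAKCCCCCCRDDDDD") == 2

    def test_kp_suppresses_cleavage(self):
        assert count_theoretical_peptides("AAAAAAKPCCCCCR") == 1

    def test_below_min_length(self):
        assert count_theoretical_peptides("AAAA") == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            count_theoretical_peptides("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            count_theoretical_peptides("AAAXAAA")

    def test_against_regex_oracle(self):
        import re

        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(rng.choice(alphabet, size=rng.integers(10, 200)))
            fragments = re.split(r"(?<=[KR])(?!P)", seq)
            expected = sum(1 for f in fragments if 7 <= len(f) <= 30)
            assert count_theoretical_peptides(seq) == expected


class TestIbaq:
    def _intensity(self, values, feature_ids):
        return ExpressionMatrix(
            pd.DataFrame(
                np.atleast_2d(np.asarray(values, dtype=float)),
                index=feature_ids,
                columns=["s1"],
            ),
            "intensity",
        )

    def test_division(self):
        mat = self._intensity([1000.0], ["p1"])
        out = ibaq_transform(mat, {"p1": 4})
        assert out.values.iloc[0, 0] == 250.0

    def test_count_one_identity(self):
        mat = self._intensity([777.0], ["p1"])
        out = ibaq_transform(mat, {"p1": 1})
        assert out.values.iloc[0, 0] == 777.0

    def test_ratio(self):
        mat = self._intensity([[100.0], [100.0]], ["p1", "p2"])
        out = ibaq_transform(mat, {"p1": 2, "p2": 10})
        assert out.values.loc["p1", "s1"] / out.values.loc["p2", "s1"] == 5.0

    def test_zero_count_dropped_with_warning(self):
        mat = self._intensity([[100.0], [100.0]], ["p1", "p2"])
        with pytest.warns(UserWarning):
            out = ibaq_transform(mat, {"p1": 0, "p2": 5})
        assert out.feature_ids == ["p2"]
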
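"""Presence filtering and DEG calling on expression studies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alumet.expression import (
    DifferentialExpression,
    ExpressionStudy,
    filter_presence,
    two_sample_t,
)
from alumet.simulate import generate_expression_study


def make_study(values, n_case, study_id="T", genes=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series(["case"] * n_case + ["control"] * (n - n_case), index=samples)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionStudy(pd.DataFrame(values, index=genes, columns=samples),
                           groups, study_id=study_id)


class TestPresenceFilter:
    def test_boundary_is_inclusive(self, rng):
        # 7/10 observed is exactly 70% -> retained; 6/10 -> removed
        base = rng.normal(size=(2, 10))
        base[0, :3] = np.nan
        base[1, :4] = np.nan
        study = make_study(base, n_case=5, genes=["keep", "drop"])
        kept = filter_presence(study, cutoff=0.70)
        assert list(kept.matrix.index) == ["keep"]

    def test_retained_set_matches_direct_count(self, rng):
        rates = [0.0, 0.25, 0.35, 0.5]
        values = rng.normal(size=(4, 40))
        for i, rate in enumerate(rates):
            miss = rng.choice(40, size=int(round(rate * 40)), replace=False)
            values[i, miss] = np.nan
        study = make_study(values, n_case=20)
        kept = filter_presence(study, cutoff=0.70)
        expected = [f"g{i}" for i, rate in enumerate(rates) if 1 - rate >= 0.70]
        assert list(kept.matrix.index) == expected

    def test_filter_preserves_raw_p_of_retained_genes(self, rng):
        study, _ = generate_expression_study(n_genes=150, n_case=8, n_control=8,
                                             missing_rate=0.25, seed=rng)
        full = DifferentialExpression(study).fit()
        filtered_study = filter_presence(study)
        filtered = DifferentialExpression(filtered_study).fit()
        shared = filtered.table.index
        pd.testing.assert_series_equal(
            full.table.loc[shared, "raw_p"], filtered.table.loc[shared, "raw_p"]
        )

    def test_empty_result_warns(self, rng):
        values = rng.normal(size=(2, 10))
        values[:, :8] = np.nan
        with pytest.warns(UserWarning, match="removed every gene"):
            filter_presence(make_study(values, n_case=5))

    def test_invalid_cutoff(self, rng):
        study = make_study(rng.normal(size=(2, 6)), n_case=3)
        with pytest.raises(ValueError):
            filter_presence(study, cutoff=0.0)


class TestTwoSampleT:
    def test_matches_scipy_gene_by_gene(self, rng):
        for equal_var in (True, False):
            case = rng.normal(size=(40, 9))
            control = rng.normal(size=(40, 11))
            t, p, _, _ = two_sample_t(case, control, equal_var=equal_var)
            for i in range(40):
                ref = sps.ttest_ind(case[i], control[i], equal_var=equal_var)
                assert t[i] == pytest.approx(ref.statistic, rel=1e-10)
                assert p[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_missing_values_omitted_pairwise(self, rng):
        case = rng.normal(size=(1, 10))
        control = rng.normal(size=(1, 10))
        case[0, :3] = np.nan
        _, p, n1, n2 = two_sample_t(case, control)
        ref = sps.ttest_ind(case[0, 3:], control[0])
        assert (n1[0], n2[0]) == (7, 10)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_conventions(self):
        # both groups constant and equal -> p = 1; constant but different -> p = 0
        _, p, _, _ = two_sample_t([[1.0, 1.0, 1.0]], [[1.0, 1.0]])
        assert p[0] == 1.0
        _, p, _, _ = two_sample_t([[1.0, 1.0, 1.0]], [[2.0, 2.0]])
        assert p[0] == 0.0

    def test_underpowered_rows_are_nan(self):
        _, p, _, _ = two_sample_t([[1.0, np.nan, np.nan]], [[1.0, 2.0]])
        assert np.isnan(p[0])


class TestDEGCalling:
    def test_identical_groups_yield_no_degs(self, rng):
        half = rng.normal(size=(30, 6))
        study = make_study(np.hstack([half, half]), n_case=6)
        results = DifferentialExpression(study).fit()
        assert (results.table["raw_p"] == 1.0).all()
        assert not results.table["is_deg"].any()

    def test_single_gene_bonferroni_is_identity(self):
        study = make_study([[1.0, 2.0, 3.0, 6.0, 7.0, 8.0]], n_case=3)
        results = DifferentialExpression(study).fit()
        assert results.table["adj_p"].iloc[0] == pytest.approx(
            results.table["raw_p"].iloc[0]
        )
        assert results.n_tested == 1

    def test_bonferroni_definition_and_direction_partition(self, rng):
        study, _ = generate_expression_study(n_genes=300, n_case=10, n_control=10,
                                             missing_rate=0.1, seed=rng)
        results = DifferentialExpression(study).fit()
        t = results.table[results.table["tested"]]
        assert np.allclose(t["adj_p"], np.minimum(1.0, t["raw_p"] * results.n_tested))
        degs = results.deg_genes("all")
        assert degs == results.deg_genes("up") | results.deg_genes("down")
        assert not (results.deg_genes("up") & results.deg_genes("down"))

    def test_underpowered_gene_flagged_not_tested(self, rng):
        values = rng.normal(size=(3, 8))
        values[0, :3] = np.nan  # only 1 case observation left
        study = make_study(values, n_case=4)
        with pytest.warns(UserWarning, match="excluded from testing"):
            results = DifferentialExpression(study).fit()
        assert not results.table["tested"].iloc[0]
        assert results.n_tested == 2
        assert results.universe == {"g1", "g2"}

    def test_planted_degs_recovered(self, rng):
        sens, null_rate = [], []
        for _ in range(20):
            study, truth = generate_expression_study(
                n_genes=550, n_case=20, n_control=20, frac_deg=50 / 550,
                effect_size=3.0, missing_rate=0.1, seed=rng,
            )
            results = DifferentialExpression(filter_presence(study)).fit()
            planted = truth["down"] | truth["up"]
            called = results.deg_genes("all")
            sens.append(len(called & planted) / len(planted))
            nulls = results.universe - planted
            null_rate.append(len(called & nulls) / len(nulls))
        assert np.mean(sens) > 0.9
        assert np.mean(null_rate) <= 0.05

    def test_family_wise_error_controlled_under_null(self, rng):
        any_deg = 0
        reps = 200
        for _ in range(reps):
            study, _ = generate_expression_study(
                n_genes=100, n_case=8, n_control=8, frac_deg=0.0,
                missing_rate=0.0, seed=rng,
            )
            results = DifferentialExpression(study).fit(alpha=0.05)
            any_deg += bool(results.table["is_deg"].any())
        # FWER <= alpha (Bonferroni is conservative); 3 sigma Monte-Carlo slack
        assert any_deg / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestStudyValidation:
    def test_duplicate_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            make_study(rng.normal(size=(2, 6)), n_case=3, genes=["g", "g"])

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match=">=2"):
            make_study(rng.normal(size=(2, 3)), n_case=1)

    def test_from_files_round_trip(self, tmp_path, rng):
        study, _ = generate_expression_study(n_genes=20, n_case=3, n_control=3,
                                             missing_rate=0.2, seed=rng)
        matrix_path = tmp_path / "m.tsv"
        samples_path = tmp_path / "s.tsv"
        study.matrix.to_csv(matrix_path, sep="\t", na_rep="NA")
        pd.DataFrame({"sample_id": study.matrix.columns,
                      "group": study.groups.to_numpy()}).to_csv(
            samples_path, sep="\t", index=False)
        loaded = ExpressionStudy.from_files(matrix_path, samples_path, study_id="X")
        assert loaded.matrix.isna().equals(study.matrix.isna())
        assert np.allclose(loaded.matrix.fillna(0).to_numpy(),
                           study.matrix.fillna(0).to_numpy(), atol=1e-5)
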
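"""Methylation group comparison and methylation-expression correlation."""

import numpy as np
import pandas as pd
import pytest

from alumet.integration import (
    METRICS,
    MethylationComparison,
    correlate_methylation_expression,
    summaries_frame,
)
from alumet.simulate import generate_methylation_expression_cohort


def random_summaries(rng, n, means=None, index_prefix="s"):
    means = means or {"pct_mC": 38, "pct_mCmC": 25.7, "pct_uCmC": 18.7,
                      "pct_mCuC": 21.8, "pct_uCuC": 33.8}
    data = {m: rng.normal(means[m], 1.0, size=n) for m in METRICS}
    return pd.DataFrame(data, index=[f"{index_prefix}{i}" for i in range(n)])


class TestMethylationComparison:
    def test_identical_groups_give_p_one(self, rng):
        block = random_summaries(rng, 5, index_prefix="a")
        other = block.copy()
        other.index = [f"b{i}" for i in range(5)]
        summaries = pd.concat([block, other])
        labels = pd.Series(["case"] * 5 + ["control"] * 5, index=summaries.index)
        result = MethylationComparison(summaries, labels).fit("case", "control")
        assert (result.table["raw_p"] == 1.0).all()

    def test_bh_family_is_the_five_metrics(self, rng):
        case = random_summaries(rng, 10, index_prefix="a")
        control = random_summaries(rng, 10, index_prefix="b")
        summaries = pd.concat([case, control])
        labels = pd.Series(["case"] * 10 + ["control"] * 10, index=summaries.index)
        result = MethylationComparison(summaries, labels).fit("case", "control")
        from alumet.stats import bh_adjust

        assert result.table["adj_p"].to_numpy() == pytest.approx(
            bh_adjust(result.table["raw_p"].to_numpy())
        )
        assert list(result.table.index) == list(METRICS)

    def test_group_swap_symmetry(self, rng):
        summaries = random_summaries(rng, 12)
        labels = pd.Series(["case"] * 6 + ["control"] * 6, index=summaries.index)
        model = MethylationComparison(summaries, labels)
        fwd = model.fit("case", "control").table
        rev = model.fit("control", "case").table
        assert fwd["raw_p"].to_numpy() == pytest.approx(rev["raw_p"].to_numpy())
        assert (fwd["mean_case"] - fwd["mean_control"]).to_numpy() == pytest.approx(
            -(rev["mean_case"] - rev["mean_control"]).to_numpy()
        )

    def test_nan_metric_dropped_with_warning(self, rng):
        summaries = random_summaries(rng, 10)
        summaries.iloc[0, summaries.columns.get_loc("pct_mC")] = np.nan
        labels = pd.Series(["case"] * 5 + ["control"] * 5, index=summaries.index)
        with pytest.warns(UserWarning, match="pct_mC"):
            result = MethylationComparison(summaries, labels).fit("case", "control")
        assert result.table.loc["pct_mC", "n_case"] == 4

    def test_overlapping_groups_rejected(self, rng):
        summaries = random_summaries(rng, 4)
        labels = pd.Series(["case"] * 4, index=summaries.index)
        with pytest.raises(ValueError):
            MethylationComparison(summaries, labels).fit("case", "case")

    def test_shifted_metric_detected_others_quiet(self, rng):
        # +1.3-point uCmC shift at SD 0.9, n=10 vs 10 (subgroup-style effect)
        hits = np.zeros(len(METRICS))
        reps = 100
        for _ in range(reps):
            case = {m: rng.normal(18.76 + (1.3 if m == "pct_uCmC" else 0.0), 0.9, 10)
                    for m in METRICS}
            control = {m: rng.normal(18.76, 0.9, 10) for m in METRICS}
            summaries = pd.DataFrame(
                {m: np.concatenate([case[m], control[m]]) for m in METRICS},
                index=[f"s{i}" for i in range(20)],
            )
            labels = pd.Series(["case"] * 10 + ["control"] * 10, index=summaries.index)
            result = MethylationComparison(summaries, labels).fit("case", "control")
            hits += (result.table["raw_p"] < 0.05).to_numpy()
        rates = hits / reps
        by_metric = dict(zip(METRICS, rates))
        assert by_metric["pct_uCmC"] > 0.8
        for m in METRICS:
            if m != "pct_uCmC":
                assert by_metric[m] <= 0.12


class TestCorrelation:
    def test_affine_function_gives_unit_correlation(self, rng):
        summaries = random_summaries(rng, 10)
        expression = pd.Series(0.05 * summaries["pct_uCmC"] + 0.3,
                               index=summaries.index)
        result = correlate_methylation_expression(summaries, expression)
        assert result.table.loc["pct_uCmC", "r"] == pytest.approx(1.0)

    def test_spearman_is_rank_invariant(self, rng):
        summaries = random_summaries(rng, 15)
        expression = pd.Series(np.exp(0.3 * summaries["pct_uCmC"]),
                               index=summaries.index)
        result = correlate_methylation_expression(summaries, expression,
                                                  method="spearman")
        assert result.table.loc["pct_uCmC", "r"] == pytest.approx(1.0)

    def test_stratum_filter_and_small_n_error(self, rng):
        summaries = random_summaries(rng, 10)
        expression = pd.Series(rng.random(10), index=summaries.index)
        result = correlate_methylation_expression(
            summaries, expression, stratum=summaries.index[:5], stratum_label="M"
        )
        assert (result.table["n"] == 5).all()
        assert result.stratum == "M"
        with pytest.raises(ValueError, match=">=3"):
            correlate_methylation_expression(summaries, expression,
                                             stratum=summaries.index[:2])

    def test_null_correlation_stays_moderate(self, rng):
        # under independence at n=20, |r| < 0.45 about 95% of the time
        within = 0
        reps = 400
        for _ in range(reps):
            summaries = random_summaries(rng, 20)
            expression = pd.Series(rng.normal(size=20), index=summaries.index)
            result = correlate_methylation_expression(summaries, expression)
            within += bool(abs(result.table.loc["pct_uCmC", "r"]) < 0.45)
        assert within / reps >= 0.92

    def test_coupled_generator_recovers_rho(self, rng):
        rs = []
        for _ in range(150):
            summaries, expression, _ = generate_methylation_expression_cohort(
                n=20, rho=0.5, seed=rng
            )
            result = correlate_methylation_expression(summaries, expression)
            rs.append(result.table.loc["pct_uCmC", "r"])
        assert abs(np.median(rs) - 0.5) < 0.15

    def test_scatter_export_carries_all_metrics(self, rng):
        summaries, expression, _ = generate_methylation_expression_cohort(
            n=10, rho=0.3, seed=rng
        )
        result = correlate_methylation_expression(summaries, expression)
        assert set(METRICS) <= set(result.scatter.columns)
        assert len(result.scatter) == 10

    def test_summaries_frame_layout(self):
        from alumet.cobra import StateMixture, compute_methylation, forward_profile

        s = compute_methylation(forward_profile(StateMixture(0.4, 0.2, 0.2, 0.2), "x"))
        frame = summaries_frame([s])
        assert list(frame.columns) == list(METRICS)
        assert frame.index.tolist() == ["x"]
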
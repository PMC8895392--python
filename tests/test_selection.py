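"""Indicator matrices, difference-from-minimum, rank averaging, strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rarerates as rr
from rarerates import ValidationError
from rarerates.selection import (diff_from_min, rank_models,
                                 scenario_mean_ranks, stratify_by_incidence,
                                 summarize_scenario)

from conftest import make_fit, make_table


def matrix_from(values, models=None, entity="e1"):
    """Single-indicator matrix builder for rank/diff tests."""
    models = models or [f"m{i+1}" for i in range(len(values))]
    idx = pd.MultiIndex.from_product([[entity], models],
                                     names=["entity", "model"])
    return pd.DataFrame({"dic": values}, index=idx)


class TestComputeIndicators:
    def test_identical_fits_identical_vectors(self):
        lam = np.random.default_rng(0).uniform(1, 4, (200, 3))
        fits = {"m1": make_fit([1, 2, 0], [1.0, 1.0, 1.0], lam),
                "m2": make_fit([1, 2, 0], [1.0, 1.0, 1.0], lam)}
        ind = rr.compute_indicators(fits)
        assert np.allclose(ind.loc["m1"], ind.loc["m2"])
        assert list(ind.columns) == list(rr.INDICATORS)

    def test_constant_draws_zero_width(self):
        lam = np.tile([2.0, 3.0], (150, 1))
        ind = rr.compute_indicators({"m1": make_fit([2, 3], [1.0, 1.0], lam)})
        assert ind.loc["m1", "width"] == 0.0

    def test_mismatched_tables_rejected(self):
        lam = np.ones((150, 2))
        f1 = make_fit([1, 2], [1.0, 1.0], lam)
        f2 = make_fit([1, 3], [1.0, 1.0], lam)
        with pytest.raises(ValidationError):
            rr.compute_indicators({"m1": f1, "m2": f2})


class TestDiffFromMin:
    def test_examples(self):
        m = matrix_from([3.0, 5.0, 9.0])
        assert list(diff_from_min(m)["dic"]) == [0.0, 2.0, 6.0]
        single = matrix_from([4.0], ["m1"])
        assert list(diff_from_min(single)["dic"]) == [0.0]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-50, 50))
    def test_shift_invariance(self, shift):
        base = matrix_from([3.0, 5.0, 9.0])
        shifted = matrix_from([3.0 + shift, 5.0 + shift, 9.0 + shift])
        assert np.allclose(diff_from_min(base)["dic"],
                           diff_from_min(shifted)["dic"])

    def test_zero_present_per_entity_indicator(self):
        rng = np.random.default_rng(1)
        idx = pd.MultiIndex.from_product(
            [[f"e{k}" for k in range(6)], ["m1", "m2", "m3"]],
            names=["entity", "model"])
        m = pd.DataFrame(rng.uniform(0, 9, (18, 2)), index=idx,
                         columns=["dic", "waic1"])
        d = diff_from_min(m)
        mins = d.groupby(level="entity").min()
        assert np.allclose(mins.to_numpy(), 0.0)


class TestRankModels:
    def test_plain_and_tied_ranks(self):
        assert list(rank_models(matrix_from([3.0, 5.0, 9.0]),
                                ["dic"])["dic"]) == [1.0, 2.0, 3.0]
        assert list(rank_models(matrix_from([3.0, 3.0, 9.0]),
                                ["dic"])["dic"]) == [1.5, 1.5, 3.0]

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            rank_models(matrix_from([1.0, 2.0]), [])

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValidationError):
            rank_models(matrix_from([1.0, 2.0]), ["aic"])

    def test_model_label_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        idx = pd.MultiIndex.from_product(
            [["e1", "e2"], ["m1", "m2", "m3", "m4"]],
            names=["entity", "model"])
        vals = pd.DataFrame(
            {k: rng.uniform(0, 5, 8) for k in ("dic", "waic1", "waic2")},
            index=idx)
        ranks = rank_models(vals, ["dic", "waic1", "waic2"])
        relabel = {"m1": "m3", "m3": "m1", "m2": "m4", "m4": "m2"}
        vals2 = vals.rename(index=relabel, level="model")
        ranks2 = rank_models(vals2, ["dic", "waic1", "waic2"])
        for (e, m) in vals.index:
            assert ranks.loc[(e, m), "avg_rank"] == pytest.approx(
                ranks2.loc[(e, relabel[m]), "avg_rank"])


class TestStratification:
    def test_threshold_examples(self):
        flags = stratify_by_incidence(
            pd.Series({"a": 0.02, "b": 0.119, "c": 0.5}))
        assert flags.loc["a"].tolist() == [True, True, True, False]
        assert flags.loc["b"].tolist() == [False, True, True, False]
        assert flags.loc["c"].tolist() == [False, False, False, True]

    def test_negative_ir_rejected(self):
        with pytest.raises(ValidationError):
            stratify_by_incidence(pd.Series({"a": -0.1}))


class TestScenarioSummaries:
    def test_single_entity_median_is_value(self):
        d = diff_from_min(matrix_from([3.0, 5.0]))
        out = summarize_scenario(d, ["e1"])
        assert out.loc[("m2", "median"), "dic"] == pytest.approx(2.0)

    def test_percentiles_match_order_statistics(self):
        rng = np.random.default_rng(3)
        entities = [f"e{k}" for k in range(40)]
        idx = pd.MultiIndex.from_product([entities, ["m1", "m2"]],
                                         names=["entity", "model"])
        m = pd.DataFrame({"dic": rng.uniform(0, 10, 80)}, index=idx)
        out = summarize_scenario(m, entities)
        vals = m.xs("m2", level="model")["dic"].to_numpy()
        assert out.loc[("m2", "median"), "dic"] == pytest.approx(
            np.median(vals))
        assert out.loc[("m2", "p2.5"), "dic"] == pytest.approx(
            np.percentile(vals, 2.5))
        assert out.loc[("m2", "p97.5"), "dic"] == pytest.approx(
            np.percentile(vals, 97.5))

    def test_empty_scenario_rejected(self):
        d = diff_from_min(matrix_from([3.0, 5.0]))
        with pytest.raises(ValidationError):
            summarize_scenario(d, [])

    def test_scenario_mean_ranks_shape(self):
        rng = np.random.default_rng(4)
        idx = pd.MultiIndex.from_product(
            [["e1", "e2", "e3"], ["m1", "m2"]], names=["entity", "model"])
        m = pd.DataFrame(
            {k: rng.uniform(0, 5, 6) for k in ("dic", "waic1", "waic2")},
            index=idx)
        ir = pd.Series({"e1": 0.01, "e2": 0.2, "e3": 0.7})
        out = scenario_mean_ranks(m, ir, ["dic"])
        assert set(out.columns) <= {"A", "B", "C", "D"}
        assert out["D"].notna().all()


class TestConstrainedPriorWidens:
    def test_lower_bound_one_forces_wider_intervals(self, quick_cfg):
        # homogeneous sparse entity: sigma >= 1 forbids the shrinkage that
        # the unconstrained prior applies, so intervals must widen
        table = make_table(np.full(27, 2), np.full(27, 2.0))
        f1 = rr.fit_bayes(table, rr.MODEL_PRIORS["m1"], quick_cfg)
        f6 = rr.fit_bayes(table, rr.MODEL_PRIORS["m6"], quick_cfg)
        ind = rr.compute_indicators({"m1": f1, "m6": f6})
        assert ind.loc["m6", "width"] > ind.loc["m1", "width"]
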
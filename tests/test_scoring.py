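import json

import numpy as np
import pytest

from idioplan import (
    PlanningOptions,
    factor_scores,
    render_report,
    run_planning,
    symptom_scores,
    within_time_variance,
)
from idioplan.cfa import CfaPattern
from idioplan.errors import DegenerateScoresError, InsufficientDataError
from idioplan.synthetic import preset, simulate_patient
from conftest import CONFIRMATORY_LOADINGS, make_series


class StubCfa:
    """Minimal CfaModel stand-in for the pure scoring algebra."""

    def __init__(self, loadings, included, item_ids):
        self.loadings = np.asarray(loadings, dtype=float)
        self.pattern = CfaPattern(
            k=self.loadings.shape[1], included=included, excluded_items=[]
        )
        self.item_ids = item_ids


class TestWithinTimeVariance:
    def test_published_confirmatory_matrix(self):
        model = StubCfa(
            CONFIRMATORY_LOADINGS,
            included=[
                ["item1", "item2", "item6"],
                ["item1", "item3", "item4", "item5", "item6", "item7", "item8", "item9"],
            ],
            item_ids=[f"item{i + 1}" for i in range(9)],
        )
        shares = within_time_variance(model)
        assert shares[0] * 100 == pytest.approx(34.27, abs=0.1)
        assert shares[1] * 100 == pytest.approx(47.27, abs=0.1)

    def test_single_unit_loading_factor(self):
        model = StubCfa(
            np.array([[1.0], [0.0], [0.0]]),
            included=[["item1", "item2", "item3"]],
            item_ids=["item1", "item2", "item3"],
        )
        assert within_time_variance(model)[0] == pytest.approx(1.0)

    def test_literal_divisor_variant(self):
        model = StubCfa(
            CONFIRMATORY_LOADINGS,
            included=[["item1", "item2", "item6"], ["item3"]],
            item_ids=[f"item{i + 1}" for i in range(9)],
        )
        np.testing.assert_allclose(
            within_time_variance(model, literal_divisor=True),
            2 * within_time_variance(model),
        )


class TestFactorScores:
    def test_published_worked_values(self):
        scores = factor_scores(
            np.array([0.3427, 0.4727]), np.array([0.2296, 0.061])
        )
        assert scores.factor_score[0] == pytest.approx(1.0)
        assert scores.factor_score[1] == pytest.approx(0.367, abs=0.005)

    def test_equal_products_both_one(self):
        s = factor_scores(np.array([0.4, 0.2]), np.array([0.1, 0.2]))
        np.testing.assert_allclose(s.factor_score, [1.0, 1.0])

    def test_null_factor(self):
        s = factor_scores(np.array([0.2, 0.5]), np.array([1.0, 0.0]))
        np.testing.assert_allclose(s.factor_score, [1.0, 0.0])

    def test_all_zero_products_rejected(self):
        with pytest.raises(DegenerateScoresError):
            factor_scores(np.array([0.0, 0.3]), np.array([0.2, 0.0]))


class TestSymptomScores:
    def test_hand_computed_single_factor(self):
        # means (4, 2) -> normalized (1, .5); q = (.8, .25); scores (100, 31.25)
        ts = make_series(np.array([[3.0, 1.0], [5.0, 3.0], [4.0, 2.0], [4.0, 2.0]]))
        model = StubCfa(
            np.array([[0.8], [0.5]]),
            included=[["item1", "item2"]],
            item_ids=["item1", "item2"],
        )
        fscores = factor_scores(np.array([0.5]), np.array([0.5]))
        table = symptom_scores(ts, model, fscores).table
        assert list(table["item_id"]) == ["item1", "item2"]
        np.testing.assert_allclose(table["symptom_score"], [100.0, 31.25])

    def test_symmetric_items_all_score_100(self):
        ts = make_series(np.full((5, 3), 4.0))
        model = StubCfa(
            np.full((3, 1), 0.7),
            included=[["item1", "item2", "item3"]],
            item_ids=["item1", "item2", "item3"],
        )
        fscores = factor_scores(np.array([0.4]), np.array([0.2]))
        table = symptom_scores(ts, model, fscores).table
        np.testing.assert_allclose(table["symptom_score"], 100.0)

    def test_excluded_items_listed_not_scored(self):
        ts = make_series(np.random.default_rng(0).integers(1, 8, (6, 3)).astype(float))
        model = StubCfa(
            np.array([[0.8], [0.5]]),
            included=[["item1", "item2"]],
            item_ids=["item1", "item2"],
        )
        fscores = factor_scores(np.array([0.5]), np.array([0.5]))
        pt = symptom_scores(ts, model, fscores)
        assert pt.excluded_items == ["item3"]
        assert "item3" not in set(pt.table["item_id"])

    def test_sorted_descending_with_max_100(self):
        ts = make_series(
            np.random.default_rng(1).integers(1, 8, (20, 4)).astype(float)
        )
        model = StubCfa(
            np.array([[0.8, 0.0], [0.6, 0.0], [0.0, 0.7], [0.0, 0.5]]),
            included=[["item1", "item2"], ["item3", "item4"]],
            item_ids=[f"item{i + 1}" for i in range(4)],
        )
        fscores = factor_scores(np.array([0.4, 0.3]), np.array([0.3, 0.1]))
        table = symptom_scores(ts, model, fscores).table
        scores = table["symptom_score"].to_numpy()
        assert scores[0] == pytest.approx(100.0)
        assert np.all(np.diff(scores) <= 0)


class TestRunPlanning:
    def test_insufficient_data_is_an_error_not_no_model(self):
        truth = preset("two-factor-dominant")
        ts, _ = simulate_patient(truth, 30, seed=0)
        with pytest.raises(InsufficientDataError):
            run_planning(ts, options=PlanningOptions(min_measurements=40))

    def test_pipeline_deterministic_bitwise(self):
        truth = preset("two-factor-dominant")
        ts, _ = simulate_patient(truth, 110, seed=5)
        _, json1 = render_report(run_planning(ts))
        _, json2 = render_report(run_planning(ts))
        assert json1 == json2

    def test_scale_invariance_of_priorities(self):
        truth = preset("two-factor-dominant")
        ts, _ = simulate_patient(truth, 110, seed=3)
        r1 = run_planning(ts)
        scaled = make_series(ts.values * 2.0, scale_min=0, scale_max=16)
        r2 = run_planning(scaled)
        assert r1.status == r2.status == "found"
        np.testing.assert_allclose(
            r1.priorities.table["symptom_score"],
            r2.priorities.table["symptom_score"],
            atol=1e-8,
        )

    def test_report_round_trip_and_gate_naming(self):
        truth = preset("two-factor-dominant")
        ts, _ = simulate_patient(truth, 110, seed=7)
        result = run_planning(ts)
        text, payload = render_report(result)
        data = json.loads(payload)
        assert json.dumps(data, sort_keys=True) == payload
        if result.status == "found":
            assert data["priorities"][0]["symptom_score"] == pytest.approx(100.0)
            assert "Symptom priorities" in text
        noise_ts, _ = simulate_patient(preset("pure-noise"), 110, seed=0)
        noise_result = run_planning(noise_ts)
        ntext, npayload = render_report(noise_result)
        assert noise_result.status == "no_model"
        assert "gate failed" in " ".join(json.loads(npayload)["diagnostics"])
        assert "No satisfactory model" in ntext
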
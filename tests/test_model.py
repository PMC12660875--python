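"""SplitWise orchestration: transformations, search, prediction, reports."""

import numpy as np
import pandas as pd
import pytest

from splitwise import (
    Dataset,
    ScenarioSpec,
    SplitWiseConfig,
    generate_scenario,
    partial_residuals,
    splitwise_fit,
    univariate_transform,
)
from splitwise.encoding import EncodingMap, build_design
from splitwise.linmod import fit_ols
from splitwise.model import _candidate_terms
from splitwise.stepwise import stepwise_select


def _fit_linear(data: Dataset, columns: list[str]):
    enc = EncodingMap.all_linear(data)
    design = build_design(data, enc)
    keep = [c for src in columns for c in design.columns_for(src)]
    return fit_ols(design.select(keep), data.y.to_numpy())


@pytest.fixture()
def step_data():
    data, truth, _ = generate_scenario(ScenarioSpec(scenario="step", n=500, seed=42))
    return data, truth


# ---------------------------------------------------------------- partial residuals
def test_partial_residuals_of_absent_predictor_are_residuals(toy_numeric):
    m = _fit_linear(toy_numeric, ["a"])
    np.testing.assert_array_equal(partial_residuals(m, toy_numeric, "b"), m.residuals)


def test_partial_residuals_match_leave_one_term_out_oracle(toy_numeric):
    m = _fit_linear(toy_numeric, ["a", "b"])
    pr = partial_residuals(m, toy_numeric, "a")
    # oracle: residuals + fitted contribution beta_a * a
    beta_a = m.params["a"]
    np.testing.assert_allclose(pr, m.residuals + beta_a * toy_numeric.predictors["a"],
                               atol=1e-10)


def test_partial_residuals_of_intercept_only_model_centre_y(toy_numeric):
    m = _fit_linear(toy_numeric, [])
    pr = partial_residuals(m, toy_numeric, "a")
    np.testing.assert_allclose(pr, toy_numeric.y - toy_numeric.y.mean(), atol=1e-10)


def test_partial_residuals_unknown_predictor(toy_numeric):
    m = _fit_linear(toy_numeric, ["a"])
    with pytest.raises(KeyError):
        partial_residuals(m, toy_numeric, "nope")


# ---------------------------------------------------------------- univariate mode
def test_univariate_pure_noise_predictor_excluded():
    rng = np.random.default_rng(0)
    n = 200
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    # orthogonalise so the sample correlation with y is exactly zero
    x = x - np.polyval(np.polyfit(y, x, 1), y)
    data = Dataset(pd.DataFrame({"x": x}), pd.Series(y, name="y"))
    enc = univariate_transform(data, SplitWiseConfig(mode="univariate"))
    assert enc["x"].kind == "excluded"


def test_univariate_recovers_step_threshold(step_data):
    data, _ = step_data
    enc = univariate_transform(data, SplitWiseConfig(mode="univariate",
                                                     min_improvement=5.0))
    assert enc["X2"].is_split
    assert enc["X2"].cutpoints[0] == pytest.approx(0.2, abs=0.15)
    assert enc["X1"].kind == "linear"


def test_univariate_prefers_linear_for_linear_truth():
    rng = np.random.default_rng(1)
    n = 400
    x = rng.standard_normal(n)
    y = 2.0 * x + rng.normal(0, 0.5, n)
    data = Dataset(pd.DataFrame({"x": x}), pd.Series(y, name="y"))
    enc = univariate_transform(data, SplitWiseConfig(mode="univariate",
                                                     min_improvement=5.0))
    assert enc["x"].kind == "linear"


# ---------------------------------------------------------------- iterative mode
def test_infinite_min_improvement_collapses_to_plain_stepwise(toy_numeric):
    cfg = SplitWiseConfig(mode="iterative", direction="both",
                          min_improvement=float("inf"))
    model = splitwise_fit(toy_numeric, cfg)
    enc = EncodingMap.all_linear(toy_numeric)
    design = build_design(toy_numeric, enc)
    terms = _candidate_terms(design, toy_numeric, enc)
    ref, ref_sel = stepwise_select(terms, design, toy_numeric.y.to_numpy(),
                                   "both", "aic")
    assert sorted(model.selected) == sorted(ref_sel)
    assert model.fit.aic == pytest.approx(ref.aic)
    assert not model.dummy_encodings()


def test_iterative_recovers_step_structure(step_data):
    data, _ = step_data
    cfg = SplitWiseConfig(mode="iterative", direction="forward", min_improvement=5.0,
                          min_support=0.2)
    model = splitwise_fit(data, cfg)
    assert "X1" in model.selected_sources()
    assert "X2" in model.selected_sources()
    enc = model.encodings["X2"]
    assert enc.is_split
    assert enc.cutpoints[0] == pytest.approx(0.2, abs=0.15)
    assert model.encodings["X1"].kind == "linear"


def test_accepted_dummies_satisfy_min_support_and_margin(step_data):
    data, _ = step_data
    cfg = SplitWiseConfig(mode="iterative", direction="forward", min_improvement=5.0,
                          min_support=0.2)
    model = splitwise_fit(data, cfg)
    n = data.n
    for enc in model.dummy_encodings():
        x = data.predictors[enc.source].to_numpy()
        from splitwise.encoding import segment_support

        assert segment_support(x, list(enc.cutpoints)).min() >= cfg.min_support - 1e-12
    accepted = [ev for ev in model.trace if ev.action == "transform" and ev.accepted]
    for ev in accepted:
        assert ev.criterion_before - ev.criterion_after >= cfg.min_improvement - 1e-9


def test_final_criterion_not_worse_than_plain_stepwise(step_data):
    data, _ = step_data
    cfg = SplitWiseConfig(mode="iterative", direction="forward", min_improvement=5.0)
    model = splitwise_fit(data, cfg)
    enc = EncodingMap.all_linear(data)
    design = build_design(data, enc)
    terms = _candidate_terms(design, data, enc)
    plain, _ = stepwise_select(terms, design, data.y.to_numpy(), "forward", "aic")
    assert model.fit.aic <= plain.aic + 1e-9


def test_empty_predictor_set_gives_intercept_only():
    y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], name="y")
    data = Dataset(pd.DataFrame(index=range(5)), y)
    model = splitwise_fit(data, SplitWiseConfig(mode="iterative"))
    assert model.selected == []
    assert model.fit.k_params == 1


def test_determinism_bitwise_identical_trace(step_data):
    data, _ = step_data
    cfg = dict(mode="iterative", direction="forward", min_improvement=5.0)
    m1 = splitwise_fit(data, SplitWiseConfig(**cfg))
    m2 = splitwise_fit(data, SplitWiseConfig(**cfg))
    assert m1.trace == m2.trace
    assert m1.fit.params.equals(m2.fit.params)


# ---------------------------------------------------------------- prediction
def test_predict_on_training_data_equals_fitted(step_data):
    data, _ = step_data
    model = splitwise_fit(data, SplitWiseConfig(mode="univariate", direction="forward"))
    np.testing.assert_allclose(model.predict(data.predictors), model.fit.fitted,
                               atol=1e-10)


def test_single_dummy_model_predicts_two_values():
    rng = np.random.default_rng(2)
    n = 300
    x = rng.standard_normal(n)
    y = 2.0 * (x > 0.0) + rng.normal(0, 0.3, n)
    data = Dataset(pd.DataFrame({"x": x}), pd.Series(y, name="y"))
    model = splitwise_fit(data, SplitWiseConfig(mode="univariate", min_improvement=3.0))
    assert model.encodings["x"].is_split
    new = pd.DataFrame({"x": np.linspace(-4, 4, 50)})
    assert len(np.unique(np.round(model.predict(new), 10))) == 2


def test_predict_with_hand_built_coefficients(step_data):
    data, _ = step_data
    model = splitwise_fit(data, SplitWiseConfig(mode="iterative", direction="forward",
                                                min_improvement=5.0))
    new = data.predictors.head(7)
    manual = np.full(7, model.fit.params["(Intercept)"])
    for col, (src, role) in model.fit.design.term_map.items():
        if role == "intercept":
            continue
        manual += model.fit.params[col] * model.fit.design.frame[col].head(7).to_numpy()
    np.testing.assert_allclose(model.predict(new), manual, atol=1e-10)


def test_predict_missing_column_raises(toy_numeric):
    model = splitwise_fit(toy_numeric, SplitWiseConfig(mode="univariate"))
    if not model.selected:
        pytest.skip("nothing selected")
    with pytest.raises(KeyError):
        model.predict(toy_numeric.predictors.drop(columns=model.selected[:1]))


# ---------------------------------------------------------------- reporting
def test_summary_reports_threshold_and_adjusted_r2(step_data):
    data, _ = step_data
    model = splitwise_fit(data, SplitWiseConfig(mode="iterative", direction="forward",
                                                min_improvement=5.0))
    text = model.summary()
    assert "X2_dummy" in text
    assert "Dummy transformations" in text
    r2, adj = model.r_squared()
    n, k = model.fit.n, model.fit.k_params
    assert adj == pytest.approx(1 - (1 - r2) * (n - 1) / (n - k), abs=1e-12)


def test_intercept_only_summary_has_empty_dummy_section():
    rng = np.random.default_rng(3)
    y = rng.standard_normal(50)
    x = rng.standard_normal(50)
    x = x - np.polyval(np.polyfit(y, x, 1), y)
    data = Dataset(pd.DataFrame({"x": x}), pd.Series(y, name="y"))
    model = splitwise_fit(data, SplitWiseConfig(mode="univariate", criterion="bic"))
    assert "(none)" in model.summary().split("Dummy transformations:")[1]


def test_json_report_round_trips(step_data):
    import json

    data, _ = step_data
    model = splitwise_fit(data, SplitWiseConfig(mode="univariate"))
    report = json.loads(model.to_json())
    assert report["response"] == "y"
    assert set(report["coefficients"]) == set(model.fit.params.index)
    assert report["config"]["mode"] == "univariate"
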
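"""Model-selection framework: enumeration counts, preselection, percentile."""

import numpy as np
import pandas as pd
import pytest

from linkerscape.config import PipelineConfig
from linkerscape.selection import (
    ModelData, Term, best_models, count_enumerated_models, fit_model,
    prepare_model_data, step1_preselect, step1_scale_selection,
    step1_subset_search, step2_fit, step3_enumerate, step4_percentile,
)


def synth_node_data(seed=0, n_windows=3, per=6, metrics=("M1", "M2", "M3"),
                    scales=("125",), beta=None, collinear_with=None):
    """Node-level table with Gaussian metric columns and a response."""
    rng = np.random.default_rng(seed)
    n = n_windows * per
    rows = {"window": np.repeat([f"W{k}" for k in range(n_windows)], per),
            "unit": [f"W{k}P{i}" for k in range(n_windows) for i in range(per)]}
    cols = {}
    for m in metrics:
        for s in scales:
            cols[f"{m}{s}"] = rng.normal(size=n)
    if collinear_with:
        src, dst = collinear_with
        cols[dst] = cols[src] + 0.01 * rng.normal(size=n)
    y = rng.normal(size=n)
    if beta:
        for col, b in beta.items():
            y = y + b * cols[col]
    wide = pd.DataFrame({**rows, **cols})
    responses = pd.DataFrame({**rows, "Y": y})
    return wide, responses


def prep(seed=0, **kwargs):
    wide, responses = synth_node_data(seed, **kwargs)
    return prepare_model_data(wide, responses, "node", ["Y"])


class TestPrepare:
    def test_columns_standardized(self):
        data = prep(1)
        for col in data.candidates:
            x = data.df[col].to_numpy()
            assert x.mean() == pytest.approx(0.0, abs=1e-10)
            assert x.std() == pytest.approx(1.0, abs=1e-6)  # population SD

    def test_constant_column_dropped(self):
        wide, responses = synth_node_data(2)
        wide["CONST125"] = 1.0
        data = prepare_model_data(wide, responses, "node", ["Y"])
        assert "CONST125" not in data.candidates

    def test_disjoint_units_error(self):
        wide, responses = synth_node_data(3)
        responses["unit"] = "other_" + responses["unit"]
        with pytest.raises(ValueError):
            prepare_model_data(wide, responses, "node", ["Y"])


class TestScaleSelection:
    def test_injected_scale_selected(self):
        hits = 0
        for seed in range(10):
            wide, responses = synth_node_data(
                seed, metrics=("M1",), scales=("125", "2000"),
                beta={"M12000": 1.2},
            )
            data = prepare_model_data(wide, responses, "node", ["Y"])
            table = step1_scale_selection(data, "Y", ["M1"], ["125", "2000"])
            hits += int(table.iloc[0]["scale"] == "2000")
        assert hits >= 8

    def test_deterministic_tie_break_smaller_scale(self):
        # identical metric at two scales: AICc ties break to the smaller scale
        wide, responses = synth_node_data(4, metrics=("M1",), scales=("125",))
        wide["M12000"] = wide["M1125"]
        data = prepare_model_data(wide, responses, "node", ["Y"])
        table = step1_scale_selection(data, "Y", ["M1"], ["125", "2000"])
        assert table.iloc[0]["scale"] == "125"


class TestPreselect:
    def test_alpha_boundary(self):
        data = prep(5)
        table = pd.DataFrame([
            {"response": "Y", "metric": "M1", "scale": "125", "degree": 1,
             "aicc": 0.0, "loglik": 0.0},
        ])
        out = step1_preselect(data, "Y", table, alpha=0.15)
        # decision follows the computed LRT p-value against 0.15
        assert out["retained"].iloc[0] == (out["lrt_p"].iloc[0] <= 0.15)

    def test_strong_effect_retained_noise_dropped(self):
        wide, responses = synth_node_data(6, metrics=("SIG", "NOISE"),
                                          beta={"SIG125": 2.0})
        data = prepare_model_data(wide, responses, "node", ["Y"])
        table = step1_scale_selection(data, "Y", ["SIG", "NOISE"], ["125"])
        out = step1_preselect(data, "Y", table, alpha=0.15).set_index("metric")
        assert bool(out.loc["SIG", "retained"])
        assert out.loc["SIG", "lrt_p"] < 0.01


class TestSubsetSearch:
    def test_enumeration_size(self):
        data = prep(7)
        retained = pd.DataFrame([
            {"metric": m, "scale": "125", "degree": 1, "retained": True}
            for m in ("M1", "M2", "M3")
        ])
        out = step1_subset_search(data, "Y", retained, max_metrics=2,
                                  collinearity=1.0)
        # 3 singles + 3 pairs
        assert len(out) == 6

    def test_collinear_pair_excluded(self):
        wide, responses = synth_node_data(8, metrics=("M1", "M2"),
                                          collinear_with=("M1125", "M2125"))
        data = prepare_model_data(wide, responses, "node", ["Y"])
        retained = pd.DataFrame([
            {"metric": m, "scale": "125", "degree": 1, "retained": True}
            for m in ("M1", "M2")
        ])
        out = step1_subset_search(data, "Y", retained, max_metrics=2,
                                  collinearity=0.7)
        assert len(out) == 2  # singletons only

    def test_empty_retention_degenerates(self):
        data = prep(9)
        retained = pd.DataFrame(
            columns=["metric", "scale", "degree", "retained"]
        )
        out = step1_subset_search(data, "Y", retained, max_metrics=2)
        assert out.empty


class TestStep3Enumeration:
    def test_toy_universe_18_models(self):
        # 3 metrics x 1 scale, max 2 metrics, quadratics free:
        # 6 singles (lin + lin+quad per metric) + 12 pairs = 18
        data = prep(10)
        cfg = PipelineConfig(collinearity_r=1.0)
        res = step3_enumerate(data, "Y", ["M1", "M2", "M3"], ["125"], cfg)
        assert res["n_universe"] == 18
        assert count_enumerated_models([1, 1, 1], 2) == 18

    def test_closed_form_matches_enumeration(self):
        data = prep(11, metrics=("M1", "M2"), scales=("125", "2000"))
        cfg = PipelineConfig(collinearity_r=1.0)
        res = step3_enumerate(data, "Y", ["M1", "M2"], ["125", "2000"], cfg)
        assert res["n_universe"] == count_enumerated_models([2, 2], 2)

    def test_collinear_duplicate_adds_only_singletons(self):
        wide, responses = synth_node_data(12, metrics=("M1", "M2"),
                                          collinear_with=("M1125", "M2125"))
        data = prepare_model_data(wide, responses, "node", ["Y"])
        cfg = PipelineConfig()
        res = step3_enumerate(data, "Y", ["M1", "M2"], ["125"], cfg)
        fitted_labels = set(res["models"]["labels"])
        assert not any("M1125" in l and "M2125" in l for l in fitted_labels)
        assert res["n_collinear_excluded"] > 0

    def test_empty_universe_errors(self):
        data = prep(13)
        cfg = PipelineConfig()
        with pytest.raises(RuntimeError):
            step3_enumerate(data, "Y", ["ABSENT"], ["125"], cfg)

    def test_subsampling_mode(self):
        data = prep(14)
        cfg = PipelineConfig(collinearity_r=1.0)
        res = step3_enumerate(data, "Y", ["M1", "M2", "M3"], ["125"], cfg,
                              max_models=10, seed=1)
        assert res["subsampled"] and len(res["aicc"]) <= 10


class TestStep2AndStep4:
    def test_step2_refit_equals_direct_call(self):
        data = prep(15, beta={"M1125": 1.0})
        terms = (Term("M1", "125", 1),)
        table = step2_fit(data, ["Y"], [terms])
        direct = fit_model(data, "Y", list(terms))
        assert table.iloc[0]["aicc"] == pytest.approx(direct.aicc)

    def test_step4_trivial_cases(self):
        dist = np.array([10.0, 12.0, 14.0, 16.0])
        pct, ok = step4_percentile(5.0, dist)
        assert pct == 1.0 and ok
        pct, ok = step4_percentile(13.0, dist)
        assert pct == 0.5 and not ok

    def test_step4_ties_conservative(self):
        dist = np.array([10.0, 10.0, 20.0])
        pct, _ = step4_percentile(10.0, dist)
        assert pct == pytest.approx(1 / 3)

    def test_step4_empty_distribution_errors(self):
        with pytest.raises(ValueError):
            step4_percentile(1.0, np.array([]))

    def test_permuted_response_small_coefficients(self):
        # same model structure on a permuted response: coefficients near 0
        rng = np.random.default_rng(16)
        wide, responses = synth_node_data(16, beta={"M1125": 1.5})
        responses["Y"] = rng.permutation(responses["Y"].to_numpy())
        data = prepare_model_data(wide, responses, "node", ["Y"])
        fit = fit_model(data, "Y", [Term("M1", "125", 1)])
        assert abs(fit.beta[1]) < 0.5

    def test_best_models_band(self):
        data = prep(17, beta={"M1125": 2.0})
        retained = pd.DataFrame([
            {"metric": m, "scale": "125", "degree": 1, "retained": True}
            for m in ("M1", "M2", "M3")
        ])
        out = step1_subset_search(data, "Y", retained, max_metrics=2)
        sets = best_models(out)
        assert sets
        assert all(any(t.metric == "M1" for t in ts) for ts in sets)


class TestQuadraticRule:
    def test_degree_two_includes_linear_column(self):
        data = prep(18)
        fit = fit_model(data, "Y", [Term("M1", "125", 2)])
        assert "M1125" in fit.names and "M1125^2" in fit.names

    def test_every_step2_structure_in_step3_universe(self):
        data = prep(19, beta={"M1125": 1.0})
        cfg = PipelineConfig(collinearity_r=1.0)
        table = step1_scale_selection(data, "Y", ["M1", "M2", "M3"], ["125"])
        presel = step1_preselect(data, "Y", table, alpha=0.99)
        subsets = step1_subset_search(data, "Y", presel, max_metrics=2)
        res3 = step3_enumerate(data, "Y", ["M1", "M2", "M3"], ["125"], cfg)
        universe_labels = set(res3["models"]["labels"])
        for ts in best_models(subsets):
            label = " + ".join(l for t in ts for l in t.labels())
            assert label in universe_labels
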
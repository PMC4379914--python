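"""The logistic solitariness model: evaluation, fitting, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import locustphase as lp
from locustphase.classifier import (
    DegenerateDesignError,
    GREGARIOUS,
    SOLITARY,
    LogisticModel,
)
from locustphase.features import MARKERS


def _fv(TDM=0.0, FOM=0.0, AI=0.0, **extra):
    d = {m: 0.0 for m in MARKERS}
    d.update(TDM=TDM, FOM=FOM, AI=AI, **extra)
    return d


def simulate_marker_cohort(rng, n, model: LogisticModel):
    """Markers from fixed normals, labels Bernoulli in the given model."""
    X = pd.DataFrame(
        {
            "TDM": rng.normal(100.0, 120.0, n),
            "FOM": rng.normal(4.0, 9.0, n),
            "AI": rng.normal(15.0, 350.0, n),
        }
    )
    eta = model.intercept + sum(
        model.coefficients[m] * X[m].to_numpy() for m in model.coefficients
    )
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


class TestModelEvaluation:
    def test_linear_predictor_at_zero_markers_is_intercept(self, model):
        assert lp.linear_predictor(model, _fv()) == pytest.approx(2.361, abs=1e-12)

    def test_zero_model_is_identically_zero(self):
        zero = LogisticModel(intercept=0.0, coefficients={"TDM": 0.0, "FOM": 0.0, "AI": 0.0})
        assert lp.linear_predictor(zero, _fv(TDM=123.0, FOM=9.0, AI=-50.0)) == 0.0

    def test_linear_predictor_hand_arithmetic(self, model):
        eta = lp.linear_predictor(model, _fv(TDM=100.0, FOM=10.0, AI=0.0))
        assert eta == pytest.approx(2.361 - 1.6 - 1.72, abs=1e-9)

    def test_logistic_midpoint_and_saturation(self):
        m0 = LogisticModel(intercept=0.0, coefficients={})
        assert lp.p_sol(m0, _fv()) == 0.5
        big = LogisticModel(intercept=500.0, coefficients={})
        assert lp.p_sol(big, _fv()) == pytest.approx(1.0)

    def test_published_p_sol_at_zero_markers(self, model):
        assert lp.p_sol(model, _fv()) == pytest.approx(
            math.exp(2.361) / (1.0 + math.exp(2.361)), abs=1e-12
        )
        assert lp.p_sol(model, _fv()) == pytest.approx(0.9138, abs=5e-4)

    def test_p_sol_monotone_decreasing_in_each_marker(self, model):
        base = lp.p_sol(model, _fv(TDM=100.0, FOM=5.0, AI=10.0))
        for marker in ("TDM", "FOM", "AI"):
            bumped = _fv(TDM=100.0, FOM=5.0, AI=10.0)
            bumped[marker] += 10.0
            assert lp.p_sol(model, bumped) < base

    def test_complement_symmetry(self, model):
        neg = LogisticModel(
            intercept=-model.intercept,
            coefficients={k: -v for k, v in model.coefficients.items()},
        )
        for tdm in (0.0, 50.0, 300.0):
            fv = _fv(TDM=tdm, FOM=3.0, AI=-20.0)
            assert lp.p_sol(model, fv) + lp.p_sol(neg, fv) == pytest.approx(1.0)

    def test_missing_marker_raises(self, model):
        with pytest.raises(KeyError):
            lp.linear_predictor(model, {"TDM": 0.0, "FOM": 0.0})


class TestClassification:
    def test_extreme_probabilities(self, model):
        assert lp.classify(model, _fv()) == SOLITARY  # p ~ 0.91
        assert lp.classify(model, _fv(TDM=500.0, FOM=20.0)) == GREGARIOUS

    def test_tie_at_threshold_goes_to_solitary(self):
        m0 = LogisticModel(intercept=0.0, coefficients={})
        assert lp.p_sol(m0, _fv()) == 0.5
        assert lp.classify(m0, _fv()) == SOLITARY

    def test_threshold_equivalent_to_eta_cut(self, model):
        # classifying at p >= thr is the same as eta >= logit(thr)
        cut = math.log(model.threshold / (1.0 - model.threshold))
        rng = np.random.default_rng(0)
        for _ in range(100):
            fv = _fv(
                TDM=rng.uniform(0, 400), FOM=rng.uniform(0, 20), AI=rng.uniform(-360, 360)
            )
            by_p = lp.classify(model, fv) == SOLITARY
            by_eta = lp.linear_predictor(model, fv) >= cut
            assert by_p == by_eta

    def test_classification_rates_hand_cases(self, model):
        always_sol = LogisticModel(intercept=50.0, coefficients={})
        feats = [_fv() for _ in range(10)]
        labels = [SOLITARY] * 5 + [GREGARIOUS] * 5
        rates = lp.classification_rates(always_sol, feats, labels)
        assert rates == {SOLITARY: 1.0, GREGARIOUS: 0.0}

    def test_classification_rates_fraction(self):
        # 10 solitary of which 9 correctly scored -> solitary rate 0.9
        m = LogisticModel(intercept=0.0, coefficients={"TDM": -1.0})
        feats = [_fv(TDM=-1.0)] * 9 + [_fv(TDM=1.0)] + [_fv(TDM=1.0)] * 5
        labels = [SOLITARY] * 10 + [GREGARIOUS] * 5
        rates = lp.classification_rates(m, feats, labels)
        assert rates[SOLITARY] == pytest.approx(0.9)
        assert rates[GREGARIOUS] == pytest.approx(1.0)

    def test_single_class_data_rejected(self, model):
        with pytest.raises(ValueError):
            lp.classification_rates(model, [_fv()], [SOLITARY])


class TestFitting:
    def test_null_design_slopes_near_zero(self, model):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {"TDM": rng.normal(0, 1, 1500), "FOM": rng.normal(0, 1, 1500), "AI": rng.normal(0, 1, 1500)}
        )
        y = (rng.random(1500) < 0.5).astype(float)
        rep = lp.fit_logistic(X, y, markers=("TDM", "FOM", "AI"))
        assert rep.converged
        # slopes within ~3 standard errors (SE ~ 2/sqrt(n) ~ 0.052)
        assert all(abs(b) < 0.16 for b in rep.model.coefficients.values())

    def test_recovers_known_three_marker_model(self, model):
        rng = np.random.default_rng(11)
        X, y = simulate_marker_cohort(rng, 2000, model)
        rep = lp.fit_logistic(X, y, markers=("TDM", "FOM", "AI"))
        assert rep.converged
        assert rep.model.intercept == pytest.approx(model.intercept, rel=0.10)
        for m, truth in model.coefficients.items():
            assert rep.model.coefficients[m] == pytest.approx(truth, rel=0.10)

    def test_consistency_error_shrinks_with_sample_size(self, model):
        def median_rel_error(n, seeds):
            errs = []
            for s in seeds:
                X, y = simulate_marker_cohort(np.random.default_rng(s), n, model)
                rep = lp.fit_logistic(X, y, markers=("TDM", "FOM", "AI"))
                errs.append(
                    np.median(
                        [
                            abs(rep.model.coefficients[m] - t) / abs(t)
                            for m, t in model.coefficients.items()
                        ]
                    )
                )
            return np.median(errs)

        e200 = median_rel_error(200, range(10))
        e1000 = median_rel_error(1000, range(10, 20))
        e5000 = median_rel_error(5000, range(20, 30))
        assert e5000 < e1000 < e200

    def test_matches_statsmodels_mle(self, model):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X, y = simulate_marker_cohort(rng, 500, model)
        rep = lp.fit_logistic(X, y, markers=("TDM", "FOM", "AI"))
        ref = sm.Logit(y, sm.add_constant(X[["TDM", "FOM", "AI"]])).fit(disp=0)
        assert rep.model.intercept == pytest.approx(ref.params["const"], abs=1e-5)
        for m in ("TDM", "FOM", "AI"):
            assert rep.model.coefficients[m] == pytest.approx(ref.params[m], abs=1e-6)
        assert rep.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"TDM": [0.0, 1.0, 2.0, 3.0]})
        y = [0, 0, 1, 1]
        rep = lp.fit_logistic(X, y, markers=("TDM",))
        assert rep.separation_flag
        assert not rep.converged
        assert rep.per_class_rate == {SOLITARY: 1.0, GREGARIOUS: 1.0}

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        X = pd.DataFrame({"TDM": x, "FOM": 2.0 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(DegenerateDesignError):
            lp.fit_logistic(X, y, markers=("TDM", "FOM"))

    def test_needs_two_animals_per_class(self):
        X = pd.DataFrame({"TDM": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            lp.fit_logistic(X, [1, 0, 0], markers=("TDM",))


class TestMarkerSelection:
    @staticmethod
    def _noise_table(rng, n):
        return pd.DataFrame({m: rng.normal(0, 1, n) for m in MARKERS})

    def test_single_informative_marker_selected_first(self):
        rng = np.random.default_rng(3)
        X = self._noise_table(rng, 600)
        y = (rng.random(600) < expit(2.0 * X["FOM"])).astype(float)
        selected, rep = lp.select_markers(X, y)
        assert selected[0] == "FOM"
        assert rep.converged

    def test_duplicated_marker_never_selected_twice(self):
        rng = np.random.default_rng(5)
        X = self._noise_table(rng, 400)
        X["TDM"] = X["FOM"]  # perfect collinearity
        y = (rng.random(400) < expit(1.5 * X["FOM"])).astype(float)
        selected, _ = lp.select_markers(X, y)
        assert not {"TDM", "FOM"} <= set(selected)

    def test_pure_noise_selects_few_or_none(self):
        rng = np.random.default_rng(8)
        X = self._noise_table(rng, 400)
        y = (rng.random(400) < 0.5).astype(float)
        selected, _ = lp.select_markers(X, y)
        # up to the nominal false-selection rate of the information criterion
        assert len(selected) <= 1

    def test_accuracy_criterion_available(self):
        rng = np.random.default_rng(9)
        X = self._noise_table(rng, 300)
        y = (rng.random(300) < expit(3.0 * X["TDM"])).astype(float)
        selected, _ = lp.select_markers(X, y, criterion="accuracy")
        assert "TDM" in selected


class TestModelSerialisation:
    def test_published_asset_round_trips(self, tmp_path, model):
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = LogisticModel.from_yaml(path)
        assert back.intercept == model.intercept
        assert back.coefficients == model.coefficients
        assert back.threshold == model.threshold

    def test_published_coefficients(self, model):
        assert model.intercept == 2.361
        assert model.coefficients == {"TDM": -0.016, "FOM": -0.172, "AI": -0.005}
        assert model.threshold == 0.5
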
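import warnings

import numpy as np
import pytest

from quadbird import (
    GeneratorConfig,
    SmoothTermSpec,
    fit_additive,
    generate_community,
    landcover_matrix,
    max_response,
    model_from_json,
    model_to_json,
    partial_response,
    predict,
    validate,
)
from quadbird.gam import MU_EPS, select_df
from quadbird.survey import LANDCOVER_CATEGORIES


def make_design(rng, n=200, hi=10.0, k=8):
    return rng.uniform(0, hi, size=(n, k))


def linear_poisson_data(rng, n=200):
    x = make_design(rng, n)
    beta = np.array([0.3, 0.1, 0.25, 0.4, 0.05, 0.2, 0.02, 0.15])
    y = rng.poisson(2.0 + x @ beta)
    return x, beta, y


ALL_LINEAR = [SmoothTermSpec(p, 1) for p in LANDCOVER_CATEGORIES]


class TestFitLinearReduction:
    def test_matches_independent_identity_link_glm(self, rng):
        """df=1 everywhere reduces to an identity-link Poisson GLM."""
        sm = pytest.importorskip("statsmodels.api")
        x, _, y = linear_poisson_data(rng)
        model = fit_additive(x, y, ALL_LINEAR)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                y,
                sm.add_constant(x),
                family=sm.families.Poisson(sm.families.links.Identity()),
            ).fit()
        slopes = np.array([t.coef[0] for t in model.terms])
        np.testing.assert_allclose(slopes, glm.params[1:], rtol=1e-4)
        intercept = model.intercept - sum(
            t.coef[0] * t.xbar for t in model.terms
        )
        assert intercept == pytest.approx(glm.params[0], rel=1e-4)

    def test_constant_response(self, rng):
        x = make_design(rng, n=60)
        y = np.full(60, 7)
        model = fit_additive(x, y, ALL_LINEAR)
        assert model.intercept == pytest.approx(7.0, abs=1e-5)
        for t in model.terms:
            assert abs(t.coef[0]) < 1e-5

    def test_score_equation_prediction_mean(self, rng):
        x, _, y = linear_poisson_data(rng)
        model = fit_additive(x, y, ALL_LINEAR)
        assert model.predict(x).mean() == pytest.approx(y.mean(), rel=1e-6)

    def test_df_precondition(self, rng):
        x = make_design(rng, n=8)
        with pytest.raises(ValueError, match="below the number of quadrats"):
            fit_additive(x, np.ones(8, dtype=int), ALL_LINEAR)

    def test_negative_counts_rejected(self, rng):
        x = make_design(rng, n=20)
        with pytest.raises(ValueError):
            fit_additive(x, np.full(20, -1), ALL_LINEAR)


class TestSmoothRecovery:
    def test_known_quadratic_effect_recovered(self, rng):
        """Partial response of a curved term correlates > 0.95 with truth."""
        x = make_design(rng, n=200)
        f = lambda g: 0.08 * (g - 4.0) ** 2
        mu = 5.0 + f(x[:, 3]) - np.mean(f(x[:, 3])) + 0.3 * x[:, 0]
        y = rng.poisson(np.maximum(mu, 0.05))
        specs = [
            SmoothTermSpec(p, 4 if i == 3 else 1)
            for i, p in enumerate(LANDCOVER_CATEGORIES)
        ]
        model = fit_additive(x, y, specs)
        grid = np.linspace(0, x[:, 3].max(), 60)
        pr = partial_response(model, LANDCOVER_CATEGORIES[3], grid)
        truth = f(grid) - np.mean(f(x[:, 3]))
        assert np.corrcoef(pr.contribution, truth)[0, 1] > 0.95

    def test_inactive_term_stays_small(self, rng):
        x = make_design(rng, n=200)
        f = lambda g: 0.08 * (g - 4.0) ** 2
        y = rng.poisson(5.0 + f(x[:, 3]))
        specs = [
            SmoothTermSpec(p, 3 if i in (2, 3) else 1)
            for i, p in enumerate(LANDCOVER_CATEGORIES)
        ]
        model = fit_additive(x, y, specs)
        grid = np.linspace(0, 10, 40)
        active = partial_response(model, LANDCOVER_CATEGORIES[3], grid)
        inactive = partial_response(model, LANDCOVER_CATEGORIES[2], grid)
        assert (
            np.abs(inactive.contribution).max()
            < 0.3 * np.abs(active.contribution).max()
        )

    def test_effective_df_hits_target(self, rng):
        x = make_design(rng, n=120)
        y = rng.poisson(4.0 + 0.1 * (x[:, 0] - 5) ** 2)
        specs = [
            SmoothTermSpec(p, 3 if i == 0 else 1)
            for i, p in enumerate(LANDCOVER_CATEGORIES)
        ]
        model = fit_additive(x, y, specs)
        assert model.terms[0].edf == pytest.approx(3.0, abs=0.1)

    def test_dispersion_near_one_poisson_above_one_negbin(self, rng):
        x = make_design(rng, n=300)
        mu = 3.0 + 0.4 * x[:, 0] + 0.2 * x[:, 1]
        disp_po, disp_nb = [], []
        for rep in range(20):
            y_po = rng.poisson(mu)
            # negative-binomial with the same mean and size 2 (var = mu + mu^2/2)
            y_nb = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
            disp_po.append(fit_additive(x, y_po, ALL_LINEAR).dispersion)
            disp_nb.append(fit_additive(x, y_nb, ALL_LINEAR).dispersion)
        assert np.mean(disp_po) == pytest.approx(1.0, abs=0.3)
        assert np.mean(disp_nb) > 1.3


class TestModelQuantities:
    def test_validate_exact_and_constant_predictions(self, rng):
        x, _, y = linear_poisson_data(rng, n=100)
        model = fit_additive(x, y, ALL_LINEAR)
        r2 = validate(model, x, y)
        # hand-coded sums of squares
        yhat = model.predict(x)
        expect = 100 * (1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())
        assert r2 == pytest.approx(expect, abs=1e-12)

    def test_validate_zero_variance_rejected(self, rng):
        x, _, y = linear_poisson_data(rng, n=50)
        model = fit_additive(x, y, ALL_LINEAR)
        with pytest.raises(ValueError):
            validate(model, x, np.full(50, 3))

    def test_linear_partial_response_closed_form(self, rng):
        x, _, y = linear_poisson_data(rng, n=100)
        model = fit_additive(x, y, ALL_LINEAR)
        t0 = model.terms[0]
        grid = np.linspace(0, 10, 11)
        pr = partial_response(model, LANDCOVER_CATEGORIES[0], grid)
        np.testing.assert_allclose(
            pr.contribution, t0.coef[0] * (grid - t0.xbar), atol=1e-10
        )

    def test_partial_response_centered_at_mean(self, rng):
        x, _, y = linear_poisson_data(rng, n=100)
        model = fit_additive(x, y, ALL_LINEAR)
        pr = partial_response(
            model, LANDCOVER_CATEGORIES[2], np.array([x[:, 2].mean()])
        )
        assert pr.contribution[0] == pytest.approx(0.0, abs=1e-10)

    def test_unknown_predictor_rejected(self, rng):
        x, _, y = linear_poisson_data(rng, n=100)
        model = fit_additive(x, y, ALL_LINEAR)
        with pytest.raises(KeyError):
            partial_response(model, "lunar_maria", np.array([1.0]))

    def test_predict_closed_form_and_clamped(self, rng):
        x, _, y = linear_poisson_data(rng, n=100)
        model = fit_additive(x, y, ALL_LINEAR)
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        closed = model.intercept + sum(
            t.coef[0] * (v[k] - t.xbar) for k, t in enumerate(model.terms)
        )
        assert predict(model, v) == pytest.approx(closed, rel=1e-10)
        # drive the linear predictor far negative: prediction clamps at eps
        far = np.full(8, -1e4)
        assert predict(model, far) == MU_EPS

    def test_prediction_invariant_to_row_order(self, rng):
        x, _, y = linear_poisson_data(rng, n=100)
        perm = rng.permutation(100)
        m1 = fit_additive(x, y, ALL_LINEAR)
        m2 = fit_additive(x[perm], y[perm], ALL_LINEAR)
        v = np.array([2, 1, 4, 3, 2, 5, 1, 7.0])
        assert predict(m1, v) == pytest.approx(predict(m2, v), rel=1e-6)

    def test_serialization_round_trip(self, rng):
        x = make_design(rng, n=150)
        y = rng.poisson(4.0 + 0.1 * (x[:, 1] - 5) ** 2)
        specs = [
            SmoothTermSpec(p, 3 if i == 1 else 1)
            for i, p in enumerate(LANDCOVER_CATEGORIES)
        ]
        model = fit_additive(x, y, specs)
        back = model_from_json(model_to_json(model))
        grid = np.linspace(0, 10, 23)
        np.testing.assert_allclose(
            partial_response(model, LANDCOVER_CATEGORIES[1], grid).contribution,
            partial_response(back, LANDCOVER_CATEGORIES[1], grid).contribution,
        )
        v = rng.uniform(0, 10, size=8)
        assert predict(model, v) == predict(back, v)


class TestDfSelection:
    def test_empty_candidate_range_returns_linear_baseline(self, rng):
        x, _, y = linear_poisson_data(rng, n=60)
        specs, trace = select_df(x, y, df_cap=0)
        assert all(s.df == 1 for s in specs)
        assert trace == []

    def test_curved_term_gets_extra_df(self, rng):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(500 + rep)
            x = make_design(r, n=150, k=4)
            f = 0.25 * (x[:, 2] - 5.0) ** 2
            y = r.poisson(4.0 + f)
            specs, _ = select_df(
                x, y, predictors=list("abcd"), df_cap=3
            )
            hits += specs[2].df > 1
        assert hits >= 9

    def test_linear_world_keeps_linear_terms(self, rng):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(900 + rep)
            x = make_design(r, n=150, k=4)
            y = r.poisson(3.0 + 0.3 * x[:, 0] + 0.2 * x[:, 3])
            specs, _ = select_df(x, y, predictors=list("abcd"), df_cap=3)
            hits += all(s.df == 1 for s in specs)
        assert hits >= 9


class TestOnSyntheticCommunity:
    def test_fit_runs_on_default_world(self, community):
        x = landcover_matrix(community.quadrats)
        resp = max_response(community.sessions)
        model = fit_additive(x, resp.y1_richness, response="richness")
        assert np.isfinite(model.r_squared)
        assert model.dispersion > 0
        # identity-link means stay positive over the land-cover simplex corners
        corners = np.eye(8) * 25.0
        assert np.isfinite(model.predict(corners)).all()
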
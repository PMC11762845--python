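import numpy as np
import pytest

from quadbird import (
    QuadratRecord,
    Scenario,
    SmoothTermSpec,
    Zone,
    apply_scenario,
    builtin_scenario,
    fit_additive,
    landcover_matrix,
    make_expansion_scenario,
    make_greening_scenario,
    predict_scenario,
    scenario_from_config,
)
from quadbird.survey import LANDCOVER_CATEGORIES


def quadrat(qid, zone, extents):
    lc = np.zeros(8)
    for cat, v in extents.items():
        lc[LANDCOVER_CATEGORIES.index(cat)] = v
    lc[0] += 25.0 - lc.sum()  # pad with arable land
    return QuadratRecord(qid, zone, lc)


@pytest.fixture()
def mixed_quadrats(community):
    return community.quadrats


@pytest.fixture()
def linear_model(rng):
    x = rng.uniform(0, 10, size=(150, 8))
    beta = np.array([0.5, 0.2, 0.4, 0.6, 0.1, 0.35, 0.05, 0.25])
    y = rng.poisson(3.0 + x @ beta)
    return fit_additive(
        x, y, [SmoothTermSpec(p, 1) for p in LANDCOVER_CATEGORIES]
    )


class TestScenarioConstruction:
    def test_expansion_b_composition(self):
        s = make_expansion_scenario("B")
        q = quadrat("q1", Zone.PERI_URBAN, {"arable_land": 25.0})
        (out,) = apply_scenario([q], s)
        expected = np.zeros(8)
        expected[1] = 22.5  # continuous urban fabric
        expected[6] = 2.5  # road networks
        np.testing.assert_allclose(out.landcover, expected)

    def test_expansion_a_single_class(self):
        s = make_expansion_scenario("A")
        q = quadrat("q1", Zone.EXTRA_URBAN, {"ligneous_crops": 10.0})
        (out,) = apply_scenario([q], s)
        assert out.landcover[1] == 25.0
        assert out.landcover.sum() == 25.0

    def test_all_variants_conserve_area(self, mixed_quadrats):
        for name in "ABCDEFGH":
            s = builtin_scenario(name)
            for q in apply_scenario(mixed_quadrats, s):
                assert q.landcover.sum() == pytest.approx(25.0, abs=1e-9)
                assert (q.landcover >= 0).all()

    def test_greening_arithmetic(self):
        s = make_greening_scenario("H")
        q = quadrat(
            "q1",
            Zone.URBAN,
            {"continuous_urban_fabric": 10.0, "green_urban_areas": 2.0},
        )
        (out,) = apply_scenario([q], s)
        assert out.landcover[1] == pytest.approx(6.0)
        assert out.landcover[3] == pytest.approx(6.0)

    def test_greening_clipped_when_donor_short(self):
        s = make_greening_scenario("E")
        q = quadrat(
            "q1",
            Zone.URBAN,
            {"continuous_urban_fabric": 0.5, "green_urban_areas": 1.0},
        )
        with pytest.warns(UserWarning, match="clipped"):
            (out,) = apply_scenario([q], s)
        assert out.landcover[1] == pytest.approx(0.0, abs=1e-9)
        assert out.landcover[3] == pytest.approx(1.5)
        assert out.landcover.sum() == pytest.approx(25.0, abs=1e-9)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            make_expansion_scenario("Z")
        with pytest.raises(ValueError):
            builtin_scenario("K")

    def test_invalid_scenario_fields_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", frozenset({Zone.URBAN}))
        with pytest.raises(ValueError):
            Scenario(
                "bad",
                frozenset({Zone.URBAN}),
                replacement=tuple([0.5] + [0.0] * 7),
            )
        with pytest.raises(ValueError):
            Scenario(
                "bad", frozenset({Zone.URBAN}), delta=tuple([1.0] + [0.0] * 7)
            )

    def test_config_parsing(self):
        s = scenario_from_config(
            {
                "name": "my_greening",
                "zones": ["urban"],
                "delta": {"green_urban_areas": 2, "continuous_urban_fabric": -2},
            }
        )
        assert s.delta[3] == 2.0
        assert Zone.URBAN in s.target_zones


class TestApplyScenario:
    def test_empty_target_zone_is_identity(self, mixed_quadrats):
        s = Scenario(
            "noop", frozenset(), replacement=tuple([1.0] + [0.0] * 7)
        )
        out = apply_scenario(mixed_quadrats, s)
        assert out == list(mixed_quadrats)

    def test_expansion_targets_only_peri_extra(self, mixed_quadrats):
        out = apply_scenario(mixed_quadrats, make_expansion_scenario("A"))
        changed = [
            o for o, q in zip(out, mixed_quadrats)
            if not np.array_equal(o.landcover, q.landcover)
        ]
        assert len(changed) == 20
        for o, q in zip(out, mixed_quadrats):
            if q.zone == Zone.URBAN:
                assert np.array_equal(o.landcover, q.landcover)

    def test_replacement_idempotent(self, mixed_quadrats):
        s = make_expansion_scenario("C")
        once = apply_scenario(mixed_quadrats, s)
        twice = apply_scenario(once, s)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.landcover, b.landcover)


class TestPredictScenario:
    def test_identity_scenario_all_zero_bit_exact(
        self, linear_model, mixed_quadrats
    ):
        s = Scenario(
            "identity",
            frozenset({Zone.URBAN, Zone.PERI_URBAN, Zone.EXTRA_URBAN}),
            delta=tuple([0.0] * 8),
        )
        res = predict_scenario(linear_model, mixed_quadrats, s)
        assert all(d == 0.0 for *_, d in res.per_quadrat)
        assert res.mean_delta == 0.0
        assert res.sd_delta == 0.0

    def test_linear_model_deltas_closed_form(self, linear_model, mixed_quadrats):
        s = make_greening_scenario("G")
        res = predict_scenario(linear_model, mixed_quadrats, s)
        slopes = np.array([t.coef[0] for t in linear_model.terms])
        for qid, base, scen, delta in res.per_quadrat:
            q = next(x for x in mixed_quadrats if x.quadrat_id == qid)
            if q.landcover[1] < 3.0:
                continue  # clipped transfer: closed form does not apply
            expect = 3.0 * (slopes[3] - slopes[1])
            assert delta == pytest.approx(expect, rel=1e-9)

    def test_mean_sd_recomputable_and_only_targets_reported(
        self, linear_model, mixed_quadrats
    ):
        res = predict_scenario(
            linear_model, mixed_quadrats, make_expansion_scenario("B")
        )
        assert len(res.per_quadrat) == 20
        deltas = np.array([d for *_, d in res.per_quadrat])
        assert res.mean_delta == pytest.approx(deltas.mean())
        assert res.sd_delta == pytest.approx(deltas.std(ddof=1))
        assert abs(res.extreme[1]) == pytest.approx(np.abs(deltas).max())

    def test_greening_gain_nondecreasing_for_monotone_model(self, rng):
        """E <= F <= G <= H per quadrat when green response rises faster."""
        x = rng.uniform(0, 12, size=(200, 8))
        y = rng.poisson(4.0 + 0.8 * x[:, 3] + 0.05 * x[:, 1])
        model = fit_additive(
            x, y, [SmoothTermSpec(p, 1) for p in LANDCOVER_CATEGORIES]
        )
        q = quadrat(
            "u1",
            Zone.URBAN,
            {"continuous_urban_fabric": 10.0, "green_urban_areas": 3.0},
        )
        gains = [
            predict_scenario(model, [q], make_greening_scenario(v)).mean_delta
            for v in "EFGH"
        ]
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))
        assert gains[0] >= 0
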
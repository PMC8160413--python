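import math

import numpy as np
import pytest

import dcepref as d
from conftest import random_partworths


@pytest.fixture()
def gbcm_partworths(space):
    rng = np.random.default_rng(7)
    levels = {s.name: np.asarray(s.levels) for s in space}
    utilities = {s.name: rng.normal(size=(30, s.n_levels)) for s in space}
    return d.PartWorthSet([f"r{i}" for i in range(30)], levels, utilities)


class TestInterpolation:
    def test_value_at_level_returns_that_utility(self, space):
        spec = space[0]  # sensitivity, linear
        u = np.array([-1.5, -0.5, 0.5, 1.5])
        for lev, ui in zip(spec.levels, u):
            assert d.utility_at_value(spec, u, lev) == pytest.approx(ui)

    def test_linear_midpoint(self):
        spec = d.AttributeSpec("cost", (25.0, 50.0))
        assert d.utility_at_value(spec, np.array([1.0, 0.0]), 37.5) == pytest.approx(0.5)
        # note: utilities need not be zero-sum for interpolation itself

    def test_log_midpoint(self):
        spec = d.AttributeSpec("retention", (1.0, 100.0), scale="log")
        out = d.utility_at_value(spec, np.array([0.6, -0.6]), 10.0)
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_linear_extrapolation_beyond_bounds(self):
        spec = d.AttributeSpec("cost", (25.0, 50.0))
        u = np.array([1.0, 0.0])
        assert d.utility_at_value(spec, u, 75.0) == pytest.approx(-1.0)
        assert d.utility_at_value(spec, u, 0.0) == pytest.approx(2.0)

    def test_log_scale_extrapolation_below_minimum(self):
        # retention 0.1 is one decade below the smallest design level
        spec = d.AttributeSpec("retention", (1.0, 10.0, 100.0), scale="log")
        u = np.array([1.0, 0.0, -1.0])
        assert d.utility_at_value(spec, u, 0.1) == pytest.approx(2.0)

    def test_log_scale_rejects_nonpositive(self):
        spec = d.AttributeSpec("retention", (1.0, 100.0), scale="log")
        with pytest.raises(ValueError):
            d.utility_at_value(spec, np.array([0.5, -0.5]), 0.0)


class TestProductUtility:
    def test_zero_partworths_give_zero_utility(self, space):
        levels = {s.name: np.asarray(s.levels) for s in space}
        utilities = {s.name: np.zeros((3, s.n_levels)) for s in space}
        pw = d.PartWorthSet(["a", "b", "c"], levels, utilities)
        for product in d.DEFAULT_PRODUCTS.values():
            np.testing.assert_allclose(d.product_utility(pw, product, space), 0.0)

    def test_best_profile_beats_worst_profile(self, space, gbcm_partworths):
        def extreme(best):
            vals = {}
            for s in space:
                u = gbcm_partworths.utilities[s.name]
                # per-respondent best differs; use population-mean best level
                mean_u = u.mean(axis=0)
                idx = mean_u.argmax() if best else mean_u.argmin()
                vals[s.name] = s.levels[idx]
            return vals

        hi = d.ProductProfile("hi", extreme(True))
        lo = d.ProductProfile("lo", extreme(False))
        u_hi = d.product_utility(gbcm_partworths, hi, space).mean()
        u_lo = d.product_utility(gbcm_partworths, lo, space).mean()
        assert u_hi > u_lo

    def test_matches_per_attribute_interpolation_sum(self, space, gbcm_partworths):
        for product in d.DEFAULT_PRODUCTS.values():
            total = d.product_utility(gbcm_partworths, product, space)
            manual = sum(
                np.asarray(
                    d.utility_at_value(
                        s, gbcm_partworths.utilities[s.name], product.values[s.name]
                    )
                )
                for s in space
            )
            np.testing.assert_allclose(total, manual, atol=1e-12)

    def test_missing_attribute_rejected(self, space, gbcm_partworths):
        bad = d.ProductProfile("bad", {"sensitivity": 90})
        with pytest.raises(ValueError):
            d.product_utility(gbcm_partworths, bad, space)


def two_product_setup(space, delta):
    """Every respondent prefers product X over Y by exactly `delta` utility."""
    levels = {s.name: np.asarray(s.levels) for s in space}
    utilities = {s.name: np.zeros((10, s.n_levels)) for s in space}
    # sensitivity utilities: linear ramp worth delta between levels 0 and 3
    utilities["sensitivity"] = np.tile(
        np.array([-delta / 2, -delta / 6, delta / 6, delta / 2]), (10, 1)
    )
    pw = d.PartWorthSet([f"r{i}" for i in range(10)], levels, utilities)
    hi = dict.fromkeys(levels, 0.0)
    lo = dict.fromkeys(levels, 0.0)
    for s in space:
        hi[s.name] = lo[s.name] = s.levels[0]
    hi["sensitivity"] = 95.0
    lo["sensitivity"] = 80.0
    return pw, [d.ProductProfile("X", hi), d.ProductProfile("Y", lo)]


class TestShares:
    def test_identical_products_split_evenly(self, space, gbcm_partworths):
        p1 = d.ProductProfile("P1", dict(d.DEFAULT_PRODUCTS["Existing product A"].values))
        p2 = d.ProductProfile("P2", dict(p1.values))
        res = d.share_of_preference(gbcm_partworths, [p1, p2], space)
        assert res.overall["P1"] == pytest.approx(50.0)
        assert res.overall["P2"] == pytest.approx(50.0)

    def test_ln3_utility_gap_gives_75_25(self, space):
        pw, products = two_product_setup(space, math.log(3.0))
        res = d.share_of_preference(pw, products, space)
        assert res.overall["X"] == pytest.approx(75.0, abs=1e-9)
        assert res.overall["Y"] == pytest.approx(25.0, abs=1e-9)

    def test_shares_normalised_per_respondent_and_overall(self, space, gbcm_partworths):
        products = list(d.DEFAULT_PRODUCTS.values())
        for method, kwargs in [
            ("logit", {}),
            ("first_choice", {}),
            ("rfc", dict(seed=1, n_draws=500)),
        ]:
            res = d.share_of_preference(
                gbcm_partworths, products, space, method=method, **kwargs
            )
            np.testing.assert_allclose(res.per_respondent.sum(axis=1), 100.0, atol=1e-9)
            assert sum(res.overall.values()) == pytest.approx(100.0, abs=1e-9)
            assert res.per_respondent.min() >= 0

    def test_logit_invariant_to_constant_utility_shift(self, space, gbcm_partworths):
        products = list(d.DEFAULT_PRODUCTS.values())[:3]
        res1 = d.share_of_preference(gbcm_partworths, products, space)
        shifted = d.PartWorthSet(
            gbcm_partworths.respondent_ids,
            {k: v.copy() for k, v in gbcm_partworths.levels.items()},
            # adding a constant within an attribute is removed by
            # zero-centering; shares must be unchanged
            {k: v + 3.7 for k, v in gbcm_partworths.utilities.items()},
        )
        res2 = d.share_of_preference(shifted, products, space)
        np.testing.assert_allclose(res1.per_respondent, res2.per_respondent, atol=1e-9)

    def test_improving_one_attribute_never_lowers_logit_share(self, space):
        pw, products = two_product_setup(space, 1.0)
        base = d.share_of_preference(pw, products, space)
        better = dict(products[1].values)
        better["sensitivity"] = 90.0  # improve Y toward preferred direction
        res = d.share_of_preference(
            pw, [products[0], d.ProductProfile("Y", better)], space
        )
        assert np.all(res.per_respondent[:, 1] >= base.per_respondent[:, 1])

    def test_dominated_product_gets_strictly_lower_share(self, space):
        rng = np.random.default_rng(9)
        levels = {s.name: np.asarray(s.levels) for s in space}
        utilities = {}
        for s in space:
            # strictly monotone utilities in the preferred direction
            mags = np.sort(rng.uniform(0.2, 1.0, (20, s.n_levels)), axis=1)
            utilities[s.name] = mags if s.direction == "higher_better" else mags[:, ::-1]
        pw = d.PartWorthSet([f"r{i}" for i in range(20)], levels, utilities)
        best = {s.name: (s.levels[-1] if s.direction == "higher_better" else s.levels[0])
                for s in space}
        worst = {s.name: (s.levels[0] if s.direction == "higher_better" else s.levels[-1])
                 for s in space}
        res = d.share_of_preference(
            pw, [d.ProductProfile("good", best), d.ProductProfile("bad", worst)], space
        )
        assert res.overall["bad"] < res.overall["good"]

    def test_logit_approaches_first_choice_at_high_temperature(self, space, gbcm_partworths):
        products = list(d.DEFAULT_PRODUCTS.values())[:3]
        fc = d.share_of_preference(gbcm_partworths, products, space, method="first_choice")
        hot = d.PartWorthSet(
            gbcm_partworths.respondent_ids,
            {k: v.copy() for k, v in gbcm_partworths.levels.items()},
            {k: 1e4 * v for k, v in gbcm_partworths.utilities.items()},
        )
        logit = d.share_of_preference(hot, products, space)
        np.testing.assert_allclose(logit.per_respondent, fc.per_respondent, atol=1e-6)

    def test_rfc_requires_seed_and_positive_noise(self, space, gbcm_partworths):
        products = list(d.DEFAULT_PRODUCTS.values())[:2]
        with pytest.raises(ValueError):
            d.share_of_preference(gbcm_partworths, products, space, method="rfc")
        with pytest.raises(ValueError):
            d.share_of_preference(
                gbcm_partworths, products, space, method="rfc", rfc_noise=0, seed=1
            )

    def test_duplicate_names_and_empty_sets_rejected(self, space, gbcm_partworths):
        p = d.DEFAULT_PRODUCTS["Existing product A"]
        with pytest.raises(ValueError):
            d.share_of_preference(gbcm_partworths, [p, p], space)
        with pytest.raises(ValueError):
            d.share_of_preference(gbcm_partworths, [p], space)


class TestScenarios:
    def test_default_scenarios_run_and_normalise(self, space, gbcm_partworths):
        results = d.run_scenarios(gbcm_partworths, space)
        assert len(results) == 5
        for res in results:
            assert sum(res.overall.values()) == pytest.approx(100.0, abs=1e-9)
        assert len(results[0].products) == 3
        assert len(results[-1].products) == 6

    def test_unknown_product_reference_rejected(self, space, gbcm_partworths):
        with pytest.raises(KeyError):
            d.run_scenarios(gbcm_partworths, space, scenarios={"s": ["nope", "also nope"]})
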
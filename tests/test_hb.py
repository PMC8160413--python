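import math

import numpy as np
import pandas as pd
import pytest

import dcepref as d
from dcepref.coding import encode_utilities
from dcepref.hb import prior_only_draws


def brute_force_loglik(beta, X, y):
    """Independent oracle: direct softmax probabilities, task by task."""
    total = 0.0
    for t in range(X.shape[0]):
        utils = [float(np.dot(X[t, a], beta)) for a in range(X.shape[1])]
        probs = [math.exp(u) for u in utils]
        total += math.log(probs[y[t]] / sum(probs))
    return total


class TestLoglik:
    def test_indifferent_respondent_on_paired_tasks(self):
        X = np.zeros((15, 2, 4))
        y = np.zeros(15, dtype=int)
        assert d.mnl_loglik(np.zeros(4), X, y) == pytest.approx(15 * math.log(0.5))

    def test_single_task_closed_form(self):
        # utilities (ln 3, 0), first alternative chosen -> ln(3/4)
        X = np.array([[[1.0], [0.0]]])
        beta = np.array([math.log(3.0)])
        assert d.mnl_loglik(beta, X, [0]) == pytest.approx(math.log(0.75))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 4))
        A = int(rng.integers(2, 4))
        p = int(rng.integers(1, 6))
        X = rng.normal(size=(T, A, p))
        y = rng.integers(0, A, size=T)
        beta = rng.normal(size=p)
        assert d.mnl_loglik(beta, X, y) == pytest.approx(
            brute_force_loglik(beta, X, y), rel=1e-12
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            d.mnl_loglik(np.zeros(2), np.zeros((3, 2, 2)), [0, 1])

    def test_overflow_safe_for_huge_utilities(self):
        X = np.array([[[1.0], [0.0]]])
        val = d.mnl_loglik(np.array([2000.0]), X, [0])
        assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-9)


class TestMcmcConfig:
    def test_burn_in_defaults_to_half(self):
        assert d.McmcConfig(n_iterations=50_000).burn_in == 25_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_iterations=0),
            dict(n_iterations=100, n_burn_in=100),
            dict(thinning=0),
            dict(proposal_step=-1.0),
            dict(prior_mean_precision=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            d.McmcConfig(**kwargs)


@pytest.fixture(scope="module")
def small_fit():
    """Small heterogeneous panel with a short chain, for structural checks."""
    spec = d.default_population_spec(n_respondents=20, seed=5)
    truth = d.sample_population(spec)
    designs = d.personalized_designs(list(spec.attribute_space), 20, base_seed=5)
    resp = d.simulate_choices(truth, designs, scale=1.0, seed=6)
    model = d.HierarchicalBayesMNL(n_iterations=2_000, random_state=3)
    model.fit(resp, list(spec.attribute_space))
    return spec, truth, resp, model


class TestFit:
    def test_draw_count_matches_config(self, small_fit):
        _, _, _, model = small_fit
        assert model.draws_.n_draws == (2_000 - 1_000) // 10

    def test_sigma_draws_symmetric_positive_definite(self, small_fit):
        _, _, _, model = small_fit
        for S in model.draws_.sigma[::20]:
            np.testing.assert_allclose(S, S.T, atol=1e-10)
            assert np.linalg.eigvalsh(S).min() > 0

    def test_partworths_zero_centered_exactly(self, small_fit):
        _, _, _, model = small_fit
        for u in model.partworths_.utilities.values():
            np.testing.assert_allclose(u.sum(axis=1), 0.0, atol=1e-9)

    def test_seeded_determinism(self, small_fit):
        spec, _, resp, model = small_fit
        again = d.HierarchicalBayesMNL(n_iterations=2_000, random_state=3)
        again.fit(resp, list(spec.attribute_space))
        np.testing.assert_array_equal(model.draws_.alpha, again.draws_.alpha)
        np.testing.assert_array_equal(model.draws_.beta, again.draws_.beta)

    def test_acceptance_rate_in_working_band(self, small_fit):
        _, _, _, model = small_fit
        assert 0.1 < model.acceptance_rate_ < 0.7

    def test_empty_responses_rejected(self, space):
        resp = d.ResponseSet(
            data=pd.DataFrame(
                {
                    "respondent_id": ["r1", "r1"],
                    "task_id": [0, 0],
                    "alternative_id": [0, 1],
                    "chosen": [1, 0],
                    "sensitivity": [80.0, 85.0],
                }
            )
        )
        model = d.HierarchicalBayesMNL(n_iterations=10, min_completed_tasks=5)
        with pytest.raises(ValueError):
            model.fit(resp, space)

    def test_prior_only_alpha_centered_at_zero(self):
        draws = prior_only_draws(
            5, 3, d.McmcConfig(n_iterations=4_000, thinning=1, seed=0)
        )
        mean = draws.alpha.mean(axis=0)
        # prior sd per component is 1/sqrt(0.01) = 10; MC error is large but
        # the posterior must be centered at the prior mean of zero
        assert np.all(np.abs(mean) < 3.0)

    def test_monotone_respondent_recovers_monotone_partworths(self):
        # respondents who always pick higher sensitivity in a
        # sensitivity-only design
        attr = d.AttributeSpec("sensitivity", (80.0, 85.0, 90.0, 95.0), "higher_better")
        rows = []
        rng = np.random.default_rng(2)
        for r in range(8):
            des = d.generate_design([attr], n_tasks=12, n_alts=2, seed=100 + r)
            for task in des.tasks:
                l0 = task.alternatives[0]["sensitivity"]
                l1 = task.alternatives[1]["sensitivity"]
                choice = 0 if l0 > l1 else 1
                for a, lev in enumerate((l0, l1)):
                    rows.append(
                        {
                            "respondent_id": f"r{r}",
                            "task_id": task.task_id,
                            "alternative_id": a,
                            "chosen": int(a == choice),
                            "sensitivity": attr.levels[lev],
                        }
                    )
        resp = d.ResponseSet(data=pd.DataFrame(rows))
        model = d.HierarchicalBayesMNL(n_iterations=4_000, random_state=1)
        model.fit(resp, [attr])
        pop = model.population_partworths_["sensitivity"]
        assert np.all(np.diff(pop) > 0)

    def test_shrinkage_with_tight_covariance_prior(self, small_fit):
        spec, _, resp, loose_model = small_fit
        tight = d.HierarchicalBayesMNL(
            n_iterations=2_000,
            prior_scale=1e-4,
            prior_df=200,
            random_state=3,
        )
        tight.fit(resp, list(spec.attribute_space))
        var_loose = loose_model.draws_.posterior_mean_beta().var(axis=0).mean()
        var_tight = tight.draws_.posterior_mean_beta().var(axis=0).mean()
        assert var_tight < var_loose

    def test_recovery_error_shrinks_with_more_respondents(self):
        errs = []
        for n in (20, 120):
            spec = d.default_population_spec(n_respondents=n, seed=21)
            truth = d.sample_population(spec)
            designs = d.personalized_designs(list(spec.attribute_space), n, base_seed=21)
            resp = d.simulate_choices(truth, designs, scale=1.0, seed=22)
            model = d.HierarchicalBayesMNL(n_iterations=4_000, random_state=8)
            model.fit(resp, list(spec.attribute_space))
            true_alpha = encode_utilities(
                list(spec.attribute_space), truth.partworths.utilities
            ).mean(axis=0)
            errs.append(
                float(np.sqrt(np.mean((model.draws_.posterior_mean_alpha() - true_alpha) ** 2)))
            )
        assert errs[1] < errs[0]


class TestExtractPartworths:
    def test_respondent_level_utilities_track_truth(self, recovery_fit, recovery_truth):
        true_beta = encode_utilities(
            list(recovery_truth.spec.attribute_space),
            recovery_truth.partworths.utilities,
        )
        est = recovery_fit.draws_.posterior_mean_beta()
        rs = [np.corrcoef(est[i], true_beta[i])[0, 1] for i in range(len(true_beta))]
        assert np.mean(rs) >= 0.8

    def test_indifferent_population_yields_near_zero_utilities(self):
        # two-level attribute, every respondent flips a fair coin
        attr = d.AttributeSpec("x", (0.0, 1.0))
        rng = np.random.default_rng(0)
        rows = []
        for r in range(30):
            for t in range(10):
                choice = int(rng.integers(2))
                for a in range(2):
                    rows.append(
                        {
                            "respondent_id": f"r{r}",
                            "task_id": t,
                            "alternative_id": a,
                            "chosen": int(a == choice),
                            "x": float(a),
                        }
                    )
        resp = d.ResponseSet(data=pd.DataFrame(rows))
        model = d.HierarchicalBayesMNL(n_iterations=4_000, random_state=4)
        model.fit(resp, [attr])
        pop = model.population_partworths_["x"]
        assert np.all(np.abs(pop) < 0.25)
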
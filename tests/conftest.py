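import numpy as np
import pytest

import dcepref as d


@pytest.fixture(scope="session")
def space():
    return d.build_default_attribute_space()


@pytest.fixture(scope="session")
def default_design(space):
    return d.generate_design(space, n_tasks=15, n_alts=2, seed=1)


@pytest.fixture(scope="session")
def recovery_truth():
    """n=200 respondents from the calibrated population (known ground truth)."""
    spec = d.default_population_spec(n_respondents=200, seed=11)
    return d.sample_population(spec)


@pytest.fixture(scope="session")
def recovery_responses(recovery_truth):
    spec = recovery_truth.spec
    designs = d.personalized_designs(
        list(spec.attribute_space), spec.n_respondents, n_tasks=15, base_seed=11
    )
    return d.simulate_choices(recovery_truth, designs, scale=1.0, seed=12)


@pytest.fixture(scope="session")
def recovery_fit(recovery_responses, recovery_truth):
    """Full-scale scaled-down MCMC fit shared by the recovery checks."""
    model = d.HierarchicalBayesMNL(n_iterations=20_000, random_state=7)
    model.fit(recovery_responses, list(recovery_truth.spec.attribute_space))
    return model


def random_partworths(rng, n_respondents=10, attrs=("a", "b", "c", "d", "e"), n_levels=4):
    levels = {name: np.arange(1.0, n_levels + 1) for name in attrs}
    utilities = {
        name: rng.normal(size=(n_respondents, n_levels)) for name in attrs
    }
    return d.PartWorthSet(
        respondent_ids=[f"r{i}" for i in range(n_respondents)],
        levels=levels,
        utilities=utilities,
    )
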
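"""Shared fixtures: one synthetic benchmark bundle plus expensive derived
artifacts (trained samples, ML-optimized test trees, site rates), built once
per session and reused across the unit and acceptance suites."""

import warnings

import numpy as np
import pytest

from sitelasso import evaluation, lasso, likelihood, trees
from sitelasso.simulate import make_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """15-taxon, 2000-site WAG+G4 (alpha 0.93) benchmark bundle."""
    return make_benchmark(seed=42)


@pytest.fixture(scope="session")
def trained(benchmark):
    """Factory returning (LassoSample, TrainingSet) for a training seed,
    memoized so criteria that sweep seeds share work."""
    cache = {}

    def get(seed, eta=200, zeta=0.05):
        key = (seed, eta, zeta)
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[key] = lasso.train_site_sampler(
                    benchmark.alignment, benchmark.model, eta, zeta, rng_seed=seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def test_trees_opt(benchmark):
    """50 random test trees with branch lengths ML-optimized on the full MSA."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluation.generate_test_trees(
            benchmark.alignment, benchmark.model, 50, rng_seed=2)


@pytest.fixture(scope="session")
def benchmark_rates(benchmark):
    """Empirical-Bayes site rates on a parsimony tree with ML branch lengths."""
    ptree = trees.parsimony_stepwise_tree(benchmark.alignment, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ptree = likelihood.optimize_branch_lengths(ptree, benchmark.alignment,
                                                   benchmark.model)
    return likelihood.site_rates_empirical_bayes(ptree, benchmark.alignment,
                                                 benchmark.model)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
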
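"""Accuracy metrics for site-sample approximations and naive baselines.

The evaluation protocol scores a trained sample on held-out random trees:
exact log-likelihoods are computed from the full alignment (optionally after
ML branch-length optimization of each test tree on the full data, which is
how realistic test trees are produced), approximate ones from the sample, and
the report collects the squared Pearson correlation, Spearman rank
correlation and the percentage error |approx - exact| / |exact| * 100.

Two naive baselines put the Lasso selection in context: a uniform random site
sample and the sites with the highest empirical-Bayes evolutionary rate, both
with uniform inflation weights m/tau so that the weighted sum is on the scale
of the full log-likelihood (for the random sample it is an unbiased
estimator of it).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import ValidationError
from .lasso import LassoSample, approximate_log_likelihood, identity_sample
from .likelihood import SiteRates, optimize_branch_lengths, total_log_likelihood
from .trees import random_tree


@dataclass
class AccuracyReport:
    r_squared: float
    spearman_rho: float
    mean_pct_error: float
    sd_pct_error: float
    n_trees: int

    def to_dict(self):
        return asdict(self)


def generate_test_trees(aln, model, n_trees: int, rng_seed, bl_mean: float = 0.1,
                        optimize_bl: bool = True):
    """Random test-tree set; with ``optimize_bl`` each tree's branch lengths
    are ML-estimated on the full alignment."""
    ss = np.random.SeedSequence(rng_seed)
    out = []
    for child in ss.spawn(n_trees):
        tree = random_tree(aln.taxa, np.random.default_rng(child), bl_mean)
        if optimize_bl:
            tree = optimize_branch_lengths(tree, aln, model)
        out.append(tree)
    return out


def evaluate_sample(sample: LassoSample, test_trees, aln, model,
                    optimize_bl: bool = False) -> AccuracyReport:
    """Score a site sample against exact log-likelihoods on a tree set."""
    if len(test_trees) < 2:
        raise ValidationError("need at least 2 test trees")
    exact = np.empty(len(test_trees))
    approx = np.empty(len(test_trees))
    for i, tree in enumerate(test_trees):
        if optimize_bl:
            tree = optimize_branch_lengths(tree, aln, model)
        exact[i] = total_log_likelihood(tree, aln, model)
        approx[i] = approximate_log_likelihood((tree, aln, model), sample)
    return accuracy_report(exact, approx)


def accuracy_report(exact: np.ndarray, approx: np.ndarray) -> AccuracyReport:
    exact = np.asarray(exact, float)
    approx = np.asarray(approx, float)
    if np.allclose(approx, approx[0]) or np.allclose(exact, exact[0]):
        r2 = 0.0 if not np.allclose(approx - exact, approx[0] - exact[0]) else 1.0
        rho = r2
    else:
        r2 = float(np.corrcoef(exact, approx)[0, 1] ** 2)
        rho = float(stats.spearmanr(exact, approx).statistic)
    pct = np.abs(approx - exact) / np.abs(exact) * 100.0
    return AccuracyReport(r2, rho, float(pct.mean()),
                          float(pct.std(ddof=1)) if len(pct) > 1 else 0.0, len(exact))


def random_site_sample(m: int, zeta: float, rng_seed) -> LassoSample:
    """floor(zeta*m) sites uniform without replacement, weights m/tau."""
    if not (0 < zeta <= 1):
        raise ValidationError("zeta must be in (0, 1]")
    if zeta == 1.0:
        return identity_sample(m)
    tau = max(1, int(np.floor(zeta * m)))
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    sites0 = np.sort(rng.choice(m, size=tau, replace=False))
    return LassoSample(sites0 + 1, np.full(tau, m / tau), 0.0, 0.0, zeta, tau / m)


def rate_based_sample(rates: SiteRates, m: int, zeta: float) -> LassoSample:
    """The floor(zeta*m) fastest sites by standardized rate, weights m/tau.

    Ties in rate are broken by site index (lower index first).
    """
    if not (0 < zeta <= 1):
        raise ValidationError("zeta must be in (0, 1]")
    if len(rates.standardized) != m:
        raise ValidationError("rate vector length does not match m")
    if zeta == 1.0:
        return identity_sample(m)
    tau = max(1, int(np.floor(zeta * m)))
    order = np.argsort(-rates.standardized, kind="stable")
    sites0 = np.sort(order[:tau])
    return LassoSample(sites0 + 1, np.full(tau, m / tau), 0.0, 0.0, zeta, tau / m)


def write_per_tree_table(path, exact, approx) -> None:
    """TSV companion to an AccuracyReport: tree_id, exact_ll, approx_ll, pct_error."""
    with open(path, "w") as fh:
        fh.write("tree_id\texact_ll\tapprox_ll\tpct_error\n")
        for i, (e, a) in enumerate(zip(exact, approx), start=1):
            fh.write(f"{i}\t{e:.6f}\t{a:.6f}\t{abs(a - e) / abs(e) * 100:.6f}\n")
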
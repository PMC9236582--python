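"""Partitioned-model training: one Lasso over the concatenation vs. one per
partition.

Both variants share the same eta training trees (one topology/branch-length
set per training index) and compute each site's log-likelihood under its own
partition's model; they differ only in whether a single Lasso is fitted over
all m sites or an independent Lasso per partition (each at the same target
fraction zeta). Branch lengths are shared across partitions; only the rate
model (gamma shape, frequencies) is unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .lasso import (LassoSample, LassoSiteSampler, TrainingSet, training_trees)
from .likelihood import (estimate_alpha, site_log_likelihoods,
                         weighted_log_likelihood)
from .models import build_model
from .msa_io import Alignment, PartitionScheme, undetermined_mask
from .trees import parsimony_stepwise_tree


@dataclass
class PartitionedSample:
    """Per-partition Lasso samples; the approximation for a tree is the sum of
    the partitions' approximate log-likelihoods."""

    scheme: PartitionScheme
    models: list
    samples: list  # one LassoSample per partition, sites 1-based WITHIN the partition

    def approximate(self, tree, aln, use_intercept: bool = True) -> float:
        total = 0.0
        for p, sample in enumerate(self.samples):
            idx = self.scheme.site_indices(p)
            sub = aln.subset_sites(idx)
            total += weighted_log_likelihood(
                tree, sub, self.models[p], sample.sites0, sample.weights,
                intercept=sample.intercept if use_intercept else 0.0)
        return total


def fit_partition_models(aln: Alignment, scheme: PartitionScheme, rng_seed=0,
                         default_model: str = "WAG+G4", n_categories: int = 4):
    """Fit one substitution model per partition.

    The gamma shape of each partition is ML-estimated on a parsimony stepwise
    tree (with co-optimized branch lengths) built from that partition's sites.
    The partition's model token (or ``default_model``) chooses the matrix.
    """
    models = []
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(scheme.partitions))
    for p, part in enumerate(scheme.partitions):
        idx = scheme.site_indices(p)
        sub = aln.subset_sites(idx)
        det = ~undetermined_mask(sub)
        if det.sum() < 2:
            raise ValidationError(f"partition {part.name!r} has fewer than 2 determined sites")
        spec = part.model or default_model
        model = build_model(spec, alpha=1.0, n_categories=n_categories, alignment=sub)
        tree = parsimony_stepwise_tree(sub, np.random.default_rng(children[p]))
        alpha = estimate_alpha(tree, sub, model)
        models.append(model.with_alpha(alpha))
    return models


def _partitioned_design(aln, scheme, models, eta, bl_mean, rng_seed):
    """Shared training trees and the (eta, m) design with per-partition models."""
    trees = training_trees(aln.taxa, eta, bl_mean, rng_seed)
    X = np.empty((eta, aln.n_sites))
    for p in range(len(scheme.partitions)):
        idx = scheme.site_indices(p)
        sub = aln.subset_sites(idx)
        for j, tree in enumerate(trees):
            X[j, idx] = site_log_likelihoods(tree, sub, models[p]).values
    return trees, X


def train_concatenated(aln, scheme, eta: int, zeta: float = 0.05, rng_seed=0,
                       bl_mean: float = 0.1, models=None):
    """Single Lasso over all sites, each site's log-likelihood computed under
    its partition's model.

    Returns (LassoSample over global 1-based sites, models, TrainingSet).
    """
    if models is None:
        models = fit_partition_models(aln, scheme, rng_seed)
    trees, X = _partitioned_design(aln, scheme, models, eta, bl_mean, rng_seed)
    y = X.sum(axis=1)
    sampler = LassoSiteSampler(zeta=zeta).fit(X, y)
    sample = sampler.to_sample(eta=eta, seed=rng_seed, model_id="partitioned")
    return sample, models, TrainingSet(trees, X, y, seed=rng_seed, model_id="partitioned")


def train_per_partition(aln, scheme, eta: int, zeta: float = 0.05, rng_seed=0,
                        bl_mean: float = 0.1, models=None) -> PartitionedSample:
    """Independent Lasso per partition (same training trees reused), each at
    target fraction zeta; sample sites are 1-based within their partition."""
    if models is None:
        models = fit_partition_models(aln, scheme, rng_seed)
    trees, X = _partitioned_design(aln, scheme, models, eta, bl_mean, rng_seed)
    samples = []
    for p in range(len(scheme.partitions)):
        idx = scheme.site_indices(p)
        Xp = X[:, idx]
        sampler = LassoSiteSampler(zeta=zeta).fit(Xp, Xp.sum(axis=1))
        samples.append(sampler.to_sample(eta=eta, seed=rng_seed,
                                         model_id=scheme.partitions[p].name))
    return PartitionedSample(scheme, models, samples)


def approximate_concatenated(tree, aln, scheme: PartitionScheme, models,
                             sample: LassoSample, use_intercept: bool = True) -> float:
    """Evaluate a concatenated-training sample: each selected site's
    log-likelihood is computed under its own partition's model."""
    pm = scheme.partition_map(aln.n_sites)
    total = sample.intercept if use_intercept else 0.0
    for p in range(len(scheme.partitions)):
        in_p = pm[sample.sites0] == p
        if not in_p.any():
            continue
        idx = scheme.site_indices(p)
        pos = {g: i for i, g in enumerate(idx)}
        local = np.array([pos[g] for g in sample.sites0[in_p]])
        sub = aln.subset_sites(idx)
        total += weighted_log_likelihood(tree, sub, models[p], local,
                                         sample.weights[in_p])
    return float(total)


def selected_fraction_per_partition(sample: LassoSample, scheme: PartitionScheme,
                                    n_sites: int) -> np.ndarray:
    """Fraction of each partition's sites present in a (global) sample."""
    pm = scheme.partition_map(n_sites)
    out = np.zeros(len(scheme.partitions))
    for p in range(len(scheme.partitions)):
        in_p = pm[sample.sites0] == p
        out[p] = in_p.sum() / (pm == p).sum()
    return out
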
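"""Greedy SPR hill-climbing: standard, Lasso-approximated, and two-phase.

Each iteration evaluates the radius-limited SPR neighbors of the current tree
lazily (no branch-length optimization; the regraft rule keeps total tree
length unchanged) in a deterministic order, and accepts the first neighbor
whose score exceeds the current one by more than epsilon — the scan then
restarts from the accepted tree. When no neighbor qualifies lazily, full
branch-length optimization is applied to the top_k best lazily-scored
neighbors, accepting the first optimized candidate that qualifies. The search
terminates when neither step finds an acceptable neighbor.

The two-phase variant first runs the search entirely under the Lasso
approximation (including its candidate optimization step, done on the sampled
sites with the Lasso weights), then restarts from that local optimum with
lazy scans still under the approximation but candidate optimization and
acceptance under the full alignment. Final log-likelihoods of every strategy
are reported on the full alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lasso import LassoSample
from .likelihood import (_prepare, optimize_branch_lengths,
                         total_log_likelihood)
from .trees import PhyloTree, spr_neighbors

DEFAULT_RADIUS = 5
DEFAULT_EPSILON = 0.1
DEFAULT_TOP_K = 50


@dataclass
class SearchTrace:
    """Accepted-move log and evaluation counters of one search run."""

    accepted: list = field(default_factory=list)  # (move_index, ll, mode)
    n_moves: int = 0
    n_full_evals: int = 0
    n_approx_evals: int = 0
    start_ll: float | None = None
    final_ll: float | None = None
    phase1_moves: int | None = None

    def record(self, move_index: int, ll: float, mode: str):
        self.accepted.append((move_index, ll, mode))
        self.n_moves += 1


class FullEvaluator:
    """Exact log-likelihood on the full alignment."""

    mode = "full"

    def __init__(self, aln, model, trace: SearchTrace):
        self.aln = aln
        self.model = model
        self.trace = trace

    def score(self, tree) -> float:
        self.trace.n_full_evals += 1
        return total_log_likelihood(tree, self.aln, self.model)

    def optimize(self, tree):
        opt = optimize_branch_lengths(tree, self.aln, self.model)
        return opt, self.score(opt)


class LassoEvaluator:
    """Weighted approximation on the sampled sites.

    Holds a dedicated sub-alignment restricted to the sampled sites whose
    pattern weights are replaced by the per-site Lasso weights, so that both
    scoring and branch-length optimization maximize the weighted objective
    intercept + sum_k w_k LL_{i_k}(T).
    """

    mode = "lasso"

    def __init__(self, aln, model, sample: LassoSample, trace: SearchTrace):
        self.model = model
        self.sample = sample
        self.trace = trace
        self.sub = aln.subset_sites(sample.sites0)
        prep = _prepare(self.sub)
        merged = np.zeros(prep.pattern.n_patterns)
        np.add.at(merged, prep.pattern.site_to_pattern, sample.weights)
        prep.pattern.pattern_weights = merged

    def score(self, tree) -> float:
        self.trace.n_approx_evals += 1
        return self.sample.intercept + total_log_likelihood(tree, self.sub, self.model)

    def optimize(self, tree):
        opt = optimize_branch_lengths(tree, self.sub, self.model)
        return opt, self.score(opt)


def _make_evaluator(aln, model, evaluator, trace):
    if evaluator == "full" or evaluator is None:
        return FullEvaluator(aln, model, trace)
    if isinstance(evaluator, LassoSample):
        return LassoEvaluator(aln, model, evaluator, trace)
    raise ValueError(f"evaluator must be 'full' or a LassoSample, got {evaluator!r}")


def _climb(tree, ev, radius, epsilon, top_k, trace, accept_ev=None):
    """Greedy first-improvement SPR climb.

    ``ev`` scores the lazy scans; ``accept_ev`` (default: ``ev``) does the
    candidate branch-length optimization and owns the acceptance score. When
    they differ (two-phase refinement), lazy acceptance is disabled and every
    iteration goes through the optimize-top_k step.
    """
    two_objectives = accept_ev is not None
    if accept_ev is None:
        accept_ev = ev
    tree, cur = accept_ev.optimize(tree)
    if trace.start_ll is None:
        trace.start_ll = cur
    while True:
        neighbors = spr_neighbors(tree, radius)
        scores = np.empty(len(neighbors))
        accepted = False
        for i, (_move, nb) in enumerate(neighbors):
            scores[i] = ev.score(nb)
            if not two_objectives and scores[i] > cur + epsilon:
                tree, cur = nb, scores[i]
                trace.record(i, cur, accept_ev.mode)
                accepted = True
                break
        if accepted:
            continue
        order = sorted(range(len(neighbors)), key=lambda i: (-scores[i], i))[:top_k]
        for i in order:
            opt, ll = accept_ev.optimize(neighbors[i][1])
            if ll > cur + epsilon:
                tree, cur = opt, ll
                trace.record(i, cur, accept_ev.mode)
                accepted = True
                break
        if not accepted:
            break
    tree, cur = accept_ev.optimize(tree)
    return tree, cur


def greedy_spr_search(start: PhyloTree, aln, model, evaluator="full",
                      radius: int = DEFAULT_RADIUS, epsilon: float = DEFAULT_EPSILON,
                      top_k: int = DEFAULT_TOP_K):
    """Greedy SPR hill-climb under one evaluation mode.

    Returns (tree with fully optimized branch lengths under the evaluator's
    objective, SearchTrace). ``trace.final_ll`` is always the full-alignment
    log-likelihood of the returned tree.
    """
    trace = SearchTrace()
    ev = _make_evaluator(aln, model, evaluator, trace)
    tree, _cur = _climb(start, ev, radius, epsilon, top_k, trace)
    trace.final_ll = total_log_likelihood(tree, aln, model)
    return tree, trace


def two_phase_search(start: PhyloTree, aln, model, sample: LassoSample,
                     radius: int = DEFAULT_RADIUS, epsilon: float = DEFAULT_EPSILON,
                     top_k: int = DEFAULT_TOP_K):
    """Lasso-approximated climb to a local optimum, then full-data refinement.

    Phase 1 runs the greedy search entirely under the weighted site sample.
    Phase 2 restarts from its result: neighbors are still scored lazily with
    the approximation, but the top_k candidates are branch-length-optimized
    on the full alignment and acceptance compares full-alignment
    log-likelihoods. Returns (tree, trace) with ``final_ll`` on the full data.
    """
    trace = SearchTrace()
    lasso_ev = LassoEvaluator(aln, model, sample, trace)
    full_ev = FullEvaluator(aln, model, trace)
    tree, _ = _climb(start, lasso_ev, radius, epsilon, top_k, trace)
    trace.phase1_moves = trace.n_moves
    tree, cur = _climb(tree, lasso_ev, radius, epsilon, top_k, trace,
                       accept_ev=full_ev)
    trace.final_ll = cur
    return tree, trace
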
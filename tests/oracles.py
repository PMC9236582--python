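"""Independent oracles for the test suite.

These deliberately avoid the pruning code paths they check: site likelihoods
are computed by exhaustive summation over all ancestral state assignments,
and gamma category means by direct numerical quadrature.
"""

import itertools

import numpy as np
from scipy import integrate, stats

from sitelasso.msa_io import ambiguity_map, states_for


def brute_force_site_lls(tree, aln, model):
    """Per-site log-likelihood by enumerating every internal-node state
    assignment (leaf ambiguity summed analytically), averaged over gamma
    categories. Exponential in the number of internal nodes: tiny trees only."""
    gam = model.gamma_categories()
    states = states_for(aln.alphabet)
    amb = ambiguity_map(aln.alphabet)
    root, parent, children, post = tree.rooted_view(
        None if tree.n_leaves > 2 else tree.leaves[0])
    internals = [v for v in post if children[v]]
    row = {t: i for i, t in enumerate(aln.taxa)}
    S = len(states)
    pi = model.frequencies
    out = []
    for site in range(aln.n_sites):
        def leaf_states(v):
            return [states.index(s) for s in amb[aln.matrix[row[tree.names[v]], site]]]

        total = 0.0
        for c in range(gam.k):
            P = {v: model.transition_matrix(tree.adj[parent[v]][v], gam.rates[c])
                 for v in post if parent[v] is not None}
            cat_lik = 0.0
            for assign in itertools.product(range(S), repeat=len(internals)):
                st = dict(zip(internals, assign))
                if tree.is_leaf(root) and st[root] not in leaf_states(root):
                    continue
                pr = pi[st[root]]
                for v in post:
                    if parent[v] is None:
                        continue
                    if children[v]:
                        pr *= P[v][st[parent[v]], st[v]]
                    else:
                        pr *= sum(P[v][st[parent[v]], s] for s in leaf_states(v))
                cat_lik += pr
            total += cat_lik / gam.k
        out.append(np.log(total))
    return np.array(out)


def gamma_category_means_quadrature(alpha, k):
    """Mean rate of each equal-probability Gamma(alpha, alpha) slice by
    numerical integration of x f(x) over the quantile intervals."""
    dist = stats.gamma(a=alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], dist.ppf(np.arange(1, k) / k), [np.inf]])
    means = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        val, _err = integrate.quad(lambda x: x * dist.pdf(x), a, b, limit=200)
        means.append(val * k)  # each slice has probability 1/k
    return np.array(means)


def strong_signal_tree(taxa, seed, internal=0.25, terminal=0.08):
    """Random topology with uniformly long internal edges and short terminal
    ones — a regime in which the generating topology is clearly identifiable."""
    from sitelasso.trees import random_stepwise_topology

    tree = random_stepwise_topology(taxa, seed)
    for u, v in tree.edges():
        is_internal = not (tree.is_leaf(u) or tree.is_leaf(v))
        tree.set_length(u, v, internal if is_internal else terminal)
    return tree


def all_unrooted_topologies(taxa):
    """Exhaustive enumeration of unrooted binary topologies (small n only),
    by recursive edge insertion; returns PhyloTree objects with 0 lengths."""
    from sitelasso.trees import PhyloTree, _attach_leaf

    taxa = list(taxa)
    base = PhyloTree()
    hub = base.new_node()
    for name in taxa[:3]:
        leaf = base.new_node()
        base.names[leaf] = name
        base.add_edge(hub, leaf, 0.0)
    result = [base]
    for name in taxa[3:]:
        nxt = []
        for t in result:
            for u, v in t.edges():
                cand = t.copy()
                _attach_leaf(cand, name, u, v)
                nxt.append(cand)
        result = nxt
    return result
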
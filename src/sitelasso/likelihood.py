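"""Per-site phylogenetic log-likelihoods and branch-length optimization.

The engine implements Felsenstein pruning over compressed site patterns with
per-node scaling against underflow. Discrete-gamma rate heterogeneity is
integrated by averaging the per-category site likelihoods with equal weights.

Branch lengths are optimized coordinate-wise: a top-down sweep maintains, for
the edge currently being optimized, the conditional likelihood of the data
above the edge (given the state at its parent end) and below it (given the
state at its child end). Writing the transition matrix in the eigenbasis of
the reversible rate matrix reduces each trial branch length to an
O(patterns x categories x states) contraction, so the derivative-free Brent
search per edge is cheap. Because every single-edge optimization maximizes the
exact current-tree likelihood in that coordinate, the total log-likelihood is
non-decreasing across every update and across sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .msa_io import Alignment, ambiguity_map, compress_patterns, states_for
from .models import SubstitutionModel
from .trees import PhyloTree

BL_BOUNDS = (1e-8, 100.0)
ALPHA_BOUNDS = (0.02, 100.0)

_EINSUM_KW = dict(optimize=True)


@dataclass
class SiteLLVector:
    """Per-site log-likelihoods of one tree; their sum is the tree log-likelihood."""

    values: np.ndarray
    tree_id: str | None = None
    model_id: str | None = None

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self):
        return len(self.values)


@dataclass
class SiteRates:
    """Empirical-Bayes posterior-mean relative rates per site.

    ``standardized`` is the zero-mean, unit-sample-sd transform of ``raw``;
    it is all zeros (with ``degenerate=True``) when no rate variation exists.
    """

    raw: np.ndarray
    standardized: np.ndarray
    degenerate: bool = False


# ----------------------------------------------------------------------
# preparation and caching

class _Prepared:
    __slots__ = ("pattern", "tips", "row_of")

    def __init__(self, aln: Alignment):
        self.pattern = compress_patterns(aln)
        states = states_for(aln.alphabet)
        amb = ambiguity_map(aln.alphabet)
        lut = {ch: np.array([1.0 if s in compat else 0.0 for s in states])
               for ch, compat in amb.items()}
        pats = self.pattern.patterns
        self.tips = np.zeros((pats.shape[0], pats.shape[1], len(states)))
        for ch, vec in lut.items():
            mask = pats == ch
            if mask.any():
                self.tips[mask] = vec
        self.row_of = {}

    def tip(self, name):
        return self.tips[self.row_of[name]]


def _prepare(aln: Alignment) -> _Prepared:
    prep = aln._cache.get("likelihood")
    if prep is None:
        prep = _Prepared(aln)
        aln._cache["likelihood"] = prep
    prep.row_of = {t: i for i, t in enumerate(aln.taxa)}
    return prep


def _check_taxa(tree: PhyloTree, aln: Alignment) -> None:
    if sorted(tree.names.values()) != sorted(aln.taxa):
        raise ValidationError("tree leaf labels do not match alignment taxa")


def _contract(D: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Move a conditional likelihood across an edge: sum_j P[c,i,j] D[.,c,j]."""
    if D.ndim == 2:  # tip vector, shared across categories
        return np.einsum("pj,cij->pci", D, P, **_EINSUM_KW)
    return np.einsum("pcj,cij->pci", D, P, **_EINSUM_KW)


def _rescale(arr: np.ndarray, logs: np.ndarray) -> np.ndarray:
    mx = arr.max(axis=(1, 2))
    mx = np.where(mx > 0, mx, 1.0)
    logs += np.log(mx)
    return arr / mx[:, None, None]


def _postorder_partials(tree, prep, model, rates, root=None):
    """Lower conditional likelihoods D[v] for all nodes of a rooted view.

    Returns (root, parent, children, postorder, D, Dlog) where D[v] has shape
    (p, k, S) for internal nodes and (p, S) for tips, and Dlog[v] accumulates
    the per-pattern log scalers of the subtree below v.
    """
    if root is None and tree.n_leaves == 2:
        root = tree.leaves[0]
    root, parent, children, post = tree.rooted_view(root)
    p = prep.pattern.n_patterns
    D, Dlog = {}, {}
    for v in post:
        if tree.is_leaf(v) and v != root:
            D[v] = prep.tip(tree.names[v])
            Dlog[v] = np.zeros(p)
            continue
        acc = None
        logs = np.zeros(p)
        for w in children[v]:
            P = model.transition_stack(tree.adj[v][w], rates)
            M = _contract(D[w], P)
            logs += Dlog[w]
            acc = M if acc is None else acc * M
        if tree.is_leaf(v):  # two-taxon case rooted at a leaf
            acc = acc * prep.tip(tree.names[v])[:, None, :]
        D[v] = _rescale(acc, logs)
        Dlog[v] = logs
    return root, parent, children, post, D, Dlog


def _root_site_lls(model, rates, D_root, Dlog_root):
    """Per-pattern (ll, per-category likelihood) at the virtual root."""
    pi = model.frequencies
    Lpc = np.einsum("pcs,s->pc", D_root, pi, **_EINSUM_KW)
    lik = Lpc.mean(axis=1)
    ll = np.log(np.maximum(lik, 1e-300)) + Dlog_root
    return ll, Lpc


def site_log_likelihoods(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                         tree_id: str | None = None, root: int | None = None) -> SiteLLVector:
    """Per-site log-likelihoods LL_i(T) by pruning.

    Pattern compression is internal; the returned vector is indexed by the
    original sites of the alignment. ``root`` places the virtual root at a
    chosen internal node; for a reversible model the result is invariant to
    that placement (pulley principle), which is a tested contract.
    """
    _check_taxa(tree, aln)
    prep = _prepare(aln)
    rates = model.gamma_categories().rates
    root, *_rest, D, Dlog = _postorder_partials(tree, prep, model, rates, root=root)
    ll_pat, _ = _root_site_lls(model, rates, D[root], Dlog[root])
    values = ll_pat[prep.pattern.site_to_pattern]
    return SiteLLVector(values, tree_id=tree_id, model_id=model.name)


def total_log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel) -> float:
    """Tree log-likelihood LL(T) = sum of per-site log-likelihoods."""
    _check_taxa(tree, aln)
    prep = _prepare(aln)
    rates = model.gamma_categories().rates
    root, *_rest, D, Dlog = _postorder_partials(tree, prep, model, rates)
    ll_pat, _ = _root_site_lls(model, rates, D[root], Dlog[root])
    return float(np.dot(ll_pat, prep.pattern.pattern_weights))


def weighted_log_likelihood(tree, aln, model, sites, weights, intercept: float = 0.0) -> float:
    """Weighted approximation intercept + sum_i w_i LL_i(T) over selected sites.

    ``sites`` are 0-based indices into ``aln``; per-site likelihoods are
    computed only at those sites.
    """
    sites = np.asarray(sites, dtype=int)
    if sites.size and (sites.min() < 0 or sites.max() >= aln.n_sites):
        raise ValidationError("site index out of range")
    sub = _site_subset(aln, sites)
    lls = site_log_likelihoods(tree, sub, model).values
    return float(intercept + np.dot(np.asarray(weights, float), lls))


def _site_subset(aln: Alignment, sites: np.ndarray) -> Alignment:
    """Cached restriction of an alignment to a fixed set of sites."""
    key = ("subset", sites.tobytes())
    sub = aln._cache.get(key)
    if sub is None:
        sub = aln.subset_sites(sites)
        aln._cache[key] = sub
    return sub


# ----------------------------------------------------------------------
# branch-length optimization

class _EdgeObjective:
    """Log-likelihood of the tree as a function of one branch length.

    Built from the conditional likelihoods above (U, at the parent state) and
    below (D, at the child state) an edge; in the eigenbasis of Q, the
    per-pattern likelihood is sum_{c,e} g[p,c,e] exp(lambda_e t r_c) / k.
    """

    def __init__(self, model, rates, U, D, const_logs, weights):
        evals, right, left = model._eigen
        self.evals = evals
        self.rates = np.asarray(rates)
        a = np.einsum("pci,ie->pce", U, right, **_EINSUM_KW)
        if D.ndim == 2:
            b = np.einsum("ej,pj->pe", left, D, **_EINSUM_KW)[:, None, :]
        else:
            b = np.einsum("ej,pcj->pce", left, D, **_EINSUM_KW)
        self.g = a * b
        self.const_logs = const_logs
        self.weights = weights
        self.k = len(self.rates)

    def __call__(self, t: float) -> float:
        expo = np.exp(self.evals[None, :] * (t * self.rates)[:, None])  # (k, S)
        lik = np.einsum("pce,ce->p", self.g, expo, **_EINSUM_KW) / self.k
        ll = np.log(np.maximum(lik, 1e-300)) + self.const_logs
        return float(np.dot(ll, self.weights))

    def maximize(self, xatol: float = 1e-6):
        # search log(t): the optimum of a typical branch sits mid-interval
        # there, whereas on the linear scale the bounded search can stall in
        # the numerically flat saturation tail
        lo, hi = np.log(BL_BOUNDS)
        res = minimize_scalar(lambda u: -self(float(np.exp(u))), bounds=(lo, hi),
                              method="bounded", options={"xatol": xatol})
        t = float(np.exp(res.x))
        return t, float(-res.fun)


def optimize_branch_lengths(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                            tol: float = 0.01, max_sweeps: int = 32,
                            xatol: float = 1e-6) -> PhyloTree:
    """Coordinate-wise ML branch-length optimization (bounded Brent per edge).

    Sweeps the edges in a fixed top-down traversal until a full sweep improves
    the log-likelihood by less than ``tol`` (default 0.01) or ``max_sweeps``
    sweeps have run; the likelihood never decreases. On non-convergence the
    best tree found is returned with ``bl_converged=False`` and a warning.
    """
    _check_taxa(tree, aln)
    tree = tree.copy()
    prep = _prepare(aln)
    rates = model.gamma_categories().rates
    weights = prep.pattern.pattern_weights
    pi = model.frequencies
    p = prep.pattern.n_patterns
    k = len(rates)

    prev_ll = None
    converged = False
    for _sweep in range(max_sweeps):
        root, parent, children, post, D, Dlog = _postorder_partials(tree, prep, model, rates)
        # upper partials, maintained during a preorder walk
        U0 = np.broadcast_to(pi, (p, k, len(pi))).copy()
        if tree.is_leaf(root):  # two-taxon case: the root leaf's data joins U
            U0 = U0 * prep.tip(tree.names[root])[:, None, :]
        stack = [(root, U0, np.zeros(p))]
        last_ll = None
        while stack:
            u, U_u, Ulog_u = stack.pop()
            kids = children[u]
            M = {w: _contract(D[w], model.transition_stack(tree.adj[u][w], rates))
                 for w in kids}
            for w in kids:
                U_w = U_u.copy()
                Ulog_w = Ulog_u.copy()
                for s in kids:
                    if s != w:
                        U_w = U_w * M[s]
                        Ulog_w = Ulog_w + Dlog[s]
                U_w = _rescale(U_w, Ulog_w)
                obj = _EdgeObjective(model, rates, U_w, D[w], Ulog_w + Dlog[w], weights)
                t_new, ll_new = obj.maximize(xatol)
                cur = obj(tree.adj[u][w])
                if ll_new >= cur:  # guard against boundary/precision quirks
                    tree.set_length(u, w, t_new)
                    last_ll = ll_new
                else:
                    last_ll = cur
                M[w] = _contract(D[w], model.transition_stack(tree.adj[u][w], rates))
                if not tree.is_leaf(w):
                    P = model.transition_stack(tree.adj[u][w], rates)
                    U_down = np.einsum("pci,cij->pcj", U_w, P, **_EINSUM_KW)
                    logs = Ulog_w.copy()
                    U_down = _rescale(U_down, logs)
                    stack.append((w, U_down, logs))
        # last_ll is the exact current-tree LL: at the final edge update all
        # partials reflect the current branch lengths
        if prev_ll is not None and last_ll - prev_ll < tol:
            converged = True
            prev_ll = last_ll
            break
        prev_ll = last_ll
    if not converged:
        warnings.warn("branch-length optimization did not converge "
                      f"(last LL {prev_ll:.4f})", stacklevel=2)
    tree.bl_converged = converged
    return tree


# ----------------------------------------------------------------------
# model-parameter estimation

def estimate_alpha(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                   optimize_lengths: bool = True, rounds: int = 2,
                   rel_tol: float = 1e-3) -> float:
    """ML estimate of the gamma shape alpha on a fixed topology.

    Bounded scalar search for alpha on a log scale over [0.02, 100],
    alternated with branch-length optimization (``rounds`` times) so the two
    sets of parameters are co-adapted.
    """
    if model.n_categories < 1:
        raise ValidationError("model must carry gamma categories")
    cur = model if model.alpha is not None else model.with_alpha(1.0)
    work_tree = tree
    lo, hi = np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])
    for _ in range(max(1, rounds)):
        if optimize_lengths:
            work_tree = optimize_branch_lengths(work_tree, aln, cur)
        res = minimize_scalar(
            lambda u: -total_log_likelihood(work_tree, aln, cur.with_alpha(float(np.exp(u)))),
            bounds=(lo, hi), method="bounded", options={"xatol": rel_tol},
        )
        cur = cur.with_alpha(float(np.exp(res.x)))
    return cur.alpha


def estimate_gtr(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                 rounds: int = 2, rel_tol: float = 1e-3) -> SubstitutionModel:
    """Coordinate-wise ML fit of the six GTR exchangeabilities on a fixed tree.

    Each exchangeability (relative to the G<->T rate fixed at 1) is optimized
    by bounded Brent on a log scale; alpha is re-fit between rounds if the
    model carries gamma categories.
    """
    from .models import SubstitutionModel as SM

    if model.alphabet != "dna":
        raise ValidationError("GTR fitting applies to DNA models")
    iu, ju = np.triu_indices(4, 1)
    work = model

    def rebuild(vals):
        S = np.zeros((4, 4))
        S[iu, ju] = vals
        S = S + S.T
        return SM("GTR", "dna", S, work.frequencies, alpha=work.alpha,
                  n_categories=work.n_categories)

    for _ in range(max(1, rounds)):
        vals = work.exchangeabilities[iu, ju].copy()
        vals = vals / vals[-1]  # identifiability: fix the last rate at 1
        for idx in range(5):
            def obj(u, idx=idx):
                v = vals.copy()
                v[idx] = np.exp(u)
                return -total_log_likelihood(tree, aln, rebuild(v))
            res = minimize_scalar(obj, bounds=(np.log(1e-3), np.log(1e3)),
                                  method="bounded", options={"xatol": rel_tol})
            vals[idx] = float(np.exp(res.x))
        work = rebuild(vals)
        if work.alpha is not None:
            work = work.with_alpha(estimate_alpha(tree, aln, work, optimize_lengths=False, rounds=1))
    return work


# ----------------------------------------------------------------------
# empirical-Bayes site rates

def site_rates_empirical_bayes(tree: PhyloTree, aln: Alignment,
                               model: SubstitutionModel) -> SiteRates:
    """Posterior-mean relative rate per site under the discrete-gamma model.

    r_hat_i = sum_c r_c P(site i | r_c) / sum_c P(site i | r_c) with the k
    equal-probability categories; the per-site scalers cancel in the ratio.
    The standardized copy uses the sample standard deviation.
    """
    _check_taxa(tree, aln)
    gam = model.gamma_categories()
    m = aln.n_sites
    if gam.k == 1:
        return SiteRates(np.ones(m), np.zeros(m), degenerate=True)
    prep = _prepare(aln)
    root, *_rest, D, Dlog = _postorder_partials(tree, prep, model, gam.rates)
    _, Lpc = _root_site_lls(model, gam.rates, D[root], Dlog[root])
    denom = Lpc.sum(axis=1)
    raw_pat = (Lpc @ gam.rates) / np.maximum(denom, 1e-300)
    raw = raw_pat[prep.pattern.site_to_pattern]
    sd = raw.std(ddof=1) if m > 1 else 0.0
    if sd <= 0:
        return SiteRates(raw, np.zeros(m), degenerate=True)
    return SiteRates(raw, (raw - raw.mean()) / sd, degenerate=False)


# ----------------------------------------------------------------------
# tabular I/O

def write_site_ll_table(path, entries) -> None:
    """Write per-site log-likelihoods as TSV: tree_id, site (1-based), ll."""
    with open(path, "w") as fh:
        fh.write("tree_id\tsite\tll\n")
        for tree_id, vec in entries:
            vals = np.asarray(vec)
            for i, ll in enumerate(vals, start=1):
                fh.write(f"{tree_id}\t{i}\t{ll:.10g}\n")


def read_site_weights(path):
    """Read a two-column site-weights TSV (site 1-based, weight > 0)."""
    sites, weights = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("site"):
                continue
            s, w = line.split("\t")
            w = float(w)
            if w <= 0:
                raise ValidationError(f"site weight must be positive, got {w} for site {s}")
            sites.append(int(s) - 1)
            weights.append(w)
    return np.array(sites, dtype=int), np.array(weights)


def write_site_weights(path, sites_1based, weights) -> None:
    with open(path, "w") as fh:
        fh.write("site\tweight\n")
        for s, w in zip(sites_1based, weights):
            fh.write(f"{s}\t{w:.10g}\n")
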
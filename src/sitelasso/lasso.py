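"""Positive-coefficient Lasso site sampling.

The method: generate eta random trees, compute the eta x m matrix X of exact
per-site log-likelihoods LL_i(T_j) (so the row sums are the tree
log-likelihoods y_j), and fit

    minimize_{beta >= 0}  sum_j (y_j - beta0 - sum_i beta_i X_ji)^2
                          + lambda * sum_i beta_i

by cyclic coordinate descent along a decreasing penalty grid with warm
starts. The penalty lambda at which roughly a target fraction zeta of the
coefficients is non-zero yields a small weighted set of sites whose weighted
per-site log-likelihood sum approximates the full-alignment log-likelihood of
any tree. Coefficients are constrained to be positive because the weighted
evaluation is meant to be usable as a site-weight vector.

Columns are standardized (centered, unit L2 norm) before fitting so selection
is scale-free; weights and intercept are mapped back to the original scale
afterwards. Duplicate alignment columns are deliberately *not* collapsed
before training: identical sites are exactly the correlated predictors the
Lasso is expected to represent by a single member.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import UnreachableFractionError, ValidationError
from .likelihood import SiteLLVector, site_log_likelihoods, weighted_log_likelihood
from .trees import draw_branch_lengths, random_stepwise_topology

DEFAULT_GRID_POINTS = 100
DEFAULT_GRID_RATIO = 1e-7


# ----------------------------------------------------------------------
# training data

@dataclass
class TrainingSet:
    """eta random trees with their per-site log-likelihood design matrix.

    ``y`` equals the row sums of ``X`` exactly, by construction.
    """

    trees: list
    X: np.ndarray
    y: np.ndarray
    seed: int | None = None
    model_id: str | None = None

    @property
    def eta(self) -> int:
        return self.X.shape[0]


def training_trees(taxa, eta: int, bl_mean: float, rng_seed):
    """The eta random training trees for a root seed (named substreams: one
    spawned child seed per tree index, shared by topology and lengths)."""
    ss = np.random.SeedSequence(rng_seed)
    out = []
    for child in ss.spawn(eta):
        rng = np.random.default_rng(child)
        topo = random_stepwise_topology(taxa, rng)
        out.append(draw_branch_lengths(topo, bl_mean, rng))
    return out


def build_training_set(aln, model, eta: int, bl_mean: float = 0.1,
                       rng_seed: int = 0) -> TrainingSet:
    """Random-tree training set: X[j, i] = LL_i(T_j), y = row sums.

    No branch-length or model-parameter optimization is performed on the
    training trees; their branch lengths are i.i.d. exponential draws.
    """
    if eta < 2:
        raise ValidationError("need at least 2 training trees")
    trees = training_trees(aln.taxa, eta, bl_mean, rng_seed)
    X = np.empty((eta, aln.n_sites))
    for j, tree in enumerate(trees):
        X[j] = site_log_likelihoods(tree, aln, model).values
    return TrainingSet(trees, X, X.sum(axis=1), seed=rng_seed, model_id=model.name)


def default_eta(n_taxa: int) -> int:
    """Training-set size by alignment depth: 2000 up to 15 sequences, 4000 above."""
    return 2000 if n_taxa <= 15 else 4000


# ----------------------------------------------------------------------
# standardization

@dataclass
class StandardizedDesign:
    X: np.ndarray            # centered, unit-L2-norm columns (invalid ones zeroed)
    column_means: np.ndarray
    column_norms: np.ndarray  # 1.0 placeholders for invalid columns
    y_mean: float
    y_centered: np.ndarray
    valid: np.ndarray        # False for zero-variance columns (forced out)


def standardize_design(X: np.ndarray, y: np.ndarray) -> StandardizedDesign:
    """Center each column and divide by its L2 norm; center y by its mean.

    Zero-variance columns (e.g. sites whose log-likelihood never varies, such
    as fully ambiguous columns with LL identically 0) are flagged and their
    standardized column zeroed, which forces their coefficient to stay 0.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    means = X.mean(axis=0)
    Xc = X - means
    norms = np.sqrt((Xc ** 2).sum(axis=0))
    scale = max(float(np.abs(X).max()), 1.0)
    valid = norms > 1e-12 * scale
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} zero-variance column(s) excluded from the "
                      "Lasso fit", stacklevel=2)
    safe = np.where(valid, norms, 1.0)
    X_std = np.where(valid, Xc / safe, 0.0)
    y_mean = float(y.mean())
    return StandardizedDesign(X_std, means, safe, y_mean, y - y_mean, valid)


# ----------------------------------------------------------------------
# coordinate descent

def lasso_objective(X, y, beta, lam: float) -> float:
    """sum of squared residuals + lam * sum |beta| (the training objective)."""
    r = y - X @ beta
    return float(r @ r + lam * np.abs(beta).sum())


def positive_cd(X, y, lam: float, beta: np.ndarray | None = None,
                tol: float = 1e-4, max_sweeps: int = 2000,
                record_objective: bool = False):
    """Cyclic coordinate descent for the positive Lasso at one penalty.

    Assumes unit-L2-norm columns. Each coordinate update is the exact
    one-dimensional minimizer (one-sided soft threshold clamped at 0), so the
    objective is non-increasing after every update and every sweep.
    Convergence: max coefficient update < tol * max|coef| (or an all-zero
    sweep). Coefficients below 1e-12 of the response norm are snapped to zero;
    they are float rounding noise at the soft threshold, not support.
    Returns (beta, n_sweeps, converged, objectives-per-sweep-or-None).
    """
    n_feat = X.shape[1]
    beta = np.zeros(n_feat) if beta is None else beta.copy()
    r = y - X @ beta
    objectives = [] if record_objective else None
    half = lam / 2.0
    floor = 1e-12 * float(np.linalg.norm(y))

    def sweep(indices):
        max_delta = 0.0
        for j in indices:
            bj = beta[j]
            z = bj + X[:, j] @ r
            new = z - half
            if new < floor:
                new = 0.0
            d = new - bj
            if d != 0.0:
                beta[j] = new
                np.subtract(r, d * X[:, j], out=r)
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        return max_delta

    all_idx = np.arange(n_feat)
    converged = False
    n_sweeps = 0
    while n_sweeps < max_sweeps:
        delta = sweep(all_idx)
        n_sweeps += 1
        if record_objective:
            objectives.append(lasso_objective(X, y, beta, lam))
        bmax = float(np.abs(beta).max())
        if delta <= tol * max(bmax, 1e-300):
            converged = True
            break
        # iterate the active set until it stabilizes, then re-check all
        active = np.nonzero(beta)[0]
        while active.size and n_sweeps < max_sweeps:
            delta = sweep(active)
            n_sweeps += 1
            if record_objective:
                objectives.append(lasso_objective(X, y, beta, lam))
            bmax = float(np.abs(beta).max())
            if delta <= tol * max(bmax, 1e-300):
                break
    return beta, n_sweeps, converged, objectives


@dataclass
class LassoPath:
    """Solutions along a decreasing log-scale penalty grid.

    At ``lambdas[0]`` (the grid maximum, the smallest penalty that forces all
    coefficients to exactly zero) the solution is all-zero; the non-zero count
    weakly increases as lambda decreases (up to solver tolerance).
    """

    lambdas: np.ndarray
    coefs: np.ndarray        # (n_grid, n_features)
    n_nonzero: np.ndarray
    converged: np.ndarray


def lambda_grid(X, y, n_points: int = DEFAULT_GRID_POINTS,
                grid_ratio: float = DEFAULT_GRID_RATIO) -> np.ndarray:
    """Log-scale penalty grid; the maximum is the smallest penalty at which
    the positive-Lasso solution is all-zero (from the max positive
    correlation: beta = 0 is optimal iff max_j X_j.y <= lambda/2)."""
    top = float((X.T @ y).max())
    lam_max = 2.0 * max(top, 1e-12)
    return lam_max * grid_ratio ** (np.arange(n_points) / (n_points - 1))


def fit_positive_lasso_path(X_std, y_centered, grid_points: int = DEFAULT_GRID_POINTS,
                            grid_ratio: float = DEFAULT_GRID_RATIO,
                            tol: float = 1e-4, max_sweeps: int = 2000) -> LassoPath:
    """Positive-Lasso path by warm-started cyclic coordinate descent."""
    lambdas = lambda_grid(X_std, y_centered, grid_points, grid_ratio)
    n_feat = X_std.shape[1]
    coefs = np.zeros((len(lambdas), n_feat))
    conv = np.zeros(len(lambdas), dtype=bool)
    beta = np.zeros(n_feat)
    for g, lam in enumerate(lambdas):
        beta, _sweeps, ok, _ = positive_cd(X_std, y_centered, lam, beta,
                                           tol=tol, max_sweeps=max_sweeps)
        coefs[g] = beta
        conv[g] = ok
    if not conv.all():
        warnings.warn(f"coordinate descent hit the sweep cap at {(~conv).sum()} of "
                      f"{len(lambdas)} grid points (strongly correlated columns); "
                      "the path continues with the best iterates", stacklevel=2)
    return LassoPath(lambdas, coefs, (coefs > 0).sum(axis=1), conv)


# ----------------------------------------------------------------------
# sample selection

@dataclass
class LassoSample:
    """A weighted site sample: approximate LL(T) ~ intercept + sum w_k LL_{i_k}(T).

    ``sites`` are 1-based site indices (user-facing convention); ``weights``
    are on the original, unstandardized scale and all positive.
    """

    sites: np.ndarray
    weights: np.ndarray
    intercept: float
    lam: float
    zeta_target: float
    zeta_achieved: float
    eta: int | None = None
    seed: int | None = None
    model_id: str | None = None

    @property
    def sites0(self) -> np.ndarray:
        """0-based site indices."""
        return self.sites - 1

    @property
    def tau(self) -> int:
        return len(self.sites)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["sites"] = self.sites.tolist()
        d["weights"] = self.weights.tolist()
        text = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LassoSample":
        if hasattr(source, "read"):
            d = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        d["sites"] = np.asarray(d["sites"], dtype=int)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)

    def write_site_weights(self, path) -> None:
        from .likelihood import write_site_weights

        write_site_weights(path, self.sites, self.weights)


def identity_sample(m: int) -> LassoSample:
    """All sites, unit weights, zero intercept: the exact-likelihood sample."""
    return LassoSample(np.arange(1, m + 1), np.ones(m), 0.0, 0.0, 1.0, 1.0)


def select_sample(path: LassoPath, zeta: float, std: StandardizedDesign,
                  eta: int | None = None, seed=None, model_id=None) -> LassoSample:
    """Pick the first grid point (largest penalty) whose non-zero fraction
    reaches zeta and map its coefficients back to the original scale.

    The achieved fraction is reported rather than truncating coefficients to
    hit zeta exactly. Raises when no grid point reaches zeta (the reachable
    fraction is bounded above by the fraction at the smallest penalty).
    """
    if not (0 < zeta <= 1):
        raise ValidationError("zeta must be in (0, 1]")
    m = path.coefs.shape[1]
    fractions = path.n_nonzero / m
    hits = np.nonzero(fractions >= zeta)[0]
    if hits.size == 0:
        raise UnreachableFractionError(
            f"target fraction zeta={zeta} is unreachable on the penalty grid; "
            f"achievable fractions span [{fractions[fractions > 0].min() if (fractions > 0).any() else 0:.4g}, "
            f"{fractions.max():.4g}]"
        )
    g = hits[0]
    beta_std = path.coefs[g]
    weights = beta_std / std.column_norms
    intercept = std.y_mean - float((beta_std * std.column_means / std.column_norms).sum())
    active = np.nonzero(weights > 0)[0]
    return LassoSample(
        sites=active + 1,
        weights=weights[active],
        intercept=intercept,
        lam=float(path.lambdas[g]),
        zeta_target=float(zeta),
        zeta_achieved=len(active) / m,
        eta=eta,
        seed=seed,
        model_id=model_id,
    )


def approximate_log_likelihood(source, sample: LassoSample,
                               use_intercept: bool = True) -> float:
    """Evaluate the approximation intercept + sum w_k LL_{i_k}.

    ``source`` is either a per-site log-likelihood vector (SiteLLVector or
    array over all m sites) or a (tree, alignment, model) triple, in which
    case per-site log-likelihoods are computed only at the sampled sites.
    Without the intercept the value is still ranking-safe across trees.
    """
    b0 = sample.intercept if use_intercept else 0.0
    if isinstance(source, (SiteLLVector, np.ndarray, list)):
        vals = np.asarray(source)
        if sample.tau and sample.sites0.max() >= len(vals):
            raise ValidationError("sample site index out of range")
        return float(b0 + sample.weights @ vals[sample.sites0])
    tree, aln, model = source
    return weighted_log_likelihood(tree, aln, model, sample.sites0, sample.weights,
                                   intercept=b0)


# ----------------------------------------------------------------------
# estimator interface

class LassoSiteSampler(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for Lasso site sampling.

    fit(X, y) takes the (eta, m) per-site log-likelihood design matrix and the
    total log-likelihoods y (default: row sums of X) and selects a weighted
    subset of columns whose weighted sum predicts y.

    Parameters
    ----------
    zeta : float
        Target fraction of selected sites (default 0.05).
    grid_points, grid_ratio : penalty grid (100 points, max/min ratio 1e7).
    tol, max_sweeps : coordinate-descent stopping rule.

    Attributes
    ----------
    sites_ : 0-based indices of the selected columns.
    weights_ : positive weights on the original scale.
    intercept_ : regression intercept beta0.
    lambda_ : penalty at the selected grid point.
    zeta_achieved_ : realized fraction len(sites_) / m.
    path_ : the full LassoPath.
    """

    def __init__(self, zeta: float = 0.05, grid_points: int = DEFAULT_GRID_POINTS,
                 grid_ratio: float = DEFAULT_GRID_RATIO, tol: float = 1e-4,
                 max_sweeps: int = 1000):
        self.zeta = zeta
        self.grid_points = grid_points
        self.grid_ratio = grid_ratio
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if y is None:
            y = X.sum(axis=1)
        y = np.asarray(y, float)
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y have inconsistent numbers of rows")
        std = standardize_design(X, y)
        path = fit_positive_lasso_path(std.X, std.y_centered, self.grid_points,
                                       self.grid_ratio, self.tol, self.max_sweeps)
        sample = select_sample(path, self.zeta, std)
        self.n_features_in_ = X.shape[1]
        self.sites_ = sample.sites0
        self.weights_ = sample.weights
        self.intercept_ = sample.intercept
        self.lambda_ = sample.lam
        self.zeta_achieved_ = sample.zeta_achieved
        self.path_ = path
        self._std = std
        return self

    def predict(self, X):
        check_is_fitted(self, "sites_")
        X = check_array(X, dtype=float)
        return self.intercept_ + X[:, self.sites_] @ self.weights_

    def to_sample(self, eta=None, seed=None, model_id=None) -> LassoSample:
        check_is_fitted(self, "sites_")
        return LassoSample(self.sites_ + 1, self.weights_.copy(), self.intercept_,
                           self.lambda_, self.zeta, self.zeta_achieved_,
                           eta=eta, seed=seed, model_id=model_id)


def train_site_sampler(aln, model, eta: int, zeta: float = 0.05,
                       rng_seed: int = 0, bl_mean: float = 0.1,
                       **lasso_kw):
    """End-to-end training: random trees -> design matrix -> positive Lasso.

    Returns (LassoSample, TrainingSet).
    """
    ts = build_training_set(aln, model, eta, bl_mean=bl_mean, rng_seed=rng_seed)
    sampler = LassoSiteSampler(zeta=zeta, **lasso_kw).fit(ts.X, ts.y)
    sample = sampler.to_sample(eta=eta, seed=rng_seed, model_id=model.name)
    return sample, ts
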
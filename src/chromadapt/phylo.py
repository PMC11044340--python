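"""Pagel's λ phylogenetic signal by maximum likelihood, with resampling.

Under Brownian motion on a rooted tree the species values are jointly normal
with covariance V, where V[i, j] is the shared root-to-MRCA path length of
tips i and j. Pagel's λ rescales the off-diagonal of V by a factor λ in
[0, λ_max]: λ = 1 recovers plain Brownian motion (trait fully structured by
the phylogeny), λ = 0 a star phylogeny (no signal). For a given λ the mean
and rate σ² have closed-form GLS estimates, so the likelihood is profiled
and maximised over λ alone. Significance is a likelihood-ratio test of the
fitted λ against λ = 0 with a χ²₁ reference distribution.

Because the data carry several individuals per species, λ is summarised over
resamples of the response matrix: each resample draws one individual per
species at random and refits λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import ConditioningError, DegenerateDataError, LabellingError

__all__ = [
    "brownian_covariance",
    "lambda_cov",
    "lambda_max",
    "PagelLambda",
    "LambdaEstimate",
    "fit_lambda",
    "LambdaSummary",
    "resample_lambda",
]


def brownian_covariance(tree):
    """Brownian-motion covariance of the tips of a rooted dendropy tree.

    Returns (labels, V) where V[i, j] is the root-to-MRCA path length of tips
    i and j, and V[i, i] the root-to-tip distance.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in leaves]
    n = len(leaves)
    pdm = tree.phylogenetic_distance_matrix()
    V = np.empty((n, n))
    for i, li in enumerate(leaves):
        V[i, i] = li.root_distance
        for j in range(i + 1, n):
            lj = leaves[j]
            d = pdm.patristic_distance(li.taxon, lj.taxon)
            V[i, j] = V[j, i] = 0.5 * (li.root_distance + lj.root_distance - d)
    return labels, V


def lambda_max(V) -> float:
    """Largest admissible λ: min over pairs of min(V_ii, V_jj)/V_ij.

    Keeps every off-diagonal entry at most as large as the smaller of the two
    diagonals it connects; for an ultrametric tree with positive terminal
    branches this is slightly above 1. A star phylogeny (no positive shared
    paths) returns 1.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    off = V[iu, ju]
    pos = off > 0
    if not np.any(pos):
        return 1.0
    caps = np.minimum(V[iu, iu], V[ju, ju])[pos] / off[pos]
    return float(caps.min())


def lambda_cov(V, lam: float):
    """λ-transformed Brownian covariance: off-diagonal scaled by λ."""
    V = np.asarray(V, dtype=float)
    lmax = lambda_max(V)
    if not 0.0 <= lam <= lmax + 1e-12:
        raise ValueError(f"lambda={lam} outside [0, {lmax:.6g}] for this tree")
    W = lam * V
    np.fill_diagonal(W, np.diag(V))
    return W


@dataclass
class LambdaEstimate:
    """One maximum-likelihood fit of Pagel's λ."""

    lambda_hat: float
    loglik: float
    loglik0: float
    lr_stat: float
    p_value: float
    mu: float
    sigma2: float
    lambda_max: float
    n_tips: int


class PagelLambda(BaseEstimator):
    """Maximum-likelihood estimator of Pagel's λ for one continuous trait.

    Parameters
    ----------
    tol : float
        Convergence tolerance of the bounded 1-D optimisation over λ.
    upper : float or None
        Upper search bound; ``None`` uses the tree's λ_max.

    Attributes (after :meth:`fit`)
    ------------------------------
    lambda_ : ML estimate of λ
    loglik_, loglik0_ : log-likelihood at λ̂ and at λ = 0
    lr_stat_, p_value_ : likelihood-ratio statistic and χ²₁ p-value
    mu_, sigma2_ : ancestral mean and Brownian rate at λ̂
    lambda_max_ : upper bound used
    """

    def __init__(self, tol: float = 1e-8, upper: float | None = None):
        self.tol = tol
        self.upper = upper

    @staticmethod
    def _profile_loglik(lam, V, D, y):
        # V(λ) assembled as λ·V with the BM diagonal D restored
        n = y.shape[0]
        W = lam * V
        np.fill_diagonal(W, D)
        try:
            cf = linalg.cho_factor(W, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise ConditioningError(f"covariance not positive definite at lambda={lam}") from exc
        one = np.ones(n)
        Wi_y = linalg.cho_solve(cf, y, check_finite=False)
        Wi_1 = linalg.cho_solve(cf, one, check_finite=False)
        mu = (one @ Wi_y) / (one @ Wi_1)
        r = y - mu
        Wi_r = linalg.cho_solve(cf, r, check_finite=False)
        sigma2 = (r @ Wi_r) / n
        if sigma2 <= 0:
            raise DegenerateDataError("zero residual variance: all trait values equal")
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return ll, mu, sigma2

    def fit(self, tree_or_cov, y, labels=None):
        """Fit λ to one value per species.

        ``tree_or_cov`` is a dendropy tree, or a pre-computed BM covariance
        matrix (then ``labels`` orders it). ``y`` is a mapping/Series keyed by
        species label, or an array aligned with the covariance order.
        """
        if isinstance(tree_or_cov, np.ndarray):
            V = np.asarray(tree_or_cov, dtype=float)
            if labels is None:
                labels = list(range(V.shape[0]))
        else:
            labels, V = brownian_covariance(tree_or_cov)
        if isinstance(y, pd.Series):
            y = y.to_dict()
        if isinstance(y, dict):
            missing = [lab for lab in labels if lab not in y]
            extra = [k for k in y if k not in set(labels)]
            if missing or extra:
                raise LabellingError(
                    f"species/tip mismatch (missing from data: {missing[:5]}, not in tree: {extra[:5]})"
                )
            yv = np.array([float(y[lab]) for lab in labels])
        else:
            yv = np.asarray(y, dtype=float)
            if yv.shape[0] != V.shape[0]:
                raise LabellingError("trait vector length does not match number of tips")
        if yv.shape[0] < 4:
            raise ValueError("Pagel's lambda needs at least 4 tips")
        if not np.all(np.isfinite(yv)):
            raise ValueError("trait values must be finite")
        if np.ptp(yv) == 0:
            raise DegenerateDataError("all trait values are identical")

        D = np.diag(V).copy()
        # back the bound off the exact singularity where cherry rows coincide
        lmax = (self.upper if self.upper is not None else lambda_max(V)) * (1.0 - 1e-6)

        def neg(lam):
            try:
                return -self._profile_loglik(lam, V, D, yv)[0]
            except ConditioningError:
                return np.inf

        res = optimize.minimize_scalar(
            neg, bounds=(0.0, lmax), method="bounded", options={"xatol": self.tol}
        )
        # evaluate the boundaries explicitly: bounded Brent can sit just inside
        cands = [(neg(0.0), 0.0), (neg(lmax), lmax), (res.fun, float(res.x))]
        fbest, lam_hat = min(cands, key=lambda t: t[0])
        ll, mu, s2 = self._profile_loglik(lam_hat, V, D, yv)
        ll0 = self._profile_loglik(0.0, V, D, yv)[0]
        lr = max(0.0, 2.0 * (ll - ll0))
        p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0

        self.labels_ = list(labels)
        self.lambda_ = float(lam_hat)
        self.loglik_ = float(ll)
        self.loglik0_ = float(ll0)
        self.lr_stat_ = float(lr)
        self.p_value_ = p
        self.mu_ = float(mu)
        self.sigma2_ = float(s2)
        self.lambda_max_ = float(lmax)
        return self

    def estimate_(self) -> LambdaEstimate:
        return LambdaEstimate(
            lambda_hat=self.lambda_,
            loglik=self.loglik_,
            loglik0=self.loglik0_,
            lr_stat=self.lr_stat_,
            p_value=self.p_value_,
            mu=self.mu_,
            sigma2=self.sigma2_,
            lambda_max=self.lambda_max_,
            n_tips=len(self.labels_),
        )


def fit_lambda(tree, values, **kwargs) -> LambdaEstimate:
    """One-shot λ fit; see :class:`PagelLambda`."""
    return PagelLambda(**kwargs).fit(tree, values).estimate_()


@dataclass
class LambdaSummary:
    """Resampled λ estimates for one chromatic variable."""

    variable: str
    mean_lambda: float
    se_lambda: float
    pct_significant: float
    n_resamples: int
    lambdas: np.ndarray
    p_values: np.ndarray


def resample_lambda(
    tree,
    individuals: pd.DataFrame,
    variable: str,
    n_resamples: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "one-per-species",
) -> LambdaSummary:
    """Resample the response matrix and summarise λ.

    Each resample draws one individual per species uniformly at random
    (``method='one-per-species'``) or bootstraps individuals within species
    and uses species means (``method='species-bootstrap'``), fits λ, and
    records the estimate and its LR-test p-value. The summary reports the
    mean λ, its standard error over resamples (sd/√n_resamples) and the
    percentage of resamples significant at ``alpha``.
    """
    labels, V = brownian_covariance(tree)
    by_species = {
        sp: grp[variable].to_numpy(dtype=float)
        for sp, grp in individuals.groupby("species")
    }
    missing = [lab for lab in labels if lab not in by_species]
    extra = [sp for sp in by_species if sp not in set(labels)]
    if missing or extra:
        raise LabellingError(
            f"species/tip mismatch (tips without individuals: {missing[:5]}, "
            f"species not in tree: {extra[:5]})"
        )
    rng = np.random.default_rng(seed)
    est = PagelLambda()
    lams = np.empty(n_resamples)
    ps = np.empty(n_resamples)
    pools = [by_species[lab] for lab in labels]
    for r in range(n_resamples):
        if method == "one-per-species":
            y = np.array([pool[rng.integers(pool.size)] for pool in pools])
        elif method == "species-bootstrap":
            y = np.array(
                [pool[rng.integers(pool.size, size=pool.size)].mean() for pool in pools]
            )
        else:
            raise ValueError(f"unknown resampling method {method!r}")
        est.fit(V, y, labels=labels)
        lams[r] = est.lambda_
        ps[r] = est.p_value_
    return LambdaSummary(
        variable=variable,
        mean_lambda=float(lams.mean()),
        se_lambda=float(lams.std(ddof=1) / np.sqrt(n_resamples)) if n_resamples > 1 else 0.0,
        pct_significant=float(100.0 * np.mean(ps < alpha)),
        n_resamples=n_resamples,
        lambdas=lams,
        p_values=ps,
    )
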
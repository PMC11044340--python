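"""Spatial generalized least squares with nugget, AICc selection, Bonferroni.

Each chromatic response is regressed on environmental predictors with a
spatially structured error: corr(εᵢ, εⱼ) = (1 − nugget)·ρ(dᵢⱼ/range) for
i ≠ j, where d is the great-circle distance in km and ρ one of five
correlation families (exponential, Gaussian, linear, spherical, rational
quadratic). The nugget is the fraction of residual variance that is
spatially uncorrelated. Fits are by maximum likelihood — β and σ² are
profiled analytically given (range, nugget), which are optimised numerically
— so AICc is comparable across candidate structures with identical fixed
effects. Model selection ranks candidates (5 families × nugget on/off, plus
an iid model) by AICc; coefficient p-values use t references with n − p
degrees of freedom and are Bonferroni-adjusted over the whole model family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConditioningError, NotFittedError

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "CORRELATION_FAMILIES",
    "correlation_matrix",
    "SpatialGLS",
    "fit_gls",
    "aicc",
    "select_structure",
    "bonferroni_adjust",
    "DEFAULT_MODEL_SPECS",
    "run_model_suite",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(coords_a, coords_b=None):
    """Pairwise great-circle distances in km between (lon, lat) degree pairs."""
    A = np.radians(np.atleast_2d(np.asarray(coords_a, dtype=float)))
    B = A if coords_b is None else np.radians(np.atleast_2d(np.asarray(coords_b, dtype=float)))
    lon1, lat1 = A[:, 0][:, None], A[:, 1][:, None]
    lon2, lat2 = B[:, 0][None, :], B[:, 1][None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def _rho_exponential(u):
    return np.exp(-u)


def _rho_gaussian(u):
    return np.exp(-(u**2))


def _rho_linear(u):
    return np.maximum(0.0, 1.0 - u)


def _rho_spherical(u):
    return np.where(u < 1.0, 1.0 - 1.5 * np.minimum(u, 1.0) + 0.5 * np.minimum(u, 1.0) ** 3, 0.0)


def _rho_rational_quadratic(u):
    return 1.0 / (1.0 + u**2)


CORRELATION_FAMILIES = {
    "exponential": _rho_exponential,
    "gaussian": _rho_gaussian,
    "linear": _rho_linear,
    "spherical": _rho_spherical,
    "rational_quadratic": _rho_rational_quadratic,
}


def correlation_matrix(coords, family: str, range_km: float, nugget: float = 0.0, dists=None):
    """Spatial correlation matrix C with C(0) = 1 on the diagonal.

    Off-diagonal entries are (1 − nugget)·ρ(d/range); duplicate coordinates
    (d = 0 off the diagonal) correlate at 1 − nugget.
    """
    if family not in CORRELATION_FAMILIES:
        raise ValueError(f"unknown correlation family {family!r}; choose from {sorted(CORRELATION_FAMILIES)}")
    if range_km <= 0:
        raise ValueError("range must be positive")
    if not 0.0 <= nugget < 1.0:
        raise ValueError("nugget must lie in [0, 1)")
    D = haversine_km(coords) if dists is None else np.asarray(dists, dtype=float)
    C = (1.0 - nugget) * CORRELATION_FAMILIES[family](D / range_km)
    np.fill_diagonal(C, 1.0)
    return C


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike Information Criterion with the finite-sample correction."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (requires n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bonferroni_adjust(p, m: int):
    """Bonferroni adjustment min(1, m·p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be at least 1")
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


class SpatialGLS(RegressorMixin, BaseEstimator):
    """ML generalized least squares with a spatial correlation structure.

    Parameters
    ----------
    family : str or None
        One of the five correlation families, or ``None``/``'none'`` for an
        iid (ordinary least squares) error model.
    use_nugget : bool
        Estimate a nugget fraction alongside the range.
    fit_intercept : bool
    n_range_grid, n_nugget_grid : coarse grid used to start the optimiser.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_, bse_, tvalues_, pvalues_ : per term (intercept first)
    coef_, intercept_ : sklearn-style views of ``params_``
    range_, nugget_ : correlation parameters (NaN where absent)
    sigma2_ : ML residual variance
    loglik_, k_, n_, aicc_ : fit summaries
    """

    def __init__(
        self,
        family: str | None = "exponential",
        use_nugget: bool = True,
        fit_intercept: bool = True,
        n_range_grid: int = 6,
        n_nugget_grid: int = 4,
        maxiter: int = 100,
    ):
        self.family = family
        self.use_nugget = use_nugget
        self.fit_intercept = fit_intercept
        self.n_range_grid = n_range_grid
        self.n_nugget_grid = n_nugget_grid
        self.maxiter = maxiter

    # -- likelihood machinery -------------------------------------------------

    @staticmethod
    def _profile(C, Z, y):
        """Profile β and σ² for a fixed correlation matrix C."""
        n = y.shape[0]
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            C = C + 1e-8 * np.eye(n)
            try:
                cf = linalg.cho_factor(C, lower=True, check_finite=False)
            except linalg.LinAlgError as exc:
                raise ConditioningError("correlation matrix not positive definite") from exc
        diag = np.diag(cf[0])
        if (diag.min() / diag.max()) ** 2 < 1e-14:
            raise ConditioningError("correlation matrix numerically singular")
        Ci_Z = linalg.cho_solve(cf, Z, check_finite=False)
        Ci_y = linalg.cho_solve(cf, y, check_finite=False)
        ZtCiZ = Z.T @ Ci_Z
        if 1.0 / np.linalg.cond(ZtCiZ) < 1e-14:
            raise ConditioningError("whitened normal equations numerically singular")
        try:
            beta = linalg.solve(ZtCiZ, Z.T @ Ci_y, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ConditioningError("design matrix is rank deficient") from exc
        r = y - Z @ beta
        Ci_r = linalg.cho_solve(cf, r, check_finite=False)
        sigma2 = float(r @ Ci_r) / n
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, ZtCiZ, float(r @ Ci_r)

    def _fit_struct(self, D, Z, y):
        """Optimise (range, nugget) for one structured family."""
        fam = self.family
        pos = D[np.triu_indices_from(D, k=1)]
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError("all coordinates coincide; no spatial structure is identifiable")
        lo, hi = np.log(np.quantile(pos, 0.01) + 1e-6), np.log(2.0 * pos.max())

        def unpack(theta):
            rng_km = float(np.exp(theta[0]))
            nug = float(1.0 / (1.0 + np.exp(-theta[1]))) if self.use_nugget else 0.0
            return rng_km, nug

        def neg(theta):
            rng_km, nug = unpack(theta)
            C = correlation_matrix(None, fam, rng_km, nug, dists=D)
            try:
                return -self._profile(C, Z, y)[0]
            except ConditioningError:
                return 1e12

        ranges = np.linspace(lo, hi, self.n_range_grid)
        nuggets = (
            np.log(np.array([0.05, 0.2, 0.5, 0.8]) / (1 - np.array([0.05, 0.2, 0.5, 0.8])))[
                : self.n_nugget_grid
            ]
            if self.use_nugget
            else [0.0]
        )
        best = None
        for r0 in ranges:
            for g0 in nuggets:
                theta = np.array([r0, g0]) if self.use_nugget else np.array([r0, 0.0])
                f = neg(theta)
                if best is None or f < best[0]:
                    best = (f, theta)
        theta0 = best[1]
        if self.use_nugget:
            res = optimize.minimize(
                neg,
                theta0,
                method="L-BFGS-B",
                bounds=[(lo, hi), (-6.0, 6.0)],
                options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-8},
            )
            theta = res.x if res.fun <= best[0] else theta0
        else:
            res = optimize.minimize_scalar(
                lambda t: neg(np.array([t, 0.0])),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            theta = np.array([res.x, 0.0]) if res.fun <= best[0] else theta0
        return unpack(theta)

    # -- public API ------------------------------------------------------------

    def fit(self, X, y, coords=None, dists=None):
        """Fit the GLS. ``coords`` are (lon, lat) degrees; ``dists`` may carry
        a precomputed distance matrix instead (km)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        Z = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        p = Z.shape[1]
        structured = self.family not in (None, "none", "iid")
        n_struct = (1 + int(self.use_nugget)) if structured else 0
        if n <= p + n_struct + 2:
            raise ValueError("too few observations for the requested model")
        if np.linalg.matrix_rank(Z) < p:
            raise ConditioningError("design matrix is rank deficient")

        if structured:
            if coords is None and dists is None:
                raise ValueError("spatial families require coords or a distance matrix")
            D = haversine_km(coords) if dists is None else np.asarray(dists, dtype=float)
            rng_km, nug = self._fit_struct(D, Z, y)
            C = correlation_matrix(None, self.family, rng_km, nug, dists=D)
        else:
            rng_km, nug = np.nan, np.nan
            C = np.eye(n)
        ll, beta, sigma2, ZtCiZ, rss_w = self._profile(C, Z, y)

        dof = n - p
        sigma2_unbiased = rss_w / dof
        cov_beta = sigma2_unbiased * linalg.inv(ZtCiZ)
        bse = np.sqrt(np.diag(cov_beta))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)

        self.params_ = beta
        self.bse_ = bse
        self.tvalues_ = tvals
        self.pvalues_ = pvals
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.range_ = float(rng_km)
        self.nugget_ = float(nug)
        self.sigma2_ = float(sigma2)
        self.loglik_ = float(ll)
        self.n_ = int(n)
        self.df_resid_ = int(dof)
        self.k_ = int(p + 1 + n_struct)
        self.aicc_ = aicc(self.loglik_, self.k_, self.n_)
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise NotFittedError("SpatialGLS must be fitted before predict")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_

    def conf_int(self, alpha: float = 0.05):
        """Two-sided (1 − alpha) confidence intervals for all terms."""
        if not hasattr(self, "params_"):
            raise NotFittedError("SpatialGLS must be fitted before conf_int")
        q = stats.t.ppf(1.0 - alpha / 2.0, df=self.df_resid_)
        return np.column_stack([self.params_ - q * self.bse_, self.params_ + q * self.bse_])


@dataclass
class GLSFit:
    """Flat record of one fitted candidate, for reporting."""

    response: str
    family: str
    use_nugget: bool
    range_km: float
    nugget: float
    loglik: float
    k: int
    n: int
    aicc: float
    model: SpatialGLS = field(repr=False)


def fit_gls(y, X, coords=None, family="exponential", use_nugget=True, dists=None) -> SpatialGLS:
    """One-shot GLS fit; see :class:`SpatialGLS`."""
    return SpatialGLS(family=family, use_nugget=use_nugget).fit(X, y, coords=coords, dists=dists)


def select_structure(
    y,
    X,
    coords=None,
    dists=None,
    families=tuple(CORRELATION_FAMILIES),
    nugget_options=(True, False),
    include_iid=True,
    response: str = "y",
) -> pd.DataFrame:
    """Fit every candidate correlation structure and rank by AICc.

    Candidates are each family with and without nugget, plus an iid model.
    Returns a DataFrame sorted by AICc with ΔAICc and Akaike weights
    w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2); fitted models ride along in the
    ``model`` column.
    """
    if dists is None:
        if coords is None:
            raise ValueError("select_structure requires coords or a distance matrix")
        dists = haversine_km(coords)
    rows = []
    failures = []
    for fam in families:
        for nug in nugget_options:
            try:
                m = SpatialGLS(family=fam, use_nugget=nug).fit(X, y, dists=dists)
            except Exception as exc:  # keep the sweep alive, report later
                failures.append((fam, nug, repr(exc)))
                continue
            rows.append(GLSFit(response, fam, nug, m.range_, m.nugget_, m.loglik_, m.k_, m.n_, m.aicc_, m))
    if include_iid:
        m = SpatialGLS(family=None).fit(X, y)
        rows.append(GLSFit(response, "none", False, np.nan, np.nan, m.loglik_, m.k_, m.n_, m.aicc_, m))
    if not rows:
        raise ConditioningError(f"every candidate failed: {failures}")
    if failures:
        warnings.warn(f"{len(failures)} candidate structure(s) failed: {failures}")
    tab = pd.DataFrame(
        {
            "response": [r.response for r in rows],
            "family": [r.family for r in rows],
            "nugget_effect": [r.use_nugget for r in rows],
            "range_km": [r.range_km for r in rows],
            "nugget": [r.nugget for r in rows],
            "loglik": [r.loglik for r in rows],
            "k": [r.k for r in rows],
            "n": [r.n for r in rows],
            "aicc": [r.aicc for r in rows],
            "model": [r.model for r in rows],
        }
    )
    tab = tab.sort_values(["aicc", "family"], kind="stable").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    w = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = w / w.sum()
    return tab


#: predictor sets per response, mirroring the published regression design
DEFAULT_MODEL_SPECS = {
    "mean_l": ["surface_area", "dist_mainland", "temperature"],
    "mean_a": ["surface_area", "sea_depth", "temperature", "precipitation"],
    "mean_b": ["surface_area", "sea_depth", "land_buffer", "temperature", "precipitation"],
    "dist_centroid": ["surface_area"],
    "contrast": ["surface_area", "dist_mainland", "temperature"],
}

PREDICTOR_LABELS = {
    "surface_area": "Surface area",
    "dist_mainland": "Distance to mainland",
    "sea_depth": "Average sea depth",
    "land_buffer": "Land buffer",
    "temperature": "Temperature",
    "precipitation": "Precipitation",
}


def _log_z(col: pd.Series) -> pd.Series:
    """Log transform (signed log when negatives occur) followed by z-scoring."""
    x = col.to_numpy(dtype=float)
    if np.any(x < 0):
        t = np.sign(x) * np.log1p(np.abs(x))
    else:
        t = np.log1p(x)
    sd = t.std(ddof=1)
    if sd == 0:
        raise ValueError(f"predictor {col.name!r} is constant")
    return pd.Series((t - t.mean()) / sd, index=col.index, name=col.name)


def run_model_suite(
    stats: pd.DataFrame,
    env: pd.DataFrame,
    model_specs: dict | None = None,
    m: int | None = None,
    families=tuple(CORRELATION_FAMILIES),
    nugget_options=(True, False),
    include_iid=True,
):
    """Fit the whole regression suite and emit report tables.

    ``stats`` carries per-individual chromatic statistics with ``lon``/``lat``
    and an ``individual_id``; ``env`` the environmental covariates per
    individual. Predictors are log-transformed and z-scored before fitting.
    The Bonferroni family size ``m`` defaults to the total predictor count
    across all models.

    Returns
    -------
    (table2, table3, candidates)
        Best structure per response; coefficient table with raw and adjusted
        p-values; and the full candidate log.
    """
    specs = model_specs if model_specs is not None else DEFAULT_MODEL_SPECS
    merged = stats.merge(env, on="individual_id", how="inner", suffixes=("", "_env"))
    if len(merged) < len(stats):
        raise ValueError("environmental covariates missing for some individuals")
    merged = merged.sort_values("individual_id", kind="stable").reset_index(drop=True)
    if m is None:
        m = sum(len(v) for v in specs.values())

    all_predictors = sorted({p for v in specs.values() for p in v})
    unknown = [p for p in all_predictors if p not in merged.columns]
    if unknown:
        raise ValueError(f"unknown predictor column(s): {unknown}")
    Xcols = {p: _log_z(merged[p]) for p in all_predictors}
    coords = merged[["lon", "lat"]].to_numpy(dtype=float)
    D = haversine_km(coords)

    t2_rows, t3_rows, cand_frames = [], [], []
    for response, predictors in specs.items():
        if response not in merged.columns:
            raise ValueError(f"unknown response column {response!r}")
        y = merged[response].to_numpy(dtype=float)
        X = np.column_stack([Xcols[p].to_numpy() for p in predictors])
        tab = select_structure(
            y, X, dists=D, families=families, nugget_options=nugget_options,
            include_iid=include_iid, response=response,
        )
        best = tab.iloc[0]
        t2_rows.append(
            {
                "response": response,
                "family": best["family"],
                "nugget_effect": bool(best["nugget_effect"]),
                "aicc": best["aicc"],
                "delta_aicc": 0.0,
                "weight": best["weight"],
            }
        )
        model: SpatialGLS = best["model"]
        for j, pred in enumerate(predictors, start=1):
            praw = float(model.pvalues_[j])
            t3_rows.append(
                {
                    "response": response,
                    "predictor": PREDICTOR_LABELS.get(pred, pred),
                    "value": float(model.params_[j]),
                    "t_value": float(model.tvalues_[j]),
                    "p": praw,
                    "p_adj": bonferroni_adjust(praw, m),
                }
            )
        cand_frames.append(tab.drop(columns="model"))
    table2 = pd.DataFrame(t2_rows)
    table3 = pd.DataFrame(t3_rows)
    candidates = pd.concat(cand_frames, ignore_index=True)
    return table2, table3, candidates
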
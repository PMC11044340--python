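"""Chromatic statistics: colour differences, genus colour centroids, contrast.

Two derived variables summarise an individual's dorsal colouration:

* **distance to the genus colour centroids** — how far the individual's mean
  CIELAB colour sits from the neighbourhood of the genus' two predominant
  ("basic") colours, measured with a range-normalised Gower dissimilarity;
* **colour contrast** — the mean CIEDE2000 difference over all unordered
  pairs of the 10 colours sampled on the individual, so a uniformly coloured
  animal scores lower than one with a disruptive (spotted/striped) pattern.

The centroid model is a trimmed (robust) K-means fit to the pooled colour
table of the whole dataset.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegenerateDataError,
    InsufficientPoolError,
    NotFittedError,
    SamplingError,
)

__all__ = [
    "ciede2000",
    "load_ciede2000_reference",
    "gower_distance",
    "ColorCentroids",
    "fit_centroids",
    "centroid_distance",
    "color_contrast",
    "permanova_source_check",
]


def ciede2000(lab1, lab2):
    """CIEDE2000 colour difference ΔE00 with kL = kC = kH = 1.

    Implements the full formula including the G chroma compensation, the
    hue-rotation term RT and the SL/SC/SH weighting functions. Inputs
    broadcast; each trailing axis must hold an (l, a, b) triplet.

    Parameters
    ----------
    lab1, lab2 : array-like, shape (..., 3)
        CIELAB triplets.

    Returns
    -------
    ndarray or float
        ΔE00, non-negative, zero iff the triplets are identical.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    if lab1.shape[-1] != 3 or lab2.shape[-1] != 3:
        raise ValueError("CIELAB inputs must have a trailing axis of length 3")
    L1, a1, b1 = np.moveaxis(lab1, -1, 0)
    L2, a2, b2 = np.moveaxis(lab2, -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    hdiff = h2p - h1p
    dhp = np.where(
        C1p * C2p == 0,
        0.0,
        np.where(
            np.abs(hdiff) <= 180.0,
            hdiff,
            np.where(hdiff > 180.0, hdiff - 360.0, hdiff + 360.0),
        ),
    )
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            np.abs(h1p - h2p) <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp**7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0**7))
    lb50 = (Lbp - 50.0) ** 2
    SL = 1.0 + 0.015 * lb50 / np.sqrt(20.0 + lb50)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / SL
    tC = dCp / SC
    tH = dHp / SH
    out = np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
    if out.ndim == 0:
        return float(out)
    return out


def load_ciede2000_reference() -> pd.DataFrame:
    """Load the published 34-pair CIEDE2000 verification dataset.

    Columns ``l1,a1,b1,l2,a2,b2,delta_e00``; the expected differences are
    printed to four decimals in the original verification table.
    """
    path = importlib.resources.files("chromadapt.data") / "ciede2000_pairs.csv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def gower_distance(x, y, ranges):
    """Gower dissimilarity between CIELAB triplets: mean of |xᵢ−yᵢ|/rangeᵢ.

    `ranges` are the per-axis spans (max − min) of the pooled colour table;
    with in-range inputs the result lies in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    if np.any(ranges <= 0):
        raise DegenerateDataError("Gower ranges must be strictly positive on every axis")
    return np.mean(np.abs(x - y) / ranges, axis=-1)


class ColorCentroids(BaseEstimator, TransformerMixin):
    """Genus colour centroid model: trimmed K-means over a pooled colour table.

    At each iteration the `trim` fraction of points farthest from their
    nearest centroid is excluded before the centroid update, which makes the
    centroids robust to gross outliers (over/under-exposed samples). After
    convergence each centroid keeps its ``n_neighbors`` nearest pool colours
    (its "basic colour" neighbourhood) and the per-axis ranges of the full,
    untrimmed pool for the Gower distance.

    Parameters
    ----------
    n_clusters : int
        Number of basic colours (2 for the green/brown genus palette).
    trim : float in [0, 0.5)
        Fraction of points excluded each iteration.
    n_neighbors : int
        Neighbourhood size per centroid.
    neighbor_metric : {'euclidean', 'ciede2000'}
        Distance used to rank pool colours around each centroid.
    aggregation : {'nearest', 'both'}
        How :meth:`centroid_distance` combines the per-centroid mean Gower
        distances: minimum over centroids (distance to the nearest basic
        colour) or their mean.
    n_restarts, max_iter, tol : K-means control.
    random_state : int or None
        Seed for the restarts.

    Attributes
    ----------
    centroids_ : ndarray (n_clusters, 3), sorted by (l, a, b)
    labels_ : ndarray (N,) nearest-centroid assignment of the full pool
    trimmed_mask_ : ndarray (N,) bool, True for points trimmed at the solution
    neighborhoods_ : ndarray (n_clusters, n_neighbors, 3)
    ranges_ : ndarray (3,) per-axis spans of the full pool
    inertia_ : trimmed within-cluster sum of squares
    n_iter_ : iterations of the best restart
    converged_ : bool
    """

    def __init__(
        self,
        n_clusters: int = 2,
        trim: float = 0.05,
        n_neighbors: int = 200,
        neighbor_metric: str = "euclidean",
        aggregation: str = "nearest",
        n_restarts: int = 50,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.trim = trim
        self.n_neighbors = n_neighbors
        self.neighbor_metric = neighbor_metric
        self.aggregation = aggregation
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("pooled colour table must be an (N, 3) CIELAB array")
        if not np.all(np.isfinite(X)):
            raise ValueError("pooled colour table contains non-finite values")
        if X.shape[0] < self.n_clusters * self.n_neighbors:
            raise InsufficientPoolError(
                f"pool of {X.shape[0]} colours cannot support {self.n_clusters} "
                f"neighbourhoods of {self.n_neighbors}"
            )
        if np.all(X == X[0]):
            raise DegenerateDataError("all pooled colours are identical")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        if not 0.0 <= self.trim < 0.5:
            raise ValueError("trim must lie in [0, 0.5)")
        n = X.shape[0]
        n_keep = max(self.n_clusters, int(np.ceil((1.0 - self.trim) * n)))
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(self.n_restarts):
            centroids = X[rng.choice(n, size=self.n_clusters, replace=False)].copy()
            converged = False
            for it in range(1, self.max_iter + 1):
                d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
                nearest = d2.argmin(axis=1)
                mind2 = d2[np.arange(n), nearest]
                keep = np.argsort(mind2, kind="stable")[:n_keep]
                new = centroids.copy()
                for j in range(self.n_clusters):
                    members = keep[nearest[keep] == j]
                    if members.size:
                        new[j] = X[members].mean(axis=0)
                    else:  # re-seed an emptied centroid at the worst kept point
                        new[j] = X[keep[-1]]
                shift = np.sqrt(((new - centroids) ** 2).sum(axis=1)).max()
                centroids = new
                if shift < self.tol:
                    converged = True
                    break
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            mind2 = d2.min(axis=1)
            keep = np.argsort(mind2, kind="stable")[:n_keep]
            inertia = mind2[keep].sum()
            if best is None or inertia < best[0]:
                best = (inertia, centroids, it, converged)

        inertia, centroids, n_iter, converged = best
        order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
        centroids = centroids[order]

        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        mind2 = d2[np.arange(n), nearest]
        keep = np.argsort(mind2, kind="stable")[:n_keep]
        trimmed = np.ones(n, dtype=bool)
        trimmed[keep] = False

        if self.neighbor_metric == "euclidean":
            dist = np.sqrt(d2)
        elif self.neighbor_metric == "ciede2000":
            dist = ciede2000(X[:, None, :], centroids[None, :, :])
        else:
            raise ValueError(f"unknown neighbor_metric {self.neighbor_metric!r}")
        hoods = np.empty((self.n_clusters, self.n_neighbors, 3))
        for j in range(self.n_clusters):
            idx = np.argsort(dist[:, j], kind="stable")[: self.n_neighbors]
            hoods[j] = X[idx]

        ranges = X.max(axis=0) - X.min(axis=0)
        if np.any(ranges <= 0):
            raise DegenerateDataError("pooled colour table has zero range on an axis")

        self.centroids_ = centroids
        self.labels_ = nearest
        self.trimmed_mask_ = trimmed
        self.neighborhoods_ = hoods
        self.ranges_ = ranges
        self.inertia_ = float(inertia)
        self.n_iter_ = n_iter
        self.converged_ = bool(converged)
        return self

    def _check_fitted(self):
        if not hasattr(self, "centroids_"):
            raise NotFittedError("ColorCentroids must be fitted before use")

    def transform(self, X):
        """Mean Gower distance from each row to each centroid's neighbourhood.

        Returns an (n, n_clusters) array.
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.n_clusters))
        for j in range(self.n_clusters):
            hood = self.neighborhoods_[j]  # (m, 3)
            d = np.abs(X[:, None, :] - hood[None, :, :]) / self.ranges_
            out[:, j] = d.mean(axis=2).mean(axis=1)
        return out

    def centroid_distance(self, X):
        """Distance-to-centroids statistic for one or many mean colours.

        For each individual mean colour, the mean Gower distance to each
        centroid's neighbourhood is computed and aggregated (min over
        centroids by default: distance to the nearest basic colour).
        """
        per = self.transform(X)
        if self.aggregation == "nearest":
            agg = per.min(axis=1)
        elif self.aggregation == "both":
            agg = per.mean(axis=1)
        else:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if np.ndim(X) == 1:
            return float(agg[0])
        return agg

    def to_dict(self) -> dict:
        """JSON-serialisable snapshot of the fitted model."""
        self._check_fitted()
        return {
            "n_clusters": self.n_clusters,
            "trim": self.trim,
            "aggregation": self.aggregation,
            "neighbor_metric": self.neighbor_metric,
            "centroids": self.centroids_.tolist(),
            "neighborhoods": self.neighborhoods_.tolist(),
            "ranges": self.ranges_.tolist(),
            "inertia": self.inertia_,
            "converged": self.converged_,
        }


def fit_centroids(pool, trim: float = 0.05, random_state: int | None = None, **kwargs) -> ColorCentroids:
    """Fit the two-centroid genus colour model on a pooled (N, 3) CIELAB table."""
    return ColorCentroids(trim=trim, random_state=random_state, **kwargs).fit(pool)


def centroid_distance(mean_lab, model: ColorCentroids):
    """Distance of a mean colour to the fitted genus centroid neighbourhoods."""
    return model.centroid_distance(mean_lab)


def color_contrast(samples):
    """Individual colour contrast: mean ΔE00 over all unordered sample pairs.

    With the standard 10 samples per individual this averages 45 pairs; a
    uniformly coloured individual scores 0, a disruptively patterned one
    scores higher.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be an (n, 3) CIELAB array")
    n = samples.shape[0]
    if n < 10:
        raise ValueError(f"colour contrast requires at least 10 samples, got {n}")
    iu, ju = np.triu_indices(n, k=1)
    return float(np.mean(ciede2000(samples[iu], samples[ju])))


def permanova_source_check(
    profiles: pd.DataFrame,
    n: int = 100,
    n_permutations: int = 999,
    n_resamples: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
):
    """Source-fidelity check: PERMANOVA of CIELAB coordinates between sources.

    Repeatedly draws a stratified random sample (``n`` individuals, 50% from
    each source), runs a PERMANOVA (pseudo-F on Euclidean distances of the
    (l, a, b) coordinates, group labels permuted) and reports the fraction of
    resamples in which no significant source difference is found.

    Parameters
    ----------
    profiles : DataFrame with columns ``l``, ``a``, ``b``, ``source``
        Individual mean colours of a single species from two sources.

    Returns
    -------
    (float, ndarray)
        Fraction of resamples with p ≥ alpha, and the per-resample p-values.
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova

    sources = profiles["source"].unique()
    if len(sources) != 2:
        raise ValueError("profiles must come from exactly two sources")
    half = n // 2
    groups = {s: profiles.index[profiles["source"] == s].to_numpy() for s in sources}
    for s, idx in groups.items():
        if len(idx) < half:
            raise SamplingError(
                f"source {s!r} has {len(idx)} profiles; {half} needed per resample"
            )
    rng = np.random.default_rng(seed)
    coords = profiles[["l", "a", "b"]].to_numpy(dtype=float)
    pos = {lab: i for i, lab in enumerate(profiles.index)}
    pvals = np.empty(n_resamples)
    for r in range(n_resamples):
        take = np.concatenate(
            [rng.choice(groups[s], size=half, replace=False) for s in sources]
        )
        rows = np.array([pos[t] for t in take])
        sub = coords[rows]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
        grouping = np.repeat(sources.astype(str), half)
        res = permanova(
            dm,
            grouping,
            permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        pvals[r] = res["p-value"]
    return float(np.mean(pvals >= alpha)), pvals
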
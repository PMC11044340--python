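"""Synthetic inputs with known ground truth for the whole pipeline.

The real study material — georeferenced field photographs, a genus phylogeny
and per-locality environmental tables — is emulated here so every downstream
stage can be exercised against planted truth:

* pure-birth (Yule) phylogenies rescaled to unit depth;
* species traits simulated under λ-transformed Brownian motion with
  intraspecific noise;
* zero-mean Gaussian process draws over sites with a named spatial
  correlation family, range, nugget and sill;
* rendered lizard-like scenes: a dorsal ROI filled with a base colour and an
  optional spotted/striped pattern at an exact coverage, with photometric
  noise, serialised as PNG;
* a full dataset bundle (individuals, tree, environmental covariates,
  generation record) whose planted effect structure mirrors the island
  syndrome: darker, more uniform, atypically coloured animals on small
  islands.

All generators are seed-deterministic; a master seed fans out to recorded
per-component seeds.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from . import imaging
from .exceptions import ConditioningError, GamutError, GeometryError, LabellingError
from .gls import correlation_matrix, haversine_km
from .phylo import brownian_covariance, lambda_cov

__all__ = [
    "simulate_tree",
    "simulate_lambda_traits",
    "simulate_spatial_field",
    "simulate_site_coords",
    "SceneSpec",
    "render_scene",
    "DatasetConfig",
    "SimulatedDataset",
    "simulate_dataset",
]

# Mediterranean-ish study window
LON_RANGE = (-9.0, 35.0)
LAT_RANGE = (31.0, 50.0)

GREEN_LAB = (55.0, -38.0, 32.0)
BROWN_LAB = (48.0, 18.0, 30.0)
ATYPICAL_LAB = (30.0, 8.0, -35.0)  # dark bluish morph


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int | None = None):
    """Pure-birth (Yule) phylogeny with ``n_species`` tips, rescaled to unit depth.

    Tips are labelled ``sp01``, ``sp02``, … in the order they appear in the
    generated topology. Branch lengths are strictly positive and the tree is
    serialisable as Newick; the same seed yields a byte-identical tree.
    """
    if n_species < 1:
        raise ValueError("n_species must be at least 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if n_species == 1:
        tree = dendropy.Tree.get(data="(sp01:1.0);", schema="newick")
        return tree
    from dendropy.simulate import treesim

    rnd = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rnd,
    )
    # the stopping speciation leaves zero-length tip edges; extend every tip
    # edge by a common exponential waiting time to keep the tree ultrametric
    # with strictly positive branch lengths
    extra = rnd.expovariate(birth_rate * n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(nd.root_distance for nd in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree


def tree_to_newick(tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_lambda_traits(
    tree,
    lam: float,
    sigma2: float = 1.0,
    n_per_species: int = 1,
    intraspecific_sd: float = 0.0,
    seed: int | None = None,
    mu: float = 0.0,
) -> pd.DataFrame:
    """Simulate individual trait values under λ-transformed Brownian motion.

    Species means are drawn from MVN(mu, sigma2 · V(λ)) where V(λ) is the
    Brownian covariance of the tree with its off-diagonal scaled by λ;
    individuals add iid N(0, intraspecific_sd²) noise.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if intraspecific_sd < 0:
        raise ValueError("intraspecific_sd must be non-negative")
    labels, V = brownian_covariance(tree)
    W = sigma2 * lambda_cov(V, lam)
    rng = np.random.default_rng(seed)
    L = linalg.cholesky(W + 1e-12 * np.eye(len(labels)), lower=True)
    means = mu + L @ rng.standard_normal(len(labels))
    rows = []
    for sp, m in zip(labels, means):
        vals = m + intraspecific_sd * rng.standard_normal(n_per_species)
        for j, v in enumerate(vals, start=1):
            rows.append({"individual_id": f"{sp}_{j:03d}", "species": sp, "value": float(v), "species_mean": float(m)})
    return pd.DataFrame(rows)


def simulate_spatial_field(
    coords,
    family: str = "exponential",
    range_km: float = 100.0,
    nugget: float = 0.0,
    sill: float = 1.0,
    seed: int | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """One draw from a zero-mean Gaussian process over (lon, lat) sites.

    Correlation at distance d follows the named family with the given range;
    a fraction ``nugget`` of the ``sill`` variance is spatially uncorrelated.
    A non-positive-definite covariance raises unless a ``jitter`` to add to
    the diagonal is configured.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if nugget == 1.0:  # pure-nugget limit: white noise field
        C = np.eye(coords.shape[0])
    else:
        C = correlation_matrix(coords, family, range_km, nugget)
    S = sill * C
    try:
        L = linalg.cholesky(S, lower=True)
    except linalg.LinAlgError:
        if jitter > 0:
            L = linalg.cholesky(S + jitter * np.eye(S.shape[0]), lower=True)
        else:
            # exact duplicates make S singular but still PSD: use an eigen
            # square root; genuinely indefinite assemblies are an error
            w, Q = linalg.eigh(S)
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ConditioningError(
                    "assembled spatial covariance is not positive definite; "
                    "configure a diagonal jitter to proceed"
                )
            L = Q * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(coords.shape[0])


def simulate_site_coords(
    n: int,
    n_clusters: int = 15,
    window=((0.0, 14.0), (36.0, 46.0)),
    cluster_sd_deg: float = 0.7,
    seed: int | None = None,
) -> np.ndarray:
    """Clustered sampling localities, the geometry of real island surveys.

    Sites group around ``n_clusters`` centres drawn uniformly in the window
    (lon, lat degree ranges), with Gaussian within-cluster scatter. Mixing
    short within-cluster distances with long between-cluster ones makes the
    shape of a spatial correlation function identifiable, unlike a uniform
    scatter over the whole basin.
    """
    rng = np.random.default_rng(seed)
    cx = rng.uniform(*window[0], n_clusters)
    cy = rng.uniform(*window[1], n_clusters)
    idx = rng.integers(0, n_clusters, n)
    return np.column_stack(
        [cx[idx] + cluster_sd_deg * rng.standard_normal(n), cy[idx] + cluster_sd_deg * rng.standard_normal(n)]
    )


_XYZ_TO_LINEAR_RGB = np.array(
    [
        [3.2404542, -1.5371385, -0.4985314],
        [-0.9692660, 1.8760108, 0.0415560],
        [0.0556434, -0.2040259, 1.0572252],
    ]
)


def _check_gamut(lab, tol: float = 1e-6):
    """Raise GamutError for CIELAB triplets whose linear-RGB lies outside [0, 1].

    Checked analytically (LAB → XYZ(D65) → linear RGB) so 8-bit quantisation
    noise cannot mislabel in-gamut colours.
    """
    lab = np.asarray(lab, dtype=float)
    from skimage.color import lab2xyz

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xyz = lab2xyz(lab.reshape(1, 1, 3)).reshape(3)
    lin = _XYZ_TO_LINEAR_RGB @ xyz
    if lin.min() < -tol or lin.max() > 1.0 + tol:
        raise GamutError(lab)


@dataclass
class SceneSpec:
    """Recipe for one rendered lizard-like scene.

    The dorsal ROI is a polygon in pixel coordinates filled with the base
    colour; spotted/striped patterns overlay the pattern colour on an exact
    ``coverage`` fraction of ROI pixels. ``noise_sd`` adds iid Gaussian
    photometric noise on all three CIELAB axes before conversion to sRGB.
    """

    width: int = 96
    height: int = 64
    background_lab: tuple = (70.0, 5.0, 25.0)
    roi: tuple = ((16, 12), (80, 12), (80, 52), (16, 52))
    base_lab: tuple = GREEN_LAB
    pattern: str = "uniform"
    pattern_lab: tuple | None = None
    coverage: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.pattern not in ("uniform", "spotted", "striped"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "uniform":
            if self.coverage != 0.0:
                raise ValueError("coverage must be 0 for a uniform pattern")
        else:
            if not 0.0 < self.coverage < 1.0:
                raise ValueError("patterned scenes need coverage in (0, 1)")
            if self.pattern_lab is None:
                raise ValueError("patterned scenes need a pattern colour")
        roi = np.asarray(self.roi, dtype=float)
        if (
            roi[:, 0].min() < 0
            or roi[:, 1].min() < 0
            or roi[:, 0].max() > self.width - 1
            or roi[:, 1].max() > self.height - 1
        ):
            raise GeometryError("ROI must lie fully inside the image")
        for lab in filter(None, (self.background_lab, self.base_lab, self.pattern_lab)):
            _check_gamut(lab)


def render_scene(spec: SceneSpec):
    """Render a scene to an sRGB image.

    Returns ``(image, roi, truth)``: an (H, W, 3) uint8 array, the ROI polygon
    vertices, and a ground-truth dict (planted colours, achieved coverage,
    count of pixels clipped during gamut mapping).
    """
    rng = np.random.default_rng(spec.seed)
    lab = np.empty((spec.height, spec.width, 3), dtype=float)
    lab[:] = np.asarray(spec.background_lab, dtype=float)

    xs, ys = imaging._polygon_pixels((spec.height, spec.width), np.asarray(spec.roi, float))
    lab[ys, xs] = np.asarray(spec.base_lab, dtype=float)
    m = xs.size
    k = 0
    if spec.pattern != "uniform":
        k = int(round(spec.coverage * m))
        if spec.pattern == "spotted":
            from scipy.ndimage import gaussian_filter

            noise = rng.standard_normal((spec.height, spec.width))
            sigma = max(1.0, min(np.ptp(xs), np.ptp(ys)) / 10.0)
            fld = gaussian_filter(noise, sigma)[ys, xs]
        else:  # striped: smooth longitudinal wave, thresholded at the coverage quantile
            period = max(4.0, np.ptp(xs) / 5.0)
            phase = rng.uniform(0, 2 * np.pi)
            fld = np.sin(2 * np.pi * xs / period + phase) + 1e-9 * ys
        top = np.argsort(fld, kind="stable")[-k:] if k > 0 else np.array([], dtype=int)
        lab[ys[top], xs[top]] = np.asarray(spec.pattern_lab, dtype=float)
        pattern_mask_idx = top
    else:
        pattern_mask_idx = np.array([], dtype=int)

    if spec.noise_sd > 0:
        lab += spec.noise_sd * rng.standard_normal(lab.shape)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        img = imaging.cielab_to_srgb(lab)
        back = imaging.srgb_to_cielab(img)
    clipped = int(np.sum(np.sqrt(((back - lab) ** 2).sum(axis=-1)) > 1.0))

    truth = {
        "base_lab": tuple(map(float, spec.base_lab)),
        "pattern": spec.pattern,
        "pattern_lab": tuple(map(float, spec.pattern_lab)) if spec.pattern_lab else None,
        "requested_coverage": float(spec.coverage),
        "achieved_coverage": float(k / m) if m else 0.0,
        "roi_pixels": int(m),
        "pattern_pixel_index": pattern_mask_idx,
        "roi_xy": (xs, ys),
        "n_clipped": clipped,
        "seed": spec.seed,
    }
    return img, np.asarray(spec.roi, dtype=float), truth


@dataclass
class DatasetConfig:
    """Generation parameters for a full synthetic dataset bundle.

    Defaults describe a desk-scale version of the study design: a few
    hundred individuals across 20 species on islands spanning several orders
    of magnitude in area, weak phylogenetic signal in colour, a moderate
    positive effect of log island area on lightness and a negative one on
    colour atypicality, and exponentially correlated spatial residuals.
    """

    n_species: int = 20
    n_individuals: int = 200
    n_sites: int = 60
    island_fraction: float = 0.6
    true_lambda: float = 0.1
    sigma2_species: float = 4.0
    beta_lightness: float = 2.0
    atypicality_base: float = 0.15
    atypicality_slope: float = 0.15
    spatial_family: str = "exponential"
    spatial_range_km: float = 100.0
    spatial_nugget: float = 0.2
    spatial_sill: float = 4.0
    individual_sd: float = 1.5
    sample_sd: float = 2.5
    pattern_coverage: float = 0.4
    render_images: bool = False
    image_size: tuple = (96, 64)
    n_samples_per_individual: int = 10
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.true_lambda <= 1.0:
            raise ValueError("true_lambda must lie in [0, 1]")
        if self.n_species < 1 or self.n_individuals < self.n_species:
            raise ValueError("need at least one individual per species")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValueError("island_fraction must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """Bundle of synthetic inputs plus the generation record."""

    individuals: pd.DataFrame
    samples: pd.DataFrame
    env: pd.DataFrame
    tree: dendropy.Tree
    newick: str
    record: dict
    images: dict = field(default_factory=dict)  # individual_id -> (image, roi)

    def write(self, out_dir):
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(out / "meta.csv", index=False)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.env.to_csv(out / "env.csv", index=False)
        (out / "tree.nwk").write_text(self.newick + "\n")
        rec = {k: v for k, v in self.record.items()}
        (out / "record.json").write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
        if self.images:
            import imageio.v3 as iio

            img_dir = out / "images"
            roi_dir = out / "rois"
            img_dir.mkdir(exist_ok=True)
            roi_dir.mkdir(exist_ok=True)
            for iid, (img, roi) in self.images.items():
                iio.imwrite(img_dir / f"{iid}.png", img)
                (roi_dir / f"{iid}.json").write_text(json.dumps(np.asarray(roi).tolist()))
        return out


def simulate_dataset(config: DatasetConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate the full synthetic bundle consumed by the pipeline.

    The planted effect structure: individual lightness increases with
    z-scored log island surface area (slope ``beta_lightness``); the mixing
    weight toward an atypical dark-blue colour decreases with log area
    (slope ``atypicality_slope``), so distance-to-centroids falls with island
    size; small-island individuals are uniformly coloured while large-island
    ones carry a spotted pattern. Residual site effects are drawn from the
    configured spatial covariance model.
    """
    if config is None:
        config = DatasetConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config object or keyword overrides, not both")
    config.validate()

    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ["tree", "traits_l", "traits_a", "traits_b", "sites", "field", "assign", "scenes"],
            ss.spawn(8),
        )
    }

    tree = simulate_tree(config.n_species, seed=seeds["tree"])
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    # --- sites and environmental covariates ---------------------------------
    rng = np.random.default_rng(seeds["sites"])
    n_sites = config.n_sites
    lon = rng.uniform(*LON_RANGE, n_sites)
    lat = rng.uniform(*LAT_RANGE, n_sites)
    is_island = np.zeros(n_sites, dtype=bool)
    is_island[: int(round(config.island_fraction * n_sites))] = True
    rng.shuffle(is_island)
    area = np.where(
        is_island,
        10 ** rng.uniform(-2, 5, n_sites),
        10 ** rng.uniform(5, np.log10(5e6), n_sites),
    )
    dist_mainland = np.where(is_island, 10 ** rng.uniform(-1, np.log10(200), n_sites), 0.0)
    sea_depth = np.where(is_island, 8.0 * dist_mainland + rng.uniform(5, 300, n_sites), 0.0)
    land_buffer = 10 ** rng.uniform(0, 3.9, n_sites)
    temperature = 28.0 - 0.45 * (lat - LAT_RANGE[0]) + rng.normal(0, 1.5, n_sites)
    precipitation = 10 ** rng.uniform(np.log10(200), np.log10(1500), n_sites)
    z_logarea = (np.log10(area) - np.log10(area).mean()) / np.log10(area).std(ddof=1)

    # --- species-level phylogenetic colour deviations ------------------------
    def species_offsets(seed):
        df = simulate_lambda_traits(
            tree, config.true_lambda, sigma2=config.sigma2_species, n_per_species=1, seed=seed
        )
        return dict(zip(df["species"], df["species_mean"]))

    off_l = species_offsets(seeds["traits_l"])
    off_a = species_offsets(seeds["traits_a"])
    off_b = species_offsets(seeds["traits_b"])
    basic = {sp: (GREEN_LAB if i % 2 == 0 else BROWN_LAB) for i, sp in enumerate(species)}

    # --- site-level spatial residual fields ----------------------------------
    coords = np.column_stack([lon, lat])
    fields = {}
    for i, name in enumerate(["l", "w"]):
        fields[name] = simulate_spatial_field(
            coords,
            family=config.spatial_family,
            range_km=config.spatial_range_km,
            nugget=config.spatial_nugget,
            sill=config.spatial_sill,
            seed=seeds["field"] + i,
        )

    # --- individuals ----------------------------------------------------------
    rng = np.random.default_rng(seeds["assign"])
    n = config.n_individuals
    sp_idx = np.concatenate(
        [np.arange(config.n_species), rng.integers(0, config.n_species, n - config.n_species)]
    )
    rng.shuffle(sp_idx)
    site_idx = rng.integers(0, n_sites, n)

    meta_rows, sample_rows, env_rows = [], [], []
    images = {}
    scene_rng = np.random.default_rng(seeds["scenes"])
    atypical = np.asarray(ATYPICAL_LAB)
    for i in range(n):
        sp = species[sp_idx[i]]
        s = site_idx[i]
        iid = f"ind{i + 1:04d}"
        base = np.asarray(basic[sp], dtype=float)
        base = base + np.array([off_l[sp], off_a[sp], off_b[sp]])
        base[0] += config.beta_lightness * z_logarea[s] + fields["l"][s]
        w = float(
            np.clip(
                config.atypicality_base
                - config.atypicality_slope * z_logarea[s]
                + 0.05 * fields["w"][s]
                + config.individual_sd / 30.0 * rng.standard_normal(),
                0.0,
                0.9,
            )
        )
        colour = (1.0 - w) * base + w * atypical
        colour[0] += config.individual_sd * rng.standard_normal()
        colour[0] = float(np.clip(colour[0], 5.0, 95.0))
        uniform = w > 0.25  # atypical small-island animals lose the disruptive pattern
        pattern_col = np.asarray(BROWN_LAB if basic[sp] is GREEN_LAB else GREEN_LAB, dtype=float)
        pattern_col = (1.0 - w) * pattern_col + w * atypical
        coverage = 0.0 if uniform else config.pattern_coverage

        if config.render_images:
            spec = SceneSpec(
                width=config.image_size[0],
                height=config.image_size[1],
                base_lab=tuple(np.clip(colour, (3, -85, -85), (97, 85, 85))),
                pattern="uniform" if uniform else "spotted",
                pattern_lab=None if uniform else tuple(np.clip(pattern_col, (3, -85, -85), (97, 85, 85))),
                coverage=coverage,
                noise_sd=config.sample_sd,
                seed=int(scene_rng.integers(2**31 - 1)),
            )
            try:
                img, roi, _ = render_scene(spec)
            except GamutError:
                # pull the colour toward mid-grey until it fits the gamut
                for shrink in (0.8, 0.6, 0.4):
                    try:
                        spec2 = SceneSpec(
                            width=spec.width,
                            height=spec.height,
                            base_lab=tuple(np.array([50, 0, 0]) + shrink * (np.array(spec.base_lab) - [50, 0, 0])),
                            pattern=spec.pattern,
                            pattern_lab=None
                            if spec.pattern_lab is None
                            else tuple(np.array([50, 0, 0]) + shrink * (np.array(spec.pattern_lab) - [50, 0, 0])),
                            coverage=spec.coverage,
                            noise_sd=spec.noise_sd,
                            seed=spec.seed,
                        )
                        img, roi, _ = render_scene(spec2)
                        break
                    except GamutError:
                        continue
                else:
                    raise
            images[iid] = (img, roi)
        else:
            k = config.n_samples_per_individual
            is_pattern = scene_rng.random(k) < coverage
            pts = np.where(is_pattern[:, None], pattern_col[None, :], colour[None, :])
            pts = pts + config.sample_sd * scene_rng.standard_normal((k, 3))
            for j in range(k):
                sample_rows.append(
                    {
                        "individual_id": iid,
                        "species": sp,
                        "point": j + 1,
                        "l": float(pts[j, 0]),
                        "a": float(pts[j, 1]),
                        "b": float(pts[j, 2]),
                    }
                )

        meta_rows.append(
            {
                "individual_id": iid,
                "species": sp,
                "image_path": f"images/{iid}.png" if config.render_images else "",
                "roi_path": f"rois/{iid}.json" if config.render_images else "",
                "lon": float(lon[s]),
                "lat": float(lat[s]),
                "georef_error_m": float(rng.uniform(5, 900)),
                "source": "author" if rng.random() < 0.05 else "community",
                "qc_taxon_ok": True,
                "qc_exposure_ok": True,
                "qc_sharp_ok": True,
                "qc_live_ok": True,
                "true_mix_weight": w,
                "true_uniform": bool(uniform),
                "true_base_l": float(colour[0]),
                "true_base_a": float(colour[1]),
                "true_base_b": float(colour[2]),
            }
        )
        env_rows.append(
            {
                "individual_id": iid,
                "surface_area": float(area[s]),
                "dist_mainland": float(dist_mainland[s]),
                "sea_depth": float(sea_depth[s]),
                "land_buffer": float(land_buffer[s]),
                "temperature": float(temperature[s]),
                "precipitation": float(precipitation[s]),
                "lon": float(lon[s]),
                "lat": float(lat[s]),
                "is_island": bool(is_island[s]),
            }
        )

    individuals = pd.DataFrame(meta_rows)
    samples = pd.DataFrame(sample_rows)
    env = pd.DataFrame(env_rows)
    missing = set(species) - set(individuals["species"])
    if missing:
        raise LabellingError(f"species with no individuals: {sorted(missing)}")

    record = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "seeds": seeds,
        "true_lambda": config.true_lambda,
        "beta_lightness_per_sd_logarea": config.beta_lightness,
        "atypicality_slope_per_sd_logarea": config.atypicality_slope,
        "spatial": {
            "family": config.spatial_family,
            "range_km": config.spatial_range_km,
            "nugget": config.spatial_nugget,
            "sill": config.spatial_sill,
        },
        "basic_colors_lab": {"green": list(GREEN_LAB), "brown": list(BROWN_LAB)},
        "atypical_color_lab": list(ATYPICAL_LAB),
    }
    return SimulatedDataset(
        individuals=individuals,
        samples=samples,
        env=env,
        tree=tree,
        newick=tree_to_newick(tree),
        record=record,
        images=images,
    )
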
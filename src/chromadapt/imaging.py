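"""Image intake: QC filtering, ROI point sampling, CIELAB conversion, profiles.

Each photographed individual contributes 10 random points drawn inside a
manually delimited dorsal region of interest (the rectangle between the
cephalic scales and the hind-leg base, bounded by the costal sides). The
pixel colours at those points are converted from 8-bit sRGB to CIELAB
(D65 white point, 2° observer — the de-facto standard for consumer
photographs) and averaged per axis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import lab2rgb, rgb2lab
from skimage.draw import polygon as _raster_polygon

from .exceptions import GeometryError, SamplingError

__all__ = [
    "QCRecord",
    "qc_filter",
    "sample_roi_points",
    "srgb_to_cielab",
    "cielab_to_srgb",
    "ColorSample",
    "IndividualProfile",
    "extract_profile",
    "profiles_to_frame",
    "read_roi",
]

#: curator-verified criteria, in the order they are reported
QC_FLAG_COLUMNS = {
    "qc_taxon_ok": "criterion (1): taxonomic identity verifiable",
    "qc_exposure_ok": "criterion (2): no extreme under/over-exposure",
    "qc_sharp_ok": "criterion (3): not blurry or grossly pixelated",
    "qc_live_ok": "criterion (5): live, unpreserved animal",
}
MAX_GEOREF_ERROR_M = 1000.0


@dataclass
class QCRecord:
    """Outcome of the image quality filters for one metadata row."""

    flags: dict
    passed: bool
    reasons: list = field(default_factory=list)


def qc_filter(row) -> QCRecord:
    """Apply the minimum-requirement filters to one metadata row.

    Criteria (1), (2), (3) and (5) are curator-supplied booleans; criterion
    (4) — georeferencing error at most 1000 m — is the only computed check.
    A missing georeferencing error fails as unverifiable.
    """
    flags = {}
    reasons = []
    for col, desc in QC_FLAG_COLUMNS.items():
        ok = bool(row.get(col, False)) if hasattr(row, "get") else bool(getattr(row, col, False))
        flags[col] = ok
        if not ok:
            reasons.append(f"failed {desc}")
    err = row.get("georef_error_m") if hasattr(row, "get") else getattr(row, "georef_error_m", None)
    if err is None or (isinstance(err, float) and np.isnan(err)):
        flags["qc_georef_ok"] = False
        reasons.append("criterion (4) unverifiable: georeferencing error missing")
    else:
        ok = float(err) <= MAX_GEOREF_ERROR_M
        flags["qc_georef_ok"] = ok
        if not ok:
            reasons.append(
                f"failed criterion (4): georeferencing error {float(err):g} m > {MAX_GEOREF_ERROR_M:g} m"
            )
    return QCRecord(flags=flags, passed=not reasons, reasons=reasons)


def _polygon_pixels(shape, roi):
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[1] != 2 or roi.shape[0] < 3:
        raise GeometryError("ROI must be a polygon of at least 3 (x, y) vertices")
    h, w = shape[:2]
    if roi[:, 0].min() < 0 or roi[:, 1].min() < 0 or roi[:, 0].max() > w - 1 or roi[:, 1].max() > h - 1:
        raise GeometryError("ROI polygon extends outside the image")
    rr, cc = _raster_polygon(roi[:, 1], roi[:, 0], shape=(h, w))
    return cc, rr  # x, y


def sample_roi_points(image, roi, n: int = 10, seed: int | None = None):
    """Draw ``n`` distinct pixels uniformly at random strictly inside the ROI.

    Points are sampled without replacement at pixel resolution and are
    deterministic for a fixed seed.

    Returns an (n, 2) integer array of (x, y) pixel coordinates.
    """
    xs, ys = _polygon_pixels(np.asarray(image).shape, roi)
    m = xs.size
    if m < n:
        raise SamplingError(f"ROI contains {m} pixels; {n} distinct points requested")
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=n, replace=False)
    return np.column_stack([xs[idx], ys[idx]]).astype(int)


def srgb_to_cielab(rgb):
    """Convert 8-bit sRGB channels to CIELAB (D65, 2° observer).

    Accepts a single (r, g, b) triplet or an (..., 3) array of uint8 values.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("sRGB input must have a trailing axis of length 3")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("sRGB channels must lie in [0, 255]")
    lab = rgb2lab(arr / 255.0)
    return lab


def cielab_to_srgb(lab, clip: bool = False):
    """Convert CIELAB to 8-bit sRGB. With ``clip=False`` out-of-gamut values
    raise nothing here; callers check gamut explicitly (see simulate module).
    """
    rgb = lab2rgb(np.asarray(lab, dtype=float))  # lab2rgb clips internally
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return np.round(rgb * 255.0).astype(np.uint8)


@dataclass
class ColorSample:
    """One CIELAB triplet sampled at a pixel."""

    l: float
    a: float
    b: float
    x: int
    y: int


@dataclass
class IndividualProfile:
    """An individual's 10 colour samples plus metadata and per-axis means."""

    individual_id: str
    species: str
    lon: float
    lat: float
    georef_error_m: float
    source: str
    samples: list  # of ColorSample
    mean_l: float
    mean_a: float
    mean_b: float
    seed: int | None = None
    image_sha256: str | None = None

    @property
    def mean_lab(self):
        return np.array([self.mean_l, self.mean_a, self.mean_b])

    def sample_array(self):
        return np.array([[s.l, s.a, s.b] for s in self.samples])


def extract_profile(image, roi, metadata, n: int = 10, seed: int | None = None) -> IndividualProfile:
    """Sample ``n`` ROI points of one image and build the colour profile.

    ``metadata`` is a mapping with at least individual_id, species, lon, lat,
    georef_error_m and source. The image SHA-256 is recorded for provenance.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("image must be 8-bit sRGB")
    pts = sample_roi_points(image, roi, n=n, seed=seed)
    lab = srgb_to_cielab(image[pts[:, 1], pts[:, 0], :3])
    samples = [
        ColorSample(float(t[0]), float(t[1]), float(t[2]), int(x), int(y))
        for t, (x, y) in zip(lab, pts)
    ]
    means = lab.mean(axis=0)
    get = metadata.get if hasattr(metadata, "get") else lambda k, d=None: getattr(metadata, k, d)
    return IndividualProfile(
        individual_id=str(get("individual_id")),
        species=str(get("species")),
        lon=float(get("lon")),
        lat=float(get("lat")),
        georef_error_m=float(get("georef_error_m", np.nan)),
        source=str(get("source", "community")),
        samples=samples,
        mean_l=float(means[0]),
        mean_a=float(means[1]),
        mean_b=float(means[2]),
        seed=seed,
        image_sha256=hashlib.sha256(image.tobytes()).hexdigest(),
    )


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format table of sampled colours: one row per individual × point."""
    rows = []
    for p in profiles:
        for i, s in enumerate(p.samples, start=1):
            rows.append(
                {
                    "individual_id": p.individual_id,
                    "species": p.species,
                    "lon": p.lon,
                    "lat": p.lat,
                    "source": p.source,
                    "point": i,
                    "l": s.l,
                    "a": s.a,
                    "b": s.b,
                    "mean_l": p.mean_l,
                    "mean_a": p.mean_a,
                    "mean_b": p.mean_b,
                }
            )
    return pd.DataFrame(rows)


def read_roi(path) -> np.ndarray:
    """Read an ROI polygon JSON (list of [x, y] pixel vertices, origin top-left)."""
    with open(path) as fh:
        verts = json.load(fh)
    return np.asarray(verts, dtype=float)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as an 8-bit RGB array."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.uint8)
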
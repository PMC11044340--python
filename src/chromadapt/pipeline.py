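"""End-to-end orchestration: QC → extraction → metrics → λ → GLS → PCA.

The pipeline consumes a data directory (simulated or curated) holding
``meta.csv``, ``env.csv``, ``tree.nwk`` and either ``samples.csv`` (direct
colour samples) or ``images/`` + ``rois/``, and writes the analysis tables:

* ``table1.csv`` — resampled Pagel's λ per chromatic variable;
* ``table2.csv`` / ``candidates.csv`` — AICc-selected spatial structures;
* ``table3.csv`` — coefficients with raw and Bonferroni-adjusted p-values;
* ``pca.csv`` / ``pca_scores.csv`` — log-PCA variance fractions and scores;
* ``manifest.json`` — seeds, input hashes and stage record for reproduction.

Display tables are rounded to 4 decimals; a full-precision twin is written
next to each (``*_raw.csv``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import imaging, metrics, ordination, phylo
from .exceptions import ChromadaptError
from .gls import DEFAULT_MODEL_SPECS, run_model_suite

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "compute_statistics"]

CHROMATIC_VARIABLES = ["mean_l", "mean_a", "mean_b", "dist_centroid", "contrast"]


class PipelineStageError(ChromadaptError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serialisable to/from JSON or YAML."""

    data_dir: str
    out_dir: str
    seed: int = 0
    trim: float = 0.05
    aggregation: str = "nearest"
    centroid_restarts: int = 20
    n_resamples: int = 10_000
    alpha: float = 0.05
    lambda_negligible_below: float = 0.25
    model_specs: dict | None = None
    pca_variables: str = "color+env"  # or "color"

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tables(df: pd.DataFrame, out: Path, name: str):
    df.to_csv(out / f"{name}.csv", index=False, float_format="%.4f")
    df.to_csv(out / f"{name}_raw.csv", index=False)


def _extract_profiles(data_dir: Path, meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Long table of sampled colours, from images or from direct samples."""
    samples_path = data_dir / "samples.csv"
    meta = meta.sort_values("individual_id", kind="stable")
    if (data_dir / "images").is_dir():
        children = np.random.SeedSequence(seed).spawn(len(meta))
        profiles = []
        for child, (_, row) in zip(children, meta.iterrows()):
            img = imaging.read_image(data_dir / row["image_path"])
            roi = imaging.read_roi(data_dir / row["roi_path"])
            profiles.append(
                imaging.extract_profile(
                    img, roi, row, seed=int(child.generate_state(1)[0] % (2**31 - 1))
                )
            )
        return imaging.profiles_to_frame(profiles)
    if samples_path.exists():
        samples = pd.read_csv(samples_path)
        merged = samples.merge(
            meta[["individual_id", "lon", "lat", "source"]], on="individual_id", how="inner"
        )
        g = merged.groupby("individual_id")[["l", "a", "b"]].transform("mean")
        merged[["mean_l", "mean_a", "mean_b"]] = g
        return merged
    raise FileNotFoundError(f"{data_dir} holds neither images/ nor samples.csv")


def compute_statistics(
    profiles: pd.DataFrame,
    trim: float = 0.05,
    aggregation: str = "nearest",
    n_restarts: int = 20,
    seed: int | None = None,
):
    """Per-individual chromatic statistics from the long profile table.

    Pools every sampled colour, fits the two-centroid genus colour model and
    returns (stats, model) where stats has one row per individual with the
    CIELAB means, distance-to-centroids and colour contrast.
    """
    pool = profiles[["l", "a", "b"]].to_numpy(dtype=float)
    model = metrics.ColorCentroids(
        trim=trim, aggregation=aggregation, n_restarts=n_restarts, random_state=seed
    ).fit(pool)
    rows = []
    for iid, grp in profiles.groupby("individual_id", sort=True):
        lab = grp[["l", "a", "b"]].to_numpy(dtype=float)
        mean = lab.mean(axis=0)
        rows.append(
            {
                "individual_id": iid,
                "species": grp["species"].iloc[0],
                "lon": grp["lon"].iloc[0],
                "lat": grp["lat"].iloc[0],
                "mean_l": mean[0],
                "mean_a": mean[1],
                "mean_b": mean[2],
                "dist_centroid": model.centroid_distance(mean),
                "contrast": metrics.color_contrast(lab),
            }
        )
    return pd.DataFrame(rows), model


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of output DataFrames.

    Any stage failure halts the run with the stage name; outputs written by
    earlier stages are preserved.
    """
    data_dir = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {
            p.name: _sha256(p) for p in sorted(data_dir.glob("*.csv")) if p.is_file()
        },
        "stages": [],
    }
    results: dict = {}
    stage = "qc"
    try:
        meta = pd.read_csv(data_dir / "meta.csv")
        records = [imaging.qc_filter(row) for _, row in meta.iterrows()]
        keep = [r.passed for r in records]
        meta_pass = meta[keep].reset_index(drop=True)
        qc = meta.assign(
            qc_pass=keep, qc_reasons=["; ".join(r.reasons) for r in records]
        )[["individual_id", "qc_pass", "qc_reasons"]]
        _write_tables(qc, out, "qc")
        results["qc"] = qc
        manifest["stages"].append({"stage": stage, "n_pass": int(sum(keep)), "n_total": len(meta)})

        stage = "extract"
        profiles = _extract_profiles(data_dir, meta_pass, config.seed)
        profiles = profiles[profiles["individual_id"].isin(meta_pass["individual_id"])]
        _write_tables(profiles, out, "profiles")
        results["profiles"] = profiles
        manifest["stages"].append({"stage": stage, "n_individuals": profiles["individual_id"].nunique()})

        stage = "metrics"
        stats, model = compute_statistics(
            profiles,
            trim=config.trim,
            aggregation=config.aggregation,
            n_restarts=config.centroid_restarts,
            seed=config.seed,
        )
        _write_tables(stats, out, "stats")
        (out / "centroid_model.json").write_text(json.dumps(model.to_dict(), sort_keys=True))
        results["stats"] = stats
        results["centroid_model"] = model
        manifest["stages"].append({"stage": stage, "centroids": model.centroids_.tolist()})

        stage = "lambda"
        tree = dendropy.Tree.get(path=str(data_dir / "tree.nwk"), schema="newick")
        stats_sp = stats.merge(
            pd.read_csv(data_dir / "meta.csv")[["individual_id"]], on="individual_id"
        )
        t1_rows = []
        lam_children = np.random.SeedSequence(config.seed).spawn(len(CHROMATIC_VARIABLES))
        for child, var in zip(lam_children, CHROMATIC_VARIABLES):
            summ = phylo.resample_lambda(
                tree,
                stats_sp,
                var,
                n_resamples=config.n_resamples,
                alpha=config.alpha,
                seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            )
            t1_rows.append(
                {
                    "variable": var,
                    "mean_lambda": summ.mean_lambda,
                    "se_lambda": summ.se_lambda,
                    "pct_significant": summ.pct_significant,
                    "n_resamples": summ.n_resamples,
                }
            )
        table1 = pd.DataFrame(t1_rows)
        _write_tables(table1, out, "table1")
        results["table1"] = table1
        negligible = bool((table1["mean_lambda"] < config.lambda_negligible_below).all())
        manifest["stages"].append({"stage": stage, "phylogenetic_signal_negligible": negligible})

        stage = "gls"
        env = pd.read_csv(data_dir / "env.csv")
        table2, table3, candidates = run_model_suite(
            stats, env, model_specs=config.model_specs
        )
        _write_tables(table2, out, "table2")
        _write_tables(table3, out, "table3")
        _write_tables(candidates, out, "candidates")
        results.update(table2=table2, table3=table3, candidates=candidates)
        manifest["stages"].append({"stage": stage, "n_models": len(table2)})

        stage = "pca"
        if config.pca_variables == "color":
            pca_df = stats[["mean_l", "mean_a", "mean_b"]]
        else:
            pca_df = stats[["individual_id", "mean_l", "mean_a", "mean_b"]].merge(
                env[
                    [
                        "individual_id",
                        "surface_area",
                        "dist_mainland",
                        "sea_depth",
                        "land_buffer",
                        "temperature",
                        "precipitation",
                    ]
                ],
                on="individual_id",
            ).drop(columns="individual_id")
        ord_res = ordination.log_pca(pca_df)
        pca_tab = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(ord_res.explained_variance_ratio))],
                "variance_fraction": ord_res.explained_variance_ratio,
                "cumulative": ord_res.cumulative_explained,
            }
        )
        _write_tables(pca_tab, out, "pca")
        _write_tables(ord_res.loadings.reset_index(names="component"), out, "pca_loadings")
        scores = pd.DataFrame(
            ord_res.scores, columns=[f"PC{i + 1}" for i in range(ord_res.scores.shape[1])]
        )
        _write_tables(scores, out, "pca_scores")
        results["pca"] = ord_res
        manifest["stages"].append(
            {"stage": stage, "explained_3": float(ord_res.cumulative_explained[min(2, len(ord_res.cumulative_explained) - 1)])}
        )
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineStageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
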
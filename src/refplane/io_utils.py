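"""Manifests, tables, configuration, and the staged pipeline runner.

A dataset manifest is a CSV (or JSON records) table with one row per
acquired image: ``experiment, exposure_ms, fov, z_um, path`` and an
optional ``true_dz_um`` column for synthetic data.  The key
(experiment, exposure_ms, fov, z_um) must be unique and every path must
resolve when the manifest is loaded.

All tables are comma-separated UTF-8 CSV with a header and '.' decimals;
nested artifacts (predictions, model sidecars) are JSON.  Logging is
structured ``key=value`` lines at INFO with per-bead detail at DEBUG.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

logger = logging.getLogger("refplane")

MANIFEST_COLUMNS = ["experiment", "exposure_ms", "fov", "z_um", "path"]


class ManifestError(ValueError):
    """Raised when a manifest fails validation."""


def read_image(path: str) -> np.ndarray:
    """Read an 8-bit grayscale TIFF or PNG as a 2-D uint8 array."""
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse an accidental single channel
        img = img[..., 0]
    return img.astype(np.uint8)


def load_manifest(path: str, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest (CSV or JSON records)."""
    if not os.path.exists(path):
        raise ManifestError(f"manifest not found: {path}")
    try:
        if path.lower().endswith(".json"):
            df = pd.read_json(path)
        else:
            df = pd.read_csv(path)
    except (ValueError, pd.errors.EmptyDataError) as err:
        raise ManifestError(f"cannot parse manifest {path}: {err}") from err
    if df.empty:
        raise ManifestError(f"manifest {path} has no rows")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing columns {missing}")
    key = ["experiment", "exposure_ms", "fov", "z_um"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = df[dup].iloc[0]
        raise ManifestError(
            f"duplicate manifest key {tuple(row[k] for k in key)} (row {dup.idxmax()})"
        )
    if check_paths:
        base = os.path.dirname(os.path.abspath(path))
        resolved = []
        for i, p in enumerate(df["path"]):
            full = p if os.path.isabs(p) else os.path.join(base, p)
            if not os.path.exists(full):
                raise ManifestError(f"manifest row {i}: image not found: {p}")
            resolved.append(full)
        df = df.assign(path=resolved)
    return df.sort_values(key).reset_index(drop=True)


def load_images(manifest: pd.DataFrame) -> dict:
    """Images keyed by (experiment, exposure_ms, fov, z_um)."""
    return {
        (r.experiment, float(r.exposure_ms), int(r.fov), float(r.z_um)):
            read_image(r.path)
        for r in manifest.itertuples()
    }


def load_config(path: str) -> dict:
    """Load a YAML (or JSON) pipeline configuration."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_prediction(pred, path: str) -> None:
    """Serialize a DZPrediction to JSON."""
    payload = {
        "dz_final": pred.dz_final,
        "per_model_mean": list(map(float, pred.per_model_mean)),
        "per_bead_per_model": pred.per_bead_per_model.tolist(),
        "out_of_range": bool(pred.out_of_range),
        "models_all_outliers": list(pred.models_all_outliers),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run simulate -> detect/features -> refp -> train -> predict.

    ``config`` mirrors the CLI: a ``seed``, a ``sweep`` section
    (SweepSpec fields), optional ``optical`` overrides (OpticalModel
    fields), a ``training`` section (TrainingConfig fields), and a
    ``predict`` section (``n_beads`` per acquisition).  Stages execute in
    order; each stage logs its counts and writes its artifact below
    ``outdir``.  A stage failure aborts the run with the stage name, and
    re-running with the same config and seed reproduces every artifact.
    Returns the artifact paths.
    """
    from . import dzreg, refp, synth
    from .profile import extract_sweep_features

    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}
    seed = int(config.get("seed", 0))

    stage = "simulate"
    try:
        optical = synth.OpticalModel(**config.get("optical", {}))
        sweep_cfg = dict(config["sweep"])
        sweep_cfg.setdefault("seed", seed)
        sweep_cfg["exposures"] = tuple(sweep_cfg.get("exposures", (6.0, 9.0, 12.0)))
        spec = synth.SweepSpec(**sweep_cfg)
        sim_dir = os.path.join(outdir, "images")
        manifest_path = synth.generate_sweep(spec, optical, sim_dir)
        artifacts["manifest"] = manifest_path
        manifest = load_manifest(manifest_path)
        images = load_images(manifest)
        logger.info("stage=simulate images=%d", len(images))

        stage = "detect"
        features, tiles = extract_sweep_features(images)
        features_path = os.path.join(outdir, "features.csv")
        features.to_csv(features_path, index=False)
        artifacts["features"] = features_path
        logger.info("stage=detect beads=%d", len(features))

        stage = "refp"
        refp_table, _ = refp.estimate_refp(features)
        refp_path = os.path.join(outdir, "refp.csv")
        refp_table.to_csv(refp_path, index=False)
        artifacts["refp"] = refp_path
        logger.info("stage=refp curves=%d refp_median=%.2f",
                    len(refp_table), refp.sweep_refp(refp_table))

        stage = "train"
        tcfg = dzreg.reduced_config(**config.get("training", {}))
        tcfg = dzreg.replace(tcfg, seed=seed)
        X, y, _ = dzreg.make_training_set(features, tiles, refp_table)
        models = dzreg.train_ensemble(X, y, tcfg)
        model_dir = os.path.join(outdir, "models")
        dzreg.save_models(models, model_dir)
        artifacts["models"] = model_dir
        logger.info("stage=train models=%d val_rmse=%s", len(models),
                    [round(m.best_val_rmse, 2) for m in models])

        stage = "predict"
        n_beads = int(config.get("predict", {}).get("n_beads", 6))
        rng = np.random.default_rng(seed + 10_000)
        group_cols = ["experiment", "exposure_ms", "fov", "z_um"]
        rows = []
        for key, g in features.groupby(group_cols, sort=True):
            idx = g.index.to_numpy()
            if len(idx) > n_beads:
                idx = rng.choice(idx, size=n_beads, replace=False)
            batch = np.stack([np.asarray(tiles[i].pixels, np.float32) for i in idx])
            pred = dzreg.predict_dz(models, batch)
            rows.append(dict(zip(group_cols, key), dz_final=pred.dz_final,
                             out_of_range=pred.out_of_range, n_beads=len(idx)))
        pred_path = os.path.join(outdir, "predictions.csv")
        pd.DataFrame(rows).to_csv(pred_path, index=False)
        artifacts["predictions"] = pred_path
        logger.info("stage=predict acquisitions=%d", len(rows))
    except Exception as err:
        logger.error("stage=%s failed error=%s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return artifacts
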
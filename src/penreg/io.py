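"""File formats: images, landmark tables, fields, homographies, checkpoints.

Images are PNG/TIFF, 8- or 16-bit, normalized to [0, 1] on load. Landmark
tables are CSV with columns ``pair_id, fixed_x, fixed_y, moving_x,
moving_y, label``. Deformation fields are NPZ archives with ``dx``/``dy``
planes and a JSON-serializable header; model checkpoints are single NPZ
files bundling the architecture config and every parameter.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .homography import Homography, PairedLandmarks
from .nn import NetworkConfig, RegistrationModel, build_network

__all__ = [
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_field",
    "write_field",
    "read_homography",
    "write_homography",
    "save_checkpoint",
    "load_checkpoint",
    "flow_to_rgb",
    "load_manifest_records",
]

CHECKPOINT_VERSION = 1


def read_image(path) -> np.ndarray:
    """Load a grayscale (or RGB, luma-converted) image normalized to [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        from .preprocess import to_grayscale

        arr = arr[..., :3]
        peak = 65535.0 if arr.dtype == np.uint16 else 255.0
        return to_grayscale(arr.astype(float) / peak)
    peak = 65535.0 if arr.dtype == np.uint16 else (255.0 if arr.dtype == np.uint8 else 1.0)
    return arr.astype(float) / peak


def write_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit PNG (grayscale) or 8-bit (RGB)."""
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    path = Path(path)
    if img.ndim == 3:
        iio.imwrite(path, (img * 255).round().astype(np.uint8))
    else:
        iio.imwrite(path, (img * 65535).round().astype(np.uint16))


def write_landmarks(path, lms: PairedLandmarks) -> None:
    df = pd.DataFrame(
        {
            "pair_id": np.arange(len(lms)),
            "fixed_x": lms.fixed_points[:, 0],
            "fixed_y": lms.fixed_points[:, 1],
            "moving_x": lms.moving_points[:, 0],
            "moving_y": lms.moving_points[:, 1],
            "label": lms.labels,
        }
    )
    df.to_csv(path, index=False)


def read_landmarks(path) -> PairedLandmarks:
    df = pd.read_csv(path)
    required = {"fixed_x", "fixed_y", "moving_x", "moving_y"}
    if not required <= set(df.columns):
        raise ValueError(f"landmark CSV {path} missing columns {required - set(df.columns)}")
    labels = list(df["label"]) if "label" in df.columns else []
    return PairedLandmarks(
        df[["fixed_x", "fixed_y"]].to_numpy(float),
        df[["moving_x", "moving_y"]].to_numpy(float),
        labels,
    )


def write_field(path, field: np.ndarray) -> None:
    field = np.asarray(field, dtype=float)
    header = {"height": field.shape[0], "width": field.shape[1], "channels": ["dx", "dy"]}
    np.savez(path, dx=field[:, :, 0], dy=field[:, :, 1], header=json.dumps(header))


def read_field(path) -> np.ndarray:
    with np.load(path, allow_pickle=False) as z:
        return np.stack([z["dx"], z["dy"]], axis=-1)


def write_homography(path, h: Homography) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": h.matrix.tolist()}, fh, indent=1)


def read_homography(path) -> Homography:
    with open(path) as fh:
        d = json.load(fh)
    return Homography(np.asarray(d["matrix"], dtype=float))


def save_checkpoint(path, model: RegistrationModel, extra: dict | None = None) -> None:
    """Single-file archive of config + theta (+ optional metadata)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "training_phase": model.training_phase,
        "extra": extra or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **model.net.params())


def load_checkpoint(path) -> RegistrationModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        params = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_network(NetworkConfig.from_dict(meta["config"]), seed=0)
    model.net.set_params(params)
    model.training_phase = meta["training_phase"]
    return model


def flow_to_rgb(field: np.ndarray, max_norm: float | None = None) -> np.ndarray:
    """HSV flow coloring: hue = direction, saturation = magnitude."""
    from matplotlib.colors import hsv_to_rgb

    field = np.asarray(field, dtype=float)
    dx, dy = field[:, :, 0], field[:, :, 1]
    mag = np.hypot(dx, dy)
    if max_norm is None:
        max_norm = max(mag.max(), 1e-9)
    hsv = np.stack(
        [
            (np.arctan2(dy, dx) / (2 * np.pi)) % 1.0,
            np.clip(mag / max_norm, 0, 1),
            np.ones_like(mag),
        ],
        axis=-1,
    )
    return hsv_to_rgb(hsv)


def load_manifest_records(manifest_path, split: str) -> list:
    """Load (fixed, moving, landmarks) records for one split of a dataset."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    records = []
    for rec in manifest["splits"][split]:
        fixed = read_image(base / rec["fixed"])
        moving = read_image(base / rec["moving"])
        lms = read_landmarks(base / rec["landmarks"]) if rec.get("landmarks") else None
        records.append((fixed, moving, lms))
    return records
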
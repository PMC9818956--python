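"""Synthetic paired-view pen scenes with known ground-truth geometry.

The farm recordings behind this problem are not public, so every stage of
the pipeline is exercised on generated scenes that emulate their structure:
a dark textured floor, a handful of brighter textured elliptical blobs
standing in for the animals, two views related by a projective transform
plus a smooth non-linear residual deformation, an affine illumination
difference between the views, and light sensor noise. Landmark pairs (3 on
blobs / "foreground", 3 on the floor / "background") are carried exactly
through the known transforms, so target registration errors have an exact
reference.

Geometry convention. The residual ground truth is the BACKWARD field
``Phi`` a perfect network should output for (fixed, moving_prereg): it
satisfies ``warp_image_dense(moving_prereg, Phi) == fixed`` by
construction. The pre-registered moving view is synthesized as
``fixed`` resampled through the numerically inverted map ``(id + Phi)^-1``,
and a fixed landmark ``p`` appears in the moving view at ``p + Phi(p)``.
The raw moving view additionally applies a random homography; undoing it
with the true homography simulates an ideal projective pre-registration.
All randomness flows from a single per-call seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .homography import (
    Homography,
    PairedLandmarks,
    fit_projective,
    map_points_projective,
    warp_image_projective,
)
from .warp import sample_field, warp_image_dense

__all__ = [
    "SceneConfig",
    "GroundTruthPair",
    "generate_scene",
    "generate_smooth_field",
    "generate_view_pair",
    "generate_pairs",
    "generate_dataset",
]


@dataclass
class SceneConfig:
    """Scene-generator parameters.

    ``n_animals`` defaults to 10, matching a typical pen occupancy of
    10-11 animals; blob sizes scale with the frame so the same config
    works at 64 x 64 (tests) and larger frames.
    """

    size: tuple[int, int] = (64, 64)
    n_animals: int = 10
    floor_texture_scale: float = 3.0
    illumination_delta: float = 0.1
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        h, w = self.size
        if h < 8 or w < 8:
            raise ValueError("scene too small")


@dataclass
class GroundTruthPair:
    """A fixed/moving view pair with exact ground-truth geometry."""

    fixed: np.ndarray
    moving_raw: np.ndarray
    moving_prereg: np.ndarray
    true_homography: Homography
    true_residual_field: np.ndarray
    landmarks: PairedLandmarks          # fixed vs moving_prereg coordinates
    raw_moving_points: np.ndarray       # same landmarks on moving_raw

    @property
    def prereg_tre(self) -> float:
        """Mean landmark error left after (ideal) projective pre-registration."""
        d = self.landmarks.moving_points - self.landmarks.fixed_points
        return float(np.linalg.norm(d, axis=1).mean())


def _smooth_noise(rng, shape, sigma):
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = n.std()
    return n / s if s > 0 else n


def generate_scene(cfg: SceneConfig, rng: np.random.Generator | None = None):
    """Dark textured floor plus brighter textured elliptical blobs.

    Returns ``(image, blobs)`` where ``blobs`` is a list of dicts with
    ``center`` (x, y), ``axes`` (a, b) and ``angle``. Blobs are placed
    without overlap; if a blob cannot be placed after 80 retries a warning
    is issued and the scene carries fewer blobs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = cfg.size
    floor = 0.22 + 0.06 * _smooth_noise(rng, (h, w), cfg.floor_texture_scale)
    img = floor.copy()

    scale = min(h, w)
    blobs = []
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(cfg.n_animals):
        placed = False
        for _try in range(80):
            a = rng.uniform(0.055, 0.10) * scale
            b = rng.uniform(0.55, 0.85) * a
            cx = rng.uniform(a + 1, w - a - 2)
            cy = rng.uniform(a + 1, h - a - 2)
            ang = rng.uniform(0, np.pi)
            ok = all(
                np.hypot(cx - bb["center"][0], cy - bb["center"][1])
                > (a + max(bb["axes"]) + 2)
                for bb in blobs
            )
            if ok:
                placed = True
                break
        if not placed:
            warnings.warn(
                f"placed only {len(blobs)} of {cfg.n_animals} blobs without overlap",
                stacklevel=2,
            )
            break
        ca, sa = np.cos(ang), np.sin(ang)
        xr = (xs - cx) * ca + (ys - cy) * sa
        yr = -(xs - cx) * sa + (ys - cy) * ca
        e = (xr / a) ** 2 + (yr / b) ** 2
        # soft edge ~1.5 px wide so intensity gradients exist for training
        wgt = np.clip((1.0 - e) / (3.0 / max(b, 1.0)), 0.0, 1.0)
        base = rng.uniform(0.55, 0.85)
        tex = base + 0.06 * _smooth_noise(rng, (h, w), 1.5)
        img = img * (1 - wgt) + tex * wgt
        blobs.append({"center": (cx, cy), "axes": (a, b), "angle": float(ang)})
    return np.clip(img, 0.0, 1.0), blobs


def generate_smooth_field(
    size: tuple[int, int],
    max_displacement: float,
    smoothness: float = 16.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random smooth H x W x 2 displacement field, max |component| bounded.

    Displacements are drawn on a coarse control grid with spacing
    ``smoothness`` (pixels), interpolated bicubically to the full grid and
    rescaled so no component exceeds ``max_displacement``. Wider spacing
    yields smoother fields (smaller diffusion energy).
    """
    if max_displacement < 0:
        raise ValueError("max_displacement must be >= 0")
    h, w = size
    if max_displacement == 0:
        return np.zeros((h, w, 2))
    if rng is None:
        rng = np.random.default_rng(seed)
    ny = max(4, int(round(h / smoothness)) + 1)
    nx = max(4, int(round(w / smoothness)) + 1)
    coarse = rng.uniform(-max_displacement, max_displacement, size=(ny, nx, 2))
    gy = np.linspace(0, h - 1, ny)
    gx = np.linspace(0, w - 1, nx)
    interp = RegularGridInterpolator((gy, gx), coarse, method="cubic")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    field = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(h, w, 2)
    peak = np.abs(field).max()
    if peak > max_displacement:
        field *= max_displacement / peak
    return field


def _invert_field(phi: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """G with (id + G) = (id + Phi)^-1 on the grid, by fixed-point iteration."""
    h, w = phi.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    p = pts.copy()
    for _ in range(n_iter):
        p = pts - sample_field(phi, p)
    g = (p - pts).reshape(h, w, 2)
    return g


def _random_homography(rng, size, magnitude) -> Homography:
    """Homography displacing the frame corners by up to ``magnitude`` px."""
    h, w = size
    if magnitude == 0:
        return Homography.identity()
    corners = np.array([[0, 0], [w - 1.0, 0], [w - 1.0, h - 1.0], [0, h - 1.0]])
    jitter = rng.uniform(-magnitude, magnitude, size=(4, 2))
    pairs = PairedLandmarks(corners, corners + jitter)
    return fit_projective(pairs)


def _sample_landmarks(rng, scene_shape, blobs, phi, n_fg=3, n_bg=3, margin=None):
    """Fixed-frame landmark positions: n_fg inside blobs, n_bg on the floor."""
    h, w = scene_shape
    if margin is None:
        margin = float(np.abs(phi).max()) + 3.0

    def in_blob(x, y):
        for bb in blobs:
            cx, cy = bb["center"]
            a, b = bb["axes"]
            ca, sa = np.cos(bb["angle"]), np.sin(bb["angle"])
            xr = (x - cx) * ca + (y - cy) * sa
            yr = -(x - cx) * sa + (y - cy) * ca
            if (xr / a) ** 2 + (yr / b) ** 2 < 0.8:
                return True
        return False

    pts, labels = [], []
    for want_fg in [True] * n_fg + [False] * n_bg:
        for _try in range(100):
            if want_fg and blobs:
                bb = blobs[rng.integers(len(blobs))]
                cx, cy = bb["center"]
                a, b = bb["axes"]
                x = cx + rng.uniform(-0.5, 0.5) * a
                y = cy + rng.uniform(-0.5, 0.5) * b
            else:
                x = rng.uniform(margin, w - 1 - margin)
                y = rng.uniform(margin, h - 1 - margin)
            inside = margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin
            if not inside:
                continue
            if want_fg and blobs and not in_blob(x, y):
                continue
            if not want_fg and in_blob(x, y):
                continue
            pts.append((x, y))
            labels.append("foreground" if (want_fg and blobs) else "background")
            break
        else:
            raise RuntimeError("could not place a landmark inside the frame after 100 attempts")
    return np.array(pts), labels


def generate_view_pair(
    cfg: SceneConfig,
    homography_magnitude: float = 8.0,
    residual_magnitude: float = 6.0,
    residual_smoothness: float = 16.0,
    seed: int | None = None,
) -> GroundTruthPair:
    """One fixed/moving pair with exact ground truth (see module docstring)."""
    if homography_magnitude < 0 or residual_magnitude < 0:
        raise ValueError("magnitudes must be non-negative")
    entropy = cfg.seed if seed is None else seed
    root = (
        entropy
        if isinstance(entropy, np.random.SeedSequence)
        else np.random.SeedSequence(entropy)
    )
    r_scene, r_field, r_hom, r_illum, r_lm = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    fixed, blobs = generate_scene(cfg, rng=r_scene)
    h, w = fixed.shape

    phi = generate_smooth_field((h, w), residual_magnitude, residual_smoothness, rng=r_field)
    if residual_magnitude == 0:
        prereg_geom = fixed.copy()
    else:
        g = _invert_field(phi)
        prereg_geom = warp_image_dense(fixed, g)

    hom = _random_homography(r_hom, (h, w), homography_magnitude)
    if homography_magnitude == 0:
        raw_geom = prereg_geom.copy()
    else:
        raw_geom = warp_image_projective(prereg_geom, hom.inverse())

    # affine illumination difference + light sensor noise on the moving view
    delta = cfg.illumination_delta
    gain = 1.0 + r_illum.uniform(-delta, delta)
    bias = r_illum.uniform(-delta / 2, delta / 2)

    def illum(img, rng):
        out = gain * img + bias
        if cfg.noise_sigma > 0:
            out = out + cfg.noise_sigma * rng.standard_normal(img.shape)
        return np.clip(out, 0.0, 1.0)

    if delta == 0 and cfg.noise_sigma == 0:
        moving_prereg, moving_raw = prereg_geom, raw_geom
    else:
        moving_prereg = illum(prereg_geom, r_illum)
        moving_raw = illum(raw_geom, r_illum)

    fixed_pts, labels = _sample_landmarks(r_lm, (h, w), blobs, phi)
    moving_pts = fixed_pts + sample_field(phi, fixed_pts)
    raw_pts = (
        map_points_projective(moving_pts, hom.inverse())
        if homography_magnitude > 0
        else moving_pts.copy()
    )
    lms = PairedLandmarks(fixed_pts, moving_pts, labels)
    return GroundTruthPair(
        fixed=fixed,
        moving_raw=moving_raw,
        moving_prereg=moving_prereg,
        true_homography=hom,
        true_residual_field=phi,
        landmarks=lms,
        raw_moving_points=raw_pts,
    )


def generate_pairs(
    n: int,
    cfg: SceneConfig | None = None,
    homography_magnitude: float = 8.0,
    residual_magnitude: float = 6.0,
    residual_smoothness: float = 16.0,
    seed: int = 0,
) -> list[GroundTruthPair]:
    """A list of independent pairs; per-pair seeds spawn from ``seed``."""
    cfg = cfg or SceneConfig()
    seeds = np.random.SeedSequence(seed).spawn(n)
    return [
        generate_view_pair(
            cfg,
            homography_magnitude=homography_magnitude,
            residual_magnitude=residual_magnitude,
            residual_smoothness=residual_smoothness,
            seed=s,
        )
        for s in seeds
    ]


def generate_dataset(
    n_train: int,
    n_finetune: int,
    n_test: int,
    out_dir,
    base_cfg: SceneConfig | None = None,
    seed: int = 0,
    homography_magnitude: float = 8.0,
    residual_magnitude: float = 6.0,
) -> dict:
    """Write a disjoint train/finetune/test dataset to disk.

    Train pairs carry no landmark files; fine-tuning and test pairs carry
    landmark CSVs and the true residual field (NPZ). Returns the manifest
    (also written as ``manifest.json``).
    """
    from . import io as pio

    base_cfg = base_cfg or SceneConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    splits = {"train": n_train, "finetune": n_finetune, "test": n_test}
    split_seeds = dict(zip(splits, np.random.SeedSequence(seed).spawn(3)))
    manifest: dict = {"seed": seed, "splits": {}}
    for split, count in splits.items():
        records = []
        for i, s in enumerate(split_seeds[split].spawn(count)):
            pair = generate_view_pair(
                base_cfg,
                homography_magnitude=homography_magnitude,
                residual_magnitude=residual_magnitude,
                seed=s,
            )
            stem = f"{split}_{i:04d}"
            fixed_p = out / f"{stem}_fixed.png"
            moving_p = out / f"{stem}_moving.png"
            pio.write_image(fixed_p, pair.fixed)
            pio.write_image(moving_p, pair.moving_prereg)
            rec = {"fixed": fixed_p.name, "moving": moving_p.name, "landmarks": None}
            if split in ("finetune", "test"):
                lm_p = out / f"{stem}_landmarks.csv"
                pio.write_landmarks(lm_p, pair.landmarks)
                field_p = out / f"{stem}_field.npz"
                pio.write_field(field_p, pair.true_residual_field)
                rec["landmarks"] = lm_p.name
                rec["field"] = field_p.name
            records.append(rec)
        manifest["splits"][split] = records
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
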
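"""Frame preparation for registration: lens undistortion, pen masking, grayscale.

Raw pen frames come from wide-angle surveillance lenses whose radial
distortion bends the pen's straight edges. The distortion model is the
classic even-order radial polynomial

    x_d = x * (1 + k1 r^2 + k2 r^4 + k3 r^6)

acting on *normalized* coordinates x = (p - center) / scale with
r^2 = x^2 + y^2. Only ``k1`` and ``k2`` are typically calibrated; ``k3``
is kept for completeness and defaults to zero.

Coordinate convention used throughout the package: x = column, y = row,
0-based, pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistortionModel",
    "distort_points",
    "undistort_points",
    "undistort_image",
    "apply_mask",
    "to_grayscale",
]

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class DistortionModel:
    """Radial lens distortion: coefficients plus the pixel normalization.

    Parameters
    ----------
    k1, k2, k3 : float
        Dimensionless radial coefficients (k3 defaults to 0).
    center : (float, float)
        Principal point in pixels, (x, y) = (column, row).
    scale : float
        Focal-equivalent factor (pixels) mapping pixel offsets to
        normalized image coordinates. Must be positive.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    def radial_factor(self, r2: np.ndarray) -> np.ndarray:
        return 1.0 + self.k1 * r2 + self.k2 * r2**2 + self.k3 * r2**3

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionModel":
        return cls(
            k1=float(d.get("k1", 0.0)),
            k2=float(d.get("k2", 0.0)),
            k3=float(d.get("k3", 0.0)),
            center=tuple(float(v) for v in d.get("center", (0.0, 0.0))),
            scale=float(d.get("scale", 1.0)),
        )

    def to_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "center": list(self.center),
            "scale": self.scale,
        }


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
    bad = ~np.isfinite(pts).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite point at index {int(np.flatnonzero(bad)[0])}")
    return pts


def distort_points(points, model: DistortionModel) -> np.ndarray:
    """Apply the radial distortion model to ideal (undistorted) points.

    Points are normalized by ``(p - center) / scale``, scaled by the radial
    polynomial, and mapped back to pixels. Returns an (n, 2) array.
    """
    pts = _as_points(points)
    c = np.asarray(model.center, dtype=float)
    norm = (pts - c) / model.scale
    r2 = (norm**2).sum(axis=1)
    out = norm * model.radial_factor(r2)[:, None]
    return out * model.scale + c


def undistort_points(
    points,
    model: DistortionModel,
    tol: float = 1e-9,
    max_iter: int = 20,
) -> np.ndarray:
    """Invert :func:`distort_points` by fixed-point iteration.

    Iterates ``p_u <- p_d / f(r(p_u))`` in normalized coordinates, where
    ``f`` is the radial polynomial. Converges whenever the polynomial is
    monotone over the observed radii (small |k|, in-frame points).

    Raises ``RuntimeError`` reporting the worst residual if the iteration
    has not reached ``tol`` (normalized units) after ``max_iter`` steps.
    """
    pts = _as_points(points)
    c = np.asarray(model.center, dtype=float)
    dist = (pts - c) / model.scale
    und = dist.copy()
    for _ in range(max_iter):
        r2 = (und**2).sum(axis=1)
        new = dist / model.radial_factor(r2)[:, None]
        step = np.abs(new - und).max() if und.size else 0.0
        und = new
        if step < tol:
            break
    else:
        # re-check the actual residual before failing
        r2 = (und**2).sum(axis=1)
        resid = np.abs(und * model.radial_factor(r2)[:, None] - dist).max()
        if not np.isfinite(resid) or resid > tol:
            raise RuntimeError(
                f"undistortion did not converge in {max_iter} iterations; "
                f"worst residual {resid:.3g} (normalized units)"
            )
    return und * model.scale + c


def _bilinear_sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear sampling with zero fill outside the frame (shared helper)."""
    h, w = img.shape
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    out = np.zeros(xs.shape, dtype=img.dtype)
    for dy in (0, 1):
        for dx in (0, 1):
            xi = x0 + dx
            yi = y0 + dy
            wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            out[ok] += wgt[ok] * img[yi[ok], xi[ok]]
    return out


def undistort_image(img: np.ndarray, model: DistortionModel) -> np.ndarray:
    """Resample a distorted frame onto the ideal (undistorted) pixel grid.

    Output pixel p takes the bilinear sample of the input at
    ``distort_points(p)`` (backward mapping); samples falling outside the
    frame fill with 0.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("undistort_image expects a 2D grayscale image")
    if model.k1 == model.k2 == model.k3 == 0.0:
        return img.copy()
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    grid = np.stack([xs.ravel(), ys.ravel()], axis=1)
    src = distort_points(grid, model)
    out = _bilinear_sample(img, src[:, 0].reshape(h, w), src[:, 1].reshape(h, w))
    return out


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out everything outside the pen. Mask is binary, same shape."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    if not (mask > 0).any():
        raise ValueError("mask selects no pixels")
    return img * (mask > 0)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion of an H x W x 3 array in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB, got shape {rgb.shape}")
    return rgb @ np.asarray(LUMA_WEIGHTS)
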
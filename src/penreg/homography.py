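"""Projective (homography) pre-registration from manual landmark pairs.

A 3x3 homography H maps moving-view points to the fixed view in
homogeneous coordinates. It is the global, linear part of the two-camera
alignment: estimated once per pen from ~35 hand-placed correspondences on
a single frame pair, then applied to every other frame of that pen.
Estimation is the normalized DLT (Hartley normalization, SVD null vector),
solved in least squares for over-determined sets; landmarks are manual and
assumed outlier-free, so no robust loop is used.

The dense residual misalignment that a single global homography cannot
express is what the deformable stage (:mod:`penreg.nn`, :mod:`penreg.train`)
is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "Homography",
    "PairedLandmarks",
    "fit_projective",
    "map_points_projective",
    "warp_image_projective",
    "ProjectiveRegistration",
]

FOREGROUND = "foreground"
BACKGROUND = "background"


@dataclass(frozen=True)
class Homography:
    """A 3x3 projective transform, normalized so matrix[2, 2] == 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {m.shape}")
        if not np.isfinite(m).all():
            raise ValueError("homography contains non-finite entries")
        if abs(m[2, 2]) < 1e-12:
            raise ValueError("homography has (near-)zero bottom-right entry")
        object.__setattr__(self, "matrix", m / m[2, 2])
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("homography is singular")

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Homography":
        m = np.eye(3)
        m[0, 2], m[1, 2] = tx, ty
        return cls(m)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.matrix @ other.matrix)


@dataclass
class PairedLandmarks:
    """Corresponding points on the fixed and moving images.

    ``labels`` tag each pair as ``"foreground"`` (on an animal) or
    ``"background"`` (on pen structure); the split matters for evaluation,
    since aligning moving animals is harder than aligning static structure.
    """

    fixed_points: np.ndarray
    moving_points: np.ndarray
    labels: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        if self.fixed_points.shape != self.moving_points.shape:
            raise ValueError("fixed and moving point lists differ in shape")
        if self.fixed_points.ndim != 2 or self.fixed_points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        n = len(self.fixed_points)
        if n < 1:
            raise ValueError("at least one landmark pair required")
        if not self.labels:
            self.labels = [BACKGROUND] * n
        if len(self.labels) != n:
            raise ValueError("labels must cover every pair")
        if not (np.isfinite(self.fixed_points).all() and np.isfinite(self.moving_points).all()):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.fixed_points)

    def subset(self, mask) -> "PairedLandmarks":
        mask = np.asarray(mask)
        return PairedLandmarks(
            self.fixed_points[mask],
            self.moving_points[mask],
            [l for l, m in zip(self.labels, mask) if m],
        )


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform taking pts to centroid 0, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2) / d if d > 1e-12 else 1.0
    t = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1.0]])
    return t


def fit_projective(pairs: PairedLandmarks) -> Homography:
    """Least-squares homography moving -> fixed by normalized DLT.

    Requires >= 4 pairs in general position. For n > 4 the algebraic
    error is minimized via the smallest right singular vector of the
    normalized design matrix.
    """
    n = len(pairs)
    if n < 4:
        raise ValueError(f"homography estimation needs >= 4 pairs, got {n}")
    tf = _hartley_normalization(pairs.fixed_points)
    tm = _hartley_normalization(pairs.moving_points)

    def _apply(t, pts):
        q = np.column_stack([pts, np.ones(len(pts))]) @ t.T
        return q[:, :2] / q[:, 2:3]

    f = _apply(tf, pairs.fixed_points)
    m = _apply(tm, pairs.moving_points)

    a = np.zeros((2 * n, 9))
    a[0::2, 0:2] = m
    a[0::2, 2] = 1.0
    a[0::2, 6:8] = -f[:, 0:1] * m
    a[0::2, 8] = -f[:, 0]
    a[1::2, 3:5] = m
    a[1::2, 5] = 1.0
    a[1::2, 6:8] = -f[:, 1:2] * m
    a[1::2, 8] = -f[:, 1]

    _, s, vt = np.linalg.svd(a)
    # rank < 8 means the configuration does not pin down 8 dof
    if s[7] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate landmark configuration (rank-deficient design matrix)")
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(tf) @ h_norm @ tm
    return Homography(h)


def map_points_projective(points, h: Homography) -> np.ndarray:
    """Homogeneous multiply + perspective divide. Points are (n, 2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    q = np.column_stack([pts, np.ones(len(pts))]) @ h.matrix.T
    w = q[:, 2]
    if np.any(np.abs(w) < 1e-12):
        idx = int(np.argmin(np.abs(w)))
        raise ValueError(f"point {idx} maps to the plane at infinity (w ~ 0)")
    return q[:, :2] / w[:, None]


def warp_image_projective(img: np.ndarray, h: Homography) -> np.ndarray:
    """Backward-warp an image by a homography (moving -> fixed convention).

    Output pixel p is the bilinear sample of the input at H^-1(p);
    out-of-frame samples fill with 0.
    """
    from .preprocess import _bilinear_sample

    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("warp_image_projective expects a 2D grayscale image")
    if np.allclose(h.matrix, np.eye(3)):
        return img.copy()
    hi = h.inverse()
    hh, ww = img.shape
    ys, xs = np.mgrid[0:hh, 0:ww].astype(float)
    grid = np.stack([xs.ravel(), ys.ravel()], axis=1)
    src = map_points_projective(grid, hi)
    return _bilinear_sample(img, src[:, 0].reshape(hh, ww), src[:, 1].reshape(hh, ww))


class ProjectiveRegistration:
    """Landmark-driven projective pre-registration, model-style interface.

    Build from a :class:`PairedLandmarks` set (or a dataframe with columns
    ``fixed_x, fixed_y, moving_x, moving_y[, label]``), then :meth:`fit`.
    """

    def __init__(self, landmarks: PairedLandmarks):
        self.landmarks = landmarks

    @classmethod
    def from_dataframe(cls, df) -> "ProjectiveRegistration":
        labels = list(df["label"]) if "label" in df else []
        return cls(
            PairedLandmarks(
                df[["fixed_x", "fixed_y"]].to_numpy(float),
                df[["moving_x", "moving_y"]].to_numpy(float),
                labels,
            )
        )

    def fit(self) -> "ProjectiveRegistrationResults":
        h = fit_projective(self.landmarks)
        mapped = map_points_projective(self.landmarks.moving_points, h)
        residuals = np.linalg.norm(mapped - self.landmarks.fixed_points, axis=1)
        return ProjectiveRegistrationResults(self, h, residuals)


class ProjectiveRegistrationResults:
    """Fitted homography plus per-landmark transfer residuals (pixels)."""

    def __init__(self, model: ProjectiveRegistration, h: Homography, residuals: np.ndarray):
        self.model = model
        self.homography = h
        self.residuals = residuals

    @property
    def params(self) -> np.ndarray:
        return self.homography.matrix

    def transform_points(self, points) -> np.ndarray:
        return map_points_projective(points, self.homography)

    def transform_image(self, img) -> np.ndarray:
        return warp_image_projective(img, self.homography)

    def summary(self) -> str:
        r = self.residuals
        lines = [
            "Projective pre-registration (normalized DLT)",
            f"  landmark pairs : {len(self.model.landmarks)}",
            f"  residual px    : mean {r.mean():.3f}  median {np.median(r):.3f}  max {r.max():.3f}",
            "  homography (moving -> fixed):",
        ]
        for row in self.homography.matrix:
            lines.append("    [" + "  ".join(f"{v: .6g}" for v in row) + "]")
        return "\n".join(lines)
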
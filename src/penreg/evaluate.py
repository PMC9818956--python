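"""Registration accuracy: target registration error and method comparison.

TRE is the gold-standard registration metric: the mean distance between
landmarks carried from the moving image into the fixed frame and their
ground-truth fixed partners. The default aggregates plain Euclidean
distances (pixels); a squared-distance variant is available and the choice
is recorded in every report. Landmarks are labelled foreground (on
animals) or background (pen structure), and the report breaks the error
down by type — aligning deformable, moving foreground is the harder task.

Method comparison follows the protocol of testing per-pair TRE samples for
normality (Shapiro-Wilk) and then applying a paired t-test when both
samples look normal, otherwise the Wilcoxon signed-rank test. Raw
p-values are reported (no multiple-testing correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .homography import FOREGROUND, BACKGROUND, PairedLandmarks

__all__ = [
    "TREReport",
    "ComparisonResult",
    "compute_tre",
    "evaluate_method",
    "compare_methods",
    "make_overlay",
]


def compute_tre(fixed_points, mapped_moving_points, convention: str = "euclidean") -> float:
    """Mean (squared) Euclidean distance between corresponding points."""
    f = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    m = np.atleast_2d(np.asarray(mapped_moving_points, dtype=float))
    if f.shape != m.shape:
        raise ValueError(f"point set shapes differ: {f.shape} vs {m.shape}")
    if len(f) < 1:
        raise ValueError("need at least one point pair")
    d = np.linalg.norm(f - m, axis=1)
    if convention == "euclidean":
        return float(d.mean())
    if convention == "squared":
        return float((d**2).mean())
    raise ValueError(f"unknown convention '{convention}'")


@dataclass
class TREReport:
    """Per-pair TREs plus pooled foreground/background/overall means.

    ``foreground_tre`` / ``background_tre`` are ``None`` (absent, not 0)
    when the test set carries no landmark of that type. Pooling: the
    overall mean is taken over all landmarks across pairs; the per-pair
    list feeds the paired statistical tests.
    """

    per_pair_tre: list[float]
    foreground_tre: float | None
    background_tre: float | None
    overall_tre: float
    convention: str = "euclidean"
    n_landmarks: int = 0

    def __post_init__(self) -> None:
        for v in list(self.per_pair_tre) + [self.overall_tre]:
            if v < 0:
                raise ValueError("TRE values must be >= 0")

    def summary(self) -> str:
        fg = "absent" if self.foreground_tre is None else f"{self.foreground_tre:.3f}"
        bg = "absent" if self.background_tre is None else f"{self.background_tre:.3f}"
        return (
            f"TRE ({self.convention}, {len(self.per_pair_tre)} pairs, "
            f"{self.n_landmarks} landmarks): overall {self.overall_tre:.3f} px, "
            f"background {bg}, foreground {fg}"
        )

    def to_dict(self) -> dict:
        return {
            "per_pair_tre": [float(v) for v in self.per_pair_tre],
            "foreground_tre": self.foreground_tre,
            "background_tre": self.background_tre,
            "overall_tre": self.overall_tre,
            "convention": self.convention,
            "n_landmarks": self.n_landmarks,
        }


def evaluate_method(method, test_set, convention: str = "euclidean") -> TREReport:
    """Apply a landmark-mapping method to every test pair and report TRE.

    ``method`` is called as ``method(fixed_img, moving_img, moving_points)``
    and must return the moving landmarks carried into the fixed frame.
    Test records are (fixed, moving, landmarks) triples or
    :class:`~penreg.simulate.GroundTruthPair` objects; landmarks must be
    labelled.
    """
    from .train import _record

    per_pair = []
    errs_by_label: dict[str, list[float]] = {FOREGROUND: [], BACKGROUND: []}
    all_errs = []
    for i, rec in enumerate(test_set):
        fixed, moving, lms = _record(rec)
        if lms is None or len(lms) < 1:
            raise ValueError(f"test record {i} carries no landmarks")
        if any(l not in (FOREGROUND, BACKGROUND) for l in lms.labels):
            raise ValueError(f"test record {i} has unlabeled landmark pairs")
        mapped = np.atleast_2d(np.asarray(method(fixed, moving, lms.moving_points), dtype=float))
        d = np.linalg.norm(mapped - lms.fixed_points, axis=1)
        vals = d**2 if convention == "squared" else d
        per_pair.append(float(vals.mean()))
        all_errs.extend(vals.tolist())
        for label, v in zip(lms.labels, vals):
            errs_by_label[label].append(float(v))
    fg = errs_by_label[FOREGROUND]
    bg = errs_by_label[BACKGROUND]
    return TREReport(
        per_pair_tre=per_pair,
        foreground_tre=float(np.mean(fg)) if fg else None,
        background_tre=float(np.mean(bg)) if bg else None,
        overall_tre=float(np.mean(all_errs)),
        convention=convention,
        n_landmarks=len(all_errs),
    )


@dataclass
class ComparisonResult:
    """Outcome of a paired method comparison on per-pair TRE samples."""

    method_a: str
    method_b: str
    normality_p: tuple[float, float]
    test_used: str
    p_value: float

    def __post_init__(self) -> None:
        if self.test_used == "paired_t" and not all(p > self._alpha for p in self.normality_p):
            raise ValueError("paired t-test requires both samples to pass normality")

    _alpha: float = 0.05

    def summary(self) -> str:
        return (
            f"{self.method_a} vs {self.method_b}: {self.test_used} "
            f"p = {self.p_value:.4g} (Shapiro-Wilk p = "
            f"{self.normality_p[0]:.3g}, {self.normality_p[1]:.3g})"
        )


def compare_methods(
    per_pair_tre_a,
    per_pair_tre_b,
    alpha: float = 0.05,
    method_a: str = "A",
    method_b: str = "B",
) -> ComparisonResult:
    """Shapiro-Wilk gated choice between paired t-test and Wilcoxon.

    Degenerate all-zero differences make the signed-rank test undefined;
    a warning is issued and p = 1 reported.
    """
    a = np.asarray(per_pair_tre_a, dtype=float)
    b = np.asarray(per_pair_tre_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples of equal length required")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")

    def _shapiro(x):
        if np.allclose(x, x[0]):
            return 0.0  # constant sample: treat as non-normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro(a), _shapiro(b)
    if np.allclose(a, b):
        warnings.warn("all paired differences are zero; signed-rank test degenerate, reporting p = 1")
        return ComparisonResult(method_a, method_b, (pa, pb), "wilcoxon_signed_rank", 1.0, alpha)
    if pa > alpha and pb > alpha:
        res = stats.ttest_rel(a, b)
        return ComparisonResult(method_a, method_b, (pa, pb), "paired_t", float(res.pvalue), alpha)
    res = stats.wilcoxon(a, b)
    return ComparisonResult(
        method_a, method_b, (pa, pb), "wilcoxon_signed_rank", float(res.pvalue), alpha
    )


def make_overlay(fixed: np.ndarray, moving_or_registered: np.ndarray) -> np.ndarray:
    """Green/magenta misalignment overlay (H x W x 3 in [0, 1]).

    The fixed image drives the green channel, the other image red + blue;
    where intensities agree the overlay renders gray.
    """
    f = np.asarray(fixed, dtype=float)
    m = np.asarray(moving_or_registered, dtype=float)
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {m.shape}")
    return np.clip(np.stack([m, f, m], axis=-1), 0.0, 1.0)
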
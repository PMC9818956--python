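"""Similarity metrics, smoothness regularization and the training losses.

The registration energy is  E(Phi) = M(I_f, I_m(Phi)) + lambda * R(Phi),
with M an intensity similarity between the fixed image and the warped
moving image and R the diffusion regularizer penalizing spatial gradients
of the displacement field. The semi-supervised variant adds
mu * (1/k) * sum_j || p_f,j - p'_j ||^2 over k annotated landmark pairs,
where p' is the landmark carried into the fixed frame.

Conventions:

* images are in [0, 1], so MSE magnitudes are on that scale;
* :func:`diffusion_regularizer` is the plain SUM over pixels of
  ||grad Phi||^2 (forward differences). Inside the composed losses it
  enters as the per-pixel MEAN, ``lambda * R / n`` — this keeps lambda
  resolution-independent and commensurate with the (mean) similarity
  term, so one default weight works at any frame size;
* NCC is a similarity in [-1, 1]; as a loss it is minimized as 1 - NCC
  (a monotone negation of maximizing NCC);
* the training-time landmark transfer is the unrolled damped fixed-point
  inversion (4 explicit steps) of the backward warp — exactly
  differentiable, and close enough to the evaluation-time inverse that
  the landmark loss optimizes the metric actually reported (see
  :func:`penreg.warp.warp_points_unrolled`).

Each loss has a ``*_grad`` companion returning (value, d value / d Phi),
used by the hand-rolled backprop in :mod:`penreg.nn`.
"""

from __future__ import annotations

import numpy as np

from .homography import PairedLandmarks
from .warp import sample_field, warp_image_dense, warp_image_dense_vjp

__all__ = [
    "similarity_mse",
    "similarity_ncc",
    "similarity_ssd",
    "diffusion_regularizer",
    "unsupervised_loss",
    "unsupervised_loss_grad",
    "semisupervised_loss",
    "semisupervised_loss_grad",
    "SIMILARITIES",
]

SIMILARITIES = ("mse", "ncc", "ssd")


def _prep(fixed, warped, mask):
    fixed = np.asarray(fixed, dtype=float)
    warped = np.asarray(warped, dtype=float)
    if fixed.shape != warped.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {warped.shape}")
    if mask is not None:
        mask = np.asarray(mask) > 0
        if mask.shape != fixed.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("mask selects no pixels")
    return fixed, warped, mask


def similarity_mse(fixed, warped, mask=None) -> float:
    """Mean squared intensity difference over included pixels."""
    fixed, warped, mask = _prep(fixed, warped, mask)
    d2 = (fixed - warped) ** 2
    return float(d2[mask].mean() if mask is not None else d2.mean())


def similarity_ssd(fixed, warped, mask=None) -> float:
    """Sum of squared differences; equals n * MSE over the included pixels."""
    fixed, warped, mask = _prep(fixed, warped, mask)
    d2 = (fixed - warped) ** 2
    return float(d2[mask].sum() if mask is not None else d2.sum())


def similarity_ncc(fixed, warped, mask=None) -> float:
    """Zero-normalized global cross-correlation in [-1, 1].

    Invariant to affine intensity changes of either image (gain > 0),
    which is what makes it robust to the between-view illumination
    differences that MSE conflates with misalignment.
    """
    fixed, warped, mask = _prep(fixed, warped, mask)
    if mask is not None:
        f, g = fixed[mask], warped[mask]
    else:
        f, g = fixed.ravel(), warped.ravel()
    fc = f - f.mean()
    gc = g - g.mean()
    a = (fc**2).sum()
    b = (gc**2).sum()
    if a < 1e-20 or b < 1e-20:
        raise ValueError("NCC undefined: zero intensity variance over included pixels")
    return float((fc * gc).sum() / np.sqrt(a * b))


def _ncc_grad_wrt_warped(fixed, warped, mask):
    """d NCC / d warped, exploiting that centered sums are mean-free."""
    if mask is not None:
        sel = mask
    else:
        sel = np.ones(fixed.shape, dtype=bool)
    f, g = fixed[sel], warped[sel]
    fc = f - f.mean()
    gc = g - g.mean()
    a = (fc**2).sum()
    b = (gc**2).sum()
    if a < 1e-20 or b < 1e-20:
        raise ValueError("NCC undefined: zero intensity variance over included pixels")
    c = (fc * gc).sum()
    grad_sel = fc / np.sqrt(a * b) - (c / (b * np.sqrt(a * b))) * gc
    grad = np.zeros_like(fixed)
    grad[sel] = grad_sel
    return float(c / np.sqrt(a * b)), grad


def diffusion_regularizer(field) -> float:
    """Sum over the grid of the squared spatial gradient of the field.

    Gradients by forward finite differences in x and y on both
    displacement channels; zero iff the field is constant.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 3 or field.shape[2] != 2:
        raise ValueError(f"field must be H x W x 2, got {field.shape}")
    dx = np.diff(field, axis=1)
    dy = np.diff(field, axis=0)
    return float((dx**2).sum() + (dy**2).sum())


def _diffusion_grad(field) -> tuple[float, np.ndarray]:
    field = np.asarray(field, dtype=float)
    dx = np.diff(field, axis=1)
    dy = np.diff(field, axis=0)
    val = float((dx**2).sum() + (dy**2).sum())
    g = np.zeros_like(field)
    g[:, 1:] += 2 * dx
    g[:, :-1] -= 2 * dx
    g[1:, :] += 2 * dy
    g[:-1, :] -= 2 * dy
    return val, g


def _similarity_value_and_grad(name, fixed, warped, mask):
    """Value and d/d(warped) of the *minimized* similarity term."""
    fixed, warped, mask = _prep(fixed, warped, mask)
    sel = mask if mask is not None else np.ones(fixed.shape, dtype=bool)
    n = int(sel.sum())
    diff = warped - fixed
    if name == "mse":
        val = float((diff[sel] ** 2).mean())
        grad = np.where(sel, 2.0 * diff / n, 0.0)
    elif name == "ssd":
        val = float((diff[sel] ** 2).sum())
        grad = np.where(sel, 2.0 * diff, 0.0)
    elif name == "ncc":
        ncc, g_ncc = _ncc_grad_wrt_warped(fixed, warped, mask)
        val = 1.0 - ncc
        grad = -g_ncc
    else:
        raise ValueError(f"unknown similarity '{name}'; choose from {SIMILARITIES}")
    return val, grad


def unsupervised_loss(fixed, moving, field, lambda_=0.01, similarity="mse", mask=None) -> float:
    """Similarity(I_f, I_m(Phi)) + lambda * mean ||grad Phi||^2."""
    val, _ = unsupervised_loss_grad(fixed, moving, field, lambda_, similarity, mask)
    return val


def unsupervised_loss_grad(
    fixed, moving, field, lambda_=0.01, similarity="mse", mask=None
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the field."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if similarity not in SIMILARITIES:
        raise ValueError(f"unknown similarity '{similarity}'; choose from {SIMILARITIES}")
    field = np.asarray(field, dtype=float)
    moving = np.asarray(moving, dtype=float)
    warped = warp_image_dense(moving, field)
    sim_val, g_warped = _similarity_value_and_grad(similarity, fixed, warped, mask)
    _, g_field = warp_image_dense_vjp(moving, field, g_warped)
    n = field.shape[0] * field.shape[1]
    reg_val, g_reg = _diffusion_grad(field)
    val = sim_val + lambda_ * reg_val / n
    grad = g_field + (lambda_ / n) * g_reg
    return float(val), grad


def _scatter_sample_grad(g_field, pts, coef):
    """Accumulate d(sample_field)/dPhi contributions: bilinear scatter of
    ``coef`` (n, 2) at continuous positions ``pts``."""
    h, w = g_field.shape[:2]
    x0 = np.floor(pts[:, 0]).astype(int)
    y0 = np.floor(pts[:, 1]).astype(int)
    fx = pts[:, 0] - x0
    fy = pts[:, 1] - y0
    for dy in (0, 1):
        for dx in (0, 1):
            xi = x0 + dx
            yi = y0 + dy
            wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            np.add.at(g_field[:, :, 0], (yi[ok], xi[ok]), wgt[ok] * coef[ok, 0])
            np.add.at(g_field[:, :, 1], (yi[ok], xi[ok]), wgt[ok] * coef[ok, 1])


def _landmark_term_grad(field, landmarks: PairedLandmarks, mu: float,
                        steps: int = 4, damping: float = 0.5):
    """mu * mean squared landmark transfer error, and its field gradient.

    The transfer is the unrolled damped fixed-point inversion of
    ``p' + Phi(p') = p`` (see :func:`penreg.warp.warp_points_unrolled`):
    ``steps`` explicit iterations, each a bilinear field sample, so the
    whole composition is exactly differentiable. Backpropagation walks
    the iterates in reverse, scattering onto the field at each iterate
    and carrying the per-point 2x2 chain factor
    (1 - damping) I - damping * J(p_k), with J the spatial Jacobian of
    the sampled field.

    ``steps=1, damping=1`` recovers the first-order transfer
    p' = p - Phi(p).
    """
    from .warp import sample_field_jacobian

    field = np.asarray(field, dtype=float)
    k = len(landmarks)
    pts = landmarks.moving_points
    iters = [pts.copy()]
    p = pts.copy()
    for _ in range(steps):
        p = p - damping * (p + sample_field(field, p) - pts)
        iters.append(p)
    err = p - landmarks.fixed_points  # (k, 2)
    val = float(mu * (err**2).sum() / k)

    g_field = np.zeros_like(field)
    g = (2.0 * mu / k) * err  # d val / d p_K
    for step in range(steps - 1, -1, -1):
        pk = iters[step]
        _scatter_sample_grad(g_field, pk, -damping * g)
        if step > 0:
            jac = sample_field_jacobian(field, pk)  # (n, 2, 2)
            g = (1.0 - damping) * g - damping * np.einsum("nc,nca->na", g, jac)
    return val, g_field


def semisupervised_loss(
    fixed, moving, field, landmarks: PairedLandmarks,
    lambda_=0.01, mu=1.0, similarity="mse", mask=None,
) -> float:
    """Unsupervised loss plus the landmark misalignment penalty."""
    val, _ = semisupervised_loss_grad(
        fixed, moving, field, landmarks, lambda_, mu, similarity, mask
    )
    return val


def semisupervised_loss_grad(
    fixed, moving, field, landmarks: PairedLandmarks,
    lambda_=0.01, mu=1.0, similarity="mse", mask=None,
) -> tuple[float, np.ndarray]:
    if landmarks is None or len(landmarks) < 1:
        raise ValueError("semisupervised loss requires at least one landmark pair")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    base_val, base_grad = unsupervised_loss_grad(fixed, moving, field, lambda_, similarity, mask)
    lm_val, lm_grad = _landmark_term_grad(field, landmarks, mu)
    return base_val + lm_val, base_grad + lm_grad
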
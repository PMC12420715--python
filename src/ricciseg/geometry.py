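"""Per-voxel Riemannian geometry of the level-set hypersurface.

A relaxed level set ``u(x, y, z)`` is viewed as the graph hypersurface
``(x, y, z, u)`` embedded in 4D Euclidean space.  Its induced metric is the
rank-one update ``g = I + v v^T`` of the identity, where ``v`` is the
(auxiliary) intensity gradient field.  Because of this special structure the
Riemann, Ricci and scalar curvatures all reduce to closed-form algebraic
expressions in ``v`` and the Hessian ``H`` (the symmetrized Jacobian of
``v``), which this module evaluates voxel-wise:

* ``Ric = (H tr(g^{-1}H) - H g^{-1} H) / (1 + |v|^2)``
* ``R   = ((tr(g^{-1}H))^2 - tr(g^{-1}H g^{-1}H)) / (1 + |v|^2)``
* total scalar curvature (Einstein-Hilbert energy) ``E = sum R sqrt(det g) dV``

Array conventions
-----------------
scalar fields  ``(nx, ny, nz)``; vector fields ``(3, nx, ny, nz)``;
3x3 tensor fields ``(3, 3, nx, ny, nz)``.  Tensor algebra is written with
explicit ``einsum`` index strings (Einstein-summation semantics).

A second, independent route to the Ricci tensor via the Christoffel-symbol
derivative form is provided as :func:`ricci_oracle_christoffel`.  It is a
cross-validation oracle for tests only and is never called by the solver.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "metric_from_gradient",
    "hessian_from_gradient",
    "ricci_tensor",
    "scalar_curvature",
    "einstein_tensor",
    "einstein_hilbert_energy",
    "riemann_component",
    "ricci_oracle_christoffel",
    "grad_norm_sq",
]

_EYE3 = np.eye(3)


def _check_finite(arr: np.ndarray, name: str) -> None:
    """Abort with the coordinates of the first offending voxel."""
    if np.isfinite(arr).all():
        return
    bad = np.argwhere(~np.isfinite(arr))
    raise ValueError(
        f"{name} contains a non-finite value at index {tuple(bad[0])} "
        f"({bad.shape[0]} offending entries in total)"
    )


def _check_vector(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 4 or v.shape[0] != 3:
        raise ValueError(f"gradient field must have shape (3, nx, ny, nz), got {v.shape}")
    _check_finite(v, "gradient field")
    return v


def _check_spacing(spacing) -> np.ndarray:
    h = np.asarray(spacing, dtype=float).reshape(-1)
    if h.size != 3 or (h <= 0).any():
        raise ValueError(f"spacing must be 3 positive lengths, got {spacing!r}")
    return h


def grad_norm_sq(v: np.ndarray) -> np.ndarray:
    """``|v|^2`` per voxel."""
    return np.einsum("i...,i...->...", v, v)


def metric_from_gradient(v: np.ndarray):
    """Metric tensor of the graph hypersurface and its exact inverse.

    Returns ``(g, g_inv, detg)`` with ``g = I + v v^T``,
    ``det g = 1 + |v|^2`` (matrix determinant lemma) and the Sherman-Morrison
    closed-form inverse ``g^{-1} = I - v v^T / (1 + |v|^2)``.
    """
    v = _check_vector(v)
    outer = np.einsum("i...,j...->ij...", v, v)
    detg = 1.0 + grad_norm_sq(v)
    g = outer + _EYE3.reshape(3, 3, 1, 1, 1)
    g_inv = -outer / detg + _EYE3.reshape(3, 3, 1, 1, 1)
    return g, g_inv, detg


def hessian_from_gradient(v: np.ndarray, spacing=(1.0, 1.0, 1.0), *, symmetrize: bool = True) -> np.ndarray:
    """Jacobian ``H_ij = dv_i/dx_j`` of the gradient field, symmetrized.

    Central differences in the interior, second-order one-sided stencils at
    the faces.  For a true gradient field ``v = grad(u)`` the Jacobian is the
    Hessian of ``u`` and already symmetric up to O(h^2); in the split
    formulation the raw Jacobian can carry an antisymmetric (curl) part,
    which the curvature formulas do not model, so it is projected out by
    default.
    """
    v = _check_vector(v)
    h = _check_spacing(spacing)
    if min(v.shape[1:]) < 3:
        raise ValueError(f"each axis needs >= 3 voxels for second-order stencils, got {v.shape[1:]}")
    H = np.empty((3, 3) + v.shape[1:], dtype=float)
    for i in range(3):
        H[i, 0], H[i, 1], H[i, 2] = np.gradient(v[i], h[0], h[1], h[2], edge_order=2)
    if symmetrize:
        H = 0.5 * (H + np.swapaxes(H, 0, 1))
    return H


def _align(*fields) -> None:
    base = fields[0].shape[-3:]
    for f in fields[1:]:
        if f.shape[-3:] != base:
            raise ValueError(f"voxel grids do not match: {base} vs {f.shape[-3:]}")


def ricci_tensor(g_inv: np.ndarray, H: np.ndarray, grad_norm_sq: np.ndarray) -> np.ndarray:
    """Ricci tensor ``(H tr(g^{-1}H) - H g^{-1} H) / (1 + |v|^2)`` per voxel."""
    _align(g_inv, H, grad_norm_sq[None, None])
    trgH = np.einsum("ij...,ji...->...", g_inv, H)
    HgH = np.einsum("ik...,kl...,lj...->ij...", H, g_inv, H)
    return (H * trgH - HgH) / (1.0 + grad_norm_sq)


def scalar_curvature(g_inv: np.ndarray, H: np.ndarray, grad_norm_sq: np.ndarray) -> np.ndarray:
    """Scalar curvature ``((tr g^{-1}H)^2 - tr(g^{-1}H g^{-1}H)) / (1 + |v|^2)``."""
    _align(g_inv, H, grad_norm_sq[None, None])
    gH = np.einsum("ik...,kj...->ij...", g_inv, H)
    trgH = np.einsum("ii...->...", gH)
    trgHgH = np.einsum("ij...,ji...->...", gH, gH)
    return (trgH**2 - trgHgH) / (1.0 + grad_norm_sq)


def einstein_tensor(R: np.ndarray, g: np.ndarray, Ric: np.ndarray) -> np.ndarray:
    """Einstein tensor ``G = R g - 2 Ric`` (3D convention).

    ``G = 0`` characterizes a locally flat (Euclidean) hypersurface, the
    smoothest configuration the regularizer drives towards.
    """
    _align(g, Ric, R[None, None])
    return R * g - 2.0 * Ric


def einstein_hilbert_energy(v: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Discrete total scalar curvature ``sum_vox R sqrt(det g) * voxel_volume``.

    The integrand simplifies to
    ``((tr g^{-1}H)^2 - tr(g^{-1}H g^{-1}H)) / sqrt(1 + |v|^2)``.
    """
    v = _check_vector(v)
    h = _check_spacing(spacing)
    _, g_inv, detg = metric_from_gradient(v)
    H = hessian_from_gradient(v, h)
    R = scalar_curvature(g_inv, H, detg - 1.0)
    integrand = R * np.sqrt(detg)
    _check_finite(integrand, "Einstein-Hilbert integrand")
    return float(integrand.sum() * np.prod(h))


def riemann_component(H: np.ndarray, grad_norm_sq: np.ndarray, i: int, k: int, j: int, l: int) -> np.ndarray:
    """Riemann curvature component ``R_ikjl = (H_ij H_kl - H_il H_jk)/(1+|v|^2)``.

    Indices are 1-based (the differential-geometry convention).
    """
    for name, idx in zip("ikjl", (i, k, j, l)):
        if idx not in (1, 2, 3):
            raise ValueError(f"index {name}={idx} is invalid; indices are 1-based in {{1,2,3}}")
    i, k, j, l = i - 1, k - 1, j - 1, l - 1
    return (H[i, j] * H[k, l] - H[i, l] * H[j, k]) / (1.0 + grad_norm_sq)


def ricci_oracle_christoffel(v: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Ricci tensor via the Christoffel/derivative form (test oracle only).

    Evaluates, with ``w = g^{-1} v = v / (1 + |v|^2)`` and the *raw*
    Jacobian ``J_ql = dv_q/dx_l``::

        R_ql = d_k(w_k J_ql) + J_ql (w^T J w) - d_l((J w)_q) - (J w)_q (J^T w)_l

    where the outer derivatives are taken by finite differences.  Agreement
    with :func:`ricci_tensor` holds in the interior for smooth gradient
    fields (second-order in the grid spacing); the two routes share no code
    beyond the stencils, which makes this a genuine cross-check.  Never used
    by the solver.
    """
    v = _check_vector(v)
    h = _check_spacing(spacing)
    if min(v.shape[1:]) < 5:
        raise ValueError(f"grid too small for the nested stencils, need >= 5 per axis, got {v.shape[1:]}")
    J = hessian_from_gradient(v, h, symmetrize=False)
    w = v / (1.0 + grad_norm_sq(v))

    Jw = np.einsum("qk...,k...->q...", J, w)        # (J w)_q
    JTw = np.einsum("ak...,a...->k...", J, w)       # (J^T w)_l
    wJw = np.einsum("a...,ak...,k...->...", w, J, w)

    Ric = np.empty_like(J)
    for q in range(3):
        for l in range(3):
            # d_k sum_k (w_k J_ql): divergence of the vector field w * J[q,l]
            div_wJ = sum(
                np.gradient(w[k] * J[q, l], h[k], axis=k, edge_order=2) for k in range(3)
            )
            d_l_Jw_q = np.gradient(Jw[q], h[l], axis=l, edge_order=2)
            Ric[q, l] = div_wJ + J[q, l] * wJw - d_l_Jw_q - Jw[q] * JTw[l]
    return Ric
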
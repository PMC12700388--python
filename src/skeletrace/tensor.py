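"""Finite-difference derivatives, the Hessian tensor field and its
eigen-decomposition.

Second derivatives are built by applying the first-derivative stencil twice,
so mixed components commute exactly and the six independent components fully
describe the symmetric tensor.  The per-voxel eigenproblem is solved in closed
form: eigenvalues via the trigonometric (Cardano) solution of the
characteristic cubic, eigenvectors via cross products of rows of
``H - lambda*I``.  Voxels where that analytic path is ill-conditioned
(near-degenerate eigenvalues) fall back to an iterative symmetric solver.
Output is sorted by descending eigenvalue magnitude, ``|l1| >= |l2| >= |l3|``,
the ordering that encodes local dimensionality (blob / line / surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericError, ParameterError
from .volume_io import ScalarVolume

__all__ = [
    "HessianField",
    "EigenField",
    "first_derivatives",
    "hessian",
    "eig3_symmetric",
]

_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")

# Relative eigenvalue gap below which the cross-product eigenvector recovery
# is considered ill-conditioned and the iterative solver is used instead.
DEGENERACY_RTOL = 1e-6


@dataclass
class HessianField:
    """Six independent components of the symmetric Hessian of a scalar field."""

    xx: np.ndarray
    yy: np.ndarray
    zz: np.ndarray
    xy: np.ndarray
    xz: np.ndarray
    yz: np.ndarray

    @property
    def shape(self):
        return self.xx.shape

    def components(self) -> tuple[np.ndarray, ...]:
        return self.xx, self.yy, self.zz, self.xy, self.xz, self.yz


@dataclass
class EigenField:
    """Per-voxel eigenvalues and eigenvectors of a Hessian field.

    ``eigenvalues[..., k]`` is the (k+1)-th eigenvalue with
    ``|l1| >= |l2| >= |l3|``; ``eigenvectors[..., k, :]`` the matching unit
    eigenvector.  Eigenvector sign is arbitrary (downstream probing is
    symmetric in +-v).
    """

    eigenvalues: np.ndarray  # (..., 3)
    eigenvectors: np.ndarray  # (..., 3, 3), [..., k, :] unit vectors

    @property
    def shape(self):
        return self.eigenvalues.shape[:-1]


def _diff(a: np.ndarray, axis: int, scheme: str) -> np.ndarray:
    """One directional derivative with replicate padding at the boundary."""
    p = np.pad(a, [(1, 1) if ax == axis else (0, 0) for ax in range(a.ndim)], mode="edge")
    sl_p = [slice(None)] * a.ndim
    sl_m = [slice(None)] * a.ndim
    sl_c = [slice(None)] * a.ndim
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(None, -2)
    sl_c[axis] = slice(1, -1)
    if scheme == "centered":
        return (p[tuple(sl_p)] - p[tuple(sl_m)]) / 2.0
    if scheme == "forward":
        return p[tuple(sl_p)] - p[tuple(sl_c)]
    raise ParameterError(f"unknown derivative scheme '{scheme}'")


def first_derivatives(S: ScalarVolume, scheme: str = "centered"):
    """Gradient components (S_x, S_y, S_z) by finite differences.

    ``forward``: S(x+e_i) - S(x); ``centered``: (S(x+e_i) - S(x-e_i)) / 2.
    """
    a = np.asarray(S.data, dtype=np.float64)
    return tuple(
        ScalarVolume(_diff(a, ax, scheme), S.voxel_size) for ax in range(3)
    )


def hessian(S: ScalarVolume, scheme: str = "centered") -> HessianField:
    """Hessian components H_ij = D_i(D_j S); the discrete stencils commute."""
    a = np.asarray(S.data, dtype=np.float64)
    dx = _diff(a, 0, scheme)
    dy = _diff(a, 1, scheme)
    dz = _diff(a, 2, scheme)
    return HessianField(
        xx=_diff(dx, 0, scheme),
        yy=_diff(dy, 1, scheme),
        zz=_diff(dz, 2, scheme),
        xy=_diff(dy, 0, scheme),
        xz=_diff(dz, 0, scheme),
        yz=_diff(dz, 1, scheme),
    )


def _cardano_eigenvalues(a11, a22, a33, a12, a13, a23):
    """Closed-form eigenvalues of symmetric 3x3 matrices (vectorized).

    Trigonometric solution of the characteristic cubic; returns the three
    roots unsorted as (e1, e2, e3) with e1 >= e2 >= e3 algebraically.
    """
    q = (a11 + a22 + a33) / 3.0
    b11, b22, b33 = a11 - q, a22 - q, a33 - q
    p2 = b11**2 + b22**2 + b33**2 + 2.0 * (a12**2 + a13**2 + a23**2)
    p = np.sqrt(p2 / 6.0)
    safe = p > 0
    ps = np.where(safe, p, 1.0)
    c11, c22, c33 = b11 / ps, b22 / ps, b33 / ps
    c12, c13, c23 = a12 / ps, a13 / ps, a23 / ps
    detB = (
        c11 * (c22 * c33 - c23**2)
        - c12 * (c12 * c33 - c23 * c13)
        + c13 * (c12 * c23 - c22 * c13)
    )
    r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    e1 = np.where(safe, e1, q)
    e2 = np.where(safe, e2, q)
    e3 = np.where(safe, e3, q)
    return e1, e2, e3


def _eigenvector_for(a11, a22, a33, a12, a13, a23, lam):
    """Unit null vector of (A - lam I) via the largest row cross product.

    Returns (vectors, quality) where quality is the norm of the chosen cross
    product relative to the matrix scale; small quality flags degeneracy.
    """
    r0 = np.stack([a11 - lam, a12, a13], axis=-1)
    r1 = np.stack([a12, a22 - lam, a23], axis=-1)
    r2 = np.stack([a13, a23, a33 - lam], axis=-1)
    c01 = np.cross(r0, r1)
    c02 = np.cross(r0, r2)
    c12 = np.cross(r1, r2)
    cand = np.stack([c01, c02, c12], axis=-2)  # (..., 3, 3)
    norms = np.linalg.norm(cand, axis=-1)
    best = np.argmax(norms, axis=-1)
    vec = np.take_along_axis(cand, best[..., None, None], axis=-2)[..., 0, :]
    n = np.take_along_axis(norms, best[..., None], axis=-1)[..., 0]
    ns = np.where(n > 0, n, 1.0)
    return vec / ns[..., None], n


def eig3_symmetric(H: HessianField) -> EigenField:
    """Analytic eigen-decomposition of a symmetric 3x3 tensor field.

    Eigenvalues come from the Cardano closed form, eigenvectors from cross
    products of rows of ``H - lambda*I``; near-degenerate voxels (relative
    eigenvalue gap < 1e-6, or a vanishing cross product) are recomputed with
    ``numpy.linalg.eigh``.  Results are sorted by descending ``|lambda|``.
    """
    comps = [np.asarray(c, dtype=np.float64) for c in H.components()]
    for name, c in zip(_COMPONENTS, comps):
        if not np.isfinite(c).all():
            vox = np.argwhere(~np.isfinite(c))[0]
            raise NumericError(f"non-finite Hessian component {name} at voxel {tuple(vox)}")
    w, v = _eig3_core(*comps)
    return EigenField(w, v)


def _eig3_core(a11, a22, a33, a12, a13, a23):
    """Vectorized decomposition on arbitrarily shaped component arrays."""
    shape = np.broadcast(a11, a22).shape
    e1, e2, e3 = _cardano_eigenvalues(a11, a22, a33, a12, a13, a23)
    lams = np.stack([e1, e2, e3], axis=-1)  # algebraic descending

    scale = np.max(np.abs(lams), axis=-1)
    scale = np.where(scale > 0, scale, 1.0)
    gap12 = np.abs(e1 - e2) / scale
    gap23 = np.abs(e2 - e3) / scale
    degen = (gap12 < DEGENERACY_RTOL) | (gap23 < DEGENERACY_RTOL)

    vecs = np.empty(shape + (3, 3), dtype=np.float64)
    quality = np.full(shape, np.inf)
    for k, lam in enumerate((e1, e2, e3)):
        vk, nk = _eigenvector_for(a11, a22, a33, a12, a13, a23, lam)
        vecs[..., k, :] = vk
        quality = np.minimum(quality, nk / scale**2)
    degen |= quality < 1e-12

    if np.any(degen):
        idx = np.nonzero(degen)
        m = np.empty((len(idx[0]), 3, 3))
        m[:, 0, 0] = a11[idx] if np.ndim(a11) else a11
        m[:, 1, 1] = a22[idx] if np.ndim(a22) else a22
        m[:, 2, 2] = a33[idx] if np.ndim(a33) else a33
        m[:, 0, 1] = m[:, 1, 0] = a12[idx] if np.ndim(a12) else a12
        m[:, 0, 2] = m[:, 2, 0] = a13[idx] if np.ndim(a13) else a13
        m[:, 1, 2] = m[:, 2, 1] = a23[idx] if np.ndim(a23) else a23
        ew, ev = np.linalg.eigh(m)
        order = np.argsort(ew, axis=-1)[:, ::-1]  # algebraic descending
        ew = np.take_along_axis(ew, order, axis=-1)
        ev = np.take_along_axis(ev, order[:, None, :], axis=-1)
        lams[idx] = ew
        vecs[idx] = np.swapaxes(ev, -1, -2)  # columns -> row vectors

    # Sort by |lambda| descending; stable so exact ties keep Cardano order.
    order = np.argsort(-np.abs(lams), axis=-1, kind="stable")
    lams = np.take_along_axis(lams, order, axis=-1)
    vecs = np.take_along_axis(vecs, order[..., None], axis=-2)
    return lams, vecs
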
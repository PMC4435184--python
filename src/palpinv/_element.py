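"""Trilinear hexahedral element stiffness for axis-aligned box elements.

All elements in the structured meshes are rectangular boxes, so the element
stiffness splits into two geometry-only matrices scaled by the Lamé constants:

    K_e = lam * K_vol(dims) + mu * K_dev(dims)

``K_dev`` carries the shear term ``2 mu B^T diag(1,1,1,1/2,1/2,1/2) B``
integrated with full 2x2x2 Gauss quadrature; ``K_vol`` carries the volumetric
term ``lam * (div u)^2`` integrated with a single centroid point (selective
reduced integration).  The one-point volumetric rule is what keeps linear
hexahedra usable at Poisson ratio 0.49: full integration locks badly for
near-incompressible material.

Local node order follows the usual counter-clockwise bottom / top convention:
(0,0,0) (1,0,0) (1,1,0) (0,1,0) (0,0,1) (1,0,1) (1,1,1) (0,1,1),
with three displacement dofs per node, node-major.
"""

from __future__ import annotations

import numpy as np

# reference corner signs, shape (8, 3)
_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _dshape(xi: np.ndarray) -> np.ndarray:
    """Reference-coordinate gradients dN/dxi at one point, shape (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        sa = _XI[a]
        g[a, 0] = 0.125 * sa[0] * (1 + xi[1] * sa[1]) * (1 + xi[2] * sa[2])
        g[a, 1] = 0.125 * sa[1] * (1 + xi[0] * sa[0]) * (1 + xi[2] * sa[2])
        g[a, 2] = 0.125 * sa[2] * (1 + xi[0] * sa[0]) * (1 + xi[1] * sa[1])
    return g


# precomputed dN/dxi at the 8 full-quadrature points and the centroid
_DSH_FULL = np.stack([_dshape(np.array([x, y, z])) for x in _GP for y in _GP for z in _GP])
_DSH_CENTER = _dshape(np.zeros(3))[None, :, :]


def _bmatrix(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24) from physical gradients (8, 3).

    Engineering-strain order: xx, yy, zz, xy, yz, zx.
    """
    b = np.zeros((6, 24))
    gx, gy, gz = dndx[:, 0], dndx[:, 1], dndx[:, 2]
    for a in range(8):
        c = 3 * a
        b[0, c] = gx[a]
        b[1, c + 1] = gy[a]
        b[2, c + 2] = gz[a]
        b[3, c] = gy[a]
        b[3, c + 1] = gx[a]
        b[4, c + 1] = gz[a]
        b[4, c + 2] = gy[a]
        b[5, c] = gz[a]
        b[5, c + 2] = gx[a]
    return b


_SHEAR_D = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])  # 2*mu*eps with engineering shear


def box_stiffness_parts(dims: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-box deviatoric and volumetric stiffness matrices.

    Parameters
    ----------
    dims : (m, 3) array of element edge lengths (dx, dy, dz).

    Returns
    -------
    k_dev, k_vol : (m, 24, 24) arrays such that the element stiffness is
        ``lam * k_vol + mu * k_dev``.
    """
    dims = np.atleast_2d(np.asarray(dims, dtype=float))
    m = dims.shape[0]
    detj = dims.prod(axis=1) / 8.0  # constant over the box
    scale = 2.0 / dims  # dN/dx = dN/dxi * 2/edge

    k_dev = np.zeros((m, 24, 24))
    for g in range(8):
        dndx = _DSH_FULL[g][None, :, :] * scale[:, None, :]  # (m, 8, 3)
        for e in range(m):
            b = _bmatrix(dndx[e])
            k_dev[e] += detj[e] * (b.T @ _SHEAR_D @ b)

    k_vol = np.zeros((m, 24, 24))
    dndx0 = _DSH_CENTER[0][None, :, :] * scale[:, None, :]
    for e in range(m):
        bvol = dndx0[e].reshape(-1)  # div row: (gx0, gy0, gz0, gx1, ...)
        k_vol[e] = 8.0 * detj[e] * np.outer(bvol, bvol)
    return k_dev, k_vol


def lame(E: np.ndarray, nu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lamé constants (lam, mu) from Young's modulus and Poisson ratio."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return lam, mu
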
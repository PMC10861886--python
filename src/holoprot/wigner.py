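"""Real Wigner-D matrices for rotating real-spherical-harmonic coefficient blocks.

A degree-l block of coefficients transforms under a rotation R by the
(2l+1)x(2l+1) orthogonal matrix D^l(R) defined by

    S_{lm}(R x) = sum_{m'} D^l_{mm'}(R) S_{lm'}(x)   for every unit vector x.

The matrix is recovered numerically from that defining relation on a fixed,
well-spread set of sample directions (a Fibonacci sphere), which is exact up to
floating point because the relation is linear and the sample matrix has full
column rank.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .basis import real_sph_harm_block

__all__ = ["real_wigner_d", "random_rotation", "check_rotation"]


def check_rotation(rot: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate that ``rot`` is a proper rotation (orthogonal, det +1)."""
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rot.T @ rot, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthogonal")
    if not np.isclose(np.linalg.det(rot), 1.0, atol=tol):
        raise ValueError("matrix determinant is not +1 (improper rotation)")
    return rot


@lru_cache(maxsize=32)
def _sample_directions(l: int) -> np.ndarray:
    """Fibonacci-sphere directions, comfortably overdetermining degree l."""
    n = max(4 * (2 * l + 1), 32)
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def _angles(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    return theta, phi


def real_wigner_d(l: int, rot: np.ndarray) -> np.ndarray:
    """Real Wigner-D matrix of degree ``l`` for proper rotation ``rot``."""
    rot = check_rotation(rot)
    if l == 0:
        return np.ones((1, 1))
    pts = _sample_directions(l)
    a = real_sph_harm_block(l, *_angles(pts))          # (N, 2l+1)
    b = real_sph_harm_block(l, *_angles(pts @ rot.T))  # S(R x)
    # b = a @ D^T  =>  solve least squares (exact relation)
    d_t, *_ = np.linalg.lstsq(a, b, rcond=None)
    return d_t.T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
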
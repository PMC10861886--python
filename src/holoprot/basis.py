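"""Orthonormal basis functions on the unit ball: real spherical harmonics and
3D Zernike radial polynomials.

The angular part uses real spherical harmonics :math:`S_{\\ell m}`, orthonormal on
the unit sphere, built from the complex harmonics with the Condon--Shortley phase
absorbed.  The radial part uses 3D Zernike polynomials :math:`R_{n\\ell}`,
normalised to unit norm under the measure :math:`r^2\\,dr` on [0, 1]:

.. math::

    \\int_0^1 R_{n\\ell}(r) R_{n'\\ell}(r)\\, r^2\\, dr = \\delta_{nn'}.

:math:`R_{n\\ell}` is nonzero only when :math:`n \\ge \\ell` and :math:`n-\\ell`
is even; the nonnegative integer :math:`(n-\\ell)/2` plays the role of a radial
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_jacobi, sph_harm_y

__all__ = [
    "BasisSpec",
    "spherical_harmonic",
    "real_sph_harm_block",
    "zernike_radial",
]


@dataclass(frozen=True)
class BasisSpec:
    """Truncation of the 3D Zernike basis.

    Parameters
    ----------
    l_max : int
        Largest spherical-harmonic degree retained.
    n_max : int
        Largest radial index retained; must satisfy ``n_max >= l_max``.
    r_max : float
        Physical radius (angstrom) mapped onto the unit ball.
    """

    l_max: int = 6
    n_max: int = 10
    r_max: float = 10.0

    def __post_init__(self) -> None:
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")
        if self.n_max < self.l_max:
            raise ValueError("n_max must be >= l_max")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    def n_list(self, l: int) -> list[int]:
        """Radial indices retained for degree ``l``: n = l, l+2, ... <= n_max."""
        if not 0 <= l <= self.l_max:
            raise ValueError(f"degree {l} outside basis (l_max={self.l_max})")
        return list(range(l, self.n_max + 1, 2))

    def index_pairs(self) -> list[tuple[int, int]]:
        """All retained (n, l) pairs, l ascending then n ascending."""
        return [(n, l) for l in range(self.l_max + 1) for n in self.n_list(l)]


def spherical_harmonic(l: int, m: int, theta, phi):
    """Real orthonormal spherical harmonic S_{lm}(theta, phi).

    ``theta`` is the polar angle in [0, pi], ``phi`` the azimuth.  Conventions:
    ``m > 0`` are the cosine-type harmonics (S_{1,1} ~ x), ``m < 0`` the
    sine-type (S_{1,-1} ~ y), ``m = 0`` the zonal ones.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds degree l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


def real_sph_harm_block(l: int, theta, phi) -> np.ndarray:
    """All 2l+1 real harmonics of degree ``l`` at the given angles.

    Returns an array of shape ``theta.shape + (2l+1,)`` with m running from
    -l to +l.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    out = np.empty(theta.shape + (2 * l + 1,))
    out[..., l] = np.real(sph_harm_y(l, 0, theta, phi))
    for m in range(1, l + 1):
        y = sph_harm_y(l, m, theta, phi)
        out[..., l + m] = np.sqrt(2.0) * (-1.0) ** m * np.real(y)
        out[..., l - m] = np.sqrt(2.0) * (-1.0) ** m * np.imag(y)
    return out


def zernike_radial(n: int, l: int, r):
    """3D Zernike radial polynomial R_{nl}(r), unit-normalised on r^2 dr.

    Zero when ``n < l`` or ``n - l`` is odd.  ``r`` must lie in [0, 1].
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("radial argument must lie in [0, 1]")
    if n < l or (n - l) % 2 != 0:
        return np.zeros_like(r)
    k = (n - l) // 2
    # R_nl(r) = sqrt(2n+3) r^l P_k^{(0, l+1/2)}(2 r^2 - 1)
    return np.sqrt(2.0 * n + 3.0) * r**l * eval_jacobi(k, 0.0, l + 0.5, 2.0 * r**2 - 1.0)
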
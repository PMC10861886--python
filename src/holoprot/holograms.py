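"""Holographic encoding: channelised point clouds -> equivariant Zernike coefficients.

An atomic neighborhood defines, per channel c, a weighted delta-function density

    rho_c(r) = sum_i  v_i^c  delta^3(r - r_i),

which is projected onto the 3D Zernike basis.  Because the density is a sum of
deltas, the projection integral collapses to a sum over atoms:

    Z^c_{n l m} = sum_i  v_i^c  R_{nl}(|r_i| / r_max)  S_{lm}(theta_i, phi_i).

Rotating the point cloud transforms each degree-l block of coefficients by the
real Wigner-D matrix of degree l (``rotate_coefficients``), which is the
rotational equivariance that downstream network layers preserve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, real_sph_harm_block, zernike_radial
from .wigner import real_wigner_d

__all__ = ["HologramCoefficients", "encode", "rotate_coefficients", "reconstruct"]


@dataclass
class HologramCoefficients:
    """Spherical-Fourier (3D Zernike) coefficients of one neighborhood.

    ``blocks[l]`` has shape ``(n_rows, 2l+1)`` with m running -l..l; rows are
    ordered channel-major: ``[(c, n) for c in channels for n in basis.n_list(l)]``.
    """

    basis: BasisSpec
    channels: tuple[str, ...]
    blocks: dict[int, np.ndarray]

    def row_labels(self, l: int) -> list[tuple[str, int]]:
        return [(c, n) for c in self.channels for n in self.basis.n_list(l)]

    def get(self, channel: str, n: int, l: int, m: int) -> float:
        """Single coefficient Z^c_{nlm}."""
        row = self.row_labels(l).index((channel, n))
        return float(self.blocks[l][row, l + m])

    def norm(self) -> float:
        return float(np.sqrt(sum(np.sum(b**2) for b in self.blocks.values())))

    def allclose(self, other: "HologramCoefficients", rtol=1e-6, atol=1e-9) -> bool:
        return all(
            np.allclose(self.blocks[l], other.blocks[l], rtol=rtol, atol=atol)
            for l in self.blocks
        )

    def __add__(self, other: "HologramCoefficients") -> "HologramCoefficients":
        return HologramCoefficients(
            self.basis, self.channels,
            {l: self.blocks[l] + other.blocks[l] for l in self.blocks},
        )

    def scaled(self, a: float) -> "HologramCoefficients":
        return HologramCoefficients(
            self.basis, self.channels, {l: a * b for l, b in self.blocks.items()}
        )


def _angles(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = np.linalg.norm(xyz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, xyz[:, 2] / np.where(r > 0, r, 1.0), 1.0)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    return r, theta, phi


def encode(neighborhood, basis: BasisSpec) -> HologramCoefficients:
    """Project a channelised point cloud onto the truncated Zernike basis.

    The encoding is linear in the channel weights and invariant to the order
    of the atoms.  Points beyond ``basis.r_max`` raise: the caller decides
    whether to clip or rescale.
    """
    channels = tuple(neighborhood.channels)
    xyz = np.asarray(neighborhood.atom_coords, dtype=float)
    n_atoms = xyz.shape[0]
    r, theta, phi = _angles(xyz) if n_atoms else (np.empty(0),) * 3
    if n_atoms and r.max() > basis.r_max * (1 + 1e-12):
        raise ValueError(
            f"point at radius {r.max():.3f} A exceeds basis r_max={basis.r_max} A"
        )
    u = r / basis.r_max if n_atoms else r

    # per-channel weights scattered onto the shared atom list
    weights = {}
    for c in channels:
        w = np.zeros(n_atoms)
        idx = neighborhood.channel_index[c]
        if len(idx):
            w[idx] = neighborhood.channel_weight[c]
        weights[c] = w

    blocks: dict[int, np.ndarray] = {}
    for l in range(basis.l_max + 1):
        ns = basis.n_list(l)
        if n_atoms == 0:
            blocks[l] = np.zeros((len(channels) * len(ns), 2 * l + 1))
            continue
        y = real_sph_harm_block(l, theta, phi)                  # (M, 2l+1)
        rad = np.stack([zernike_radial(n, l, u) for n in ns])   # (Nn, M)
        rows = [rad @ (y * weights[c][:, None]) for c in channels]
        blocks[l] = np.concatenate(rows, axis=0)
    return HologramCoefficients(basis=basis, channels=channels, blocks=blocks)


def rotate_coefficients(coeffs: HologramCoefficients, rotation: np.ndarray) -> HologramCoefficients:
    """Apply the per-degree real Wigner-D matrices to each coefficient block.

    Equivalent to encoding the rotated point cloud; degree-0 coefficients are
    untouched (they are the rotation-invariant part).
    """
    blocks = {}
    for l, b in coeffs.blocks.items():
        d = real_wigner_d(l, rotation)
        blocks[l] = b @ d.T
    return HologramCoefficients(coeffs.basis, coeffs.channels, blocks)


def reconstruct(coeffs: HologramCoefficients, grid_points: np.ndarray) -> dict[str, np.ndarray]:
    """Band-limited density field at the given points (validation utility).

    ``grid_points`` are in the same physical units as the encoded cloud and
    must lie inside the ball of radius ``basis.r_max``.
    """
    xyz = np.atleast_2d(np.asarray(grid_points, dtype=float))
    r, theta, phi = _angles(xyz)
    if len(r) and r.max() > coeffs.basis.r_max * (1 + 1e-12):
        raise ValueError("grid point outside the basis ball")
    u = r / coeffs.basis.r_max
    fields = {c: np.zeros(xyz.shape[0]) for c in coeffs.channels}
    for l in range(coeffs.basis.l_max + 1):
        y = real_sph_harm_block(l, theta, phi)                  # (P, 2l+1)
        ns = coeffs.basis.n_list(l)
        rad = np.stack([zernike_radial(n, l, u) for n in ns])   # (Nn, P)
        labels = coeffs.row_labels(l)
        for row, (c, n) in enumerate(labels):
            ni = ns.index(n)
            fields[c] += rad[ni] * (y @ coeffs.blocks[l][row])
    return fields
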
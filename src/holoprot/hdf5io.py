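"""HDF5 containers for neighborhoods and hologram coefficients.

Layout (one group per item, zero-padded decimal keys preserving order):

``neighborhoods.h5``::

    /<k>/atom_coords   (M, 3) float  -- re-centred coordinates, angstrom
    /<k>/<channel>/index, /<k>/<channel>/weight
    attrs: chain, site, ins_code, label, channels

``coefficients.h5``::

    /<k>/l<degree>     (rows, 2l+1) float
    attrs: label; file attrs: l_max, n_max, r_max, channels
"""

from __future__ import annotations

import h5py
import numpy as np

from .basis import BasisSpec
from .holograms import HologramCoefficients
from .structure import Neighborhood

__all__ = [
    "save_neighborhoods", "load_neighborhoods",
    "save_coefficients", "load_coefficients",
]


def save_neighborhoods(path, neighborhoods: list[Neighborhood]) -> None:
    with h5py.File(path, "w") as f:
        for k, nb in enumerate(neighborhoods):
            g = f.create_group(f"{k:06d}")
            g.attrs["chain"], g.attrs["site"], g.attrs["ins_code"] = nb.focal_residue
            g.attrs["label"] = nb.label or ""
            g.attrs["channels"] = list(nb.channels)
            g.create_dataset("atom_coords", data=nb.atom_coords)
            for ch in nb.channels:
                cg = g.create_group(ch)
                cg.create_dataset("index", data=nb.channel_index[ch])
                cg.create_dataset("weight", data=nb.channel_weight[ch])


def load_neighborhoods(path) -> list[Neighborhood]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            channels = tuple(g.attrs["channels"])
            out.append(Neighborhood(
                focal_residue=(str(g.attrs["chain"]), int(g.attrs["site"]),
                               str(g.attrs["ins_code"])),
                label=str(g.attrs["label"]) or None,
                channels=channels,
                atom_coords=np.asarray(g["atom_coords"]),
                channel_index={ch: np.asarray(g[ch]["index"], dtype=int)
                               for ch in channels},
                channel_weight={ch: np.asarray(g[ch]["weight"], dtype=float)
                                for ch in channels},
            ))
    return out


def save_coefficients(path, coeffs: list[HologramCoefficients],
                      labels: list[str] | None = None) -> None:
    if not coeffs:
        raise ValueError("nothing to save")
    basis = coeffs[0].basis
    with h5py.File(path, "w") as f:
        f.attrs["l_max"], f.attrs["n_max"], f.attrs["r_max"] = (
            basis.l_max, basis.n_max, basis.r_max)
        f.attrs["channels"] = list(coeffs[0].channels)
        for k, c in enumerate(coeffs):
            g = f.create_group(f"{k:06d}")
            if labels is not None:
                g.attrs["label"] = labels[k]
            for l, b in c.blocks.items():
                g.create_dataset(f"l{l}", data=b)


def load_coefficients(path) -> tuple[list[HologramCoefficients], list[str | None]]:
    out, labels = [], []
    with h5py.File(path, "r") as f:
        basis = BasisSpec(l_max=int(f.attrs["l_max"]), n_max=int(f.attrs["n_max"]),
                          r_max=float(f.attrs["r_max"]))
        channels = tuple(f.attrs["channels"])
        for key in sorted(f.keys()):
            g = f[key]
            blocks = {int(name[1:]): np.asarray(g[name]) for name in g.keys()}
            out.append(HologramCoefficients(basis, channels, blocks))
            labels.append(str(g.attrs["label"]) if "label" in g.attrs else None)
    return out, labels
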
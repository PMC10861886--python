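"""Synthetic inputs for building and testing every stage without downloads.

Three generators:

* ``make_class_dataset`` -- labelled point-cloud classes whose identity is
  carried *only* by rotation-invariant geometry (shell radii); every sample is
  randomly rotated, so any classifier that beats chance must be
  rotation-robust.
* ``make_polyalanine`` / ``build_chain`` -- ideal-geometry peptide backbones
  with prescribed (phi, psi), the substrate for backbone-shear experiments.
* ``make_random_neighborhood`` -- uniform-in-ball channelised clouds.

All generators are pure functions of their arguments (bit-reproducible given
the seed).
"""

from __future__ import annotations

import numpy as np
import biotite.structure as bst
from biotite.sequence import ProteinSequence

from .geometry import place_atom
from .network import AA_ALPHABET
from .structure import DEFAULT_CHANNELS, ELEMENT_CHANNELS, Neighborhood, Structure
from .wigner import random_rotation

__all__ = [
    "make_class_dataset",
    "make_random_neighborhood",
    "make_polyalanine",
    "build_chain",
    "make_synthetic_protein_g",
    "SYNTHETIC_PROTEIN_G_SEQUENCE",
]

# ideal backbone internal coordinates (angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.4
TORSION_CB = 123.0  # dihedral(C_i, N_i, CA_i, CB_i); fixes a consistent handedness

_D = np.deg2rad


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


# class templates: per class a list of (shell radius, n points on that shell).
# Mean radii are pairwise distinct so a radius-only classifier separates them.
_CLASS_SHELLS = [
    [(3.0, 12)],
    [(6.5, 12)],
    [(3.0, 6), (8.0, 6)],
    [(4.75, 12)],
    [(2.0, 4), (8.0, 8)],
]


def _class_template(k: int) -> np.ndarray:
    pts = []
    for radius, n in _CLASS_SHELLS[k]:
        pts.append(radius * _fibonacci_directions(n))
    return np.concatenate(pts, axis=0)


def _template_channels(n_points: int, channels: tuple[str, ...]):
    """Deterministic channel assignment shared by all classes."""
    elements = ["C", "N", "O", "S", "H"]
    elem_of = [elements[i % 5] for i in range(n_points)]
    idx = {}
    wt = {}
    all_idx = np.arange(n_points)
    for ch in channels:
        if ch in ELEMENT_CHANNELS:
            sub = np.array([i for i in all_idx if elem_of[i] == ELEMENT_CHANNELS[ch]],
                           dtype=int)
            idx[ch] = sub
            wt[ch] = np.ones(len(sub))
        elif ch == "charge":
            idx[ch] = all_idx.copy()
            wt[ch] = np.array([0.5 * (-1) ** i for i in range(n_points)])
        elif ch == "SASA":
            idx[ch] = all_idx.copy()
            wt[ch] = 1.0 + (all_idx % 3).astype(float)
        else:
            raise ValueError(f"unknown channel {ch!r}")
    return idx, wt


def make_class_dataset(
    n_classes: int = 3,
    n_per_class: int = 100,
    jitter: float = 0.25,
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> list[tuple[Neighborhood, str]]:
    """Labelled neighborhoods whose classes differ only by invariant geometry.

    Each class has a fixed template point cloud (concentric shells with
    class-specific radii); a sample is a uniformly random rotation of the
    template plus isotropic Gaussian jitter of SD ``jitter`` angstrom.  Labels
    are the first ``n_classes`` letters of the amino-acid alphabet.
    """
    if not 2 <= n_classes <= len(_CLASS_SHELLS):
        raise ValueError(f"n_classes must be in [2, {len(_CLASS_SHELLS)}]")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_classes):
        template = _class_template(k)
        idx, wt = _template_channels(len(template), channels)
        label = AA_ALPHABET[k]
        for _ in range(n_per_class):
            rot = random_rotation(rng)
            coords = template @ rot.T
            if jitter > 0:
                coords = coords + rng.normal(0.0, jitter, coords.shape)
            nb = Neighborhood(
                focal_residue=("X", k, ""),
                label=label,
                channels=tuple(channels),
                atom_coords=coords,
                channel_index={c: v.copy() for c, v in idx.items()},
                channel_weight={c: v.copy() for c, v in wt.items()},
            )
            out.append((nb, label))
    return out


def make_random_neighborhood(
    n_atoms: int,
    radius: float = 10.0,
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> Neighborhood:
    """Uniform-in-ball random channelised cloud (testing utility)."""
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_atoms, 3))
    dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    r = radius * 0.999 * rng.uniform(0, 1, n_atoms) ** (1.0 / 3.0)
    coords = dirs * r[:, None]
    elements = rng.choice(["C", "N", "O", "S", "H"], size=n_atoms,
                          p=[0.35, 0.15, 0.2, 0.05, 0.25])
    idx, wt = {}, {}
    all_idx = np.arange(n_atoms)
    for ch in channels:
        if ch in ELEMENT_CHANNELS:
            sub = all_idx[elements == ELEMENT_CHANNELS[ch]]
            idx[ch] = sub
            wt[ch] = np.ones(len(sub))
        elif ch == "charge":
            idx[ch] = all_idx.copy()
            wt[ch] = rng.normal(0.0, 0.3, n_atoms)
        elif ch == "SASA":
            idx[ch] = all_idx.copy()
            wt[ch] = rng.uniform(0.0, 20.0, n_atoms)
        else:
            raise ValueError(f"unknown channel {ch!r}")
    return Neighborhood(("X", 0, ""), None, tuple(channels), coords, idx, wt)


# ---------------------------------------------------------------------------
# ideal-geometry peptide chains
# ---------------------------------------------------------------------------

def build_chain(
    sequence: str,
    phi: np.ndarray | float,
    psi: np.ndarray | float,
    chain_id: str = "A",
) -> Structure:
    """Peptide chain with ideal bond lengths/angles and prescribed dihedrals.

    ``phi``/``psi`` in degrees, scalar or per-residue arrays; omega is fixed at
    180 (trans).  Atoms per residue: N, CA, C, O and CB (except glycine).
    phi[0] and psi[-1] only orient terminal substituents.
    """
    n = len(sequence)
    if n < 3:
        raise ValueError("need at least 3 residues")
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,)).copy()
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n,)).copy()

    bb_n = np.zeros((n, 3))
    bb_ca = np.zeros((n, 3))
    bb_c = np.zeros((n, 3))
    bb_n[0] = (0.0, 0.0, 0.0)
    bb_ca[0] = (BOND_N_CA, 0.0, 0.0)
    bb_c[0] = place_atom((0.0, 1.0, 0.0), bb_n[0], bb_ca[0],
                         BOND_CA_C, _D(ANGLE_N_CA_C), 0.0)
    for i in range(1, n):
        bb_n[i] = place_atom(bb_n[i - 1], bb_ca[i - 1], bb_c[i - 1],
                             BOND_C_N, _D(ANGLE_CA_C_N), _D(psi[i - 1]))
        bb_ca[i] = place_atom(bb_ca[i - 1], bb_c[i - 1], bb_n[i],
                              BOND_N_CA, _D(ANGLE_C_N_CA), _D(180.0))
        bb_c[i] = place_atom(bb_c[i - 1], bb_n[i], bb_ca[i],
                             BOND_CA_C, _D(ANGLE_N_CA_C), _D(phi[i]))

    names, coords, res_ids, res_names, elems = [], [], [], [], []
    for i, aa in enumerate(sequence):
        res3 = ProteinSequence.convert_letter_1to3(aa)
        atoms = [("N", bb_n[i], "N"), ("CA", bb_ca[i], "C"), ("C", bb_c[i], "C")]
        o = place_atom(bb_n[i], bb_ca[i], bb_c[i],
                       BOND_C_O, _D(ANGLE_CA_C_O), _D(psi[i] + 180.0))
        atoms.append(("O", o, "O"))
        if aa != "G":
            cb = place_atom(bb_c[i], bb_n[i], bb_ca[i],
                            BOND_CA_CB, _D(ANGLE_N_CA_CB), _D(TORSION_CB))
            atoms.append(("CB", cb, "C"))
        for name, xyz, elem in atoms:
            names.append(name)
            coords.append(xyz)
            res_ids.append(i + 1)
            res_names.append(res3)
            elems.append(elem)

    arr = bst.AtomArray(len(names))
    coords64 = np.asarray(coords, dtype=np.float64)
    arr.coord = coords64
    arr.chain_id = np.full(len(names), chain_id, dtype="U4")
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.res_name = np.asarray(res_names, dtype="U5")
    arr.atom_name = np.asarray(names, dtype="U6")
    arr.element = np.asarray(elems, dtype="U2")
    arr.hetero = np.zeros(len(names), dtype=bool)
    return Structure(arr, coord=coords64)


def make_polyalanine(n_residues: int, phi: float = -57.0, psi: float = -47.0) -> Structure:
    """Ideal poly-alanine chain with uniform (phi, psi); omega = 180."""
    return build_chain("A" * n_residues, phi, psi)


# --- synthetic stand-in for protein G (B1 domain) --------------------------

SYNTHETIC_PROTEIN_G_SEQUENCE = (
    "MTYKLILNGKTLKGETTTEAVDAATAEKVFKQYANDNGVDGEWTYDDATKTFTVTE"
)

# (start, end) 1-based inclusive, secondary structure of the B1 domain
_PROTEIN_G_SHEETS = [(1, 8), (13, 19), (42, 46), (51, 55)]
_PROTEIN_G_HELIX = (23, 36)


def make_synthetic_protein_g() -> Structure:
    """SYNTHETIC stand-in for the 56-residue protein G B1 domain.

    Carries the real B1-domain sequence, but coordinates are built from ideal
    backbone geometry with per-segment (phi, psi) set by the domain's known
    secondary structure (four beta strands and one alpha helix, loops
    elsewhere).  It is *not* the crystal structure: it has correct local
    geometry and realistic site count for backbone-perturbation experiments,
    not the native tertiary fold.
    """
    n = len(SYNTHETIC_PROTEIN_G_SEQUENCE)
    phi = np.full(n, -80.0)
    psi = np.full(n, 100.0)
    for a, b in _PROTEIN_G_SHEETS:
        phi[a - 1:b] = -120.0
        psi[a - 1:b] = 130.0
    a, b = _PROTEIN_G_HELIX
    phi[a - 1:b] = -57.0
    psi[a - 1:b] = -47.0
    return build_chain(SYNTHETIC_PROTEIN_G_SEQUENCE, phi, psi)
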
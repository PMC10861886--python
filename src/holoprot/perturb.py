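"""In-silico backbone shear perturbation and distortion / energy-response scans.

A shear at site i twists the two flanking backbone dihedrals in compensation:

    [phi_i, psi_{i-1}]  ->  [phi_i + delta, psi_{i-1} - delta],

rotating rigid groups of atoms about the N_i-CA_i and CA_{i-1}-C_{i-1} axes.
The compensation keeps the distortion local: far-away residues move an order
of magnitude less than the perturbed site.  Structural distortion is the RMS
change of all pairwise atom distances that are below a cutoff (default 10
angstrom, evaluated on the unperturbed structure), signed by the direction of
the psi change (negative for delta > 0).  The network-energy response is
Delta E = E(perturbed) - E(wild type), with E the sum over sites of the
wild-type amino acid's pseudoenergy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .geometry import dihedral, rotation_about_axis
from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = ["ShearSpec", "DistortionResult", "apply_shear", "distortion",
           "measure_phi_psi", "shear_scan"]


@dataclass(frozen=True)
class ShearSpec:
    """A shear perturbation: residue index ``site`` (0-based) and angle ``delta`` (degrees)."""

    site: int
    delta: float
    max_delta: float = 20.0

    def __post_init__(self):
        if abs(self.delta) > self.max_delta + 1e-9:
            raise ValueError(f"|delta| exceeds the {self.max_delta} degree cap")


@dataclass
class DistortionResult:
    spec: ShearSpec
    signed_rms: float
    delta_e: float | None


def measure_phi_psi(structure: Structure, i: int) -> tuple[float, float]:
    """(phi_i, psi_{i-1}) in degrees; the pair a shear at site i changes."""
    prev_c = structure.backbone_coords(i - 1, "C")
    n = structure.backbone_coords(i, "N")
    ca = structure.backbone_coords(i, "CA")
    c = structure.backbone_coords(i, "C")
    prev_n = structure.backbone_coords(i - 1, "N")
    prev_ca = structure.backbone_coords(i - 1, "CA")
    if any(p is None for p in (prev_c, n, ca, c, prev_n, prev_ca)):
        raise ValueError(f"residue {i} or {i-1} lacks backbone atoms")
    phi = np.rad2deg(dihedral(prev_c, n, ca, c))
    psi_prev = np.rad2deg(dihedral(prev_n, prev_ca, prev_c, n))
    return float(phi), float(psi_prev)


def _rotate_subset(coords: np.ndarray, mask: np.ndarray, origin: np.ndarray,
                   axis: np.ndarray, angle_deg: float) -> np.ndarray:
    rot = rotation_about_axis(axis, np.deg2rad(angle_deg))
    out = coords.copy()
    out[mask] = (coords[mask] - origin) @ rot.T + origin
    return out


def apply_shear(structure: Structure, spec: ShearSpec) -> Structure:
    """Apply the compensating [phi_i + delta, psi_{i-1} - delta] backbone shear.

    The C-terminal side of each rotation axis moves rigidly (lever convention:
    the N-terminal part of the chain stays fixed), so all bond lengths and bond
    angles are preserved exactly; only the two targeted dihedrals change.
    """
    i = spec.site
    if i <= 0 or i >= structure.n_residues - 1:
        raise ValueError("shear site must be an interior residue "
                         "(phi_i and psi_{i-1} must both exist)")
    if spec.delta == 0.0:
        return structure.copy()
    arr = structure.array.copy()
    res_of = structure.residue_index_of_atoms()
    coords = structure.coords.copy()

    phi0, psi0 = measure_phi_psi(structure, i)

    # phi_i: rotate about the N_i -> CA_i axis; everything C-terminal of CA_i
    # moves, i.e. residues > i plus residue i's atoms other than N (and its H).
    n_i = structure.backbone_coords(i, "N")
    ca_i = structure.backbone_coords(i, "CA")
    mask_phi = (res_of > i) | (
        (res_of == i) & ~np.isin(arr.atom_name, ["N", "H", "H1", "H2", "H3"])
    )
    axis = ca_i - n_i
    coords = _rotate_subset(coords, mask_phi, n_i, axis, spec.delta)

    # psi_{i-1}: rotate about CA_{i-1} -> C_{i-1}; residues >= i move, plus the
    # carbonyl oxygen of residue i-1 (it rides with the peptide plane).
    ca_p = structure.backbone_coords(i - 1, "CA")
    c_p = structure.backbone_coords(i - 1, "C")
    mask_psi = (res_of >= i) | (
        (res_of == i - 1) & np.isin(arr.atom_name, ["O", "OXT"])
    )
    axis2 = c_p - ca_p
    coords = _rotate_subset(coords, mask_psi, ca_p, axis2, -spec.delta)

    out = Structure(arr, coord=coords)

    phi1, psi1 = measure_phi_psi(out, i)
    d_phi = (phi1 - phi0 - spec.delta + 180.0) % 360.0 - 180.0
    d_psi = (psi1 - psi0 + spec.delta + 180.0) % 360.0 - 180.0
    if abs(d_phi) > 1e-6 or abs(d_psi) > 1e-6:
        raise AssertionError(
            f"shear did not hit its dihedral targets (residual {d_phi:.2e}, {d_psi:.2e} deg)"
        )
    return out


def distortion(
    wt: Structure,
    perturbed: Structure,
    spec: ShearSpec,
    cutoff: float = 10.0,
    include_hydrogens: bool = False,
) -> float:
    """Signed RMS change of sub-cutoff pairwise atom distances.

    Pairs are selected by their distance in the *wild-type* structure; heavy
    atoms only by default.  The sign is that of the psi change, i.e.
    ``-sign(delta)``.
    """
    a_wt, a_p = wt.array, perturbed.array
    if a_wt.array_length() != a_p.array_length():
        raise ValueError("structures have different atom counts")
    sel = np.ones(a_wt.array_length(), dtype=bool)
    if not include_hydrogens:
        sel = a_wt.element != "H"
    d0 = pdist(wt.coords[sel])
    d1 = pdist(perturbed.coords[sel])
    mask = d0 < cutoff
    if not mask.any():
        return 0.0
    rms = float(np.sqrt(np.mean((d1[mask] - d0[mask]) ** 2)))
    sign = -np.sign(spec.delta) if spec.delta != 0 else 0.0
    return float(sign * rms) if spec.delta != 0 else rms


def shear_scan(
    model,
    structure: Structure,
    sites: list[int] | None = None,
    deltas: list[float] | None = None,
    cutoff: float = 10.0,
    max_delta: float = 20.0,
) -> pd.DataFrame:
    """Shear every (site, delta) pair and tabulate distortion and Delta E.

    ``model=None`` skips the network-energy column (geometry-only scan).
    Per-site failures are logged and the scan continues.  The result is sorted
    by site then delta.
    """
    from .scoring import network_energy  # deferred: scoring imports this module's types

    if sites is None:
        sites = list(range(1, structure.n_residues - 1))
    if deltas is None:
        deltas = [d for d in range(-20, 21, 2)]
    e_wt = network_energy(model, structure) if model is not None else None
    rows = []
    for site in sites:
        for delta in deltas:
            spec = ShearSpec(site=site, delta=float(delta), max_delta=max_delta)
            try:
                pert = apply_shear(structure, spec) if delta != 0 else structure.copy()
                srms = distortion(structure, pert, spec, cutoff=cutoff)
                de = None
                if model is not None:
                    de = network_energy(model, pert) - e_wt
                rows.append({
                    "site": site,
                    "aa": structure.residue_label(site),
                    "delta_deg": float(delta),
                    "signed_rms_A": srms,
                    "delta_E": de if de is not None else np.nan,
                })
            except Exception as exc:
                logger.warning("shear failed at site %d delta %s: %s", site, delta, exc)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["site", "delta_deg"]).reset_index(drop=True)
    return df
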
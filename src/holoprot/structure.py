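"""Structure parsing, physicochemical annotation, and microenvironment extraction.

A microenvironment (``Neighborhood``) is the set of all atoms within a fixed
radius (default 10 angstrom, strict upper bound) of a focal residue's alpha
carbon, *excluding* the focal residue's own atoms, re-centred on that alpha
carbon.  Atoms are spread over channels: one channel per element
(C, N, O, S, H, unit weight) plus optional ``charge`` and ``SASA`` channels
whose weights are the annotated per-atom values.

Parsing is backed by biotite; SASA uses biotite's Shrake-Rupley implementation
with a fixed quadrature point count, and partial charges come from a bundled
formal-charge template (CSV, user-overridable).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Neighborhood",
    "ParseError",
    "read_structure",
    "annotate",
    "extract_neighborhoods",
    "add_noise",
    "load_charge_table",
    "DEFAULT_CHANNELS",
    "ELEMENT_CHANNELS",
]

ELEMENT_CHANNELS = {
    "carbon": "C",
    "nitrogen": "N",
    "oxygen": "O",
    "sulfur": "S",
    "hydrogen": "H",
}
DEFAULT_CHANNELS = ("carbon", "nitrogen", "oxygen", "sulfur", "hydrogen", "charge", "SASA")
KNOWN_ELEMENTS = frozenset(ELEMENT_CHANNELS.values())
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Formal charges of the charged side-chain groups; everything else is 0.
RESIDUE_FORMAL_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """A single atom with optional physicochemical annotations."""

    element: str
    coords: np.ndarray
    residue_id: tuple[str, int, str]
    residue_name: str
    atom_name: str
    charge: float | None = None
    sasa: float | None = None

    @property
    def element_known(self) -> bool:
        return self.element in KNOWN_ELEMENTS


class Structure:
    """Parsed macromolecular coordinates with residue-level accessors.

    Thin wrapper around a biotite ``AtomArray``; per-atom ``charge`` and
    ``sasa`` annotations are attached by :func:`annotate`.
    """

    def __init__(self, array: bst.AtomArray, coord: np.ndarray | None = None):
        if array.array_length() == 0:
            raise ParseError("structure contains no atoms")
        self.array = array
        # biotite stores coordinates in float32; geometry (dihedrals, shear
        # round trips) needs full double precision, so keep a float64 master.
        self._coord = np.array(array.coord if coord is None else coord,
                               dtype=np.float64)
        if coord is not None:
            array.coord = self._coord  # keep the float32 view in sync
        self._starts = bst.get_residue_starts(array, add_exclusive_stop=True)
        self._label_cache: list[str | None] | None = None

    # -- residue level -------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self._starts) - 1

    def residue_slice(self, i: int) -> slice:
        return slice(self._starts[i], self._starts[i + 1])

    def residue_id(self, i: int) -> tuple[str, int, str]:
        k = self._starts[i]
        a = self.array
        icode = a.ins_code[k] if "ins_code" in a.get_annotation_categories() else ""
        return (str(a.chain_id[k]), int(a.res_id[k]), str(icode))

    def residue_name(self, i: int) -> str:
        return str(self.array.res_name[self._starts[i]])

    def residue_label(self, i: int) -> str | None:
        """1-letter amino-acid label, or None for non-standard residues."""
        if self._label_cache is None:
            self._label_cache = [None] * self.n_residues
        if self._label_cache[i] is None:
            try:
                self._label_cache[i] = ProteinSequence.convert_letter_3to1(
                    self.residue_name(i)
                )
            except KeyError:
                self._label_cache[i] = ""
        return self._label_cache[i] or None

    def atom_index(self, i: int, atom_name: str) -> int | None:
        sl = self.residue_slice(i)
        hits = np.nonzero(self.array.atom_name[sl] == atom_name)[0]
        return int(sl.start + hits[0]) if len(hits) else None

    def backbone_coords(self, i: int, atom_name: str) -> np.ndarray | None:
        """Coordinates of a named backbone atom (N, CA, C, O) of residue i."""
        idx = self.atom_index(i, atom_name)
        return None if idx is None else self._coord[idx].copy()

    def find_residue(self, chain: str, res_id: int, ins_code: str = "") -> int:
        for i in range(self.n_residues):
            if self.residue_id(i) == (chain, res_id, ins_code):
                return i
        raise KeyError(f"residue {chain}/{res_id}{ins_code!r} not found")

    # -- atom level ----------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """Full-precision (float64) coordinate array, shape (n_atoms, 3)."""
        return self._coord

    @property
    def elements(self) -> np.ndarray:
        return self.array.element

    def residue_index_of_atoms(self) -> np.ndarray:
        out = np.empty(self.array.array_length(), dtype=int)
        for i in range(self.n_residues):
            out[self.residue_slice(i)] = i
        return out

    @property
    def is_annotated(self) -> bool:
        cats = self.array.get_annotation_categories()
        return "charge" in cats and "sasa" in cats

    def atoms(self):
        """Iterate over :class:`Atom` views (convenience, not the fast path)."""
        a = self.array
        res_of = self.residue_index_of_atoms()
        annotated = self.is_annotated
        for k in range(a.array_length()):
            i = res_of[k]
            yield Atom(
                element=str(a.element[k]),
                coords=self._coord[k].copy(),
                residue_id=self.residue_id(i),
                residue_name=str(a.res_name[k]),
                atom_name=str(a.atom_name[k]),
                charge=float(a.charge[k]) if annotated else None,
                sasa=float(a.sasa[k]) if annotated else None,
            )

    # -- geometry helpers ---------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """New Structure with coordinates rigidly transformed (for tests/sanity)."""
        coord = self._coord
        if rotation is not None:
            coord = coord @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coord = coord + np.asarray(translation, dtype=float)
        return Structure(self.array.copy(), coord=coord)

    def copy(self) -> "Structure":
        return Structure(self.array.copy(), coord=self._coord)

    def to_pdb(self, path) -> None:
        arr = self.array.copy()
        arr.coord = self._coord
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(str(path))


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_structure(path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    First model only; alternate locations resolved to the highest occupancy;
    waters removed; atoms with unrecognised elements are kept but flagged (they
    are excluded from element channels downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffixes[0] if path.suffixes else ""
        format = {".pdb": "pdb", ".ent": "pdb", ".cif": "mmcif", ".mmcif": "mmcif"}.get(
            suffix.lower(), "pdb"
        )
    try:
        if format == "pdb":
            with _open_maybe_gz(path) as fh:
                pdb = PDBFile.read(fh)
            array = pdb.get_structure(
                model=1, altloc="occupancy", extra_fields=["occupancy"]
            )
        elif format == "mmcif":
            cif = CIFFile.read(str(path))
            array = _cif_get_structure(cif, model=1, altloc="occupancy")
        else:
            raise ValueError(f"unknown format {format!r}")
    except ValueError:
        raise
    except Exception as exc:  # biotite raises various parse exceptions
        raise ParseError(f"could not parse {path.name}: {exc}") from exc
    if array.array_length() == 0:
        raise ParseError(f"{path.name}: no atoms in first model")
    array = array[~np.isin(array.res_name, list(WATER_NAMES))]
    array.element = np.char.upper(array.element)
    unknown = ~np.isin(array.element, list(KNOWN_ELEMENTS))
    if unknown.any():
        logger.warning(
            "%s: %d atoms with elements outside {C,N,O,S,H} flagged "
            "(kept, but excluded from element channels)",
            path.name, int(unknown.sum()),
        )
    return Structure(array)


def load_charge_table(path=None) -> dict[tuple[str, str], float]:
    """Load a (residue name, atom name) -> partial charge template table."""
    if path is None:
        path = Path(__file__).parent / "data" / "charges.csv"
    table: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("res_name"):
            raise ValueError("charge table must have a res_name,atom_name,charge header")
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, atom, q = line.split(",")
            table[(res.strip(), atom.strip())] = float(q)
    return table


def annotate(
    structure: Structure,
    probe_radius: float = 1.4,
    charge_table: dict[tuple[str, str], float] | None = None,
    sasa_points: int = 256,
) -> Structure:
    """Attach per-atom SASA (Shrake-Rupley) and partial charge annotations.

    SASA uses a rolling probe of ``probe_radius`` angstrom and a fixed number
    of quadrature points per atom.  Charges are looked up by
    (residue name, atom name) in the template table; unmatched atoms get 0.
    """
    arr = structure.array
    has_h = bool(np.isin(arr.element, ["H"]).any())
    vdw = "Single" if has_h else "ProtOr"
    try:
        sasa = bst.sasa(arr, probe_radius=probe_radius, point_number=sasa_points,
                        vdw_radii=vdw)
    except Exception:
        # fall back to the element-generic radius set (handles e.g. ions/ligands)
        sasa = bst.sasa(arr, probe_radius=probe_radius, point_number=sasa_points,
                        vdw_radii="Single")
    sasa = np.nan_to_num(np.asarray(sasa, dtype=float), nan=0.0)
    sasa[sasa < 0] = 0.0

    if charge_table is None:
        charge_table = load_charge_table()
    charge = np.zeros(arr.array_length())
    for k in range(arr.array_length()):
        key = (str(arr.res_name[k]), str(arr.atom_name[k]))
        if key in charge_table:
            charge[k] = charge_table[key]
    # sanity: residues whose charge-carrying atoms are absent (e.g. truncated
    # side chains) end up short of their formal charge -- worth a warning
    incomplete = 0
    for i in range(structure.n_residues):
        sl = structure.residue_slice(i)
        want = RESIDUE_FORMAL_CHARGE.get(structure.residue_name(i), 0.0)
        if want and not np.isclose(charge[sl].sum(), want):
            incomplete += 1
    if incomplete:
        logger.warning("%d charged residues carry less than their formal charge "
                       "(missing side-chain atoms?)", incomplete)

    arr.set_annotation("sasa", sasa)
    arr.set_annotation("charge", charge)
    structure._label_cache = None
    return structure


@dataclass
class Neighborhood:
    """Channelised point cloud around one focal residue.

    ``atom_coords`` holds each neighbour atom once (re-centred on the focal
    alpha carbon); channels refer into it by index so that coordinate noise is
    applied identically to the same atom across channels.
    """

    focal_residue: tuple[str, int, str]
    label: str | None
    channels: tuple[str, ...]
    atom_coords: np.ndarray                    # (M, 3), angstrom
    channel_index: dict[str, np.ndarray]       # channel -> indices into atom_coords
    channel_weight: dict[str, np.ndarray]      # channel -> per-point weights

    def coords(self, channel: str) -> np.ndarray:
        return self.atom_coords[self.channel_index[channel]]

    def weights(self, channel: str) -> np.ndarray:
        return self.channel_weight[channel]

    @property
    def n_atoms(self) -> int:
        return self.atom_coords.shape[0]

    def max_radius(self) -> float:
        if self.n_atoms == 0:
            return 0.0
        return float(np.linalg.norm(self.atom_coords, axis=1).max())


def extract_neighborhoods(
    structure: Structure,
    radius: float = 10.0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> list[Neighborhood]:
    """One :class:`Neighborhood` per standard residue possessing an alpha carbon.

    Inclusion is a strict upper bound (distance < ``radius``); the focal
    residue's own atoms are excluded; coordinates are re-centred on the focal
    alpha carbon.  Neighbour atoms may come from any residue, including
    non-standard ones, as long as their element channel is recognised.
    """
    channels = tuple(channels)
    needs_annotation = bool({"charge", "SASA"} & set(channels))
    if needs_annotation and not structure.is_annotated:
        raise ValueError("charge/SASA channels requested but structure is not "
                         "annotated; call annotate() first")
    arr = structure.array
    res_of = structure.residue_index_of_atoms()
    coords = structure.coords
    out: list[Neighborhood] = []
    for i in range(structure.n_residues):
        label = structure.residue_label(i)
        if label is None:
            continue
        ca = structure.backbone_coords(i, "CA")
        if ca is None:
            logger.warning("residue %s lacks CA; skipped", structure.residue_id(i))
            continue
        rel = coords - ca
        dist = np.linalg.norm(rel, axis=1)
        mask = (dist < radius) & (res_of != i)
        sel = np.nonzero(mask)[0]
        atom_coords = rel[sel]
        local = {g: j for j, g in enumerate(sel)}
        ch_index: dict[str, np.ndarray] = {}
        ch_weight: dict[str, np.ndarray] = {}
        for ch in channels:
            if ch in ELEMENT_CHANNELS:
                sub = sel[arr.element[sel] == ELEMENT_CHANNELS[ch]]
                ch_index[ch] = np.array([local[g] for g in sub], dtype=int)
                ch_weight[ch] = np.ones(len(sub))
            elif ch == "charge":
                ch_index[ch] = np.arange(len(sel), dtype=int)
                ch_weight[ch] = np.asarray(arr.charge[sel], dtype=float)
            elif ch == "SASA":
                ch_index[ch] = np.arange(len(sel), dtype=int)
                ch_weight[ch] = np.asarray(arr.sasa[sel], dtype=float)
            else:
                raise ValueError(f"unknown channel {ch!r}")
        out.append(
            Neighborhood(
                focal_residue=structure.residue_id(i),
                label=label,
                channels=channels,
                atom_coords=atom_coords,
                channel_index=ch_index,
                channel_weight=ch_weight,
            )
        )
    return out


def add_noise(neighborhood: Neighborhood, sigma: float, seed: int) -> Neighborhood:
    """Gaussian coordinate noise (training augmentation).

    Each atom's position is perturbed by an independent isotropic Gaussian of
    standard deviation ``sigma``; the same atom moves identically in every
    channel.  Points pushed beyond the extraction radius are retained: noise is
    an augmentation, not a re-query of the structure.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    coords = neighborhood.atom_coords.copy()
    if sigma > 0 and coords.size:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, sigma, size=coords.shape)
    return replace(neighborhood, atom_coords=coords)
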
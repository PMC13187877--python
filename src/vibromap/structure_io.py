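"""Protein structure I/O, residue bookkeeping, and the phosphoaspartate patch.

Structures are held as a flat, ordered list of atom records plus a mapping
from residue keys (chain, sequence number, insertion code) to contiguous
0-based residue ordinals.  Author numbering from the PDB file is kept
verbatim; ordinals are what the downstream numerical stages index with.

Reading goes through Bio.PDB (first MODEL only, altloc ' '/'A'); writing is
a direct fixed-column PDB v3.3 formatter so that names, numbering and
coordinates round-trip losslessly to three decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "ProteinStructure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "apply_phospho_patch",
    "select_region",
    "PHOSPHO_RESIDUE_NAME",
]

WATER_NAMES = {"HOH", "WAT"}

#: residue label given to a patched aspartate (PDB chemical component for
#: aspartyl phosphate)
PHOSPHO_RESIDUE_NAME = "PHD"


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a structure."""


def mass_of_element(element: str) -> float:
    """Standard atomic weight (amu) for an element symbol."""
    key = element.strip().capitalize()
    try:
        return float(atom_weights[key])
    except KeyError:
        raise PDBParseError(f"unknown element symbol {element!r}") from None


def _infer_element(atom_name: str) -> str:
    """First alphabetic character of the atom name, as used by legacy PDBs."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Address of a residue: (chain, author seq number, insertion code)."""

    chain_id: str
    residue_seq: int
    insertion_code: str = ""

    def __str__(self) -> str:  # e.g. "A55" or "A55B"
        return f"{self.chain_id}{self.residue_seq}{self.insertion_code}"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    mass: float
    insertion_code: str = ""
    charge: float = 0.0
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not (self.mass > 0):
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.serial <= 0:
            raise ValueError(f"atom {self.name}: serial must be positive")

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class ProteinStructure:
    """Ordered atoms plus contiguous residue ordinals.

    ``residue_index`` maps each :class:`ResidueKey` to an ordinal in
    ``0..R-1`` following order of first appearance in the atom list.
    """

    atoms: list[AtomRecord]
    title: str = ""
    residue_index: dict[ResidueKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residue_index:
            self.residue_index = self._build_index(self.atoms)
        self.validate()

    @staticmethod
    def _build_index(atoms: Sequence[AtomRecord]) -> dict[ResidueKey, int]:
        index: dict[ResidueKey, int] = {}
        for atom in atoms:
            key = atom.residue_key
            if key not in index:
                index[key] = len(index)
        return index

    def validate(self) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        for atom in self.atoms:
            ident = (atom.chain_id, atom.residue_seq, atom.insertion_code, atom.name)
            if ident in seen:
                raise ValueError(f"duplicate atom {ident} in structure")
            seen.add(ident)
            if atom.residue_key not in self.residue_index:
                raise ValueError(f"atom {atom.name} has unindexed residue {atom.residue_key}")
        ordinals = sorted(self.residue_index.values())
        if ordinals != list(range(len(ordinals))):
            raise ValueError("residue ordinals are not contiguous from 0")

    # -- convenience views used by every numerical stage -------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (Å), in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def atom_residue_ordinals(self) -> np.ndarray:
        """Per-atom residue ordinal (length N)."""
        return np.array([self.residue_index[a.residue_key] for a in self.atoms], dtype=int)

    @property
    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys sorted by ordinal."""
        return [k for k, _ in sorted(self.residue_index.items(), key=lambda kv: kv[1])]

    @property
    def residue_labels(self) -> list[str]:
        """Human-readable labels, e.g. 'ASP A55'."""
        names = {}
        for atom in self.atoms:
            names.setdefault(atom.residue_key, atom.residue_name)
        return [f"{names[k]} {k}" for k in self.residue_keys]

    def atoms_of_residue(self, key: ResidueKey) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_key == key]

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        """Copy of the structure with replaced coordinates (N x 3)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return ProteinStructure(atoms, title=self.title, residue_index=dict(self.residue_index))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_pdb(
    path: str | Path,
    keep_waters: bool = False,
    chain_filter: Iterable[str] | None = None,
) -> ProteinStructure:
    """Read the first MODEL of a PDB file into a :class:`ProteinStructure`.

    Masses are assigned from the element (standard atomic weights); waters
    (HOH/WAT) are dropped unless ``keep_waters``; ``chain_filter`` keeps only
    the named chains.  Alternate locations keep altloc ' ' or 'A'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bio_structure = parser.get_structure(path.stem, str(path))
        except PDBConstructionException as exc:
            raise PDBParseError(f"{path}: {exc}") from exc
    models = list(bio_structure.get_models())
    if not models:
        raise PDBParseError(f"{path}: no coordinate records found")
    chains = set(chain_filter) if chain_filter is not None else None

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in models[0]:
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            resname = residue.get_resname().strip()
            if not keep_waters and resname in WATER_NAMES:
                continue
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                element = (atom.element or "").strip() or _infer_element(atom.get_name())
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.get_name(),
                        element=element,
                        residue_name=resname,
                        residue_seq=int(resseq),
                        chain_id=str(chain.id),
                        insertion_code=icode.strip(),
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        mass=mass_of_element(element),
                        hetero=bool(hetflag.strip()),
                    )
                )
    if not atoms:
        raise PDBParseError(f"{path}: zero atoms after filtering")
    return ProteinStructure(atoms, title=path.stem)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: single-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a fixed-column PDB v3.3 file (coordinates to 3 decimals)."""
    path = Path(path)
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    prev_chain: str | None = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        record = "HETATM" if atom.hetero else "ATOM  "
        x, y, z = atom.coords
        charge_str = ""
        if atom.charge:
            q = int(round(atom.charge)) if abs(atom.charge - round(atom.charge)) < 0.26 else 0
            if q:
                charge_str = f"{abs(q)}{'-' if q < 0 else '+'}"
        lines.append(
            f"{record}{atom.serial:>5d} {_format_atom_name(atom.name, atom.element)} "
            f"{atom.residue_name:>3s} {atom.chain_id:1s}{atom.residue_seq:>4d}"
            f"{atom.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element.strip().upper():>2s}{charge_str:<2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structure editing
# ---------------------------------------------------------------------------


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = axis / np.linalg.norm(axis)
    seed = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, z) * z
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z, e1)
    return e1, e2, z


def apply_phospho_patch(
    structure: ProteinStructure,
    target: ResidueKey,
    acceptor_residues: tuple[str, ...] = ("ASP",),
) -> ProteinStructure:
    """Attach a PO3(2-) group to the side-chain carboxylate of ``target``.

    The phosphorus is bonded to a carboxylate oxygen (OD2, falling back to
    OD1) at 1.6 Å along the C-O direction; three terminal oxygens sit at
    1.5 Å in ideal tetrahedral geometry.  The residue is relabelled to the
    phosphoaspartate component and the added charge of -2 is spread evenly
    over the terminal oxygens.  Geometry is placed analytically; downstream
    minimisation is expected to relax it.
    """
    if target not in structure.residue_index:
        raise KeyError(f"target residue {target} not found")
    res_atoms = structure.atoms_of_residue(target)
    resname = res_atoms[0].residue_name
    if resname == PHOSPHO_RESIDUE_NAME or any(a.element.strip().upper() == "P" for a in res_atoms):
        raise ValueError(f"residue {target} is already phosphorylated")
    if resname not in acceptor_residues:
        raise ValueError(f"residue {target} is {resname}, not an acceptor {acceptor_residues}")

    by_name = {a.name: a for a in res_atoms}
    anchor = by_name.get("OD2") or by_name.get("OD1")
    if anchor is None:
        raise ValueError(f"residue {target} lacks a carboxylate oxygen (OD1/OD2)")
    if "CG" in by_name:
        direction = anchor.coords - by_name["CG"].coords
    else:
        centroid = np.mean([a.coords for a in res_atoms], axis=0)
        direction = anchor.coords - centroid
    norm = np.linalg.norm(direction)
    if norm < 1e-6:
        direction = np.array([0.0, 0.0, 1.0])
        norm = 1.0
    e1, e2, z = _orthonormal_frame(direction / norm)

    p_pos = anchor.coords + 1.6 * z
    tetra = math.radians(109.471)  # ideal O-P-O / O(bridge)-P-O angle
    new_atoms: list[AtomRecord] = []
    mass_p = mass_of_element("P")
    mass_o = mass_of_element("O")
    new_atoms.append(
        AtomRecord(
            serial=1,  # renumbered below
            name="P",
            element="P",
            residue_name=PHOSPHO_RESIDUE_NAME,
            residue_seq=target.residue_seq,
            chain_id=target.chain_id,
            insertion_code=target.insertion_code,
            coords=p_pos,
            mass=mass_p,
        )
    )
    for k, name in enumerate(("O1P", "O2P", "O3P")):
        phi = 2.0 * math.pi * k / 3.0
        # terminal bonds make the tetrahedral angle with the P->O(bridge) bond (-z)
        bond_dir = -math.cos(tetra) * z + math.sin(tetra) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        new_atoms.append(
            AtomRecord(
                serial=1,
                name=name,
                element="O",
                residue_name=PHOSPHO_RESIDUE_NAME,
                residue_seq=target.residue_seq,
                chain_id=target.chain_id,
                insertion_code=target.insertion_code,
                coords=p_pos + 1.5 * bond_dir,
                mass=mass_o,
                charge=-2.0 / 3.0,
            )
        )

    # insert the new atoms right after the target residue, relabel it, and
    # renumber serials; everything else is copied bit-identically
    atoms: list[AtomRecord] = []
    last_target_pos = max(i for i, a in enumerate(structure.atoms) if a.residue_key == target)
    for i, a in enumerate(structure.atoms):
        if a.residue_key == target:
            a = replace(a, residue_name=PHOSPHO_RESIDUE_NAME)
        atoms.append(a)
        if i == last_target_pos:
            atoms.extend(new_atoms)
    atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    return ProteinStructure(atoms, title=structure.title)


def select_region(
    structure: ProteinStructure, first: ResidueKey, last: ResidueKey
) -> ProteinStructure:
    """Substructure of the closed residue-ordinal interval [first, last]."""
    index = structure.residue_index
    if first not in index:
        raise KeyError(f"residue {first} not found")
    if last not in index:
        raise KeyError(f"residue {last} not found")
    lo, hi = index[first], index[last]
    if lo > hi:
        raise ValueError(f"first residue {first} comes after last residue {last}")
    keep = {k for k, o in index.items() if lo <= o <= hi}
    atoms = [replace(a) for a in structure.atoms if a.residue_key in keep]
    if not atoms:
        raise ValueError("empty selection")
    atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    return ProteinStructure(atoms, title=structure.title)
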
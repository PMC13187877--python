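"""Trajectory metrics: optimal rigid superposition, RMSD series, per-residue
RMSF profiles, and geometric detectors for salt bridges and hydrogen bonds.

Trajectories are plain F x N x 3 coordinate arrays (Å) tied to the atom
metadata of a :class:`~vibromap.structure_io.ProteinStructure`; coordinates
are treated as a single pre-imaged molecule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .structure_io import ProteinStructure, ResidueKey, PDBParseError

__all__ = [
    "Trajectory",
    "FluctuationSummary",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "detect_salt_bridges",
    "count_hbonds",
    "read_multimodel_pdb",
    "read_frame_table",
]

ACIDIC_OXYGENS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
                  ("PHD", "OD1"), ("PHD", "OD2")}
BASIC_NITROGENS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                   ("HIS", "ND1"), ("HIS", "NE2")}


@dataclass
class Trajectory:
    """Multi-frame coordinates sharing one structure's atom metadata."""

    frames: np.ndarray  # (F, N, 3) Å
    times: np.ndarray  # (F,) ps
    structure: ProteinStructure

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least two frames")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError("frame atom count does not match structure")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class FluctuationSummary:
    """A series (RMSD over frames) or profile (RMSF over residues), Å."""

    values: np.ndarray
    mean: float
    std: float
    temperature: float | None = None
    kind: str = "series"
    index: np.ndarray | None = None  # times (ps) or residue ordinals

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        kind: str,
        temperature: float | None = None,
        index: np.ndarray | None = None,
        summary_slice: slice = slice(None),
    ) -> "FluctuationSummary":
        values = np.asarray(values, dtype=float)
        window = values[summary_slice]
        return cls(values, float(np.mean(window)), float(np.std(window)), temperature, kind, index)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1); apply as ``mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mob_c = mobile - np.average(mobile, axis=0, weights=w)
    ref_c = reference - np.average(reference, axis=0, weights=w)
    # degenerate (collinear) sets have a rank-deficient covariance
    cov = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    dflip = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ dflip @ u.T
    translation = np.average(reference, axis=0, weights=w) - (
        np.average(mobile, axis=0, weights=w) @ rotation.T
    )
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.average(np.sum((fitted - reference) ** 2, axis=1), weights=w)))
    return rotation, translation, rmsd


def _resolve_selection(structure: ProteinStructure, selection: Sequence[int] | None) -> np.ndarray:
    if selection is None:
        return np.arange(structure.n_atoms)
    sel = np.asarray(selection, dtype=int)
    if len(sel) == 0:
        raise ValueError("empty atom selection")
    if sel.min() < 0 or sel.max() >= structure.n_atoms:
        raise ValueError("selection index out of range")
    return sel


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Sequence[int] | None = None,
    equilibration_fraction: float = 0.1,
    equilibration_frames: int | None = None,
    mass_weighted: bool = True,
    temperature: float | None = None,
) -> FluctuationSummary:
    """Per-frame RMSD after superposition onto a reference frame.

    The summary mean/SD skip an initial equilibration window (a frame count,
    or by default 10% of the frames), mirroring the convention of ignoring
    the initial relaxation of a production run; the full series is kept.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise ValueError("reference frame index out of range")
    sel = _resolve_selection(traj.structure, selection)
    weights = traj.structure.masses[sel] if mass_weighted else None
    ref = traj.frames[reference_frame][sel]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, values[f] = kabsch_superpose(traj.frames[f][sel], ref, weights)
    skip = equilibration_frames if equilibration_frames is not None else int(
        round(equilibration_fraction * traj.n_frames)
    )
    skip = min(skip, traj.n_frames - 1)
    return FluctuationSummary.from_values(
        values, "series", temperature, traj.times, summary_slice=slice(skip, None)
    )


def rmsf_per_residue(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    mass_weighted: bool = True,
    temperature: float | None = None,
) -> FluctuationSummary:
    """Per-residue RMSF about the mean structure after iterative superposition.

    All frames are superposed onto the mean structure (two passes: mean of
    raw frames, then mean of fitted frames), and the residue RMSF is the
    mass-weighted RMS positional fluctuation of its atoms.
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for an RMSF profile")
    sel = _resolve_selection(traj.structure, selection)
    weights = traj.structure.masses[sel] if mass_weighted else None
    frames = traj.frames[:, sel, :]
    mean = frames.mean(axis=0)
    for _ in range(2):
        fitted = np.empty_like(frames)
        for f in range(len(frames)):
            rot, trans, _ = kabsch_superpose(frames[f], mean, weights)
            fitted[f] = frames[f] @ rot.T + trans
        mean = fitted.mean(axis=0)
        frames = fitted
    per_atom_msf = np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0)

    ordinals = traj.structure.atom_residue_ordinals[sel]
    masses = traj.structure.masses[sel]
    n_res = traj.structure.n_residues
    msf_sum = np.zeros(n_res)
    m_sum = np.zeros(n_res)
    np.add.at(msf_sum, ordinals, per_atom_msf * masses)
    np.add.at(m_sum, ordinals, masses)
    covered = m_sum > 0
    profile = np.full(n_res, np.nan)
    profile[covered] = np.sqrt(msf_sum[covered] / m_sum[covered])
    values = profile[covered]
    return FluctuationSummary.from_values(
        values, "profile", temperature, np.flatnonzero(covered)
    )


# ---------------------------------------------------------------------------
# contact detectors
# ---------------------------------------------------------------------------


def detect_salt_bridges(
    structure: ProteinStructure,
    cutoff: float = 4.0,
    charged_bead_labels: tuple[set[str], set[str]] | None = None,
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs with an acidic side-chain oxygen within ``cutoff`` Å of a
    basic side-chain nitrogen; each unordered pair reported once, sorted.

    For coarse-grained input, ``charged_bead_labels`` supplies (acidic residue
    names, basic residue names) whose single beads act as the charged sites.
    """
    acidic, basic = [], []
    for i, atom in enumerate(structure.atoms):
        if charged_bead_labels is not None:
            neg, pos = charged_bead_labels
            if atom.residue_name in neg:
                acidic.append(i)
            elif atom.residue_name in pos:
                basic.append(i)
        else:
            if (atom.residue_name, atom.name) in ACIDIC_OXYGENS:
                acidic.append(i)
            elif (atom.residue_name, atom.name) in BASIC_NITROGENS:
                basic.append(i)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    coords = structure.coords
    for i in acidic:
        for j in basic:
            ki, kj = structure.atoms[i].residue_key, structure.atoms[j].residue_key
            if ki == kj:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.add(tuple(sorted((ki, kj))))  # type: ignore[arg-type]
    return sorted(pairs)


def count_hbonds(
    structure: ProteinStructure,
    region: tuple[ResidueKey, ResidueKey] | None = None,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> tuple[int, list[tuple[ResidueKey, ResidueKey]]]:
    """Hydrogen bonds inside a residue interval by geometric criterion.

    A bond is a backbone/side-chain donor (N or O with an attached hydrogen,
    H within 1.25 Å) and an acceptor (O, or N without hydrogens) with
    donor-acceptor distance <= ``dist_cutoff`` and donor-H-acceptor angle
    >= ``angle_cutoff`` degrees.  Pairs bonded through any H are counted once
    per donor-acceptor residue pair direction.
    """
    if region is not None:
        first, last = region
        index = structure.residue_index
        if first not in index or last not in index:
            raise ValueError("region residue not found")
        lo, hi = index[first], index[last]
        if lo > hi:
            raise ValueError("empty region")
    else:
        lo, hi = 0, structure.n_residues - 1
    ordinals = structure.atom_residue_ordinals
    in_region = (ordinals >= lo) & (ordinals <= hi)

    coords = structure.coords
    elements = [a.element.strip().upper() for a in structure.atoms]
    hydrogens = [i for i, e in enumerate(elements) if e == "H" and in_region[i]]
    heavies_n_o = [i for i, e in enumerate(elements) if e in ("N", "O") and in_region[i]]

    # attach each hydrogen to its nearest N/O within covalent range
    donor_of_h: dict[int, int] = {}
    donors_with_h: set[int] = set()
    for h in hydrogens:
        best, best_d = None, 1.25
        for i in heavies_n_o:
            d = float(np.linalg.norm(coords[h] - coords[i]))
            if d < best_d:
                best, best_d = i, d
        if best is not None:
            donor_of_h[h] = best
            donors_with_h.add(best)

    acceptors = [i for i in heavies_n_o if elements[i] == "O" or i not in donors_with_h]

    found: set[tuple[int, int]] = set()
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    count = 0
    for h, donor in donor_of_h.items():
        for acc in acceptors:
            if acc == donor or ordinals[acc] == ordinals[donor]:
                continue
            d_da = float(np.linalg.norm(coords[donor] - coords[acc]))
            if d_da > dist_cutoff:
                continue
            v1 = coords[donor] - coords[h]
            v2 = coords[acc] - coords[h]
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < angle_cutoff:
                continue
            key = (donor, acc)
            if key in found:
                continue
            found.add(key)
            count += 1
            pairs.append(
                (structure.atoms[donor].residue_key, structure.atoms[acc].residue_key)
            )
    return count, pairs


# ---------------------------------------------------------------------------
# trajectory input
# ---------------------------------------------------------------------------


def read_multimodel_pdb(path: str | Path, structure: ProteinStructure | None = None,
                        frame_interval_ps: float = 1.0) -> Trajectory:
    """Read every MODEL of a multi-model PDB as one trajectory frame."""
    from .structure_io import read_pdb  # first model defines the metadata

    path = Path(path)
    meta = structure if structure is not None else read_pdb(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = parser.get_structure(path.stem, str(path))
    frames = []
    for model in bio:
        coords = np.array(
            [a.get_coord() for a in model.get_atoms() if a.get_altloc() in (" ", "A")],
            dtype=float,
        )
        if coords.shape[0] != meta.n_atoms:
            raise PDBParseError(
                f"{path}: MODEL {model.id} has {coords.shape[0]} atoms, expected {meta.n_atoms}"
            )
        frames.append(coords)
    if len(frames) < 2:
        raise PDBParseError(f"{path}: need at least two MODELs for a trajectory")
    frames_arr = np.stack(frames)
    times = np.arange(len(frames)) * frame_interval_ps
    return Trajectory(frames_arr, times, meta)


def read_frame_table(path: str | Path, structure: ProteinStructure,
                     frame_interval_ps: float = 1.0) -> Trajectory:
    """Read a whitespace-delimited table of x y z rows, one block of N atoms
    per frame (blank-line separated blocks or a flat multiple of N rows)."""
    data = np.loadtxt(path, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("frame table must have three columns (x y z)")
    n = structure.n_atoms
    if data.shape[0] % n != 0:
        raise ValueError(f"row count {data.shape[0]} is not a multiple of {n} atoms")
    frames = data.reshape(-1, n, 3)
    times = np.arange(len(frames)) * frame_interval_ps
    return Trajectory(frames, times, structure)
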
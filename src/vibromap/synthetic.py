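"""Synthetic structures, homolog pairs, and harmonic trajectories.

Everything here is a pure function of its spec and seed, built so each
pipeline stage can be tested against known statistical structure: ideal
bead-per-residue geometries, a pair of homologs that differ only in
cross-link count and a phospho-like modification, and trajectories drawn
from the exact harmonic equilibrium distribution of a mode set (frames are
independent; these emulate equilibrium fluctuation statistics, not
kinetics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .nma import (
    KB_KCAL_MOL_K,
    KCAL_PER_MOL_TO_INTERNAL,
    NormalModeSet,
    Springs,
    enm_springs,
)
from .pulling import CGModel, CGParams, build_cg_model
from .structure_io import AtomRecord, ProteinStructure
from .trajectory import Trajectory

__all__ = [
    "SyntheticSpec",
    "HomologModel",
    "make_structure",
    "make_homolog_pair",
    "simulate_harmonic_trajectory",
    "harmonic_position_variance",
    "BEAD_MASS_AMU",
    "PHOSPHO_EXTRA_MASS_AMU",
]

#: average residue mass used for one-bead-per-residue models
BEAD_MASS_AMU = 110.0
#: mass of the PO3 moiety carried by the phospho-like bead
PHOSPHO_EXTRA_MASS_AMU = 79.0
#: the phospho bead couples to the bead this many ordinals downstream
#: (mimicking the modified-aspartate / partner-aspartate contact)
PHOSPHO_PARTNER_OFFSET = 7

# NMA spring stiffnesses for homolog models, kcal mol^-1 Å^-2: the backbone
# network is a plain ENM; cross-links (hydrogen-bond-like) are stiffer and
# the phospho contact stiffer still, so the modification is visible in the
# transport maps
ENM_FORCE_CONSTANT = 1.0
ENM_CUTOFF = 10.0
CROSSLINK_NMA_K = 3.0
PHOSPHO_NMA_K = 10.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic bead-per-residue structure."""

    n_residues: int
    geometry: Literal["ideal_helix", "extended_chain", "lattice"] = "ideal_helix"
    crosslink_count: int = 0
    phospho_site: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.crosslink_count < 0:
            raise ValueError("crosslink_count must be non-negative")


def _helix_coords(n: int, rise: float = 1.5, twist_deg: float = 100.0, radius: float = 2.3) -> np.ndarray:
    i = np.arange(n)
    phi = np.radians(twist_deg) * i
    return np.stack([radius * np.cos(phi), radius * np.sin(phi), rise * i], axis=1)


def _extended_coords(n: int, spacing: float = 3.8) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 2] = spacing * np.arange(n)
    return coords


def _lattice_coords(n: int, spacing: float = 3.8) -> np.ndarray:
    side = math.ceil(n ** (1.0 / 3.0))
    pts = []
    for a in range(side):
        for b in range(side):
            for c in range(side):
                pts.append((a, b, c))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * spacing
    return np.array(pts[:n], dtype=float) * spacing


def make_structure(spec: SyntheticSpec, bead_mass: float = BEAD_MASS_AMU) -> ProteinStructure:
    """Cα-style bead-per-residue structure on an ideal geometry.

    ideal_helix: 1.5 Å rise, 100° twist, 2.3 Å radius per residue;
    extended_chain: 3.8 Å spacing on a line; lattice: cubic grid.
    Deterministic given the spec (the seed matters only for stages that
    place cross-links).
    """
    if spec.geometry == "ideal_helix":
        coords = _helix_coords(spec.n_residues)
    elif spec.geometry == "extended_chain":
        coords = _extended_coords(spec.n_residues)
    elif spec.geometry == "lattice":
        coords = _lattice_coords(spec.n_residues)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    atoms = []
    for i in range(spec.n_residues):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                element="C",
                residue_name="GLY",
                residue_seq=i + 1,
                chain_id="A",
                coords=coords[i],
                mass=bead_mass,
            )
        )
    return ProteinStructure(atoms, title=f"synthetic_{spec.geometry}_{spec.n_residues}")


def _place_crosslinks(
    n: int, count: int, region: tuple[int, int], rng: np.random.Generator, min_sep: int = 3
) -> np.ndarray:
    """Seeded uniform choice of ``count`` bead pairs with |i-j| >= min_sep,
    both endpoints inside the closed ordinal interval ``region``."""
    lo, hi = region
    eligible = [
        (i, j) for i in range(lo, hi + 1) for j in range(i + min_sep, hi + 1)
    ]
    if count > len(eligible):
        raise ValueError(f"cannot place {count} cross-links in region {region}")
    idx = rng.choice(len(eligible), size=count, replace=False)
    return np.array(sorted(eligible[k] for k in sorted(idx)), dtype=int).reshape(-1, 2)


@dataclass
class HomologModel:
    """One member of a synthetic homolog pair: the bead structure, the spring
    network used for normal-mode/transport analysis, and the coarse-grained
    pulling model."""

    structure: ProteinStructure
    springs: Springs  # NMA spring network (backbone ENM + cross-links [+ phospho])
    cg: CGModel
    crosslinks: np.ndarray  # (L, 2) bead ordinals
    phospho_site: int | None = None
    phospho_partner: int | None = None


def _nma_springs_with_links(
    structure: ProteinStructure,
    crosslinks: np.ndarray,
    phospho_bond: tuple[int, int] | None,
) -> Springs:
    base = enm_springs(structure.coords, ENM_CUTOFF, ENM_FORCE_CONSTANT)
    pairs = [base.pairs]
    ks = [base.k]
    r0s = [base.r0]
    coords = structure.coords
    existing = {tuple(p) for p in base.pairs.tolist()}

    def _add(i: int, j: int, k: float) -> None:
        i, j = min(i, j), max(i, j)
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if (i, j) in existing:
            # stiffen the existing ENM spring instead of duplicating it
            mask = (base.pairs[:, 0] == i) & (base.pairs[:, 1] == j)
            ks[0] = np.where(mask, ks[0] + k, ks[0])
        else:
            pairs.append(np.array([[i, j]]))
            ks.append(np.array([k]))
            r0s.append(np.array([dist]))
            existing.add((i, j))

    for i, j in crosslinks:
        _add(int(i), int(j), CROSSLINK_NMA_K)
    if phospho_bond is not None:
        _add(phospho_bond[0], phospho_bond[1], PHOSPHO_NMA_K)
    return Springs(np.concatenate(pairs), np.concatenate(ks), np.concatenate(r0s))


def make_homolog_pair(
    n_residues: int = 128,
    strong_links: int = 9,
    weak_links: int = 2,
    seed: int = 0,
    phospho_site: int | None = None,
    cg_params: CGParams = CGParams(),
) -> tuple[HomologModel, HomologModel]:
    """Two bead models identical except for their stabilising contacts.

    Model A carries ``strong_links`` cross-links in the C-terminal region and
    a phospho-like modification (extra PO3 mass plus one stiff spring to the
    bead ``PHOSPHO_PARTNER_OFFSET`` ordinals downstream); model B carries
    ``weak_links`` cross-links (a subset of A's) and no modification.  The
    backbone geometry (ideal helix) is shared, so transport maps and pulls
    are directly comparable.
    """
    if not (strong_links > weak_links >= 0):
        raise ValueError("need strong_links > weak_links >= 0")
    spec = SyntheticSpec(n_residues, "ideal_helix", seed=seed)
    base = make_structure(spec)

    # C-terminal cross-link region: the last ~40% of the chain (residues
    # 79..128 of a 128-residue chain)
    region_len = min(n_residues - 2, max(8, round(n_residues * 50 / 128)))
    region = (n_residues - region_len, n_residues - 1)
    rng = np.random.default_rng(seed)
    links_a = _place_crosslinks(n_residues, strong_links, region, rng)
    links_b = links_a[:weak_links].copy()

    if phospho_site is None:
        # residue 55 of a 128-residue chain, scaled proportionally for other
        # lengths; the partner must stay clear of the pulling handle
        phospho_site = min(54, max(1, round(0.43 * n_residues)))
    partner = phospho_site + PHOSPHO_PARTNER_OFFSET
    if not (0 <= phospho_site < n_residues and partner <= n_residues - 2):
        raise ValueError("phospho site/partner outside the chain interior")

    struct_a = make_structure(spec)
    struct_a.atoms[phospho_site].mass += PHOSPHO_EXTRA_MASS_AMU
    struct_a.atoms[phospho_site].residue_name = "PHD"
    struct_b = make_structure(spec)

    springs_a = _nma_springs_with_links(struct_a, links_a, (phospho_site, partner))
    springs_b = _nma_springs_with_links(struct_b, links_b, None)

    # CG pulling models: cross-links from the same tables; the phospho
    # contact is a stiff unbreakable-by-default (large threshold) link
    rows_a = [(int(i), int(j)) for i, j in links_a]
    rows_a.append((phospho_site, partner, 5.0 * cg_params.crosslink_k, np.nan, 0.6))
    rows_b = [(int(i), int(j)) for i, j in links_b]
    cg_a = build_cg_model(struct_a, rows_a, cg_params)
    cg_b = build_cg_model(struct_b, rows_b, cg_params)

    model_a = HomologModel(struct_a, springs_a, cg_a, links_a, phospho_site, partner)
    model_b = HomologModel(struct_b, springs_b, cg_b, links_b, None, None)
    return model_a, model_b


# ---------------------------------------------------------------------------
# harmonic trajectories
# ---------------------------------------------------------------------------


def harmonic_position_variance(modes: NormalModeSet, temperature: float) -> np.ndarray:
    """Closed-form per-atom positional variance (Å^2, summed over Cartesian
    components) of the classical harmonic ensemble:
    sum_a (k_B T / w_a^2) |e_a,atom|^2 / m_atom over internal modes."""
    kbt = KB_KCAL_MOL_K * KCAL_PER_MOL_TO_INTERNAL * temperature  # amu Å^2 ps^-2
    idx = modes.nonzero
    omega = modes.omega_ps[idx]
    v = modes.eigenvectors[:, idx]
    n = len(modes.masses)
    d = modes.dim
    per_coord = (v**2) @ (kbt / omega**2)  # mass-weighted variance per DOF
    return per_coord.reshape(n, d).sum(axis=1) / modes.masses


def simulate_harmonic_trajectory(
    modes: NormalModeSet,
    temperature: float,
    n_frames: int,
    seed: int,
    frame_interval_ps: float = 1.0,
    structure: ProteinStructure | None = None,
) -> Trajectory:
    """Frames drawn independently from the classical harmonic equilibrium
    distribution: each internal mode amplitude is Gaussian with variance
    k_B T / w^2 in mass-weighted coordinates; rigid-body modes are not
    excited.  Frame 0 is the reference geometry.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if modes.reference_coords is None:
        raise ValueError("mode set carries no reference coordinates")
    ref = modes.reference_coords
    n, d = ref.shape
    if d != 3:
        raise ValueError("harmonic trajectories are defined for 3-D structures")
    kbt = KB_KCAL_MOL_K * KCAL_PER_MOL_TO_INTERNAL * temperature
    idx = modes.nonzero
    omega = modes.omega_ps[idx]
    v = modes.eigenvectors[:, idx]
    sigma = np.sqrt(kbt) / omega  # mass-weighted mode amplitude SD

    rng = np.random.default_rng(seed)
    amps = rng.standard_normal((n_frames - 1, len(omega))) * sigma
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(modes.masses, d))
    displ = (amps @ v.T) * inv_sqrt_m  # (F-1, N*d) Cartesian displacements
    frames = np.empty((n_frames, n, 3))
    frames[0] = ref
    frames[1:] = ref[None, :, :] + displ.reshape(n_frames - 1, n, d)
    times = np.arange(n_frames) * frame_interval_ps

    if structure is None:
        atoms = [
            AtomRecord(
                serial=i + 1,
                name="CA",
                element="C",
                residue_name="GLY",
                residue_seq=i + 1,
                chain_id="A",
                coords=ref[i],
                mass=float(modes.masses[i]),
            )
            for i in range(n)
        ]
        structure = ProteinStructure(atoms, title="harmonic_reference")
    return Trajectory(frames, times, structure)
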
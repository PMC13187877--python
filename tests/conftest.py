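"""Shared fixtures: toy structures, disordered chains, and cached mode sets."""

from __future__ import annotations

import numpy as np
import pytest

from vibromap import nma
from vibromap.structure_io import AtomRecord, ProteinStructure, mass_of_element
from vibromap.synthetic import SyntheticSpec, make_structure


def toy_atom(serial, name, elem, res, seq, chain, xyz, **kw):
    return AtomRecord(
        serial, name, elem, res, seq, chain,
        np.asarray(xyz, dtype=float), mass_of_element(elem), **kw
    )


@pytest.fixture
def asp_lys_structure() -> ProteinStructure:
    """An ASP side-chain carboxylate 3.0 Å from a LYS NZ (one salt bridge)."""
    atoms = [
        toy_atom(1, "N", "N", "ASP", 1, "A", (0, 0, 0)),
        toy_atom(2, "CA", "C", "ASP", 1, "A", (1.5, 0, 0)),
        toy_atom(3, "CB", "C", "ASP", 1, "A", (2.0, 1.4, 0)),
        toy_atom(4, "CG", "C", "ASP", 1, "A", (3.5, 1.5, 0)),
        toy_atom(5, "OD1", "O", "ASP", 1, "A", (4.2, 0.5, 0)),
        toy_atom(6, "OD2", "O", "ASP", 1, "A", (4.0, 2.7, 0)),
        toy_atom(7, "CA", "C", "LYS", 2, "A", (1.5, 0, 3.8)),
        toy_atom(8, "NZ", "N", "LYS", 2, "A", (5.0, 2.0, 2.5)),
    ]
    return ProteinStructure(atoms, title="asp_lys")


def disordered_chain_hessian(seed: int, n: int = 64, lo: float = 0.8, hi: float = 1.2,
                             k: float = 1.0, spacing: float = 3.8) -> nma.Hessian:
    """1-D mass-disordered chain (uniform masses in [lo, hi])."""
    rng = np.random.default_rng(seed)
    masses = rng.uniform(lo, hi, n)
    return nma.build_chain_hessian(masses, nma.chain_springs(n, k, spacing), spacing=spacing)


@pytest.fixture(scope="session")
def helix20_modes():
    """Modes of a 20-residue helix ENM, shared across tests (read-only)."""
    s = make_structure(SyntheticSpec(20, "ideal_helix"))
    pot = nma.PotentialModel("enm", cutoff=10.0, force_constant=1.0)
    hessian = nma.build_hessian(s, pot)
    return s, hessian, nma.normal_modes(hessian)


def random_spring_network(seed: int, n: int = 6):
    """Random 3-D coordinates (minimum separation enforced) with springs on
    all pairs within a cutoff; natural lengths offset so the geometry is NOT
    a minimum (generic anharmonic point for derivative checks)."""
    rng = np.random.default_rng(seed)
    while True:
        coords = rng.uniform(0, 6.0, (n, 3))
        diff = coords[:, None] - coords[None, :]
        dist = np.linalg.norm(diff, axis=-1) + np.eye(n) * 99
        if dist.min() > 1.2:
            break
    iu, ju = np.triu_indices(n, k=1)
    mask = dist[iu, ju] < 5.0
    pairs = np.stack([iu[mask], ju[mask]], axis=1)
    k = rng.uniform(0.5, 2.0, len(pairs))
    r0 = dist[pairs[:, 0], pairs[:, 1]] * rng.uniform(0.8, 1.2, len(pairs))
    springs = nma.Springs(pairs, k, r0)
    masses = rng.uniform(1.0, 20.0, n)
    return coords, masses, springs
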
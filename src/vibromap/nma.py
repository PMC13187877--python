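"""Normal-mode engine: spring-network potentials, staged energy minimization,
mass-weighted Hessians, eigenmodes, and harmonic heat capacity.

Internal unit system
--------------------
Lengths in Å, masses in amu, energies in kcal/mol for the potential surface.
Mass-weighted Hessians are converted to ps^-2 (angular frequency squared)
using 1 kcal/mol = 418.400 amu Å^2 ps^-2, so that eigenfrequencies come out
as omega in ps^-1 and are reported as wavenumbers via
nu[cm^-1] = omega / (2 pi c) with c = 0.0299792458 cm/ps
(1 ps^-1 = 5.30884 cm^-1).

Desk-scale potentials are elastic-network / explicit spring lists; the
transport and thermodynamic machinery downstream is potential-agnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.optimize

from .structure_io import ProteinStructure

__all__ = [
    "KCAL_PER_MOL_TO_INTERNAL",
    "WAVENUMBER_PER_ANGULAR_PS",
    "KB_KCAL_MOL_K",
    "SECOND_RADIATION_CM_K",
    "Springs",
    "PotentialModel",
    "Hessian",
    "NormalModeSet",
    "MinimizationReport",
    "MinimizationError",
    "UnstableModesError",
    "enm_springs",
    "chain_springs",
    "spring_energy",
    "spring_gradient",
    "spring_hessian_cartesian",
    "build_hessian",
    "build_chain_hessian",
    "minimize",
    "normal_modes",
    "heat_capacity",
    "HeatCapacity",
]

# 1 kcal/mol expressed in amu Å^2 ps^-2 (= 4184 J/mol / (10 J/mol per unit))
KCAL_PER_MOL_TO_INTERNAL = 418.400
# omega [ps^-1] -> wavenumber [cm^-1]; 1/(2 pi c), c = 0.0299792458 cm/ps
WAVENUMBER_PER_ANGULAR_PS = 1.0 / (2.0 * math.pi * 0.0299792458)  # 5.30884
# Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_MOL_K = 1.380649e-23 * 6.02214076e23 / 4184.0  # 1.98720e-3
# h*c/k_B in cm K (x = c2 * nu[cm^-1] / T)
SECOND_RADIATION_CM_K = 1.43876877


class MinimizationError(RuntimeError):
    """Energy diverged (NaN/inf) during a minimization stage."""


class UnstableModesError(RuntimeError):
    """Hessian has negative eigenvalues beyond tolerance (not at a minimum)."""


@dataclass
class Springs:
    """Explicit pairwise harmonic springs: E = 1/2 k (|ri-rj| - r0)^2."""

    pairs: np.ndarray  # (S, 2) int
    k: np.ndarray  # (S,) kcal mol^-1 Å^-2
    r0: np.ndarray  # (S,) Å

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.k = np.asarray(self.k, dtype=float).reshape(-1)
        self.r0 = np.asarray(self.r0, dtype=float).reshape(-1)
        if not (len(self.pairs) == len(self.k) == len(self.r0)):
            raise ValueError("springs: pairs/k/r0 length mismatch")
        if np.any(self.k <= 0):
            raise ValueError("springs: force constants must be positive")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("springs: self-pair")

    @property
    def n_springs(self) -> int:
        return len(self.pairs)


def enm_springs(coords: np.ndarray, cutoff: float, force_constant: float) -> Springs:
    """Elastic-network springs: all pairs within ``cutoff``, r0 = current distance."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    mask = dist[iu, ju] <= cutoff
    pairs = np.stack([iu[mask], ju[mask]], axis=1)
    if len(pairs) == 0:
        raise ValueError("no spring within cutoff; structure is disconnected")
    degree = np.zeros(n, dtype=int)
    np.add.at(degree, pairs.ravel(), 1)
    if np.any(degree == 0):
        floppy = np.flatnonzero(degree == 0)
        raise ValueError(f"atoms with zero ENM neighbours under cutoff {cutoff} Å: {floppy.tolist()}")
    r0 = dist[pairs[:, 0], pairs[:, 1]]
    return Springs(pairs, np.full(len(pairs), force_constant), r0)


def chain_springs(n: int, force_constant: float, r0: float) -> Springs:
    """Nearest-neighbour springs of a linear chain of ``n`` sites."""
    pairs = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    return Springs(pairs, np.full(n - 1, force_constant), np.full(n - 1, r0))


@dataclass
class PotentialModel:
    """Desk-scale harmonic potential: ENM by cutoff or an explicit spring list.

    kind='enm' resolves springs from the reference geometry it is bound to
    (all pairs within ``cutoff``, natural length = reference distance);
    kind='pairwise_springs' uses the explicit list.
    """

    kind: str = "enm"
    cutoff: float = 12.0  # Å
    force_constant: float = 1.0  # kcal mol^-1 Å^-2
    springs: Springs | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("enm", "pairwise_springs"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.kind == "enm":
            if self.cutoff <= 0:
                raise ValueError("enm cutoff must be positive")
            if self.force_constant <= 0:
                raise ValueError("enm force constant must be positive")
        elif self.springs is None:
            raise ValueError("pairwise_springs model needs an explicit spring list")

    def bind(self, coords: np.ndarray) -> Springs:
        """Resolve the spring list for a concrete geometry."""
        if self.kind == "enm":
            return enm_springs(coords, self.cutoff, self.force_constant)
        assert self.springs is not None
        n = len(coords)
        if np.any(self.springs.pairs >= n) or np.any(self.springs.pairs < 0):
            raise ValueError("spring references an atom outside the structure")
        return self.springs


# ---------------------------------------------------------------------------
# spring-network energy, gradient, Hessian (any dimensionality)
# ---------------------------------------------------------------------------


def _pair_geometry(coords: np.ndarray, springs: Springs):
    rij = coords[springs.pairs[:, 0]] - coords[springs.pairs[:, 1]]
    dist = np.linalg.norm(rij, axis=1)
    if np.any(dist < 1e-10):
        raise FloatingPointError("coincident atoms on a spring")
    return rij, dist


def spring_energy(coords: np.ndarray, springs: Springs) -> float:
    """Total spring energy, kcal/mol."""
    _, dist = _pair_geometry(coords, springs)
    return float(0.5 * np.sum(springs.k * (dist - springs.r0) ** 2))


def spring_gradient(coords: np.ndarray, springs: Springs) -> np.ndarray:
    """dE/dr, kcal mol^-1 Å^-1, shape (N, d)."""
    rij, dist = _pair_geometry(coords, springs)
    coeff = springs.k * (dist - springs.r0) / dist
    force = coeff[:, None] * rij
    grad = np.zeros_like(coords)
    np.add.at(grad, springs.pairs[:, 0], force)
    np.add.at(grad, springs.pairs[:, 1], -force)
    return grad


def spring_hessian_cartesian(coords: np.ndarray, springs: Springs) -> np.ndarray:
    """Analytic second derivatives, kcal mol^-1 Å^-2, shape (N*d, N*d).

    Per spring: K = k [u u^T + (1 - r0/r)(I - u u^T)] with u the unit bond
    vector; at the natural length this reduces to the familiar ENM k u u^T.
    """
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    rij, dist = _pair_geometry(coords, springs)
    u = rij / dist[:, None]
    h = np.zeros((n, d, n, d))
    eye = np.eye(d)
    for s in range(springs.n_springs):
        i, j = springs.pairs[s]
        uu = np.outer(u[s], u[s])
        block = springs.k[s] * (uu + (1.0 - springs.r0[s] / dist[s]) * (eye - uu))
        h[i, :, i, :] += block
        h[j, :, j, :] += block
        h[i, :, j, :] -= block
        h[j, :, i, :] -= block
    return h.reshape(n * d, n * d)


@dataclass
class Hessian:
    """Mass-weighted Hessian in ps^-2, with the geometry it was built at."""

    matrix: np.ndarray  # (N*d, N*d), symmetric
    masses: np.ndarray  # (N,), amu
    coords: np.ndarray  # (N, d), Å
    dim: int = 3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, d = self.coords.shape
        if d != self.dim:
            raise ValueError("coords dimensionality does not match dim")
        if self.matrix.shape != (n * d, n * d):
            raise ValueError("Hessian shape mismatch")
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-8 * scale:
            raise ValueError("Hessian is not symmetric to 1e-8 relative")
        # exact symmetrization guards eigh against roundoff asymmetry
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n_atoms(self) -> int:
        return len(self.masses)


def _mass_weight(h_cart: np.ndarray, masses: np.ndarray, dim: int) -> np.ndarray:
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), dim)
    return h_cart * inv_sqrt_m[:, None] * inv_sqrt_m[None, :] * KCAL_PER_MOL_TO_INTERNAL


def build_hessian(
    structure: ProteinStructure,
    model: PotentialModel,
    gradient_warn_tol: float = 1e-6,
) -> Hessian:
    """Mass-weighted analytic Hessian of the spring network at the structure's
    geometry.  Warns if the geometry is not a stationary point of the model
    (modes are only meaningful at a minimum)."""
    coords = structure.coords
    springs = model.bind(coords)
    grad = spring_gradient(coords, springs)
    if np.abs(grad).max() > gradient_warn_tol:
        warnings.warn(
            "structure is not at a minimum of the potential "
            f"(|grad|_max = {np.abs(grad).max():.3g} kcal/mol/Å); "
            "minimize before normal-mode analysis",
            stacklevel=2,
        )
    h_cart = spring_hessian_cartesian(coords, springs)
    return Hessian(_mass_weight(h_cart, structure.masses, 3), structure.masses, coords, dim=3)


def build_chain_hessian(masses: np.ndarray, springs: Springs, spacing: float = 1.0) -> Hessian:
    """Mass-weighted Hessian of a 1-D chain (sites on a line, one DOF each)."""
    masses = np.asarray(masses, dtype=float)
    coords = (np.arange(len(masses), dtype=float) * spacing)[:, None]
    h_cart = spring_hessian_cartesian(coords, springs)
    return Hessian(_mass_weight(h_cart, masses, 1), masses, coords, dim=1)


# ---------------------------------------------------------------------------
# staged minimization
# ---------------------------------------------------------------------------

#: mirrors the staged protocol: steepest descent, then conjugate gradient to
#: 1e-6 kcal/mol, then L-BFGS to 1e-7 kcal/mol (step counts are budgets)
DEFAULT_SCHEDULE: tuple[tuple[str, int, float], ...] = (
    ("steepest_descent", 10_000, 1e-6),
    ("conjugate_gradient", 50_000, 1e-6),
    ("lbfgs", 500_000, 1e-7),
)


@dataclass
class StageReport:
    method: str
    max_steps: int
    tol: float
    steps_used: int
    final_energy: float
    final_energy_change: float
    converged: bool


@dataclass
class MinimizationReport:
    stages: list[StageReport] = field(default_factory=list)
    converged: bool = False

    @property
    def final_energy(self) -> float:
        return self.stages[-1].final_energy if self.stages else math.nan


def _check_finite(energy: float, stage: str) -> None:
    if not math.isfinite(energy):
        raise MinimizationError(f"energy diverged (non-finite) during stage {stage!r}")


def _steepest_descent(fun, jac, x0, max_steps, tol):
    """Backtracking-line-search steepest descent; stops when the accepted
    energy decrease per step falls below tol."""
    x = x0.copy()
    e = fun(x)
    _check_finite(e, "steepest_descent")
    step = 1.0
    last_change = 0.0
    for it in range(max_steps):
        g = jac(x)
        gnorm = np.linalg.norm(g)
        if gnorm < 1e-12:
            return x, e, it, last_change, True
        direction = -g / gnorm
        accepted = False
        for _ in range(40):
            x_new = x + step * direction
            e_new = fun(x_new)
            _check_finite(e_new, "steepest_descent")
            if e_new < e:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return x, e, it, last_change, True  # no descent possible: at minimum
        last_change = e - e_new
        x, e = x_new, e_new
        step *= 1.6
        if last_change < tol:
            return x, e, it + 1, last_change, True
    return x, e, max_steps, last_change, False


def _scipy_stage(method, fun, jac, x0, max_steps, tol):
    energies: list[float] = [fun(x0)]

    def cb(xk):
        e = fun(xk)
        _check_finite(e, method)
        energies.append(e)

    scipy_name = {"conjugate_gradient": "CG", "lbfgs": "L-BFGS-B"}[method]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.optimize.minimize(
            fun,
            x0,
            jac=jac,
            method=scipy_name,
            callback=cb,
            options={"maxiter": max_steps, "gtol": 1e-12}
            if scipy_name == "CG"
            else {"maxiter": max_steps, "gtol": 1e-12, "ftol": 1e-16},
        )
    _check_finite(float(res.fun), method)
    change = abs(energies[-2] - energies[-1]) if len(energies) >= 2 else 0.0
    converged = change <= tol
    return res.x, float(res.fun), int(res.nit), change, converged


def minimize(
    structure: ProteinStructure,
    model: PotentialModel,
    schedule: Sequence[tuple[str, int, float]] = DEFAULT_SCHEDULE,
) -> tuple[ProteinStructure, MinimizationReport]:
    """Staged energy minimization of the spring-network potential.

    ``schedule`` is a list of (method, max_steps, tol) stages with method in
    {steepest_descent, conjugate_gradient, lbfgs}; tol is the energy change
    per accepted step (kcal/mol) below which a stage stops.  The spring list
    of an ENM model is resolved once from the *input* geometry and held fixed
    across stages.
    """
    coords0 = structure.coords
    springs = model.bind(coords0)
    shape = coords0.shape

    def fun(x: np.ndarray) -> float:
        return spring_energy(x.reshape(shape), springs)

    def jac(x: np.ndarray) -> np.ndarray:
        return spring_gradient(x.reshape(shape), springs).ravel()

    x = coords0.ravel().copy()
    report = MinimizationReport()
    for method, max_steps, tol in schedule:
        if method == "steepest_descent":
            x, e, steps, change, conv = _steepest_descent(fun, jac, x, max_steps, tol)
        elif method in ("conjugate_gradient", "lbfgs"):
            x, e, steps, change, conv = _scipy_stage(method, fun, jac, x, max_steps, tol)
        else:
            raise ValueError(f"unknown minimization method {method!r}")
        report.stages.append(
            StageReport(method, max_steps, tol, steps, e, change, conv)
        )
    report.converged = bool(report.stages and report.stages[-1].converged)
    return structure.with_coords(x.reshape(shape)), report


# ---------------------------------------------------------------------------
# normal modes
# ---------------------------------------------------------------------------


@dataclass
class NormalModeSet:
    """Eigenmodes of a mass-weighted Hessian.

    ``frequencies_cm`` ascend (zero modes first); ``eigenvectors`` holds the
    orthonormal mass-weighted displacement patterns as columns, signs fixed
    so the first non-negligible component is positive.
    """

    frequencies_cm: np.ndarray  # (M,), cm^-1, ascending
    eigenvectors: np.ndarray  # (N*d, M), orthonormal columns
    n_zero_modes: int
    masses: np.ndarray  # (N,), amu
    dim: int = 3
    reference_coords: np.ndarray | None = None  # (N, d), Å; geometry of the minimum

    def __post_init__(self) -> None:
        v = self.eigenvectors
        gram = v.T @ v
        if np.abs(gram - np.eye(gram.shape[0])).max() > 1e-6:
            raise ValueError("eigenvector matrix is not orthonormal")
        if np.any(self.frequencies_cm < 0):
            raise ValueError("negative frequency in mode set")
        if np.any(np.diff(self.frequencies_cm) < -1e-9):
            raise ValueError("frequencies are not ascending")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def omega_ps(self) -> np.ndarray:
        """Angular frequencies, ps^-1."""
        return self.frequencies_cm / WAVENUMBER_PER_ANGULAR_PS

    @property
    def nonzero(self) -> np.ndarray:
        """Index array of internal (non-rigid-body) modes."""
        return np.arange(self.n_zero_modes, self.n_modes)


def normal_modes(hessian: Hessian, zero_tol_factor: float = 1e-8) -> NormalModeSet:
    """Eigendecomposition of the mass-weighted Hessian.

    Eigenvalues with |lambda| < zero_tol_factor * max|lambda| are rigid-body
    (zero) modes; a negative eigenvalue beyond that tolerance means the
    geometry is not a minimum and raises :class:`UnstableModesError`.
    """
    evals, evecs = np.linalg.eigh(hessian.matrix)
    scale = max(np.abs(evals).max(), 1e-300)
    tol = zero_tol_factor * scale
    unstable = int(np.sum(evals < -tol))
    if unstable:
        raise UnstableModesError(
            f"{unstable} unstable mode(s): Hessian has negative curvature; "
            "structure is not at a minimum"
        )
    zero = np.abs(evals) <= tol
    n_zero = int(np.sum(zero))
    evals = np.where(zero, 0.0, np.maximum(evals, 0.0))
    order = np.argsort(evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: first component with non-negligible magnitude positive
    for c in range(evecs.shape[1]):
        col = evecs[:, c]
        idx = np.flatnonzero(np.abs(col) > 1e-8 * np.abs(col).max())
        if len(idx) and col[idx[0]] < 0:
            evecs[:, c] = -col
    freqs_cm = np.sqrt(evals) * WAVENUMBER_PER_ANGULAR_PS
    return NormalModeSet(
        freqs_cm, evecs, n_zero, hessian.masses, dim=hessian.dim,
        reference_coords=hessian.coords.copy(),
    )


# ---------------------------------------------------------------------------
# harmonic heat capacity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatCapacity:
    quantum: float  # kcal mol^-1 K^-1
    classical_limit: float  # (n internal modes) * k_B
    temperature: float  # K


def heat_capacity(modes: NormalModeSet, temperature: float) -> HeatCapacity:
    """Quantum harmonic heat capacity Cv = k_B sum x^2 e^x/(e^x-1)^2 over the
    internal modes, x = h c nu / (k_B T); the classical limit (one k_B per
    internal mode, i.e. 3N-6 k_B for a 3-D structure) is returned alongside."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    nu = modes.frequencies_cm[modes.nonzero]
    x = SECOND_RADIATION_CM_K * nu / temperature
    # x^2 e^x / (e^x - 1)^2 evaluated stably: (x / (2 sinh(x/2)))^2
    with np.errstate(over="ignore"):
        half = np.minimum(x / 2.0, 350.0)
        term = (x / (2.0 * np.sinh(half))) ** 2
    cv = KB_KCAL_MOL_K * float(np.sum(term))
    classical = KB_KCAL_MOL_K * len(nu)
    return HeatCapacity(cv, classical, temperature)
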
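"""Constant-velocity pulling of coarse-grained bead-spring models.

A chain of beads (one per residue) is held together by stiff backbone
springs and weaker breakable cross-links; a harmonic restraint couples the
centre-of-mass separation of two groups (main body vs pulling handle) along
a fixed axis to a virtual point moving at constant velocity.  Dynamics are
Langevin (BAOAB splitting); with zero friction the integrator reduces to
velocity Verlet, which is used for energy-conservation audits.

Units: nm, ps, amu, kJ/mol (1 amu nm^2 ps^-2 = 1 kJ/mol exactly), so spring
constants in kJ mol^-1 nm^-2 and forces in kJ mol^-1 nm^-1 need no
conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .structure_io import ProteinStructure

__all__ = [
    "KB_KJ_MOL_K",
    "CGParams",
    "CGModel",
    "PullProtocol",
    "ForceProfile",
    "RuptureEvent",
    "build_cg_model",
    "run_pull",
    "max_force",
    "rupture_force",
    "detect_ruptures",
    "IntegrationError",
    "write_force_profile",
    "write_crosslink_table",
    "read_crosslink_table",
]

KB_KJ_MOL_K = 1.380649e-23 * 6.02214076e23 / 1000.0  # 8.31446e-3 kJ/mol/K


@dataclass(frozen=True)
class CGParams:
    """Construction defaults for the bead-spring model.

    Backbone springs are 10x stiffer than cross-links so unfolding proceeds
    by cross-link rupture rather than backbone stretching.  A cross-link
    breaks permanently once stretched ``rupture_extension`` past its natural
    length; the defaults give a rupture barrier of 1/2 k dr^2 = 45 kJ/mol
    (~18 k_B T at 300 K), the scale of a strong hydrogen-bond cluster, so
    rupture is enthalpy-dominated but thermally assisted.  Next-nearest-
    neighbour springs give the chain enthalpic bending rigidity (a bare
    bead-spring chain is an entropic coil whose tension *grows* with
    temperature, which would mask the rupture mechanics).
    """

    crosslink_k: float = 4000.0  # kJ mol^-1 nm^-2
    backbone_k: float = 40000.0  # kJ mol^-1 nm^-2
    rupture_extension: float = 0.15  # nm
    angle_k: float = 10000.0  # i,i+2 spring, kJ mol^-1 nm^-2


@dataclass
class CGModel:
    positions: np.ndarray  # (N, 3) nm
    masses: np.ndarray  # (N,) amu
    bond_pairs: np.ndarray  # (B, 2) backbone springs
    bond_k: np.ndarray
    bond_r0: np.ndarray
    link_pairs: np.ndarray  # (L, 2) breakable cross-links
    link_k: np.ndarray
    link_r0: np.ndarray
    link_rupture_ext: np.ndarray
    group_a: np.ndarray  # main body bead indices
    group_b: np.ndarray  # pulling handle bead indices
    link_active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.masses)
        for name in ("bond_pairs", "link_pairs"):
            arr = np.asarray(getattr(self, name), dtype=np.int64).reshape(-1, 2)
            setattr(self, name, arr)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} references a missing bead")
        for name in ("bond_k", "bond_r0", "link_k", "link_r0", "link_rupture_ext"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(-1))
        self.group_a = np.asarray(self.group_a, dtype=np.int64)
        self.group_b = np.asarray(self.group_b, dtype=np.int64)
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise ValueError("pull groups must be non-empty")
        if set(self.group_a.tolist()) & set(self.group_b.tolist()):
            raise ValueError("pull groups must be disjoint")
        if self.link_active is None:
            # fresh model: the bond graph must be connected before pulling
            # (post-pull copies carry their broken-link state and are exempt)
            self.link_active = np.ones(len(self.link_pairs), dtype=bool)
            if not self._connected():
                raise ValueError("bond graph is disconnected before pulling")

    def _connected(self) -> bool:
        n = len(self.masses)
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.bond_pairs:
            adj[i].append(j)
            adj[j].append(i)
        for (i, j), act in zip(self.link_pairs, self.link_active):
            if act:
                adj[i].append(j)
                adj[j].append(i)
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        return bool(seen.all())

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def n_active_links(self) -> int:
        return int(self.link_active.sum())

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


@dataclass(frozen=True)
class PullProtocol:
    """Constant-velocity pulling protocol (defaults mirror a standard
    umbrella-pulling setup: 1,500 kJ mol^-1 nm^-2 spring, 0.01 nm/ps,
    2 fs timestep, samples every 1 ps, reaction coordinate along z)."""

    spring_constant: float = 1500.0  # kJ mol^-1 nm^-2
    pull_rate: float = 0.01  # nm/ps
    temperature: float = 300.0  # K
    timestep_fs: float = 2.0
    record_interval_ps: float = 1.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0
    friction_ps: float = 1.0  # Langevin friction; 0 disables the thermostat
    max_extension_factor: float = 3.0  # stop at this multiple of the initial end-to-end
    max_time_ps: float | None = None
    # stop early once every cross-link has ruptured and the load has decayed
    # below half its running peak (the profile past that point is backbone
    # stretching, not unfolding); ignored for models without cross-links
    stop_after_ruptures: bool = True

    def __post_init__(self) -> None:
        if self.spring_constant <= 0 or self.timestep_fs <= 0 or self.record_interval_ps <= 0:
            raise ValueError("protocol parameters must be positive")
        if self.pull_rate < 0 or self.temperature < 0 or self.friction_ps < 0:
            raise ValueError("protocol parameters must be non-negative")
        ax = np.asarray(self.axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(ax)), 1.0, rel_tol=1e-9):
            raise ValueError("axis must be a unit vector")


@dataclass
class ForceProfile:
    times: np.ndarray  # ps
    separations: np.ndarray  # COM separation along the axis, nm
    forces: np.ndarray  # restraint spring force, kJ mol^-1 nm^-1
    protocol: PullProtocol
    energies: np.ndarray | None = None  # total energy at sample times (audits)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.separations) == len(self.forces)):
            raise ValueError("profile columns must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RuptureEvent:
    time: float  # ps
    force_before: float  # kJ mol^-1 nm^-1
    links: tuple[tuple[int, int], ...]  # bead pairs broken at this event


def build_cg_model(
    structure: ProteinStructure,
    crosslink_table: Sequence[tuple] | np.ndarray,
    params: CGParams = CGParams(),
    group_a: Sequence[int] | None = None,
    group_b: Sequence[int] | None = None,
) -> CGModel:
    """Bead-spring model from a bead-per-residue structure (Å -> nm).

    Backbone springs join consecutive beads at their current spacing;
    cross-links come from the table rows (i, j[, k, r0, rupture_ext]) with
    missing entries filled from ``params`` and the current geometry.  The
    default pull groups are all-but-last (main body) and the last bead
    (handle).
    """
    if structure.n_atoms != structure.n_residues:
        raise ValueError("CG model needs a bead-per-residue structure")
    pos = structure.coords * 0.1  # Å -> nm
    n = len(pos)
    bond_pairs = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    bond_k = np.full(n - 1, params.backbone_k)
    if params.angle_k > 0 and n > 2:
        angle_pairs = np.stack([np.arange(n - 2), np.arange(2, n)], axis=1)
        bond_pairs = np.concatenate([bond_pairs, angle_pairs])
        bond_k = np.concatenate([bond_k, np.full(n - 2, params.angle_k)])
    bond_r0 = np.linalg.norm(pos[bond_pairs[:, 0]] - pos[bond_pairs[:, 1]], axis=1)
    rows = list(crosslink_table)
    link_pairs, link_k, link_r0, link_ext = [], [], [], []
    for row in rows:
        row = list(row)
        i, j = int(row[0]), int(row[1])
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"cross-link ({i}, {j}) references a missing bead")
        k = float(row[2]) if len(row) > 2 and not np.isnan(float(row[2])) else params.crosslink_k
        dist = float(np.linalg.norm(pos[i] - pos[j]))
        r0 = float(row[3]) if len(row) > 3 and not np.isnan(float(row[3])) else dist
        ext = (
            float(row[4])
            if len(row) > 4 and not np.isnan(float(row[4]))
            else params.rupture_extension
        )
        link_pairs.append((i, j))
        link_k.append(k)
        link_r0.append(r0)
        link_ext.append(ext)
    return CGModel(
        positions=pos,
        masses=structure.masses.copy(),
        bond_pairs=bond_pairs,
        bond_k=bond_k,
        bond_r0=bond_r0,
        link_pairs=np.array(link_pairs, dtype=np.int64).reshape(-1, 2),
        link_k=np.array(link_k),
        link_r0=np.array(link_r0),
        link_rupture_ext=np.array(link_ext),
        group_a=np.array(group_a if group_a is not None else np.arange(n - 1), dtype=np.int64),
        group_b=np.array(group_b if group_b is not None else [n - 1], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# integrator core (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forces(pos, bond_pairs, bond_k, bond_r0, link_pairs, link_k, link_r0, active):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    pot = 0.0
    for s in range(bond_pairs.shape[0]):
        i, j = bond_pairs[s, 0], bond_pairs[s, 1]
        dx = pos[i] - pos[j]
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        c = bond_k[s] * (r - bond_r0[s]) / r
        pot += 0.5 * bond_k[s] * (r - bond_r0[s]) ** 2
        for a in range(3):
            f[i, a] -= c * dx[a]
            f[j, a] += c * dx[a]
    for s in range(link_pairs.shape[0]):
        if not active[s]:
            continue
        i, j = link_pairs[s, 0], link_pairs[s, 1]
        dx = pos[i] - pos[j]
        r = math.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        c = link_k[s] * (r - link_r0[s]) / r
        pot += 0.5 * link_k[s] * (r - link_r0[s]) ** 2
        for a in range(3):
            f[i, a] -= c * dx[a]
            f[j, a] += c * dx[a]
    return f, pot


@njit(cache=True)
def _pull_loop(
    pos,
    vel,
    masses,
    bond_pairs,
    bond_k,
    bond_r0,
    link_pairs,
    link_k,
    link_r0,
    link_break_r,
    active,
    group_a,
    group_b,
    axis,
    kappa,
    rate,
    dt,
    n_steps,
    record_every,
    friction,
    kbt,
    seed,
    early_stop,
):
    np.random.seed(seed)
    n = pos.shape[0]
    m_a = 0.0
    for i in group_a:
        m_a += masses[i]
    m_b = 0.0
    for i in group_b:
        m_b += masses[i]

    def _zeta(p):
        za = 0.0
        for i in group_a:
            za += masses[i] * (p[i, 0] * axis[0] + p[i, 1] * axis[1] + p[i, 2] * axis[2])
        zb = 0.0
        for i in group_b:
            zb += masses[i] * (p[i, 0] * axis[0] + p[i, 1] * axis[1] + p[i, 2] * axis[2])
        return zb / m_b - za / m_a

    zeta0 = _zeta(pos)

    c1 = math.exp(-friction * dt) if friction > 0.0 else 1.0
    noise = math.sqrt(kbt * (1.0 - c1 * c1)) if friction > 0.0 else 0.0

    n_rec = n_steps // record_every
    rec_t = np.empty(n_rec)
    rec_zeta = np.empty(n_rec)
    rec_force = np.empty(n_rec)
    rec_energy = np.empty(n_rec)
    break_step = np.full(link_pairs.shape[0], -1, dtype=np.int64)
    break_force = np.zeros(link_pairs.shape[0])

    f, pot = _forces(pos, bond_pairs, bond_k, bond_r0, link_pairs, link_k, link_r0, active)
    zeta = _zeta(pos)
    target = zeta0
    bias = kappa * (target - zeta)
    for i in group_b:
        w = masses[i] / m_b
        for a in range(3):
            f[i, a] += bias * w * axis[a]
    for i in group_a:
        w = masses[i] / m_a
        for a in range(3):
            f[i, a] -= bias * w * axis[a]

    r_idx = 0
    for step in range(n_steps):
        # B
        for i in range(n):
            for a in range(3):
                vel[i, a] += 0.5 * dt * f[i, a] / masses[i]
        # A
        for i in range(n):
            for a in range(3):
                pos[i, a] += 0.5 * dt * vel[i, a]
        # O
        if friction > 0.0:
            for i in range(n):
                s = noise / math.sqrt(masses[i])
                for a in range(3):
                    vel[i, a] = c1 * vel[i, a] + s * np.random.normal()
        # A
        for i in range(n):
            for a in range(3):
                pos[i, a] += 0.5 * dt * vel[i, a]

        t = (step + 1) * dt
        target = zeta0 + rate * t
        zeta = _zeta(pos)
        bias = kappa * (target - zeta)

        # rupture check on the stretched links
        for s in range(link_pairs.shape[0]):
            if not active[s]:
                continue
            i, j = link_pairs[s, 0], link_pairs[s, 1]
            dx0 = pos[i, 0] - pos[j, 0]
            dx1 = pos[i, 1] - pos[j, 1]
            dx2 = pos[i, 2] - pos[j, 2]
            r = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
            if r > link_r0[s] + link_break_r[s]:
                active[s] = False
                break_step[s] = step + 1
                break_force[s] = bias

        f, pot = _forces(pos, bond_pairs, bond_k, bond_r0, link_pairs, link_k, link_r0, active)
        for i in group_b:
            w = masses[i] / m_b
            for a in range(3):
                f[i, a] += bias * w * axis[a]
        for i in group_a:
            w = masses[i] / m_a
            for a in range(3):
                f[i, a] -= bias * w * axis[a]
        # B
        for i in range(n):
            for a in range(3):
                vel[i, a] += 0.5 * dt * f[i, a] / masses[i]

        if not np.isfinite(pot):
            return rec_t[:r_idx], rec_zeta[:r_idx], rec_force[:r_idx], rec_energy[:r_idx], break_step, break_force, t, 2

        if (step + 1) % record_every == 0:
            ke = 0.0
            for i in range(n):
                for a in range(3):
                    ke += 0.5 * masses[i] * vel[i, a] ** 2
            rec_t[r_idx] = t
            rec_zeta[r_idx] = zeta
            rec_force[r_idx] = bias
            rec_energy[r_idx] = ke + pot + 0.5 * kappa * (target - zeta) ** 2
            r_idx += 1
            if early_stop and link_pairs.shape[0] > 0:
                any_active = False
                for s in range(link_pairs.shape[0]):
                    if active[s]:
                        any_active = True
                        break
                if not any_active:
                    running_max = 0.0
                    for k in range(r_idx):
                        if rec_force[k] > running_max:
                            running_max = rec_force[k]
                    if bias < 0.5 * running_max:
                        return rec_t[:r_idx], rec_zeta[:r_idx], rec_force[:r_idx], rec_energy[:r_idx], break_step, break_force, t, 1

    return rec_t[:r_idx], rec_zeta[:r_idx], rec_force[:r_idx], rec_energy[:r_idx], break_step, break_force, n_steps * dt, 0


class IntegrationError(RuntimeError):
    """Integrator blow-up (non-finite energy); carries the last stable time."""

    def __init__(self, message: str, last_stable_time: float):
        super().__init__(message)
        self.last_stable_time = last_stable_time


def run_pull(
    model: CGModel, protocol: PullProtocol
) -> tuple[ForceProfile, CGModel, list[RuptureEvent]]:
    """Run the constant-velocity pull; returns the recorded force profile,
    the final model (broken links deactivated), and the logged rupture
    events.  Fully deterministic for a fixed seed."""
    dt = protocol.timestep_fs * 1e-3  # fs -> ps
    record_every = max(1, int(round(protocol.record_interval_ps / dt)))
    if protocol.max_time_ps is not None:
        total_time = protocol.max_time_ps
    else:
        pull_distance = max(
            (protocol.max_extension_factor - 1.0) * model.end_to_end, 10.0 * dt * protocol.pull_rate
        )
        total_time = pull_distance / protocol.pull_rate if protocol.pull_rate > 0 else 100.0
    n_steps = max(record_every, int(round(total_time / dt)))

    pos = model.positions.copy()
    vel = np.zeros_like(pos)
    if protocol.temperature > 0:
        # Maxwell-Boltzmann start; with friction_ps = 0 the run is then NVE
        rng = np.random.default_rng(protocol.seed)
        sigma = np.sqrt(KB_KJ_MOL_K * protocol.temperature / model.masses)
        vel = rng.standard_normal(pos.shape) * sigma[:, None]
    active = model.link_active.copy()
    kbt = KB_KJ_MOL_K * protocol.temperature

    rec_t, rec_z, rec_f, rec_e, break_step, break_force, last_t, status = _pull_loop(
        pos,
        vel,
        model.masses,
        model.bond_pairs,
        model.bond_k,
        model.bond_r0,
        model.link_pairs if len(model.link_pairs) else np.zeros((0, 2), dtype=np.int64),
        model.link_k,
        model.link_r0,
        model.link_rupture_ext,
        active,
        model.group_a,
        model.group_b,
        np.asarray(protocol.axis, dtype=float),
        protocol.spring_constant,
        protocol.pull_rate,
        dt,
        n_steps,
        record_every,
        protocol.friction_ps,
        kbt,
        protocol.seed % (2**31 - 1),
        protocol.stop_after_ruptures,
    )
    if status == 2:
        raise IntegrationError(
            f"integrator diverged at t = {last_t:.3f} ps", last_stable_time=float(last_t)
        )

    events: list[RuptureEvent] = []
    by_time: dict[float, list[int]] = {}
    for s, bstep in enumerate(break_step):
        if bstep >= 0:
            by_time.setdefault(float(bstep * dt), []).append(s)
    for t_evt in sorted(by_time):
        links = tuple(
            (int(model.link_pairs[s, 0]), int(model.link_pairs[s, 1])) for s in by_time[t_evt]
        )
        events.append(
            RuptureEvent(t_evt, float(break_force[by_time[t_evt][0]]), links)
        )

    profile = ForceProfile(rec_t, rec_z, rec_f, protocol, energies=rec_e)
    final = replace(
        model,
        positions=pos,
        link_active=active,
        bond_pairs=model.bond_pairs.copy(),
        link_pairs=model.link_pairs.copy(),
    )
    return profile, final, events


def max_force(profile: ForceProfile) -> tuple[float, float]:
    """Maximum recorded restraint force and the time it occurred (by direct
    scan of the stored samples)."""
    if len(profile.forces) == 0:
        raise ValueError("empty force profile")
    idx = int(np.argmax(profile.forces))
    return float(profile.forces[idx]), float(profile.times[idx])


def rupture_force(
    profile: ForceProfile,
    events: Sequence[RuptureEvent] | None = None,
    smooth_ps: float = 10.0,
    aggregate: str = "mean",
) -> float:
    """Characteristic unfolding force of a pull: the smoothed restraint load
    at the logged rupture events.

    The raw restraint force carries thermal COM jitter of order
    sqrt(kappa * k_B T), so the profile is moving-average smoothed over
    ``smooth_ps`` first.  ``aggregate`` is 'mean' (the average load at which
    the model's stabilising contacts failed — the default, statistically
    robust for models with few links) or 'max' (the strongest single
    rupture).  Without events, returns the global smoothed peak.
    """
    if len(profile.forces) == 0:
        raise ValueError("empty force profile")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    dt = float(np.median(np.diff(profile.times))) if len(profile.times) > 1 else smooth_ps
    w = max(1, int(round(smooth_ps / dt)))
    smoothed = uniform_filter1d(profile.forces, size=w, mode="nearest")
    if events:
        vals = []
        for ev in events:
            i = int(np.argmin(np.abs(profile.times - ev.time)))
            vals.append(float(smoothed[i]))
        return float(np.mean(vals)) if aggregate == "mean" else float(np.max(vals))
    return float(smoothed.max())


def detect_ruptures(
    profile: ForceProfile,
    drop_fraction: float = 0.2,
    window_ps: float = 20.0,
    logged_events: Sequence[RuptureEvent] | None = None,
    min_peak_fraction: float = 0.05,
    smooth_ps: float | None = None,
) -> list[RuptureEvent]:
    """Force-drop rupture detection on the recorded profile.

    The force is smoothed with a moving average (``smooth_ps``, default a
    fifth of the window) to suppress thermal fluctuation, then an event is a
    sample at least ``drop_fraction`` below the trailing-window local
    maximum, provided that maximum exceeds ``min_peak_fraction`` of the
    profile's global peak (drops from negligible load are not ruptures).
    Consecutive below-threshold samples merge into one event.  If
    integrator-logged link breakages are given, detected events within the
    window of a logged event adopt its broken-link list.
    """
    if len(profile.times) < 2:
        raise ValueError("profile too short")
    dt = float(np.median(np.diff(profile.times)))
    w = max(2, int(round(window_ps / dt)))
    if len(profile.forces) < w:
        w = len(profile.forces)
    smooth_n = max(1, int(round((smooth_ps if smooth_ps is not None else window_ps / 5.0) / dt)))
    forces = uniform_filter1d(profile.forces, size=smooth_n, mode="nearest") if smooth_n > 1 else profile.forces
    # trailing-window local maximum (exclusive of the current sample)
    trail_max = maximum_filter1d(forces, size=w, mode="nearest", origin=w // 2 - 1)
    shifted = np.concatenate([[forces[0]], trail_max[:-1]])
    floor = min_peak_fraction * float(forces.max())
    is_drop = (forces <= (1.0 - drop_fraction) * shifted) & (shifted > floor)
    events: list[RuptureEvent] = []
    in_event = False
    for i, flag in enumerate(is_drop):
        if flag and not in_event:
            t = float(profile.times[i])
            peak = float(shifted[i])
            links: tuple[tuple[int, int], ...] = ()
            if logged_events:
                for ev in logged_events:
                    if abs(ev.time - t) <= window_ps:
                        links = links + ev.links
            events.append(RuptureEvent(t, peak, links))
            in_event = True
        elif not flag:
            in_event = False
    return events


# ---------------------------------------------------------------------------
# plain-text exports
# ---------------------------------------------------------------------------


def write_force_profile(profile: ForceProfile, path: str | Path) -> None:
    path = Path(path)
    lines = ["time_ps\tcom_separation_nm\tforce_kJ_mol_nm"]
    for t, z, f in zip(profile.times, profile.separations, profile.forces):
        lines.append(f"{t:.6g}\t{z:.8g}\t{f:.8g}")
    path.write_text("\n".join(lines) + "\n")


def write_crosslink_table(model: CGModel, path: str | Path) -> None:
    path = Path(path)
    lines = ["i\tj\tk_spring\tr0\trupture_extension"]
    for s in range(len(model.link_pairs)):
        i, j = model.link_pairs[s]
        lines.append(
            f"{i}\t{j}\t{model.link_k[s]:.8g}\t{model.link_r0[s]:.8g}\t{model.link_rupture_ext[s]:.8g}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_crosslink_table(path: str | Path) -> np.ndarray:
    """Rows of (i, j, k_spring, r0, rupture_extension)."""
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.size == 0:
        return np.zeros((0, 5))
    if data.shape[1] != 5:
        raise ValueError("cross-link table must have 5 columns")
    return data
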
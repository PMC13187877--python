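"""Vibrational energy transport: per-mode diffusivity, frequency-band and
thermal averaging, residue-residue communication maps, and an independent
wave-packet oracle.

The per-mode energy diffusivity follows the Allen-Feldman harmonic-transport
formulation: near-resonant modes exchange energy through heat-flux matrix
elements built from the mass-weighted force-constant matrix,

    D_a = (pi / (d * w_a^2)) * sum_{b != a} |S_ab|^2 * g_eta(w_a - w_b)

    S_ab = (w_a + w_b)/2 * W_ab,
    W_ab^c = (1 / (2 sqrt(w_a w_b))) * sum_{i,j} (r_i^c - r_j^c)
             * e_a(i) . Phi_ij . e_b(j)

with Phi the mass-weighted Hessian blocks, d the spatial dimensionality,
and g_eta a unit-area Gaussian replacing the delta function in a finite
spectrum.  W is the harmonic velocity matrix (Å/ps), so D carries Å^2/ps.
Rigid-body modes are excluded from every sum.

The wave-packet oracle never touches this formula: it propagates exact
harmonic dynamics from a localized kinetic-energy excitation and measures
the growth rate of the energy-weighted mean-square displacement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nma import Hessian, NormalModeSet, SECOND_RADIATION_CM_K, WAVENUMBER_PER_ANGULAR_PS
from .structure_io import ProteinStructure

__all__ = [
    "ModeDiffusivity",
    "BandSpec",
    "BandAverages",
    "CommunicationMap",
    "VEDProfile",
    "ColorClass",
    "ColorThresholds",
    "OracleResult",
    "mode_diffusivity",
    "wavepacket_oracle",
    "band_average",
    "thermal_average",
    "communication_map",
    "difference_map",
    "ved_profile",
    "classify_ved",
    "top_residues",
]

#: partners further than this many broadening widths contribute < 1e-10 and
#: are skipped; the same window is used by the map decomposition so that the
#: residue-pair partition sums exactly to the per-mode values
PARTNER_WINDOW_SIGMAS = 7.0

#: default reference temperature for the classical amplitude convention
REFERENCE_TEMPERATURE_K = 300.0


@dataclass
class ModeDiffusivity:
    """Per-mode Allen-Feldman diffusivities aligned with a mode set.

    ``values`` has one entry per mode (Å^2/ps); rigid-body modes carry NaN
    and are excluded from every average.  ``broadening_cm`` records the
    Gaussian width actually used for each mode.
    """

    values: np.ndarray
    broadening_cm: np.ndarray
    n_zero_modes: int

    def __post_init__(self) -> None:
        finite = self.values[self.n_zero_modes :]
        if np.any(finite < -1e-12):
            raise ValueError("negative mode diffusivity")

    @property
    def internal_values(self) -> np.ndarray:
        return self.values[self.n_zero_modes :]


@dataclass(frozen=True)
class BandSpec:
    """Frequency bands: ``modes_per_band`` modes nearest each center (cm^-1)."""

    centers: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 300.0, 400.0)
    modes_per_band: int = 10

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.centers):
            raise ValueError("band centers must be positive")
        if list(self.centers) != sorted(self.centers):
            raise ValueError("band centers must ascend")
        if self.modes_per_band < 1:
            raise ValueError("modes_per_band must be >= 1")


@dataclass
class BandAverages:
    centers: tuple[float, ...]
    values: np.ndarray  # per-center average
    memberships: list[np.ndarray]  # mode indices (into the full mode set) per center


class ColorClass(enum.Enum):
    RED = "red"
    ORANGE = "orange"
    BLUE = "blue"
    BELOW_RANGE = "below_range"


@dataclass(frozen=True)
class ColorThresholds:
    """VED color bands on the map's printed scale: red above ``red_min``,
    orange in [orange_min, red_min], blue in [blue_min, orange_min)."""

    red_min: float = 1.0e7
    orange_min: float = 9.0e6
    blue_min: float = 8.0e6

    def __post_init__(self) -> None:
        if not (0 < self.blue_min < self.orange_min < self.red_min):
            raise ValueError("thresholds must satisfy 0 < blue < orange < red")

    def rescaled_to(self, values: np.ndarray, percentile: float = 90.0) -> "ColorThresholds":
        """Thresholds mapped onto a data set: red_min at the given percentile,
        keeping the printed bands' relative spacing."""
        ref = float(np.percentile(values, percentile))
        if ref <= 0:
            raise ValueError("cannot rescale thresholds to non-positive data")
        s = ref / self.red_min
        return ColorThresholds(self.red_min * s, self.orange_min * s, self.blue_min * s)


@dataclass
class CommunicationMap:
    """Residue x residue energy-diffusivity matrix at one temperature/band."""

    matrix: np.ndarray  # (R, R), Å^2/ps
    temperature: float  # K
    band: BandSpec
    residue_labels: list[str]
    temperature_reference: float | None = None  # set on difference maps

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        r = len(self.residue_labels)
        if self.matrix.shape != (r, r):
            raise ValueError("map shape does not match residue labels")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-9 * max(np.abs(self.matrix).max(), 1e-300):
            raise ValueError("communication map must be symmetric")

    @property
    def is_difference(self) -> bool:
        return self.temperature_reference is not None

    @property
    def total(self) -> float:
        """Sum over all ordered residue pairs (the decomposed global VED)."""
        return float(self.matrix.sum())


@dataclass
class VEDProfile:
    """Per-residue vibrational energy diffusivity (row sums of a map)."""

    values: np.ndarray
    temperature: float
    residue_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.residue_labels):
            raise ValueError("profile length does not match labels")


# ---------------------------------------------------------------------------
# per-mode diffusivity
# ---------------------------------------------------------------------------


def _local_broadening(omega: np.ndarray, factor: float = 3.0, half_window: int = 5) -> np.ndarray:
    """Per-mode Gaussian width: ``factor`` x local mean mode spacing (ps^-1)."""
    m = len(omega)
    if m < 2:
        raise ValueError("need at least two internal modes")
    eta = np.empty(m)
    for a in range(m):
        lo = max(0, a - half_window)
        hi = min(m - 1, a + half_window)
        eta[a] = factor * (omega[hi] - omega[lo]) / max(hi - lo, 1)
    floor = 1e-6 * omega[-1]
    return np.maximum(eta, floor)


def _gaussian(x: np.ndarray, eta: float) -> np.ndarray:
    return np.exp(-0.5 * (x / eta) ** 2) / (eta * math.sqrt(2.0 * math.pi))


def _velocity_operators(hessian: Hessian) -> list[np.ndarray]:
    """[R_c, H] commutators, one (Nd x Nd) matrix per Cartesian direction c;
    entry blocks are (r_i^c - r_j^c) Phi_ij."""
    d = hessian.dim
    ops = []
    for c in range(d):
        r_c = np.repeat(hessian.coords[:, c], d)
        ops.append(hessian.matrix * (r_c[:, None] - r_c[None, :]))
    return ops


def mode_diffusivity(
    modes: NormalModeSet,
    hessian: Hessian,
    broadening: float | None = None,
    broadening_factor: float = 3.0,
) -> ModeDiffusivity:
    """Allen-Feldman diffusivity per internal mode (Å^2/ps).

    ``broadening`` fixes a uniform Gaussian width in cm^-1; by default the
    width is ``broadening_factor`` times the local mean mode spacing around
    each mode, which adapts to the spectral density of a finite system.
    """
    if broadening is not None and broadening <= 0:
        raise ValueError("broadening must be positive")
    if modes.eigenvectors.shape[0] != hessian.matrix.shape[0]:
        raise ValueError("mode set and Hessian dimensions do not match")
    d = hessian.dim
    idx = modes.nonzero
    omega = modes.omega_ps[idx]
    v = modes.eigenvectors[:, idx]
    m = len(omega)
    if broadening is not None:
        eta = np.full(m, broadening / WAVENUMBER_PER_ANGULAR_PS)
    else:
        eta = _local_broadening(omega, factor=broadening_factor)

    # X_c[a, b] = e_a^T (R_c H - H R_c) e_b  (antisymmetric)
    x_ops = [v.T @ (op @ v) for op in _velocity_operators(hessian)]
    sqrt_w = np.sqrt(omega)
    denom = 2.0 * np.outer(sqrt_w, sqrt_w)
    s_pref = 0.5 * (omega[:, None] + omega[None, :]) / denom
    s2 = np.zeros((m, m))
    for x in x_ops:
        s2 += (s_pref * x) ** 2

    values = np.zeros(m)
    for a in range(m):
        window = PARTNER_WINDOW_SIGMAS * eta[a]
        partners = np.flatnonzero(np.abs(omega - omega[a]) <= window)
        partners = partners[partners != a]
        if len(partners) == 0:
            continue
        g = _gaussian(omega[partners] - omega[a], eta[a])
        values[a] = math.pi / (d * omega[a] ** 2) * float(np.dot(s2[a, partners], g))

    full = np.full(modes.n_modes, np.nan)
    full[idx] = values
    eta_full = np.full(modes.n_modes, np.nan)
    eta_full[idx] = eta * WAVENUMBER_PER_ANGULAR_PS
    return ModeDiffusivity(full, eta_full, modes.n_zero_modes)


# ---------------------------------------------------------------------------
# wave-packet oracle
# ---------------------------------------------------------------------------


@dataclass
class OracleResult:
    diffusivity: float  # Å^2/ps
    times: np.ndarray  # ps
    msd: np.ndarray  # Å^2, energy-weighted mean-square displacement
    energy_drift: float  # max relative deviation of total energy
    fit_slope: float
    fit_window: tuple[float, float]


def wavepacket_oracle(
    hessian: Hessian,
    source_atom: int,
    t_max: float,
    n_times: int = 400,
    freq_window_cm: tuple[float, float] | None = None,
    fit_plateau_fractions: tuple[float, float] = (0.2, 0.6),
) -> OracleResult:
    """Brute-force transport estimate from exact harmonic dynamics.

    A kinetic-energy kick is applied at ``source_atom`` (rigid-body modes
    projected out; optionally band-passed to ``freq_window_cm``), site
    energies are tracked analytically, and the diffusivity is half the slope
    per spatial dimension of the energy-weighted mean-square displacement
    <R^2(t)>.  In a finite system <R^2> saturates at the uniform-energy
    plateau (the mean squared distance from the source), so the asymptotic
    slope is fitted over the first contiguous stretch where <R^2> lies
    between ``fit_plateau_fractions`` of that plateau — past the ballistic
    transient, before boundary saturation.  ``t_max`` must be long enough to
    reach the window; extending it further does not change the estimate.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    n, d = hessian.coords.shape
    if not (0 <= source_atom < n):
        raise ValueError("source_atom out of range")

    evals, evecs = np.linalg.eigh(hessian.matrix)
    scale = max(np.abs(evals).max(), 1e-300)
    nonzero = evals > 1e-8 * scale
    omega = np.sqrt(evals[nonzero])
    v = evecs[:, nonzero]

    # unit velocity kick at the source site, equally split over its DOFs
    qdot0 = np.zeros(n * d)
    qdot0[source_atom * d : source_atom * d + d] = 1.0 / math.sqrt(d)
    amp = v.T @ qdot0  # mode velocity amplitudes
    if freq_window_cm is not None:
        lo, hi = (f / WAVENUMBER_PER_ANGULAR_PS for f in freq_window_cm)
        amp = np.where((omega >= lo) & (omega <= hi), amp, 0.0)
    if not np.any(amp != 0.0):
        raise ValueError("excitation has no overlap with the selected modes")

    times = np.linspace(0.0, t_max, n_times + 1)[1:]
    wt = np.outer(omega, times)
    sin_wt, cos_wt = np.sin(wt), np.cos(wt)
    q_modes = (amp / omega)[:, None] * sin_wt  # (M, T)
    qdot_modes = amp[:, None] * cos_wt
    q = v @ q_modes  # (Nd, T) mass-weighted displacements
    qdot = v @ qdot_modes
    hq = v @ (evals[nonzero][:, None] * q_modes)

    ke = 0.5 * (qdot.reshape(n, d, -1) ** 2).sum(axis=1)  # (N, T)
    pe = 0.5 * (q.reshape(n, d, -1) * hq.reshape(n, d, -1)).sum(axis=1)
    site_energy = ke + pe
    total = site_energy.sum(axis=0)
    e0 = 0.5 * float(np.sum(amp**2))
    energy_drift = float(np.abs(total - e0).max() / e0)

    disp2 = np.sum((hessian.coords - hessian.coords[source_atom]) ** 2, axis=1)
    msd = (disp2[:, None] * site_energy).sum(axis=0) / total

    # fit window: first contiguous run between the plateau fractions
    plateau = float(disp2.mean())
    lo_frac, hi_frac = fit_plateau_fractions
    idx = np.flatnonzero((msd >= lo_frac * plateau) & (msd <= hi_frac * plateau))
    if len(idx) == 0:
        raise ValueError(
            "no samples in the fit window; increase t_max or n_times"
        )
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run = idx[: breaks[0] + 1] if len(breaks) else idx
    if len(run) < 4:
        raise ValueError("fit window too sparse; increase n_times")
    slope = float(np.polyfit(times[run], msd[run], 1)[0])
    return OracleResult(
        diffusivity=slope / (2.0 * d),
        times=times,
        msd=msd,
        energy_drift=energy_drift,
        fit_slope=slope,
        fit_window=(float(times[run[0]]), float(times[run[-1]])),
    )


# ---------------------------------------------------------------------------
# band and thermal averaging
# ---------------------------------------------------------------------------


def band_memberships(modes: NormalModeSet, band: BandSpec) -> list[np.ndarray]:
    """For each band center, the ``modes_per_band`` internal modes nearest in
    frequency (ties broken toward lower frequency); indices into the full
    mode set."""
    idx = modes.nonzero
    if len(idx) == 0:
        raise ValueError("empty spectrum")
    if len(idx) < band.modes_per_band:
        raise ValueError(
            f"need at least {band.modes_per_band} internal modes, have {len(idx)}"
        )
    freqs = modes.frequencies_cm[idx]
    out = []
    for center in band.centers:
        order = sorted(range(len(idx)), key=lambda a: (abs(freqs[a] - center), freqs[a]))
        chosen = np.array(sorted(idx[order[: band.modes_per_band]]))
        out.append(chosen)
    return out


def band_average(D: ModeDiffusivity, modes: NormalModeSet, band: BandSpec) -> BandAverages:
    """Average the per-mode diffusivity over each band's member modes."""
    members = band_memberships(modes, band)
    values = np.array([float(np.mean(D.values[m])) for m in members])
    return BandAverages(band.centers, values, members)


def _bose_occupation(nu_cm: np.ndarray, temperature: float) -> np.ndarray:
    x = SECOND_RADIATION_CM_K * np.asarray(nu_cm) / temperature
    return 1.0 / np.expm1(x)


def thermal_average(
    band_values: BandAverages | np.ndarray,
    temperature: float,
    band: BandSpec,
    weighting: str = "classical",
    scale_with_temperature: bool = True,
    reference_temperature: float = REFERENCE_TEMPERATURE_K,
) -> float:
    """Thermally averaged VED over the bands.

    Classical weighting gives every mode the same k_B T of energy, so the
    band mean is uniform and, with the amplitude convention enabled, scaled
    by T / T_ref (vibrational amplitudes grow linearly with T in a classical
    harmonic system).  Quantum weighting uses Bose occupations of the band
    centers instead, with no extra scaling.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    values = band_values.values if isinstance(band_values, BandAverages) else np.asarray(band_values)
    if weighting == "classical":
        mean = float(np.mean(values))
        if scale_with_temperature:
            mean *= temperature / reference_temperature
        return mean
    if weighting == "quantum":
        w = _bose_occupation(np.array(band.centers), temperature)
        return float(np.sum(w * values) / np.sum(w))
    raise ValueError(f"unknown weighting {weighting!r}")


# ---------------------------------------------------------------------------
# communication maps
# ---------------------------------------------------------------------------


def _pairwise_mode_decomposition(
    modes: NormalModeSet,
    hessian: Hessian,
    D: ModeDiffusivity,
    mode_list: np.ndarray,
    residue_of_atom: np.ndarray,
    n_residues: int,
) -> dict[int, np.ndarray]:
    """Residue-pair decomposition of D_a for each mode in ``mode_list``.

    The heat-flux matrix element is a sum over atom pairs; restricting it to
    i in residue I, j in residue J gives partial elements S^{(IJ)}_ab.  Each
    partner's contribution w_ab |S_ab|^2 is apportioned over residue pairs
    proportionally to |S^{(IJ)}_ab|^2, so entries are non-negative, pairs
    with no force-constant coupling get exactly zero, and the sum over all
    ordered pairs reproduces D_a to roundoff.
    """
    d = hessian.dim
    idx = modes.nonzero
    omega_all = modes.omega_ps
    eta_all = D.broadening_cm / WAVENUMBER_PER_ANGULAR_PS
    v = modes.eigenvectors
    n = hessian.n_atoms
    ops = _velocity_operators(hessian)

    # residue indicator (R x N), beads-per-residue aware
    p = np.zeros((n_residues, n))
    p[residue_of_atom, np.arange(n)] = 1.0

    out: dict[int, np.ndarray] = {}
    omega_int = omega_all[idx]
    for a in mode_list:
        wa = omega_all[a]
        eta = eta_all[a]
        window = PARTNER_WINDOW_SIGMAS * eta
        partners = idx[(np.abs(omega_int - wa) <= window) & (idx != a)]
        cmat = np.zeros((n_residues, n_residues))
        if len(partners) == 0:
            out[a] = cmat
            continue
        ea = v[:, a].reshape(n, d)
        g = _gaussian(omega_all[partners] - wa, eta)
        for b, gb in zip(partners, g):
            wb = omega_all[b]
            pref = 0.5 * (wa + wb) / (2.0 * math.sqrt(wa * wb))
            weight = math.pi / (d * wa**2) * gb
            eb = v[:, b].reshape(n, d)
            s_norm2 = 0.0  # |S_ab|^2 over Cartesian components
            restricted2 = np.zeros((n_residues, n_residues))
            for op in ops:
                # atom-pair resolved flux: F_ij = pref * e_a(i).(R_c H - H R_c)_ij.e_b(j)
                blocks = op.reshape(n, d, n, d)
                f = pref * np.einsum("iu,iujv,jv->ij", ea, blocks, eb)
                f_res = p @ f @ p.T  # S^{(IJ)} for this component
                s_norm2 += float(f_res.sum()) ** 2
                restricted2 += f_res**2
            denom = restricted2.sum()
            if denom > 0.0:
                cmat += weight * s_norm2 * restricted2 / denom
        out[a] = 0.5 * (cmat + cmat.T)
    return out


def communication_map(
    modes: NormalModeSet,
    D: ModeDiffusivity,
    structure: ProteinStructure,
    band: BandSpec,
    temperature: float,
    hessian: Hessian,
    weighting: str = "classical",
    scale_with_temperature: bool = True,
) -> CommunicationMap:
    """Residue x residue communication map: the band- and thermally averaged
    VED decomposed over residue pairs.

    The decomposition is exact: summing the map over all ordered pairs
    recovers ``thermal_average(band_average(D))``.
    """
    if len(D.values) != modes.n_modes:
        raise ValueError("diffusivity not aligned with mode set")
    residue_of_atom = structure.atom_residue_ordinals
    if len(residue_of_atom) != hessian.n_atoms:
        raise ValueError("structure and Hessian atom counts differ")
    n_res = structure.n_residues
    members = band_memberships(modes, band)
    needed = np.unique(np.concatenate(members))
    per_mode = _pairwise_mode_decomposition(modes, hessian, D, needed, residue_of_atom, n_res)

    band_maps = []
    for chosen in members:
        band_maps.append(np.mean([per_mode[a] for a in chosen], axis=0))
    if weighting == "classical":
        matrix = np.mean(band_maps, axis=0)
        if scale_with_temperature:
            matrix = matrix * (temperature / REFERENCE_TEMPERATURE_K)
    elif weighting == "quantum":
        w = _bose_occupation(np.array(band.centers), temperature)
        matrix = np.tensordot(w / w.sum(), np.array(band_maps), axes=1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    # clamp sub-roundoff negatives from the projection split
    floor = -1e-9 * max(abs(matrix).max(), 1e-300)
    matrix = np.where((matrix < 0) & (matrix > floor), 0.0, matrix)
    return CommunicationMap(matrix, temperature, band, structure.residue_labels)


def difference_map(map_hi: CommunicationMap, map_lo: CommunicationMap) -> CommunicationMap:
    """Elementwise map_hi - map_lo (e.g. the 340 K - 300 K energy difference)."""
    if map_hi.residue_labels != map_lo.residue_labels:
        raise ValueError("maps cover different residues")
    if map_hi.band != map_lo.band:
        raise ValueError("maps use different band specs")
    return CommunicationMap(
        map_hi.matrix - map_lo.matrix,
        temperature=map_hi.temperature,
        band=map_hi.band,
        residue_labels=list(map_hi.residue_labels),
        temperature_reference=map_lo.temperature,
    )


def ved_profile(cmap: CommunicationMap) -> VEDProfile:
    """Per-residue VED: row sums of the communication map (total coupling of
    each residue, local term included)."""
    return VEDProfile(cmap.matrix.sum(axis=1), cmap.temperature, list(cmap.residue_labels))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_ved(value: float, thresholds: ColorThresholds = ColorThresholds()) -> ColorClass:
    """Color class of a VED value on the map's printed scale: red above the
    top threshold, orange in [orange_min, red_min] (upper bound inclusive),
    blue in [blue_min, orange_min), below_range otherwise."""
    if value < 0:
        raise ValueError("VED value must be non-negative")
    if value > thresholds.red_min:
        return ColorClass.RED
    if thresholds.orange_min <= value <= thresholds.red_min:
        return ColorClass.ORANGE
    if thresholds.blue_min <= value < thresholds.orange_min:
        return ColorClass.BLUE
    return ColorClass.BELOW_RANGE


@dataclass(frozen=True)
class RankedResidue:
    ordinal: int
    label: str
    value: float
    color: ColorClass


def top_residues(
    profile: VEDProfile, thresholds: ColorThresholds = ColorThresholds()
) -> list[RankedResidue]:
    """Residues falling in a color band, sorted by VED descending (ties by
    residue ordinal)."""
    ranked = []
    for ordinal, (value, label) in enumerate(zip(profile.values, profile.residue_labels)):
        color = classify_ved(float(value), thresholds)
        if color is not ColorClass.BELOW_RANGE:
            ranked.append(RankedResidue(ordinal, label, float(value), color))
    ranked.sort(key=lambda r: (-r.value, r.ordinal))
    return ranked
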
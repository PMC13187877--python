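"""Energy transport: mode diffusivity vs the wave-packet oracle, band and
thermal averaging, communication-map algebra, and VED classification."""

import numpy as np
import pytest

from tests.conftest import disordered_chain_hessian
from vibromap import nma, transport
from vibromap.synthetic import make_homolog_pair
from vibromap.transport import (
    BandSpec,
    ColorClass,
    ColorThresholds,
    VEDProfile,
    band_average,
    classify_ved,
    communication_map,
    difference_map,
    mode_diffusivity,
    thermal_average,
    top_residues,
    ved_profile,
    wavepacket_oracle,
)


@pytest.fixture(scope="module")
def chain_transport():
    """64-bead mass-disordered chain with modes and diffusivities."""
    h = disordered_chain_hessian(seed=0)
    modes = nma.normal_modes(h)
    return h, modes, mode_diffusivity(modes, h)


@pytest.fixture(scope="module")
def homolog_maps():
    """Homolog pair communication maps at 300 K (seed 1, 32 beads)."""
    out = {}
    for tag, model in zip("AB", make_homolog_pair(32, 9, 2, seed=1)):
        pot = nma.PotentialModel("pairwise_springs", springs=model.springs)
        h = nma.build_hessian(model.structure, pot)
        modes = nma.normal_modes(h)
        D = mode_diffusivity(modes, h)
        freqs = modes.frequencies_cm[modes.nonzero]
        centers = tuple(float(c) for c in np.percentile(freqs, [20, 40, 60, 80]))
        band = BandSpec(centers, 8)
        cmap = communication_map(modes, D, model.structure, band, 300.0, h)
        out[tag] = (model, modes, D, band, h, cmap)
    return out


class TestModeDiffusivity:
    def test_isolated_oscillator_has_no_transport(self):
        """A single internal mode has no resonant partner, so D = 0."""
        springs = nma.Springs([[0, 1]], [1.0], [3.8])
        h = nma.build_chain_hessian(np.array([1.0, 1.0]), springs, spacing=3.8)
        modes = nma.normal_modes(h)
        D = mode_diffusivity(modes, h, broadening=5.0)
        assert D.values[modes.nonzero[0]] == 0.0

    def test_values_nonnegative_and_zero_modes_flagged(self, chain_transport):
        _, modes, D = chain_transport
        assert np.all(np.isnan(D.values[: modes.n_zero_modes]))
        assert np.all(D.internal_values >= 0.0)

    def test_ordered_chain_diverges_as_broadening_shrinks(self):
        """Perfect chain: harmonic transport is ballistic, so D grows like
        1/eta as the Gaussian width shrinks toward the level spacing (no
        converged value exists; below the spacing the sum is empty)."""
        h = nma.build_chain_hessian(np.ones(32), nma.chain_springs(32, 1.0, 3.8), spacing=3.8)
        modes = nma.normal_modes(h)
        mid = modes.n_modes // 2
        d_wide = mode_diffusivity(modes, h, broadening=30.0).values[mid]
        d_narrow = mode_diffusivity(modes, h, broadening=15.0).values[mid]
        assert d_narrow > 1.5 * d_wide

    def test_broadening_varies_smoothly(self, chain_transport):
        """No >10x jump in mid-spectrum D when the width doubles."""
        h, modes, _ = chain_transport
        d3 = mode_diffusivity(modes, h, broadening_factor=3.0)
        d6 = mode_diffusivity(modes, h, broadening_factor=6.0)
        sel = slice(modes.n_modes // 4, 3 * modes.n_modes // 4)
        ratio = d6.values[sel] / d3.values[sel]
        assert np.nanmax(ratio) < 10.0 and np.nanmin(ratio) > 0.1

    def test_agrees_with_wavepacket_oracle_midband(self, chain_transport):
        """Allen-Feldman band average vs direct wave-packet spreading on a
        disordered chain (single seed; the acceptance suite covers five)."""
        h, modes, D = chain_transport
        band = BandSpec((100.0, 130.0), 10)
        ba = band_average(D, modes, band)
        for value, members in zip(ba.values, ba.memberships):
            lo = modes.frequencies_cm[members].min() - 1e-9
            hi = modes.frequencies_cm[members].max() + 1e-9
            est = np.mean([
                wavepacket_oracle(h, s, t_max=6.0, freq_window_cm=(lo, hi)).diffusivity
                for s in (30, 32, 34)
            ])
            assert value == pytest.approx(est, rel=0.25)


class TestWavepacketOracle:
    def test_total_energy_conserved(self, chain_transport):
        h, _, _ = chain_transport
        res = wavepacket_oracle(h, source_atom=32, t_max=6.0)
        assert res.energy_drift < 1e-6

    def test_excitation_locality(self):
        """End vs middle excitation: same total energy, different early spread."""
        h = disordered_chain_hessian(seed=2)
        end = wavepacket_oracle(h, source_atom=2, t_max=6.0)
        mid = wavepacket_oracle(h, source_atom=32, t_max=6.0)
        # early-time spread from the end is one-sided, hence slower
        assert end.msd[5] != pytest.approx(mid.msd[5], rel=0.05)

    def test_stronger_disorder_transports_less(self):
        def chain(lo, hi):
            return disordered_chain_hessian(seed=7, lo=lo, hi=hi)

        d_weak = wavepacket_oracle(chain(0.9, 1.1), 32, t_max=6.0).diffusivity
        d_strong = wavepacket_oracle(chain(0.5, 2.0), 32, t_max=6.0).diffusivity
        assert d_strong < d_weak

    def test_rejects_bad_inputs(self, chain_transport):
        h, _, _ = chain_transport
        with pytest.raises(ValueError):
            wavepacket_oracle(h, 32, t_max=-1.0)
        with pytest.raises(ValueError):
            wavepacket_oracle(h, 999, t_max=1.0)


class TestBandAveraging:
    def test_constant_field_is_preserved(self, chain_transport):
        _, modes, D = chain_transport
        const = transport.ModeDiffusivity(
            np.where(np.isnan(D.values), np.nan, 4.2), D.broadening_cm, D.n_zero_modes
        )
        ba = band_average(const, modes, BandSpec((50.0, 100.0, 150.0), 10))
        np.testing.assert_allclose(ba.values, 4.2)

    def test_ten_mode_spectrum_exhausts_every_band(self):
        h = nma.build_chain_hessian(np.ones(11), nma.chain_springs(11, 1.0, 3.8))
        modes = nma.normal_modes(h)  # 10 internal modes
        D = mode_diffusivity(modes, h)
        ba = band_average(D, modes, BandSpec((50.0, 100.0, 400.0), 10))
        assert np.ptp(ba.values) == 0.0
        for members in ba.memberships:
            assert len(members) == 10

    def test_nearest_mode_selection_matches_direct_sort(self, chain_transport):
        """With D_a = nu_a, a band average is the mean frequency of the 10
        nearest modes, recomputed here by explicit sort."""
        _, modes, D = chain_transport
        synth = transport.ModeDiffusivity(
            modes.frequencies_cm.astype(float).copy(), D.broadening_cm, D.n_zero_modes
        )
        synth.values[: modes.n_zero_modes] = np.nan
        center = 100.0
        ba = band_average(synth, modes, BandSpec((center,), 10))
        freqs = modes.frequencies_cm[modes.nonzero]
        nearest = sorted(freqs, key=lambda f: (abs(f - center), f))[:10]
        assert ba.values[0] == pytest.approx(np.mean(nearest), rel=1e-12)

    def test_insufficient_modes_rejected(self):
        h = nma.build_chain_hessian(np.ones(5), nma.chain_springs(5, 1.0, 3.8))
        modes = nma.normal_modes(h)
        D = mode_diffusivity(modes, h)
        with pytest.raises(ValueError, match="internal modes"):
            band_average(D, modes, BandSpec((50.0,), 10))


class TestThermalAverage:
    BAND = BandSpec((50.0, 100.0, 150.0, 200.0, 300.0, 400.0), 10)

    def test_uniform_band_values_pass_through(self):
        v = np.full(6, 3.3)
        out = thermal_average(v, 300.0, self.BAND, scale_with_temperature=False)
        assert out == pytest.approx(3.3)

    def test_classical_amplitude_scaling_is_linear_in_t(self):
        v = np.arange(1.0, 7.0)
        a300 = thermal_average(v, 300.0, self.BAND)
        a340 = thermal_average(v, 340.0, self.BAND)
        assert a340 / a300 == pytest.approx(340.0 / 300.0, rel=1e-12)

    def test_quantum_weights_follow_bose_occupation(self):
        """400 cm^-1 is down-weighted relative to 50 cm^-1 by the occupation
        ratio, evaluated here from the closed form."""
        band = BandSpec((50.0, 400.0), 10)
        lo_only = thermal_average(np.array([1.0, 0.0]), 300.0, band, weighting="quantum")
        hi_only = thermal_average(np.array([0.0, 1.0]), 300.0, band, weighting="quantum")
        x = nma.SECOND_RADIATION_CM_K * np.array([50.0, 400.0]) / 300.0
        n_bose = 1.0 / np.expm1(x)
        assert hi_only / lo_only == pytest.approx(n_bose[1] / n_bose[0], rel=1e-9)


class TestCommunicationMaps:
    def test_symmetry_nonnegativity_completeness(self, homolog_maps):
        for tag in "AB":
            model, modes, D, band, h, cmap = homolog_maps[tag]
            assert np.array_equal(cmap.matrix, cmap.matrix.T)
            assert cmap.matrix.min() >= 0.0
            total = thermal_average(band_average(D, modes, band), 300.0, band)
            assert cmap.total == pytest.approx(total, rel=1e-6)

    def test_decoupled_networks_have_zero_cross_block(self):
        """Two disjoint chains in one structure: no cross-block transport."""
        from vibromap.synthetic import SyntheticSpec, make_structure

        s = make_structure(SyntheticSpec(12, "extended_chain"))
        coords = s.coords.copy()
        coords[6:] += np.array([60.0, 0.0, 0.0])  # separate the halves
        s2 = s.with_coords(coords)
        pairs = [[i, i + 1] for i in range(5)] + [[i, i + 1] for i in range(6, 11)]
        pairs += [[i, i + 2] for i in range(4)] + [[i, i + 2] for i in range(6, 10)]
        springs = nma.Springs(pairs, np.ones(len(pairs)), [
            float(np.linalg.norm(coords[i] - coords[j])) for i, j in pairs
        ])
        h = nma.build_hessian(s2, nma.PotentialModel("pairwise_springs", springs=springs))
        modes = nma.normal_modes(h)
        D = mode_diffusivity(modes, h)
        freqs = modes.frequencies_cm[modes.nonzero]
        band = BandSpec((float(np.median(freqs)),), 8)
        cmap = communication_map(modes, D, s2, band, 300.0, h)
        assert np.abs(cmap.matrix[:6, 6:]).max() == 0.0

    def test_phospho_pair_entry_exceeds_unmodified(self, homolog_maps):
        model_a = homolog_maps["A"][0]
        site, partner = model_a.phospho_site, model_a.phospho_partner
        assert homolog_maps["A"][5].matrix[site, partner] > homolog_maps["B"][5].matrix[site, partner]

    def test_difference_map_algebra(self, homolog_maps):
        model, modes, D, band, h, m300 = homolog_maps["A"]
        m340 = communication_map(modes, D, model.structure, band, 340.0, h)
        self_diff = difference_map(m300, m300)
        assert np.abs(self_diff.matrix).max() == 0.0
        d1 = difference_map(m340, m300)
        d2 = difference_map(m300, m340)
        np.testing.assert_array_equal(d1.matrix, -d2.matrix)
        assert d1.temperature_reference == 300.0
        # classical amplitude scaling: difference = (340/300 - 1) * map300
        np.testing.assert_allclose(
            d1.matrix, (340.0 / 300.0 - 1.0) * m300.matrix, rtol=1e-9, atol=1e-15
        )

    def test_label_mismatch_rejected(self, homolog_maps):
        a = homolog_maps["A"][5]
        smaller = transport.CommunicationMap(
            a.matrix[:4, :4], 300.0, a.band, a.residue_labels[:4]
        )
        with pytest.raises(ValueError):
            difference_map(a, smaller)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.05e7, ColorClass.RED),
            (1.0e7 + 1.0, ColorClass.RED),
            (1.0e7, ColorClass.ORANGE),  # upper bound inclusive
            (9.5e6, ColorClass.ORANGE),
            (9.0e6, ColorClass.ORANGE),  # lower bound inclusive
            (9.0e6 - 1.0, ColorClass.BLUE),
            (8.0e6, ColorClass.BLUE),  # lower bound inclusive
            (5.0e6, ColorClass.BELOW_RANGE),
            (0.0, ColorClass.BELOW_RANGE),
        ],
    )
    def test_printed_color_bands(self, value, expected):
        assert classify_ved(value) is expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            classify_ved(-1.0)

    def test_top_residues_ordering_and_filtering(self):
        labels = [f"GLY A{i+1}" for i in range(5)]
        profile = VEDProfile(np.array([1e6, 1.2e7, 9.5e6, 1.2e7, 8.5e6]), 300.0, labels)
        ranked = top_residues(profile)
        assert [r.ordinal for r in ranked] == [1, 3, 2, 4]  # tie broken by ordinal
        assert ranked[0].color is ColorClass.RED
        assert ranked[2].color is ColorClass.ORANGE

        uniform = VEDProfile(np.full(5, 5e6), 300.0, labels)
        assert top_residues(uniform) == []

    def test_threshold_rescaling_marks_phospho_site(self, homolog_maps):
        model_a, _, _, _, _, cmap = homolog_maps["A"]
        profile = ved_profile(cmap)
        thresholds = ColorThresholds().rescaled_to(profile.values, 90.0)
        ranked = top_residues(profile, thresholds)
        assert ranked, "rescaled thresholds should color the top decile"
        assert all(r.value >= thresholds.blue_min for r in ranked)
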
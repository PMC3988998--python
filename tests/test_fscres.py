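"""FSC, resolution estimation, model maps, filters, phase randomization."""

import numpy as np
import pytest
import pandas as pd

import cryokit as ck
from cryokit.fscres import (bfactor_filter, bfactor_transfer, fsc,
                            model_to_map, phase_randomize_beyond,
                            resolution_at, solvent_correct_reference,
                            solvent_transfer, true_fsc_from_phase_randomized)
from cryokit.volmap import DensityMap, FscCurve, make_shells


def _noise_map(seed, n=32, voxel=2.0):
    rng = np.random.default_rng(seed)
    return DensityMap(rng.standard_normal((n, n, n)), voxel_size=voxel)


class TestFsc:
    def test_self_correlation_is_one(self, phantom):
        curve = fsc(phantom, phantom)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)

    def test_scale_invariance(self, phantom):
        scaled = phantom.copy(data=3.7 * phantom.data)
        curve = fsc(phantom, scaled)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)

    def test_independent_noise_within_null_bound(self):
        """FSC of independent white-noise maps stays within ±3/√n(shell)
        for at least 95% of shells."""
        a, b = _noise_map(1, n=48), _noise_map(2, n=48)
        shells = make_shells(a.shape, a.voxel_size, 24)
        curve = fsc(a, b, shells)
        sel = curve.n_voxels > 0
        bound = 3.0 / np.sqrt(curve.n_voxels[sel])
        frac = np.mean(np.abs(curve.fsc[sel]) <= bound)
        assert frac >= 0.95

    def test_grid_mismatch_rejected(self, phantom):
        other = DensityMap(np.zeros((16, 16, 16)), voxel_size=phantom.voxel_size)
        with pytest.raises(ValueError, match="mismatch"):
            fsc(phantom, other)


class TestResolutionAt:
    def test_interpolated_crossing(self):
        """A curve crossing 0.143 exactly midway between shells at s = 0.05
        and 0.06 crosses at s = 0.055, i.e. 18.2 Å."""
        s = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        f = np.array([0.9, 0.8, 0.7, 0.6, 0.143 + 0.1, 0.143 - 0.1])
        est = resolution_at(FscCurve(s=s, fsc=f, n_voxels=np.ones(6)), 0.143)
        assert est.crossed
        assert est.resolution == pytest.approx(1.0 / 0.055, rel=1e-6)

    def test_never_dropping_curve_flags_nyquist(self):
        s = np.linspace(0.01, 0.25, 10)
        est = resolution_at(FscCurve(s=s, fsc=np.ones(10), n_voxels=np.ones(10)),
                            0.5)
        assert not est.crossed
        assert est.resolution == pytest.approx(1.0 / 0.25)

    def test_step_curve_crosses_at_step(self):
        s = np.array([0.02, 0.04, 0.06, 0.08])
        f = np.array([1.0, 1.0, 0.0, 0.0])
        est = resolution_at(FscCurve(s=s, fsc=f, n_voxels=np.ones(4)), 0.5)
        assert 0.04 < 1.0 / est.resolution < 0.06

    def test_curve_below_threshold_flagged(self):
        s = np.array([0.02, 0.04])
        est = resolution_at(FscCurve(s=s, fsc=np.array([0.1, 0.05]),
                                     n_voxels=np.ones(2)), 0.5)
        assert not est.crossed and est.flag


class TestModelToMap:
    def test_single_carbon_peaks_at_center(self):
        atoms = pd.DataFrame({"element": ["C"], "x": [16.0], "y": [16.0],
                              "z": [16.0]})
        m = model_to_map(atoms, voxel_size=1.0, box=32, per_atom_B=100.0)
        assert np.unravel_index(np.argmax(m.data), m.shape) == (16, 16, 16)

    def test_linearity_in_atoms(self):
        a1 = pd.DataFrame({"element": ["C"], "x": [12.0], "y": [16.0], "z": [16.0]})
        a2 = pd.DataFrame({"element": ["C"], "x": [20.0], "y": [16.0], "z": [16.0]})
        both = pd.concat([a1, a2], ignore_index=True)
        m = model_to_map(both, 1.0, 32)
        m1, m2 = model_to_map(a1, 1.0, 32), model_to_map(a2, 1.0, 32)
        np.testing.assert_allclose(m.data, m1.data + m2.data, atol=1e-12)

    def test_integral_proportional_to_electron_count(self):
        atoms = pd.DataFrame({"element": ["C", "N", "O", "S"],
                              "x": [12.0, 20.0, 16.0, 16.0],
                              "y": [16.0, 16.0, 12.0, 20.0],
                              "z": [16.0, 16.0, 16.0, 16.0]})
        m = model_to_map(atoms, 1.0, 32, per_atom_B=100.0)
        total_e = 6 + 7 + 8 + 16
        assert m.data.sum() * 1.0 ** 3 == pytest.approx(total_e, rel=0.01)

    def test_atom_outside_box_rejected(self):
        atoms = pd.DataFrame({"element": ["C"], "x": [100.0], "y": [0.0],
                              "z": [0.0]})
        with pytest.raises(ValueError, match="outside"):
            model_to_map(atoms, 1.0, 32)


class TestBfactorFilter:
    def test_zero_b_is_identity(self, phantom):
        out = bfactor_filter(phantom, 0.0)
        np.testing.assert_allclose(out.data, phantom.data, atol=1e-10)

    def test_semigroup_property(self, phantom):
        one = bfactor_filter(bfactor_filter(phantom, 300.0), 500.0)
        two = bfactor_filter(phantom, 800.0)
        np.testing.assert_allclose(one.data, two.data, atol=1e-9)

    def test_b2000_attenuation_at_20A(self):
        # exp(-2000/(4*400)) = exp(-1.25): about a third
        assert bfactor_transfer(1.0 / 20.0, 2000.0) == \
            pytest.approx(0.2865, abs=0.0005)


class TestSolventCorrection:
    def test_zero_scale_is_identity(self, phantom):
        out = solvent_correct_reference(phantom, scale=0.0)
        np.testing.assert_allclose(out.data, phantom.data, atol=1e-10)

    def test_low_frequency_limit_scales_by_one_fifth(self):
        assert solvent_transfer(0.0, scale=0.8) == pytest.approx(0.2)

    def test_correction_negligible_by_10A(self):
        # the subtracted term at 10 Å is exp(-2000/400) = exp(-5) of its DC value
        residual = (1.0 - solvent_transfer(1.0 / 10.0)) / 0.8
        assert residual == pytest.approx(np.exp(-5.0), rel=1e-9)
        assert residual < 0.01

    def test_transfer_monotone_increasing_from_02_to_1(self):
        # strictly increasing until the Gaussian underflows to exactly 1
        s = np.linspace(0, 0.2, 100)
        t = solvent_transfer(s)
        assert t[0] == pytest.approx(0.2)
        assert np.all(np.diff(t) > 0)
        assert solvent_transfer(0.5) == pytest.approx(1.0, abs=1e-9)

    def test_dc_amplitude_of_corrected_map(self, phantom):
        out = solvent_correct_reference(phantom, scale=0.8, B=2000.0)
        assert out.data.sum() == pytest.approx(0.2 * phantom.data.sum(), rel=1e-9)


class TestPhaseRandomization:
    def test_cutoff_beyond_nyquist_is_identity(self, phantom):
        out = phase_randomize_beyond(phantom, 2.0 * phantom.voxel_size, seed=0)
        np.testing.assert_array_equal(out.data, phantom.data)

    def test_power_spectrum_preserved(self, phantom):
        out = phase_randomize_beyond(phantom, 20.0, seed=1)
        pa = np.abs(np.fft.fftn(phantom.data))
        pb = np.abs(np.fft.fftn(out.data))
        np.testing.assert_allclose(pb, pa, rtol=1e-8, atol=1e-8)

    def test_fsc_vanishes_beyond_cutoff_only(self, phantom):
        cutoff = 20.0
        out = phase_randomize_beyond(phantom, cutoff, seed=2)
        shells = make_shells(phantom.shape, phantom.voxel_size, 16)
        curve = fsc(phantom, out, shells)
        below = (curve.s < 1.0 / cutoff * 0.9) & (curve.s > 0)
        beyond = curve.s > 1.0 / cutoff * 1.1
        np.testing.assert_allclose(curve.fsc[below], 1.0, atol=1e-6)
        bound = 4.0 / np.sqrt(np.maximum(curve.n_voxels[beyond], 1))
        assert np.all(np.abs(curve.fsc[beyond]) < bound)

    def test_mask_inflated_fsc_is_corrected_downward(self):
        """For half-maps sharing a multiplicative envelope (a mask artifact
        that inflates FSC), the noise-substitution-corrected curve is ≤ the
        raw curve beyond the cutoff."""
        from cryokit.diffmap import sphere_region

        rng = np.random.default_rng(5)
        n, voxel = 48, 2.0
        mask = sphere_region((n, n, n), voxel, (n * voxel / 2,) * 3,
                             6.0).astype(float)  # tight, sharp-edged mask
        sig = ck.make_phantom(4, box=n, voxel_size=voxel).data
        a = DensityMap(sig + 0.3 * rng.standard_normal((n, n, n)), voxel)
        b = DensityMap(sig + 0.3 * rng.standard_normal((n, n, n)), voxel)
        shells = make_shells((n, n, n), voxel, 16)
        cutoff = 12.0
        raw = fsc(a.copy(data=a.data * mask), b.copy(data=b.data * mask), shells)
        ar = phase_randomize_beyond(a, cutoff, 7)
        br = phase_randomize_beyond(b, cutoff, 8)
        rand = fsc(ar.copy(data=ar.data * mask), br.copy(data=br.data * mask),
                   shells)
        corrected = true_fsc_from_phase_randomized(raw, rand, cutoff)
        beyond = raw.s > 1.0 / cutoff
        # the randomized comparison retains only the mask contribution, which
        # is positive here, so the correction can only lower the curve
        assert np.all(rand.fsc[beyond] > 0)
        assert np.all(corrected.fsc[beyond] <= raw.fsc[beyond] + 1e-12)


class TestResolutionMonotonicity:
    def test_added_noise_never_improves_resolution(self, small_phantom):
        """Adding independent noise to one half map cannot sharpen the
        estimated resolution (statistically, over seeds)."""
        rng_pairs = [(101, 201), (102, 202), (103, 203)]
        shells = make_shells(small_phantom.shape, small_phantom.voxel_size, 16)
        worse = 0
        for sa, sb in rng_pairs:
            rng = np.random.default_rng(sa)
            half_a = small_phantom.copy(
                data=small_phantom.data + rng.normal(0, 0.2, small_phantom.shape))
            clean = resolution_at(fsc(half_a, small_phantom, shells), 0.143)
            rng2 = np.random.default_rng(sb)
            half_b = small_phantom.copy(
                data=small_phantom.data + rng2.normal(0, 0.6, small_phantom.shape))
            noisy = resolution_at(fsc(half_a, half_b, shells), 0.143)
            if noisy.resolution >= clean.resolution - 1e-9:
                worse += 1
        assert worse == len(rng_pairs)
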
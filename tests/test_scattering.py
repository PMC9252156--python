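"""Speckle synthesis, q-maps, radial profiles, rings and noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xpcsre as xr
from xpcsre.errors import EmptyRingError, OutOfWindowError, ParameterError


class TestWavelength:
    def test_beamline_energy(self):
        # 8.54 keV photons have a 1.452 A wavelength
        assert xr.energy_to_wavelength(8.54) == pytest.approx(1.452, abs=5e-4)

    def test_defining_constant(self):
        assert xr.energy_to_wavelength(12.398419843) == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(e=st.floats(min_value=0.1, max_value=100))
    def test_halving_energy_doubles_wavelength(self, e):
        assert xr.energy_to_wavelength(e / 2) == pytest.approx(
            2 * xr.energy_to_wavelength(e), rel=1e-12
        )

    def test_non_positive_energy_rejected(self):
        with pytest.raises(ParameterError):
            xr.energy_to_wavelength(0.0)


class TestQMapPhysical:
    geometry = xr.Geometry(
        photon_energy=8.54, detector_distance=21.2, pixel_size=75.0, beam_center=(64.0, 64.0)
    )

    def test_beam_centre_has_zero_q(self):
        q = xr.q_map_physical(self.geometry, (128, 128))
        assert q[64, 64] == 0.0

    def test_small_angle_limit_agreement(self):
        # q ~ 2 pi d px / (lambda L) within 0.01% at USAXS geometry
        q = xr.q_map_physical(self.geometry, (128, 128))
        d = 60.0  # pixels from centre
        approx = (
            2 * np.pi * d * 75e-6 / (self.geometry.wavelength * 1e-10 * 21.2) * 1e-9
        )  # nm^-1
        assert q[64, 64 + 60] == pytest.approx(approx, rel=1e-4)

    def test_q_monotone_in_radius(self):
        q = xr.q_map_physical(self.geometry, (128, 128))
        row = q[64, 64:]
        assert np.all(np.diff(row) > 0)

    def test_usaxs_q_range_reproduced(self):
        # the 21.2 m / 75 um / 8.54 keV geometry reaches ~3.2e-3 nm^-1
        # about 21 pixels from the beam centre
        q = xr.q_map_physical(self.geometry, (128, 128))
        assert q[64, 64 + 21] == pytest.approx(3.2e-3, rel=0.05)


class TestSpeckleSynthesis:
    def test_centre_pixel_zero_after_mean_removal(self):
        rng = np.random.default_rng(0)
        f = xr.ConcentrationField(values=rng.uniform(-1, 1, (64, 64)))
        frame = xr.speckle_from_field(f)
        assert frame.intensity[32, 32] == pytest.approx(0.0, abs=1e-16)

    def test_cosine_gives_two_pixels(self):
        n, k = 64, 5
        xcoord = np.arange(n)
        f = xr.ConcentrationField(values=np.cos(2 * np.pi * k * xcoord[None, :] / n) * np.ones((n, 1)))
        frame = xr.speckle_from_field(f)
        nz = np.argwhere(frame.intensity > 1e-12 * frame.intensity.max())
        assert len(nz) == 2
        assert sorted(c for _, c in nz) == [32 - k, 32 + k]

    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(-1, 1, (48, 48))
        frame = xr.speckle_from_field(xr.ConcentrationField(values=u))
        direct = 48**2 * ((u - u.mean()) ** 2).sum()
        assert frame.intensity.sum() == pytest.approx(direct, rel=1e-8)

    def test_point_symmetry_for_real_fields(self):
        rng = np.random.default_rng(2)
        frame = xr.speckle_from_field(xr.ConcentrationField(values=rng.uniform(-1, 1, (64, 64))))
        i = frame.intensity
        # I(q) = I(-q): flip about the centre (drop the unmatched Nyquist row/col)
        sub = i[1:, 1:]
        assert np.allclose(sub, sub[::-1, ::-1], rtol=1e-8, atol=1e-6 * i.max())


class TestRadialProfile:
    def test_constant_frame_flat_profile(self):
        qmap = xr.q_map_simulation(64)
        prof = xr.radial_profile(np.ones((64, 64)), qmap, n_bins=10)
        filled = prof.counts > 0
        assert np.allclose(prof.intensity[filled], 1.0)

    def test_indicator_ring_lands_in_its_bin(self):
        qmap = xr.q_map_simulation(64)
        target = 1.5
        img = np.where(np.abs(qmap - target) < 0.05, 1.0, 0.0)
        prof = xr.radial_profile(img, qmap, n_bins=16)
        nonzero = np.flatnonzero(np.nan_to_num(prof.intensity) > 0)
        hit = np.argmin(np.abs(prof.q - target))
        assert hit in nonzero

    def test_gaussian_peak_recovered(self):
        qmap = xr.q_map_simulation(128)
        q0, w = 1.0, 0.25
        img = np.exp(-((qmap - q0) ** 2) / w**2)
        prof = xr.radial_profile(img, qmap, n_bins=32)
        q_peak, xi = xr.xi_usaxs(prof)
        assert q_peak == pytest.approx(q0, abs=0.05)
        assert xi == pytest.approx(2 * np.pi / q0, rel=0.05)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            xr.radial_profile(np.ones((32, 32)), xr.q_map_simulation(32), n_bins=2)


class TestXiUsaxs:
    def test_arithmetic(self):
        prof = xr.RadialProfile(
            q=np.array([0.01, 0.0314, 0.05]),
            intensity=np.array([1.0, 5.0, 1.0]),
            counts=np.array([10, 10, 10]),
        )
        q_peak, xi = xr.xi_usaxs(prof, refine=False)
        assert q_peak == pytest.approx(0.0314)
        assert xi == pytest.approx(200.1, abs=0.1)

    def test_flat_profile_raises_out_of_window(self):
        prof = xr.RadialProfile(
            q=np.linspace(0.1, 1, 8), intensity=np.ones(8), counts=np.full(8, 5)
        )
        with pytest.raises(OutOfWindowError):
            xr.xi_usaxs(prof)

    def test_edge_peak_raises(self):
        prof = xr.RadialProfile(
            q=np.linspace(0.1, 1, 8),
            intensity=np.linspace(1, 8, 8),  # maximum on the last bin
            counts=np.full(8, 5),
        )
        with pytest.raises(OutOfWindowError):
            xr.xi_usaxs(prof)


class TestQRing:
    def test_mid_ring_has_enough_pixels(self):
        sp = xr.SpeckleSeries(
            frames=[xr.SpeckleFrame(intensity=np.ones((128, 128)))],
            qmap=xr.q_map_simulation(128),
        )
        qmax = sp.qmap.max()
        ring = xr.make_q_ring(sp, qmax / 2, 2 * np.pi / 128)
        assert ring.size >= 8

    def test_full_cover_is_everything_but_centre(self):
        sp = xr.SpeckleSeries(
            frames=[xr.SpeckleFrame(intensity=np.ones((32, 32)))],
            qmap=xr.q_map_simulation(32),
        )
        ring = xr.make_q_ring(sp, 0.0, 100.0)
        assert ring.size == 32 * 32 - 1

    def test_ring_membership_point_symmetric(self):
        sp = xr.SpeckleSeries(
            frames=[xr.SpeckleFrame(intensity=np.ones((64, 64)))],
            qmap=xr.q_map_simulation(64),
        )
        ring = xr.make_q_ring(sp, 1.0, 0.1)
        mask = np.zeros((64, 64), dtype=bool)
        mask.ravel()[ring.pixel_indices] = True
        sub = mask[1:, 1:]
        assert np.array_equal(sub, sub[::-1, ::-1])

    def test_empty_ring_raises(self):
        sp = xr.SpeckleSeries(
            frames=[xr.SpeckleFrame(intensity=np.ones((32, 32)))],
            qmap=xr.q_map_simulation(32),
        )
        with pytest.raises(EmptyRingError, match="q_halfwidth"):
            xr.make_q_ring(sp, 100.0, 0.01)


class TestSelectAnalysisQ:
    @staticmethod
    def _peaked_series(q0: float, n_frames: int = 4) -> xr.SpeckleSeries:
        qmap = xr.q_map_simulation(64)
        img = np.exp(-((qmap - q0) ** 2) / 0.1**2)
        frames = [xr.SpeckleFrame(intensity=img.copy(), time=float(k)) for k in range(n_frames)]
        return xr.SpeckleSeries(frames=frames, qmap=qmap)

    def test_constructed_peak_recovered(self):
        sp = self._peaked_series(1.2)
        assert xr.select_analysis_q(sp, 3) == pytest.approx(1.2, abs=0.06)

    def test_average_of_two_shifted_peaks(self):
        a = self._peaked_series(0.9, 1)
        b = self._peaked_series(1.1, 1)
        sp = xr.SpeckleSeries(
            frames=[a.frames[0], xr.SpeckleFrame(intensity=b.frames[0].intensity, time=1.0)],
            qmap=a.qmap,
        )
        assert xr.select_analysis_q(sp, 2) == pytest.approx(1.0, abs=0.06)

    def test_excess_early_frames_clipped_with_warning(self):
        sp = self._peaked_series(1.2, 2)
        with pytest.warns(UserWarning, match="clip"):
            q = xr.select_analysis_q(sp, 50)
        assert q == pytest.approx(1.2, abs=0.06)


class TestAddNoise:
    def test_zero_fraction_identity(self, frozen_speckle):
        out = xr.add_noise(frozen_speckle, 0.0, seed=1)
        assert np.array_equal(out.stack(), frozen_speckle.stack())

    def test_mean_increase_is_half_amplitude(self, frozen_speckle):
        frac = 0.1
        out = xr.add_noise(frozen_speckle, frac, seed=2)
        i_max = frozen_speckle.stack().max()
        delta = out.stack().mean() - frozen_speckle.stack().mean()
        assert delta == pytest.approx(frac * i_max / 2, rel=0.01)

    def test_seeded_determinism_and_nonnegativity(self, frozen_speckle):
        a = xr.add_noise(frozen_speckle, 0.04, seed=5)
        b = xr.add_noise(frozen_speckle, 0.04, seed=5)
        assert np.array_equal(a.stack(), b.stack())
        assert np.all(a.stack() >= 0)
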
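"""VACF, DOS, projections, decay subtraction, peaks, maps, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersmd.md import Trajectory
from sersmd.spectra import (Mode, SpectralMap, Spectrum, average_spectra,
                            classify_modes, compare_conditions, detect_peaks,
                            dos, fit_exp_decay, project_angle_velocity,
                            project_bond_velocity, read_spectrum_csv,
                            spectrum_of_series, subtract_decay,
                            subtract_decay_twopass, vacf, write_spectrum_csv)
from sersmd.units import cm1_to_thz, thz_to_cm1


def make_traj(positions, velocities, dt=0.05, atoms=None):
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    n_atoms = positions.shape[1]
    return Trajectory(dt=dt,
                      atom_indices=np.asarray(atoms if atoms is not None
                                              else range(n_atoms)),
                      velocities=velocities, positions=positions,
                      elements=["C"] * n_atoms)


def synthetic_spectrum(n=32768, dt=0.05, a=2.0, b=-0.001, peaks=()):
    freq = np.fft.rfftfreq(n, d=dt) * 1e3
    amp = a * np.exp(b * freq)
    for center, width, height in peaks:
        amp = amp + height / (1 + ((freq - center) / width) ** 2)
    return Spectrum(freq_thz=freq, amplitude=amp, dt_fs=dt, n_samples=n)


class TestBondProjection:
    def test_axial_vibration_fully_projected(self):
        n = 64
        pos = np.tile([[0, 0, 0], [0, 0, 1.5]], (n, 1, 1))
        vel = np.zeros((n, 2, 3))
        vel[:, 1, 2] = np.sin(np.linspace(0, 6, n))
        si, sj = project_bond_velocity(make_traj(pos, vel), (0, 1))
        np.testing.assert_allclose(sj, vel[:, 1, 2], atol=1e-12)
        np.testing.assert_allclose(si, 0.0, atol=1e-12)

    def test_rigid_rotation_projects_to_zero(self):
        n, r, omega = 256, 1.2, 0.01
        t = np.arange(n) * 0.05
        pos = np.zeros((n, 2, 3))
        pos[:, 1, 0] = r * np.cos(omega * t)
        pos[:, 1, 1] = r * np.sin(omega * t)
        vel = np.zeros((n, 2, 3))
        vel[:, 1, 0] = -r * omega * np.sin(omega * t)
        vel[:, 1, 1] = r * omega * np.cos(omega * t)
        _, sj = project_bond_velocity(make_traj(pos, vel), (0, 1))
        np.testing.assert_allclose(sj, 0.0, atol=1e-12)

    def test_constant_velocity_along_static_bond(self):
        n = 32
        pos = np.tile([[0, 0, 0], [0, 0, 2.0]], (n, 1, 1))
        vel = np.zeros((n, 2, 3))
        vel[:, 0, 2] = 0.37
        si, _ = project_bond_velocity(make_traj(pos, vel), (0, 1))
        np.testing.assert_allclose(si, 0.37)

    def test_coincident_atoms_rejected(self):
        pos = np.zeros((4, 2, 3))
        with pytest.raises(ValueError, match="coincident"):
            project_bond_velocity(make_traj(pos, np.zeros((4, 2, 3))), (0, 1))


class TestAngleProjection:
    def bent_triatomic(self, n=64):
        pos = np.tile([[1.5, 0, 0], [0, 0, 0], [-1.0, 1.1, 0]], (n, 1, 1))
        return pos

    def test_scissor_motion_is_bending(self):
        n = 64
        pos = self.bent_triatomic(n)
        vel = np.zeros((n, 3, 3))
        vel[:, 0, 1] = 0.02      # end atom moving perpendicular to its bond
        s = project_angle_velocity(make_traj(pos, vel), (0, 1, 2))
        assert np.abs(s).min() > 0.01
        si, _ = project_bond_velocity(make_traj(pos, vel), (0, 1))
        np.testing.assert_allclose(si, 0.0, atol=1e-12)

    def test_bond_axis_motion_is_not_bending(self):
        n = 16
        pos = self.bent_triatomic(n)
        vel = np.zeros((n, 3, 3))
        vel[:, 0, 0] = 0.05      # along the 0-1 bond (x axis)
        s = project_angle_velocity(make_traj(pos, vel), (0, 1, 2))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_out_of_plane_motion_excluded(self):
        n = 16
        pos = self.bent_triatomic(n)
        vel = np.zeros((n, 3, 3))
        vel[:, 0, 2] = 0.05      # molecule is planar in z=0
        s = project_angle_velocity(make_traj(pos, vel), (0, 1, 2))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_collinear_triple_rejected(self):
        n = 8
        pos = np.tile([[1.0, 0, 0], [0, 0, 0], [-2.0, 0, 0]], (n, 1, 1))
        with pytest.raises(ValueError, match="collinear"):
            project_angle_velocity(make_traj(pos, np.zeros((n, 3, 3))), (0, 1, 2))


class TestVacf:
    def test_cosine_closed_form(self):
        n, dt, f0 = 32768, 0.05, 30.0
        t = np.arange(n) * dt
        v = np.cos(2 * np.pi * f0 * 1e-3 * t)
        g = vacf(v, dt)
        lags = np.arange(512)
        expected = np.cos(2 * np.pi * f0 * 1e-3 * g.lag_fs[lags])
        # the all-origins (1/N) estimator carries a (1 - tau/N) envelope and
        # an O(1/(N sin(omega dt))) double-frequency cross term
        phase = 2 * np.pi * f0 * 1e-3 * dt
        bound = 1.5 / (n * np.sin(phase))
        assert np.abs(g.g[lags] - expected * (1 - lags / n)).max() < bound

    def test_normalized_and_bounded(self):
        rng = np.random.default_rng(0)
        g = vacf(rng.standard_normal(4096), 0.05)
        assert g.g[0] == pytest.approx(1.0)
        assert np.abs(g.g).max() <= 1.0 + 1e-9

    def test_constant_series(self):
        g = vacf(np.full(1024, 3.3), 0.05, max_lag=100)
        np.testing.assert_allclose(g.g, 1.0 - np.arange(101) / 1024, rtol=1e-9)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        n = 65536
        g = vacf(rng.standard_normal(n), 0.05, max_lag=100)
        assert np.abs(g.g[1:]).max() < 3.0 / np.sqrt(n) * 3

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(2048)
        g_fwd = vacf(v, 0.05)
        g_rev = vacf(v[::-1].copy(), 0.05)
        np.testing.assert_allclose(g_fwd.g, g_rev.g, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            vacf(np.zeros(128), 0.05)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_bounded_for_any_series(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(512) * rng.uniform(0.1, 10)
        g = vacf(v, 0.05)
        assert np.abs(g.g).max() <= 1.0 + 1e-9


class TestDos:
    def test_grid_spacing_and_length(self):
        n, dt = 32768, 0.05
        g = vacf(np.cos(np.arange(n) * 0.01) + 0.001 * np.arange(n) % 7, dt)
        spec = dos(g, dt)
        assert len(spec.freq_thz) == n // 2 + 1
        assert spec.bin_thz == pytest.approx(1e3 / (n * dt))
        assert spec.bin_cm1 == pytest.approx(20.359, abs=1e-3)

    def test_on_grid_cosine_gives_single_dominant_bin(self):
        n, dt = 8192, 0.05
        k = 250                                # on-grid bin index
        f0 = k / (n * dt)                      # 1/fs
        v = np.cos(2 * np.pi * f0 * np.arange(n) * dt)
        spec = dos(vacf(v, dt), dt)
        assert spec.amplitude[1:].argmax() + 1 == k

    def test_delta_vacf_flat_spectrum(self):
        g = vacf(np.r_[1.0, np.zeros(511)], 0.05, max_lag=511)
        # G is a Kronecker delta; its Fourier magnitude is exactly flat
        spec = dos(g, 0.05)
        np.testing.assert_allclose(spec.amplitude, spec.amplitude[0], rtol=1e-9)

    def test_doubling_window_halves_bin_spacing(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(32768)
        s1 = dos(vacf(v[:16384], 0.05), 0.05)
        s2 = dos(vacf(v, 0.05), 0.05)
        assert s1.bin_thz == pytest.approx(2 * s2.bin_thz)
        assert s1.bin_cm1 == pytest.approx(40.718, abs=1e-3)

    def test_nonnegative_amplitude(self):
        rng = np.random.default_rng(4)
        spec = spectrum_of_series(rng.standard_normal(2048), 0.05)
        assert spec.amplitude.min() >= 0.0


class TestExpDecay:
    def test_exact_recovery(self):
        spec = synthetic_spectrum()
        fit = fit_exp_decay(spec, "head")
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(-0.001, abs=1e-6)

    def test_flat_spectrum_degenerate_fit(self):
        spec = synthetic_spectrum(a=1.7, b=0.0)
        fit = fit_exp_decay(spec, "head")
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.a == pytest.approx(1.7, rel=1e-9)

    def test_head_fit_with_peaks_within_5_percent(self):
        spec = synthetic_spectrum(peaks=[(20.0, 0.3, 1.0), (45.0, 0.3, 0.7),
                                         (70.0, 0.3, 0.5)])
        fit = fit_exp_decay(spec, "head")
        assert abs(fit.a - 2.0) / 2.0 < 0.05
        assert abs(fit.b + 0.001) / 0.001 < 0.05

    def test_tail_region_fit(self):
        spec = synthetic_spectrum()
        fit = fit_exp_decay(spec, "tail")
        assert fit.region == "tail"
        assert fit.b < 0

    def test_zeroed_bin_does_not_break_fit(self):
        # a zero amplitude inside the head region must not break the fit
        # (peak masking or the nonlinear fallback absorbs it)
        spec = synthetic_spectrum()
        spec.amplitude[2] = 0.0
        fit = fit_exp_decay(spec, "head")
        assert abs(fit.b + 0.001) / 0.001 < 0.2

    def test_subtraction_of_pure_exponential_leaves_nothing(self):
        spec = synthetic_spectrum()
        out = subtract_decay(spec)
        assert out.amplitude.max() < 1e-6 * spec.amplitude.max()
        assert out.decay_subtracted

    def test_zero_amplitude_fit_is_identity(self):
        spec = synthetic_spectrum(peaks=[(30.0, 0.8, 1.0)])
        from sersmd.spectra import ExpDecayFit
        fit = ExpDecayFit(a=0.0, b=-0.1, region="head",
                          indices=np.arange(2), residual=0.0)
        out = subtract_decay(spec, fit)
        np.testing.assert_allclose(out.amplitude, spec.amplitude)

    def test_double_subtraction_rejected(self):
        spec = synthetic_spectrum()
        once = subtract_decay(spec)
        with pytest.raises(ValueError, match="already"):
            subtract_decay(once)

    @pytest.mark.parametrize("subtract",
                             [subtract_decay, subtract_decay_twopass])
    def test_peak_bins_unmoved_by_subtraction(self, subtract):
        centers = [20.0, 45.0, 70.0]
        spec = synthetic_spectrum(peaks=[(c, 0.8, 1.0) for c in centers])
        before = [m.freq_cm1 for m in detect_peaks(spec, 0.05)]
        out = subtract(spec)
        after = [m.freq_cm1 for m in detect_peaks(out, 0.05)]
        for c in centers:
            c_cm1 = thz_to_cm1(c)
            b = min(before, key=lambda f: abs(f - c_cm1))
            a = min(after, key=lambda f: abs(f - c_cm1))
            assert a == b


class TestPeaks:
    def test_single_cosine_single_mode(self):
        n, dt = 8192, 0.05
        f0 = 250 / (n * dt)
        v = np.cos(2 * np.pi * f0 * np.arange(n) * dt)
        spec = dos(vacf(v, dt), dt)
        modes = detect_peaks(spec, 0.5)
        assert len(modes) == 1
        assert abs(modes[0].freq_cm1 - thz_to_cm1(f0 * 1e3)) <= spec.bin_cm1

    def test_flat_spectrum_no_modes(self):
        spec = Spectrum(freq_thz=np.linspace(0, 10, 101),
                        amplitude=np.ones(101), dt_fs=0.05, n_samples=100)
        assert detect_peaks(spec, 0.1) == []

    def test_equal_peaks_frequency_ascending_tie_order(self):
        amp = np.zeros(101)
        amp[[30, 60]] = 5.0
        spec = Spectrum(freq_thz=np.linspace(0, 10, 101), amplitude=amp,
                        dt_fs=0.05, n_samples=100)
        modes = detect_peaks(spec, 0.1)
        assert len(modes) == 2
        assert modes[0].freq_cm1 < modes[1].freq_cm1

    def test_threshold_validated(self):
        spec = synthetic_spectrum()
        with pytest.raises(ValueError):
            detect_peaks(spec, 0.0)


class TestClassify:
    def _map(self, bond_modes, bin_cm1=20.0):
        return SpectralMap(condition={}, bin_cm1=bin_cm1,
                           bonds={k: [Mode(f, i) for f, i in v]
                                  for k, v in bond_modes.items()})

    def test_frequency_in_all_ring_bonds_is_breathing(self):
        ring = [f"b{i}" for i in range(6)]
        smap = self._map({b: [(1550.0, 1.0), (800.0 + 30 * i, 0.5)]
                          for i, b in enumerate(ring)})
        out = classify_modes(smap, ring)
        for b in ring:
            labels = {m.assignment for m in out.bonds[b] if m.freq_cm1 == 1550.0}
            assert labels == {"breathing"}

    def test_five_of_six_stays_stretch(self):
        ring = [f"b{i}" for i in range(6)]
        modes = {b: [(1550.0, 1.0)] for b in ring[:5]}
        modes[ring[5]] = [(900.0, 1.0)]
        out = classify_modes(self._map(modes), ring)
        assert all(m.assignment == "stretch" for m in out.bonds["b0"])

    def test_empty_ring_no_relabel(self):
        smap = self._map({"b0": [(1550.0, 1.0)]})
        out = classify_modes(smap, [])
        assert out.bonds["b0"][0].assignment == "stretch"

    def test_within_one_bin_counts_as_shared(self):
        ring = ["b0", "b1"]
        smap = self._map({"b0": [(1550.0, 1.0)], "b1": [(1565.0, 1.0)]},
                         bin_cm1=20.0)
        out = classify_modes(smap, ring)
        assert out.bonds["b0"][0].assignment == "breathing"


class TestCompare:
    def _map(self, bond_modes, bin_cm1=20.0):
        return SpectralMap(condition={}, bin_cm1=bin_cm1,
                           bonds={k: [Mode(f, i) for f, i in v]
                                  for k, v in bond_modes.items()})

    def test_identical_maps_zero_shifts_unit_ratios(self):
        m = self._map({"a": [(1550.0, 1.0), (900.0, 0.4)]})
        table = compare_conditions(m, m)
        matched = table[table.status == "matched"]
        assert len(matched) == 2
        assert (matched.shift_cm1 == 0).all()
        assert (matched.amplitude_ratio == 1.0).all()

    def test_uniform_amplitude_scaling(self):
        ref = self._map({"a": [(1550.0, 1.0)], "b": [(700.0, 0.5)]})
        double = self._map({"a": [(1550.0, 2.0)], "b": [(700.0, 1.0)]})
        table = compare_conditions(ref, double)
        matched = table[table.status == "matched"]
        assert (matched.amplitude_ratio == 2.0).all()
        assert (matched.shift_cm1 == 0).all()

    def test_known_shift_reported_exactly(self):
        ref = self._map({"a": [(1550.0, 1.0)], "b": [(700.0, 1.0)]})
        shifted = self._map({"a": [(1590.0, 1.0)], "b": [(700.0, 1.0)]})
        table = compare_conditions(ref, shifted)
        row = table[(table.bond == "a") & (table.status == "matched")].iloc[0]
        assert row.shift_cm1 == pytest.approx(40.0)

    def test_far_modes_appear_and_vanish(self):
        ref = self._map({"a": [(1550.0, 1.0)]})
        other = self._map({"a": [(900.0, 1.0)]})
        table = compare_conditions(ref, other)
        assert set(table.status) == {"appeared", "vanished"}

    def test_bond_in_one_map_only_reported(self):
        ref = self._map({"a": [(1550.0, 1.0)], "only_ref": [(500.0, 1.0)]})
        other = self._map({"a": [(1550.0, 1.0)]})
        table = compare_conditions(ref, other)
        assert (table.status == "bond_only_in_reference").sum() == 1


class TestUnits:
    def test_thz_to_cm1_constant(self):
        assert thz_to_cm1(0.61035) == pytest.approx(20.36, abs=0.01)

    def test_zero_maps_to_zero(self):
        assert thz_to_cm1(0.0) == 0.0

    def test_round_trip_identity(self):
        f = 123.456
        assert cm1_to_thz(thz_to_cm1(f)) == pytest.approx(f, rel=1e-12)


class TestSpectrumIO:
    def test_csv_round_trip(self, tmp_path):
        spec = synthetic_spectrum(n=2048, peaks=[(30.0, 0.8, 1.0)])
        spec.source = "bond C(2)-C(3) end C(2)"
        out = subtract_decay(spec)
        p = tmp_path / "s.csv"
        write_spectrum_csv(p, out)
        back = read_spectrum_csv(p)
        assert back.source == out.source
        assert back.decay_subtracted
        np.testing.assert_allclose(back.amplitude, out.amplitude, atol=1e-7)
        np.testing.assert_allclose(back.freq_thz, out.freq_thz, rtol=1e-6)

    def test_map_json_round_trip(self, tmp_path):
        smap = SpectralMap(condition={"vz": 25.0}, bin_cm1=20.36,
                           bonds={"C(2)-C(3)": [Mode(1550.0, 1.0, "breathing")]})
        p = tmp_path / "m.json"
        smap.to_json(p)
        back = SpectralMap.from_json(p)
        assert back.condition == {"vz": 25.0}
        assert back.bonds["C(2)-C(3)"][0].assignment == "breathing"


def test_average_spectra_requires_same_grid():
    a = synthetic_spectrum(n=1024)
    b = synthetic_spectrum(n=2048)
    with pytest.raises(ValueError, match="grids"):
        average_spectra([a, b])
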
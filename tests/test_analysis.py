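import types

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionslab.analysis import (
    bragg_curve,
    compare_phantoms,
    lateral_rms,
    lateral_straggle,
    lateral_straggle_ci,
    longitudinal_straggle,
    straggle_stats,
)
from ionslab.transport import DepthDoseRecord, TrackEnsemble


def make_ensemble(x, y=None, z=None, stopped=None):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    stopped = (np.ones_like(x, dtype=bool) if stopped is None
               else np.asarray(stopped, dtype=bool))
    return TrackEnsemble(x, y, z, stopped, np.zeros_like(x))


class TestStraggleEstimators:
    def test_no_spread(self):
        assert longitudinal_straggle(make_ensemble([2.0, 2.0, 2.0])) == 0.0

    def test_hand_arithmetic(self):
        ens = make_ensemble([1.0, 3.0])
        st_ = straggle_stats(ens)
        assert st_.R_p_mm == pytest.approx(2.0)
        assert st_.sigma_longitudinal_mm == pytest.approx(1.0)

    def test_single_ion_lateral(self):
        ens = make_ensemble([5.0], y=[3.0], z=[1.0])
        assert lateral_straggle(ens) == pytest.approx(2.0)

    def test_on_axis_beam_zero(self):
        assert lateral_straggle(make_ensemble([1.0, 2.0])) == 0.0

    @given(st.integers(2, 60), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_summation(self, n, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        x = rng.normal(50.0, 2.0, n)
        y = rng.normal(0.0, 1.0, n)
        z = rng.normal(0.0, 1.0, n)
        ens = make_ensemble(x, y, z)
        # direct elementwise evaluation of the printed formulas
        sig_long = (sum(v * v for v in x) / n - (sum(x) / n) ** 2) ** 0.5
        sig_lat = (sum(((abs(a) + abs(b)) / 2) ** 2
                       for a, b in zip(y, z)) / n) ** 0.5
        assert longitudinal_straggle(ens) == pytest.approx(sig_long, rel=1e-12)
        assert lateral_straggle(ens) == pytest.approx(sig_lat, rel=1e-12)

    def test_gaussian_sampling_recovers_sigma(self):
        rng = np.random.Generator(np.random.PCG64(0))
        x = rng.normal(60.0, 0.5, 100_000)
        assert longitudinal_straggle(make_ensemble(x)) == pytest.approx(
            0.5, rel=0.01)

    def test_lateral_estimator_expectation_constant(self):
        """For iid Gaussian y,z of width s the printed lateral estimator
        converges to s*sqrt((1+2/pi)/2), not s; checked by brute force."""
        s = 0.7
        rng = np.random.Generator(np.random.PCG64(1))
        y = rng.normal(0.0, s, 1_000_000)
        z = rng.normal(0.0, s, 1_000_000)
        ens = make_ensemble(np.zeros_like(y), y, z)
        expected = s * np.sqrt((1.0 + 2.0 / np.pi) / 2.0)
        assert lateral_straggle(ens) == pytest.approx(expected, rel=0.01)
        assert lateral_rms(ens) == pytest.approx(s, rel=0.01)

    def test_transmitted_ions_excluded(self):
        ens = make_ensemble([1.0, 3.0, 99.0], stopped=[True, True, False])
        assert straggle_stats(ens).R_p_mm == pytest.approx(2.0)
        assert straggle_stats(ens).n_excluded == 1

    def test_too_few_ions_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_straggle(make_ensemble([1.0]))
        with pytest.raises(ValueError):
            lateral_straggle(make_ensemble([1.0], stopped=[False]))

    def test_bootstrap_ci_shrinks_with_ions(self):
        rng = np.random.Generator(np.random.PCG64(2))
        wide, narrow = [], []
        for n in (1000, 10_000):
            y = rng.normal(0.0, 0.5, n)
            z = rng.normal(0.0, 0.5, n)
            lo, hi = lateral_straggle_ci(
                make_ensemble(np.zeros_like(y), y, z), seed=3)
            (wide if n == 1000 else narrow).append(hi - lo)
        assert narrow[0] < wide[0]


def triangular_record(centers, peak_index):
    n = centers.size
    profile = np.maximum(
        0.1, 1.0 - np.abs(np.arange(n) - peak_index) / (0.6 * n))
    return DepthDoseRecord(centers, profile, {})


class TestBraggCurve:
    def test_peak_at_bin_center_is_fixed_point(self):
        centers = np.linspace(0.05, 9.95, 100)
        rec = triangular_record(centers, 60)
        curve = bragg_curve(rec)
        assert curve.peak_position_mm == pytest.approx(centers[60], abs=1e-12)

    def test_parabola_vertex_between_bins(self):
        centers = np.linspace(0.05, 9.95, 100)
        x0 = centers[70] + 0.4 * (centers[1] - centers[0])
        profile = 5.0 - (centers - x0) ** 2
        curve = bragg_curve(DepthDoseRecord(centers, profile, {}))
        assert abs(curve.peak_position_mm - x0) < 0.1 * (centers[1] - centers[0])

    def test_entrance_window_mean(self):
        centers = np.linspace(0.05, 9.95, 100)
        rec = triangular_record(centers, 90)
        curve = bragg_curve(rec, entrance_fraction=0.05)
        assert curve.entrance_LET_eV_per_A == pytest.approx(
            rec.ionization[:5].mean())

    def test_all_zero_rejected(self):
        centers = np.linspace(0.05, 9.95, 100)
        with pytest.raises(ValueError, match="zero"):
            bragg_curve(DepthDoseRecord(centers, np.zeros(100), {}))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="10"):
            bragg_curve(DepthDoseRecord(np.arange(5.0), np.ones(5), {}))


def fake_result(energy, peak_mm, sigma=0.5, name="A", recoil=1.0,
                n_ions=64, seed=0):
    """Stub with just the attributes the scan summary consumes."""
    h = 0.2
    # uniform grid with a bin center exactly on the requested peak
    centers = peak_mm + (np.arange(200.0) - 150.0) * h
    profile = np.maximum(0.05, 1.0 - np.abs(np.arange(200) - 150) / 120.0)
    rng = np.random.Generator(np.random.PCG64(seed))
    y = rng.normal(0.0, sigma, n_ions)
    z = rng.normal(0.0, sigma, n_ions)
    ens = TrackEnsemble(np.full(n_ions, peak_mm), y, z,
                        np.ones(n_ions, dtype=bool), np.zeros(n_ions))
    return types.SimpleNamespace(
        depth_dose=DepthDoseRecord(centers, profile, {}),
        ensemble=ens,
        phantom=types.SimpleNamespace(name=name),
        energy_MeV=energy,
        total_recoil_eV_per_A_ion=recoil,
    )


class TestComparePhantoms:
    def test_self_comparison_is_zero(self):
        scan = [fake_result(354.0, 60.0), fake_result(356.0, 61.0)]
        cmp = compare_phantoms(scan, scan)
        assert cmp.mean_abs_peak_diff_pct == 0.0
        assert cmp.mean_straggle_diff_mm == 0.0
        assert cmp.mean_recoil_diff_pct == 0.0

    def test_two_energy_hand_arithmetic(self):
        scan_a = [fake_result(354.0, 60.0), fake_result(356.0, 62.0)]
        scan_b = [fake_result(354.0, 61.2, name="B"),
                  fake_result(356.0, 62.62, name="B")]
        cmp = compare_phantoms(scan_a, scan_b)
        assert cmp.mean_abs_peak_diff_pct == pytest.approx(1.5, abs=1e-6)

    def test_grid_mismatch_lists_energies(self):
        scan_a = [fake_result(354.0, 60.0)]
        scan_b = [fake_result(358.0, 60.0)]
        with pytest.raises(ValueError, match="358"):
            compare_phantoms(scan_a, scan_b)

    def test_absolute_difference_symmetric(self):
        scan_a = [fake_result(354.0, 60.0, sigma=0.4, seed=1)]
        scan_b = [fake_result(354.0, 63.0, sigma=0.6, name="B", seed=2)]
        ab = compare_phantoms(scan_a, scan_b)
        ba = compare_phantoms(scan_b, scan_a)
        assert ab.mean_straggle_diff_mm == pytest.approx(
            ba.mean_straggle_diff_mm, rel=1e-12)
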
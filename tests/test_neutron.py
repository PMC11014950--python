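"""Virtual neutron observables: ISF, resolution windows, Debye–Waller fits."""

import numpy as np
import pytest

from hydradyn.core import Trajectory
from hydradyn.neutron import (
    INSTRUMENTS,
    ElasticScan,
    ISF,
    ResolutionSpec,
    default_q_grid,
    dw_fit,
    elastic_intensity,
    intermediate_scattering,
    load_elastic_scan,
    neutron_weights,
    resolution_window,
    scan_pipeline,
    write_elastic_scan,
)
from hydradyn.synthetic import HarmonicSpec, gen_harmonic
from hydradyn.units import HBAR_UEV_PS


def _traj(pos, dt=1.0):
    return Trajectory(np.asarray(pos, dtype=float), dt, 300.0)


class TestISF:
    def test_static_system_unity(self):
        pos = np.tile(np.random.default_rng(0).normal(size=(1, 5, 3)), (40, 1, 1))
        isf = intermediate_scattering(_traj(pos), np.ones(5, bool), default_q_grid())
        assert np.allclose(isf.values, 1.0)

    def test_t0_exactly_one_and_bounded(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(size=(60, 4, 3)), axis=0)
        isf = intermediate_scattering(_traj(pos), np.ones(4, bool), default_q_grid())
        assert np.all(isf.values[:, 0] == 1.0)
        assert np.all(isf.values <= 1.0) and np.all(isf.values >= -1.0)

    def test_two_site_jump_long_time_limit(self):
        """Single atom hopping between two sites d apart, equal occupancy.

        Averaging the four origin/end site combinations gives
        I(Q,∞) = 1 − (1 − sinc(Qd))/2.
        """
        d = 2.0
        rng = np.random.default_rng(2)
        sites = rng.integers(0, 2, 4000)  # fast exchange, equal occupancy
        pos = np.zeros((4000, 1, 3))
        pos[:, 0, 0] = sites * d
        q = np.array([0.5, 1.0, 1.5])
        isf = intermediate_scattering(_traj(pos), np.ones(1, bool), q, origin_stride=1)
        expected = 1.0 - 0.5 * (1.0 - np.sinc(q * d / np.pi))
        assert np.allclose(isf.values[:, -50:].mean(axis=1), expected, atol=0.02)

    def test_empty_selection(self):
        with pytest.raises(ValueError, match="empty"):
            intermediate_scattering(
                _traj(np.zeros((10, 3, 3))), np.zeros(3, bool), default_q_grid()
            )


class TestResolutionWindow:
    @pytest.mark.parametrize("shape", ["gaussian", "lorentzian", "pseudo_voigt"])
    def test_r0_is_one(self, shape):
        res = ResolutionSpec(shape, 24.5)
        r = resolution_window(res, np.arange(0.0, 100.0, 5.0))
        assert r[0] == 1.0
        assert np.all(np.diff(r) <= 0)

    def test_lorentzian_einv_time(self):
        g = 24.5
        res = ResolutionSpec("lorentzian", g)
        t_e = 2 * HBAR_UEV_PS / g
        r = resolution_window(res, np.array([0.0, t_e]))
        assert r[1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("shape,fwhm", [("gaussian", 24.5), ("lorentzian", 17.5)])
    def test_forward_transform_recovers_fwhm(self, shape, fwhm):
        """Numeric FT of R(t) reproduces the stated energy FWHM within 1%."""
        res = ResolutionSpec(shape, fwhm)
        t = np.arange(0.0, 4000.0, 0.5)
        r = resolution_window(res, t)
        omega = np.linspace(0.0, 4 * fwhm, 4000) / HBAR_UEV_PS
        spec = np.array([np.trapezoid(r * np.cos(w * t), t) for w in omega])
        spec /= spec[0]
        half = omega[np.argmin(np.abs(spec - 0.5))] * HBAR_UEV_PS
        assert 2 * half == pytest.approx(fwhm, rel=0.01)


class TestElasticIntensity:
    def test_static_system_q_independent(self):
        pos = np.tile(np.random.default_rng(3).normal(size=(1, 5, 3)), (200, 1, 1))
        isf = intermediate_scattering(_traj(pos, dt=5.0), np.ones(5, bool), default_q_grid())
        res = ResolutionSpec("gaussian", 24.5)
        intens = elastic_intensity(isf, res)
        assert np.allclose(intens, intens[0], rtol=1e-12)

    def test_mode_consistency_gaussian_system(self):
        """Peak-height and windowed-integration modes agree within 2 %."""
        traj, _, _ = gen_harmonic(
            HarmonicSpec(40, 0.05, relaxation_time=2.0), 290, 1200, 5.0, 4
        )
        isf = intermediate_scattering(
            traj, np.ones(traj.n_atoms, bool), default_q_grid(), max_lag=1500.0,
            origin_stride=10,
        )
        res = ResolutionSpec("gaussian", 5.0, integration_half_width=2.5)
        peak = elastic_intensity(isf, res, "peak_height")
        integ = elastic_intensity(isf, res, "integrated")
        ratio = (peak / peak[0]) / (integ / integ[0])
        assert np.allclose(ratio, 1.0, atol=0.02)

    def test_monotone_in_sigma2(self):
        res = ResolutionSpec("gaussian", 5.0)
        out = []
        for s2 in (0.15, 0.10, 0.05, 0.02):
            traj, _, _ = gen_harmonic(
                HarmonicSpec(30, s2, relaxation_time=2.0), 290, 800, 5.0, 5
            )
            isf = intermediate_scattering(
                traj, np.ones(traj.n_atoms, bool), np.array([1.0]), max_lag=1500.0
            )
            out.append(float(elastic_intensity(isf, res)[0]))
        assert out == sorted(out)  # smaller σ² → brighter elastic line

    def test_short_grid_warns(self):
        isf = ISF(np.array([1.0]), np.arange(0.0, 10.0), np.ones((1, 10)))
        with pytest.warns(UserWarning, match="t-grid"):
            elastic_intensity(isf, ResolutionSpec("gaussian", 5.0))


class TestDWFit:
    def test_exact_recovery_from_dw_form(self):
        q = default_q_grid()
        u2 = 0.45
        scan = ElasticScan(
            q, np.array([10.0, 290.0]),
            np.column_stack([0.9 * np.ones_like(q), 0.9 * np.exp(-q**2 * u2 / 3)]),
            t_base=10.0,
        )
        fit = dw_fit(scan)
        assert fit.u2[1] == pytest.approx(u2, abs=1e-12)
        assert fit.u2[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept[1] == pytest.approx(1.0, rel=1e-12)
        assert fit.residual_rms[1] < 1e-12

    def test_ga_flag_on_large_displacement(self):
        q = default_q_grid()
        u2 = 2.0  # max Q²u²/3 = 1.8²·2/3 > 1
        scan = ElasticScan(
            q, np.array([10.0, 290.0]),
            np.column_stack([np.ones_like(q), np.exp(-q**2 * u2 / 3)]),
            t_base=10.0,
        )
        fit = dw_fit(scan)
        assert fit.ga_flag[1] > 1.0

    def test_too_few_q_points(self):
        q = np.array([0.5, 1.0])
        scan = ElasticScan(q, np.array([10.0]), np.ones((2, 1)), t_base=10.0)
        with pytest.raises(ValueError, match="3 Q points"):
            dw_fit(scan)

    def test_nonpositive_intensity_rejected(self):
        q = default_q_grid()
        ints = np.ones((len(q), 1))
        ints[3] = 0.0
        scan = ElasticScan(q, np.array([10.0]), ints, t_base=10.0)
        with pytest.raises(ValueError, match="non-positive"):
            dw_fit(scan)


class TestGaussianDynamicsRelation:
    def test_u2_is_3sigma2_and_half_msd_plateau(self):
        """σ² ladder: u²(fit) = 3σ² and windowed MSD = 6σ² = 2·u²."""
        from hydradyn.msd import compute_msd, msd_window_average

        res = ResolutionSpec("gaussian", 5.0)
        sigmas = [0.004, 0.03, 0.06, 0.09]
        temps = [10.0, 100.0, 200.0, 290.0]
        systems = []
        for s2, T in zip(sigmas, temps):
            traj, table, _ = gen_harmonic(
                HarmonicSpec(50, s2, relaxation_time=2.0), T, 2500, 5.0, int(T)
            )
            systems.append((traj, table))
        series, fit, _ = scan_pipeline(
            systems, res, max_lag=1200.0, origin_stride=10
        )
        expected = 3 * (np.array(sigmas) - sigmas[0])
        assert np.allclose(fit.u2[1:], expected[1:], rtol=0.04)
        for (traj, _), s2 in zip(systems[1:], sigmas[1:]):
            curve = compute_msd(traj)
            v, err = msd_window_average(curve, (6000.0, 10000.0))
            assert abs(v - 6 * s2) < max(3 * err, 0.05 * 6 * s2)


class TestScanIO:
    def test_round_trip(self, tmp_path):
        q = default_q_grid(5)
        scan = ElasticScan(
            q, np.array([10.0, 150.0]),
            np.abs(np.random.default_rng(6).normal(1.0, 0.05, (5, 2))),
            t_base=10.0, mode="integrated",
        )
        path = tmp_path / "scan.tsv"
        write_elastic_scan(scan, path)
        back = load_elastic_scan(path)
        assert back.mode == "integrated"
        assert back.t_base == 10.0
        assert np.allclose(back.intensities, scan.intensities)

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Q\tintensity\n0.5\t1.0\n")
        with pytest.raises(ValueError, match="columns"):
            load_elastic_scan(p)

    def test_missing_base_temperature(self, tmp_path):
        p = tmp_path / "bad2.tsv"
        p.write_text("Q\tT\tintensity\n0.5\t100\t1.0\n0.6\t100\t1.0\n")
        with pytest.raises(ValueError, match="T_base"):
            load_elastic_scan(p, t_base=10.0)

    def test_duplicates_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("Q\tT\tintensity\n0.5\t10\t1.0\n0.5\t10\t1.1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_elastic_scan(p)


class TestWeights:
    def test_zero_weight_water_changes_nothing(self):
        """Excluding unweighted D₂O leaves the protein-H u² untouched."""
        from hydradyn.synthetic import WaterKineticsSpec, gen_water_system, _concat

        traj_p, table_p, _ = gen_harmonic(
            HarmonicSpec(20, 0.05, relaxation_time=2.0), 290, 600, 5.0, 8
        )
        traj_w, table_w, _, _ = gen_water_system(
            WaterKineticsSpec(4, 0.01, 0.0), 290, 600, 5.0, 9
        )
        pos = np.concatenate([traj_p.positions, traj_w.positions + 300.0], axis=1)
        table = _concat([table_p, table_w])
        traj = Trajectory(pos, 5.0, 290.0)
        sel = neutron_weights(table, "protein_H")
        isf_with = intermediate_scattering(traj, sel, default_q_grid(), max_lag=500.0)
        isf_protein_only = intermediate_scattering(
            traj_p, np.ones(traj_p.n_atoms, bool), default_q_grid(), max_lag=500.0
        )
        assert np.array_equal(isf_with.values, isf_protein_only.values)

    def test_deuterate_exchangeable_excludes(self):
        from conftest import SER_ATOMS, build_residues
        from hydradyn.core import classify_exchangeable

        table, coords = build_residues([("SER", SER_ATOMS)])
        table = classify_exchangeable(table, coords=coords)
        sel = neutron_weights(table, "deuterate_exchangeable")
        assert int(np.sum(sel)) == int(np.sum(table.protein_H)) - 2
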
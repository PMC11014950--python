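"""MSD estimators: FFT/direct equivalence, windows, blocking, mobility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydradyn.core import Trajectory
from hydradyn.msd import (
    MSDCurve,
    blocking_error,
    compute_msd,
    mobility_change,
    msd_by_subset,
    msd_window_average,
    per_residue_msd,
    powerlaw_fit,
)
from hydradyn.synthetic import HarmonicSpec, gen_harmonic

from hydradyn.synthetic import _concat  # noqa: F401 (used via helpers)


def _traj(pos, dt=1.0, T=300.0):
    return Trajectory(np.asarray(pos, dtype=float), dt, T)


class TestComputeMsd:
    def test_static_atoms_zero(self):
        pos = np.tile(np.random.default_rng(0).normal(size=(1, 7, 3)), (50, 1, 1))
        curve = compute_msd(_traj(pos))
        assert np.allclose(curve.values, 0.0, atol=1e-10)

    def test_uniform_drift_quadratic(self):
        v = np.array([0.3, -0.1, 0.2])
        t = np.arange(40)[:, None, None]
        pos = np.zeros((40, 3, 3)) + v * t
        curve = compute_msd(_traj(pos))
        expected = np.sum(v**2) * curve.lag_times**2
        assert np.allclose(curve.values, expected, rtol=1e-10, atol=1e-10)

    def test_fft_equals_direct_on_random_trajectories(self):
        """Twenty random walks: FFT estimator == O(N²) estimator to 1e-10."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            n = int(rng.integers(40, 160))
            m = int(rng.integers(1, 6))
            pos = np.cumsum(rng.normal(size=(n, m, 3)), axis=0)
            traj = _traj(pos)
            a = compute_msd(traj).values
            b = compute_msd(traj, method="direct").values
            scale = np.maximum(np.abs(b), 1e-12)
            worst = max(worst, float(np.max(np.abs(a - b) / scale)))
        assert worst < 1e-10

    def test_empty_selection_raises(self):
        traj = _traj(np.zeros((10, 4, 3)))
        with pytest.raises(ValueError, match="empty"):
            compute_msd(traj, np.zeros(4, dtype=bool))

    def test_max_lag_beyond_span_raises(self):
        traj = _traj(np.zeros((10, 4, 3)))
        with pytest.raises(ValueError, match="max_lag"):
            compute_msd(traj, max_lag=100.0)

    def test_wrapped_trajectory_rejected(self):
        traj = Trajectory(np.zeros((10, 2, 3)), 1.0, 300.0, unwrapped=False)
        with pytest.raises(ValueError, match="wrapped"):
            compute_msd(traj)

    def test_ou_plateau(self):
        traj, table, truth = gen_harmonic(HarmonicSpec(30, 0.2), 300, 4000, 5.0, 7)
        curve = compute_msd(traj)
        value, err = msd_window_average(curve, (10000, 18000))
        assert value == pytest.approx(truth["msd_plateau"], rel=0.05)


class TestWindowAverage:
    def test_constant_curve(self):
        curve = MSDCurve(np.arange(20.0), np.r_[0.0, np.full(19, 3.3)])
        v, e = msd_window_average(curve, (5, 15))
        assert v == pytest.approx(3.3) and e == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_midpoint(self):
        t = np.arange(0, 10001, 5.0)
        curve = MSDCurve(t, 0.002 * t)
        v, _ = msd_window_average(curve, (6000, 8000))
        assert v == pytest.approx(0.002 * 7000, rel=1e-6)

    def test_window_outside_range_raises(self):
        curve = MSDCurve(np.arange(10.0), np.r_[0.0, np.ones(9)])
        with pytest.raises(ValueError, match="window"):
            msd_window_average(curve, (50, 60))


class TestSubsets:
    def test_weighted_average_identity(self):
        from hydradyn.synthetic import RotorSpec, gen_methyl_rotor
        from hydradyn.synthetic import _concat as concat

        h_traj, h_table, _ = gen_harmonic(HarmonicSpec(10, 0.05), 290, 400, 5.0, 1)
        r_traj, r_table, _ = gen_methyl_rotor(RotorSpec(4, 1.03, 0.5), 290, 400, 5.0, 2)
        pos = np.concatenate([h_traj.positions, r_traj.positions + 100.0], axis=1)
        table = concat([h_table, r_table])
        traj = _traj(pos, dt=5.0)
        out = msd_by_subset(traj, table, window=(500, 1500))
        n_m = int(np.sum(table.methyl_H))
        n_nm = int(np.sum(table.non_methyl_H))
        f = n_m / (n_m + n_nm)
        combined = f * out["methyl_H"][0] + (1 - f) * out["non_methyl_H"][0]
        assert out["all_H"][0] == pytest.approx(combined, rel=1e-9)

    def test_missing_subset_omitted(self):
        traj, table, _ = gen_harmonic(HarmonicSpec(5, 0.05), 290, 200, 5.0, 1)
        out = msd_by_subset(traj, table, window=(200, 600))
        assert "methyl_H" not in out and "all_H" in out


class TestPerResidue:
    def test_gradient_ordering(self):
        """Per-residue MSD ordering follows the per-residue variance."""
        from hydradyn.core import _concat_tables

        parts, tables = [], []
        sig = np.linspace(0.02, 0.2, 6)
        for i, s2 in enumerate(sig):
            t, a, _ = gen_harmonic(HarmonicSpec(4, s2), 290, 1500, 5.0, 100 + i)
            a.residue_index[:] = i + 1
            parts.append(t.positions + 30.0 * i)
            tables.append(a)
        traj = _traj(np.concatenate(parts, axis=1), dt=5.0)
        table = _concat_tables(tables)
        df = per_residue_msd(traj, table, window=(3000, 7000))
        vals = df["msd"].to_numpy()
        assert len(vals) == 6
        assert np.all(np.diff(vals) > 0)

    def test_residue_without_h_warns(self):
        from conftest import build_residues

        table, coords = build_residues([], waters=0)
        # one carbon-only residue + one hydrogenated residue
        from conftest import ALA_ATOMS

        table, coords = build_residues([("ALA", ALA_ATOMS)])
        table2 = table.subset(np.ones(len(table), dtype=bool))
        # strip hydrogens from a cloned residue-2 copy
        import numpy as _np

        no_h = table.subset(~table.is_hydrogen)
        no_h.residue_index[:] = 2
        from hydradyn.core import _concat_tables

        merged = _concat_tables([table2, no_h])
        pos = _np.concatenate([coords, coords[~table.is_hydrogen] + 50.0])
        traj = _traj(_np.tile(pos, (20, 1, 1)))
        with pytest.warns(UserWarning, match="no hydrogens"):
            df = per_residue_msd(traj, merged, window=(2, 10))
        assert len(df) == 1


class TestMobilityChange:
    def test_equal_is_neutral(self):
        h = pd.Series({1: 0.5, 2: 0.7})
        out = mobility_change(h, h.copy())
        assert (out["change_percent"] == 0).all()
        assert (out["class"] == "neutral").all()

    def test_boundary_is_strict(self):
        h = pd.Series({1: 1.6, 2: 0.9})
        d = pd.Series({1: 1.0, 2: 1.0})
        out = mobility_change(h, d)
        assert out.loc[1, "change_percent"] == pytest.approx(60.0)
        assert out.loc[1, "class"] == "neutral"  # +60 is not > +60
        assert out.loc[2, "class"] == "neutral"  # -10 is not < -10
        d2 = pd.Series({1: 1.0})
        h2 = pd.Series({1: 0.8})  # -20 % is strictly below -10
        assert mobility_change(h2, d2).loc[1, "class"] == "hindered"

    def test_zero_dry_raises(self):
        with pytest.raises(ValueError, match="positive"):
            mobility_change(pd.Series({1: 1.0}), pd.Series({1: 0.0}))

    def test_key_mismatch_raises(self):
        with pytest.raises(ValueError, match="keys"):
            mobility_change(pd.Series({1: 1.0}), pd.Series({2: 1.0}))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_antisymmetry(self, a, b):
        """Swapping states maps a change c to −100c/(100+c)."""
        h = pd.Series({1: a})
        d = pd.Series({1: b})
        c = mobility_change(h, d).loc[1, "change_percent"]
        c_swapped = mobility_change(d, h).loc[1, "change_percent"]
        assert c_swapped == pytest.approx(-100.0 * c / (100.0 + c), rel=1e-9)


class TestBlocking:
    def test_constant_zero(self):
        assert blocking_error(np.full(64, 2.5)) == 0.0

    def test_iid_normal(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=4096)
        err = blocking_error(x)
        assert err == pytest.approx(1 / np.sqrt(4096), rel=0.2)

    def test_ar1_inflation(self):
        """AR(1) error inflated by sqrt((1+φ)/(1−φ)) over the iid value."""
        phi = 0.9
        rng = np.random.default_rng(12)
        n = 2**15
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        err = blocking_error(x)
        expected = np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n)
        assert err == pytest.approx(expected, rel=0.3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="8"):
            blocking_error(np.arange(5.0))


class TestPowerlaw:
    def test_brownian_exponent_one(self):
        t = np.arange(0.0, 2000.0, 5.0)
        curve = MSDCurve(t, 6 * 1e-3 * t)
        a, beta = powerlaw_fit(curve)
        assert beta == pytest.approx(1.0, abs=1e-6)

    def test_half_exponent_exact(self):
        t = np.arange(0.0, 2000.0, 5.0)
        vals = np.zeros_like(t)
        vals[1:] = 0.3 * t[1:] ** 0.5
        curve = MSDCurve(t, vals)
        a, beta = powerlaw_fit(curve)
        assert beta == pytest.approx(0.5, abs=1e-9)
        assert a == pytest.approx(0.3, rel=1e-9)

    def test_nonpositive_values_raise(self):
        t = np.arange(0.0, 100.0, 5.0)
        curve = MSDCurve(t, np.zeros_like(t))
        with pytest.raises(ValueError, match="non-positive"):
            powerlaw_fit(curve, (5, 50))
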
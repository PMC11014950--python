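"""Mean squared displacement estimators and direct-space observables.

MSD(t) is the average over selected atoms and time origins of
|r(t₀+t) − r(t₀)|².  The default estimator uses all origins through the
FFT autocorrelation identity and agrees with the O(N²) double loop to
machine precision; a strided direct estimator is available when memory
or origin decorrelation matters.

The scalar per-temperature observable MSD_t(T) is the arithmetic mean
of MSD(t) over a lag window (default 6–8 ns), with a blocking
(Flyvbjerg–Petersen) standard error.  Residue mobility change between
hydrated and dry states is the percent change of windowed residue MSDs,
classified as hindered (< −10 %), neutral, or enhanced (> +60 %) with
strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AtomTable, Trajectory

__all__ = [
    "MSDCurve",
    "MSDvsT",
    "compute_msd",
    "msd_window_average",
    "msd_by_subset",
    "per_residue_msd",
    "mobility_change",
    "blocking_error",
    "powerlaw_fit",
]


@dataclass
class MSDCurve:
    lag_times: np.ndarray  # ps, starting at 0
    values: np.ndarray  # Ų
    errors: np.ndarray | None = None
    selection_label: str = ""
    temperature: float = 0.0
    origin_stride: int = 1

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if self.values[0] > 1e-9 or np.any(self.values < -1e-12):
            raise ValueError("MSD must be non-negative and zero at lag 0")


@dataclass
class MSDvsT:
    temperatures: np.ndarray
    msd_t: np.ndarray
    errors: np.ndarray
    window: tuple[float, float]
    selection_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T": self.temperatures, "msd": self.msd_t, "error": self.errors}
        )


# ---------------------------------------------------------------------------
# estimators


def _msd_fft_per_atom(pos: np.ndarray, n_lags: int) -> np.ndarray:
    """All-origin MSD for positions (N, M, 3) → (n_lags, M).

    Kneller/nMoldyn decomposition: MSD(m) = S_ab(m)/(N−m) − 2·S2(m)/(N−m)
    with S2 the positional autocorrelation, done by FFT over the frame
    axis for every atom and coordinate at once.
    """
    n, m_atoms, _ = pos.shape
    sq = np.einsum("nmc,nmc->nm", pos, pos)  # |r|² per frame/atom
    # autocorrelation via zero-padded rFFT along frames
    n_fft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(pos, n=n_fft, axis=0)
    acf = np.fft.irfft(f * np.conj(f), n=n_fft, axis=0)[:n]
    s2 = acf.sum(axis=2).real  # (N, M): Σ_n r(n)·r(n+m)
    # S_ab(m) = Σ_{n<N−m} (|r(n)|² + |r(n+m)|²) via running sums
    css = np.concatenate([np.zeros((1, m_atoms)), np.cumsum(sq, axis=0)])
    total = css[n]
    out = np.empty((n_lags, m_atoms))
    for lag in range(n_lags):
        sab = (total - css[lag]) + (total - (css[n] - css[n - lag]))
        out[lag] = sab / (n - lag) - 2.0 * s2[lag] / (n - lag)
    np.maximum(out, 0.0, out=out)  # clip FFT roundoff at tiny lags
    return out


def _msd_direct_per_atom(pos: np.ndarray, n_lags: int, origin_stride: int) -> np.ndarray:
    """O(N²) reference estimator, origins thinned by ``origin_stride``."""
    n = pos.shape[0]
    out = np.zeros((n_lags, pos.shape[1]))
    for lag in range(1, n_lags):
        origins = np.arange(0, n - lag, origin_stride)
        d = pos[origins + lag] - pos[origins]
        out[lag] = np.einsum("nmc,nmc->m", d, d) / len(origins)
    return out


def compute_msd(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    max_lag: float | None = None,
    origin_stride: int = 1,
    *,
    method: str = "fft",
    selection_label: str = "",
) -> MSDCurve:
    """MSD(t) averaged over selected atoms and time origins.

    ``max_lag`` is in ps and must be shorter than the trajectory;
    ``method='fft'`` uses every origin, ``method='direct'`` honours
    ``origin_stride``.
    """
    if not traj.unwrapped:
        raise ValueError("trajectory is wrapped; MSD needs continuous coordinates")
    if selection is None:
        selection = np.ones(traj.n_atoms, dtype=bool)
    selection = np.asarray(selection)
    if selection.dtype == bool and not selection.any():
        raise ValueError("empty atom selection")
    pos = traj.positions[:, selection, :]
    if pos.shape[1] == 0:
        raise ValueError("empty atom selection")
    n = traj.n_frames
    if max_lag is None:
        n_lags = n
    else:
        n_lags = int(round(max_lag / traj.timestep)) + 1
        if n_lags > n:
            raise ValueError(
                f"max_lag {max_lag} ps exceeds trajectory span "
                f"{(n - 1) * traj.timestep} ps"
            )
    if method == "fft":
        per_atom = _msd_fft_per_atom(pos, n_lags)
        stride = 1
    elif method == "direct":
        per_atom = _msd_direct_per_atom(pos, n_lags, origin_stride)
        stride = origin_stride
    else:
        raise ValueError(f"unknown method {method!r}")
    values = per_atom.mean(axis=1)
    values[0] = 0.0
    return MSDCurve(
        lag_times=np.arange(n_lags) * traj.timestep,
        values=values,
        selection_label=selection_label,
        temperature=traj.temperature,
        origin_stride=stride,
    )


# ---------------------------------------------------------------------------
# windowed observables


def blocking_error(series: np.ndarray) -> float:
    """Flyvbjerg–Petersen blocking standard error of the mean.

    Repeatedly halves the series by pair averaging; the error estimate
    at each level is sqrt(var/(n−1)).  Returns the estimate at the
    first plateau — the first level whose successor agrees within its
    own uncertainty — or the maximum over levels if no plateau forms.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("blocking needs at least 8 samples")
    if np.allclose(x, x[0]):
        return 0.0
    errs = []
    uncert = []
    while x.size >= 2:
        n = x.size
        err2 = x.var(ddof=0) / (n - 1)
        errs.append(np.sqrt(err2))
        uncert.append(np.sqrt(err2) / np.sqrt(2.0 * (n - 1)))
        if n < 4:
            break
        x = 0.5 * (x[: 2 * (n // 2) : 2] + x[1 : 2 * (n // 2) : 2])
    errs_a = np.asarray(errs)
    for i in range(len(errs_a) - 1):
        if errs_a[i + 1] <= errs_a[i] + uncert[i]:
            return float(errs_a[i])
    return float(errs_a.max())


def msd_window_average(
    curve: MSDCurve, window: tuple[float, float] = (6000.0, 8000.0)
) -> tuple[float, float]:
    """Mean of MSD(t) over the lag window (ps) with a blocking error."""
    lo, hi = window
    mask = (curve.lag_times >= lo) & (curve.lag_times <= hi)
    if not mask.any() or lo < curve.lag_times[0] or hi > curve.lag_times[-1]:
        raise ValueError(
            f"window {window} ps outside curve range "
            f"[{curve.lag_times[0]}, {curve.lag_times[-1]}] ps"
        )
    vals = curve.values[mask]
    err = blocking_error(vals) if vals.size >= 8 else float(np.std(vals) / np.sqrt(vals.size))
    return float(vals.mean()), err


def msd_by_subset(
    traj: Trajectory,
    atoms: AtomTable,
    window: tuple[float, float] = (6000.0, 8000.0),
    max_lag: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Windowed MSDs of all protein H, methyl H and non-methyl H.

    The all-H value is exactly the methyl-fraction-weighted average of
    the two sub-populations (identical origin sets).  Subsets without
    atoms are omitted.
    """
    subsets = {
        "all_H": atoms.protein_H,
        "methyl_H": atoms.methyl_H,
        "non_methyl_H": atoms.non_methyl_H,
    }
    out = {}
    for label, mask in subsets.items():
        if not mask.any():
            continue
        curve = compute_msd(traj, mask, max_lag=max_lag, selection_label=label)
        out[label] = msd_window_average(curve, window)
    if not out:
        raise ValueError("no protein hydrogens present")
    return out


def per_residue_msd(
    traj: Trajectory,
    atoms: AtomTable,
    window: tuple[float, float] = (6000.0, 8000.0),
    max_lag: float | None = None,
) -> pd.DataFrame:
    """Windowed MSD over each residue's hydrogen atoms.

    Indexed by (subunit_id, residue_index, residue_name); residues
    without hydrogens are omitted with a warning.
    """
    prot_h = atoms.protein_H
    keys = []
    rows = []
    prot = atoms.protein
    residues = pd.DataFrame(
        {
            "subunit": atoms.subunit_id[prot],
            "resid": atoms.residue_index[prot],
            "resname": atoms.residue_name[prot],
        }
    ).drop_duplicates(subset=["subunit", "resid"])
    for _, r in residues.iterrows():
        mask = prot_h & (atoms.subunit_id == r.subunit) & (atoms.residue_index == r.resid)
        if not mask.any():
            warnings.warn(
                f"residue {r.subunit}:{r.resid}:{r.resname} has no hydrogens; omitted"
            )
            continue
        curve = compute_msd(traj, mask, max_lag=max_lag)
        value, err = msd_window_average(curve, window)
        keys.append((int(r.subunit), int(r.resid), str(r.resname)))
        rows.append((value, err))
    idx = pd.MultiIndex.from_tuples(keys, names=["subunit", "resid", "resname"])
    return pd.DataFrame(rows, index=idx, columns=["msd", "error"])


def mobility_change(
    msd_hydrated: pd.DataFrame | Mapping[object, float],
    msd_dry: pd.DataFrame | Mapping[object, float],
    thresholds: tuple[float, float] = (-10.0, 60.0),
) -> pd.DataFrame:
    """Per-residue percent mobility change on hydration.

    change = (MSD_hydrated − MSD_dry)/MSD_dry · 100; a residue is
    'hindered' iff change < thresholds[0], 'enhanced' iff change >
    thresholds[1] (strict), else 'neutral'.
    """
    h = _as_series(msd_hydrated)
    d = _as_series(msd_dry)
    if not h.index.equals(d.index):
        if set(h.index) != set(d.index):
            missing = set(h.index) ^ set(d.index)
            raise ValueError(f"residue keys differ between states: {sorted(missing)[:5]} ...")
        d = d.reindex(h.index)
    if (d <= 0).any():
        raise ValueError("dry MSD must be positive for every residue")
    change = (h - d) / d * 100.0
    lo, hi = thresholds
    # strict inequalities; values exactly on a threshold are neutral, so
    # guard against floating-point noise at the boundary
    at_lo = np.isclose(change, lo, rtol=1e-9, atol=1e-9)
    at_hi = np.isclose(change, hi, rtol=1e-9, atol=1e-9)
    cls = np.where(
        (change < lo) & ~at_lo,
        "hindered",
        np.where((change > hi) & ~at_hi, "enhanced", "neutral"),
    )
    return pd.DataFrame(
        {"change_percent": change, "class": cls,
         "threshold_lo": lo, "threshold_hi": hi},
        index=h.index,
    )


def _as_series(x) -> pd.Series:
    if isinstance(x, pd.DataFrame):
        return x["msd"]
    if isinstance(x, pd.Series):
        return x
    return pd.Series(dict(x))


def powerlaw_fit(
    curve: MSDCurve, window: tuple[float, float] = (5.0, 1000.0)
) -> tuple[float, float]:
    """(prefactor A, exponent β) of MSD ≈ A·t^β by log-log least squares."""
    lo, hi = window
    mask = (curve.lag_times >= lo) & (curve.lag_times <= hi)
    t = curve.lag_times[mask]
    y = curve.values[mask]
    if t.size < 2:
        raise ValueError("power-law window contains fewer than 2 points")
    if np.any(y <= 0):
        raise ValueError("non-positive MSD values in power-law window")
    beta, ln_a = np.polyfit(np.log(t), np.log(y), 1)
    return float(np.exp(ln_a)), float(beta)
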
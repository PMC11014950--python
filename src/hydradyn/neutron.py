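"""Virtual elastic fixed-window scans and Debye–Waller fitting.

The incoherent intermediate scattering function of the selected
hydrogens is computed directly from displacements with the isotropic
powder average ⟨exp(iQ·d)⟩ = sinc(Q|d|) (exact for the self term).
Instrument resolution enters as a multiplicative window R(t) in the
time domain — the normalised Fourier transform of the Gaussian,
Lorentzian or pseudo-Voigt energy profile — and the elastic intensity
is either the spectral peak height S(Q, ω=0) (used for simulated data)
or the integral of S(Q, ω) over ±w around the elastic line (used for
experimental scans).

The elastic scan I(Q,T), normalised per Q to the base temperature, is
fitted per temperature by ln[I(Q,T)/I(Q,T_base)] = a − Q²⟨u²(T)⟩/3 with
a floating intercept over Q 0.4–1.8 Å⁻¹; the Gaussian-approximation
flag trips when max(Q²⟨u²⟩)/3 exceeds one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .core import AtomTable, Trajectory
from .msd import MSDvsT
from .units import FWHM_TO_SIGMA, HBAR_UEV_PS

__all__ = [
    "ResolutionSpec",
    "ElasticScan",
    "DWFitResult",
    "ISF",
    "INSTRUMENTS",
    "default_q_grid",
    "neutron_weights",
    "intermediate_scattering",
    "resolution_window",
    "elastic_intensity",
    "dw_fit",
    "scan_pipeline",
    "load_elastic_scan",
    "write_elastic_scan",
]


@dataclass(frozen=True)
class ResolutionSpec:
    shape: str  # 'gaussian' | 'lorentzian' | 'pseudo_voigt'
    fwhm: float  # Γ_res, μeV
    eta: float = 0.5  # pseudo-Voigt Lorentzian weight
    integration_half_width: float | None = None  # μeV

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("resolution FWHM must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("pseudo-Voigt mixing must lie in [0, 1]")


#: backscattering presets: PG(002) analyser FWHM and elastic windows
INSTRUMENTS: dict[str, ResolutionSpec] = {
    "OSIRIS": ResolutionSpec("pseudo_voigt", 24.5, 0.5, 12.5),
    "IRIS": ResolutionSpec("pseudo_voigt", 17.5, 0.5, 8.5),
}


def default_q_grid(n: int = 15) -> np.ndarray:
    """Common momentum-transfer range of the presets, 0.4–1.8 Å⁻¹."""
    return np.linspace(0.4, 1.8, n)


@dataclass
class ISF:
    """Incoherent intermediate scattering function I(Q, t)."""

    q_grid: np.ndarray  # Å⁻¹
    t_grid: np.ndarray  # ps
    values: np.ndarray  # (nQ, nt); values[:, 0] == 1
    temperature: float = 0.0
    selection_label: str = ""


@dataclass
class ElasticScan:
    q_grid: np.ndarray
    temperatures: np.ndarray
    intensities: np.ndarray  # (nQ, nT)
    t_base: float
    mode: str = "peak_height"  # or 'integrated'

    def base_column(self) -> np.ndarray:
        j = int(np.argmin(np.abs(self.temperatures - self.t_base)))
        if abs(self.temperatures[j] - self.t_base) > 1e-6:
            raise ValueError(f"base temperature {self.t_base} K not in scan")
        return self.intensities[:, j]


@dataclass
class DWFitResult:
    temperatures: np.ndarray
    u2: np.ndarray  # ⟨u²(T)⟩, Ų
    intercept: np.ndarray  # exp(a): floating amplitude ratio
    fit_q2_range: tuple[float, float]
    residual_rms: np.ndarray
    ga_flag: np.ndarray  # max(Q²u²)/3 per temperature
    errors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T": self.temperatures,
                "u2": self.u2,
                "intercept": self.intercept,
                "residual_rms": self.residual_rms,
                "ga_flag": self.ga_flag,
            }
        )


# ---------------------------------------------------------------------------
# scattering


def neutron_weights(atoms: AtomTable, weighting: str = "protein_H") -> np.ndarray:
    """Boolean mask of atoms contributing incoherent signal.

    'protein_H' (default) — protein hydrogens only: D₂O hydration water
    contributes negligibly and is excluded.  'all_H' includes water
    hydrogens; 'deuterate_exchangeable' additionally zero-weights
    exchangeable protein hydrogens, emulating H/D exchange.
    """
    if weighting == "protein_H":
        return atoms.protein_H
    if weighting == "all_H":
        return atoms.is_hydrogen
    if weighting == "deuterate_exchangeable":
        return atoms.protein_H & ~atoms.is_exchangeable
    raise ValueError(f"unknown weighting {weighting!r}")


def intermediate_scattering(
    traj: Trajectory,
    selection: np.ndarray,
    q_grid: np.ndarray,
    max_lag: float | None = None,
    origin_stride: int = 10,
    selection_label: str = "",
) -> ISF:
    """Powder-averaged self ISF: I(Q,t) = ⟨ sinc(Q·|r(t₀+t) − r(t₀)|) ⟩."""
    if not traj.unwrapped:
        raise ValueError("trajectory is wrapped")
    selection = np.asarray(selection)
    pos = traj.positions[:, selection, :]
    if pos.shape[1] == 0:
        raise ValueError("empty atom selection")
    q = np.asarray(q_grid, dtype=float)
    n = traj.n_frames
    if max_lag is None:
        n_lags = n // 2
    else:
        n_lags = int(round(max_lag / traj.timestep)) + 1
        if n_lags > n:
            raise ValueError("max_lag exceeds trajectory span")
    out = np.empty((len(q), n_lags))
    out[:, 0] = 1.0
    for lag in range(1, n_lags):
        origins = np.arange(0, n - lag, origin_stride)
        d = pos[origins + lag] - pos[origins]
        dist = np.sqrt(np.einsum("omc,omc->om", d, d)).ravel()
        # np.sinc(x) = sin(πx)/(πx)
        out[:, lag] = np.sinc(np.outer(q, dist) / np.pi).mean(axis=1)
    return ISF(
        q_grid=q,
        t_grid=np.arange(n_lags) * traj.timestep,
        values=out,
        temperature=traj.temperature,
        selection_label=selection_label,
    )


def resolution_window(res: ResolutionSpec, t_grid: np.ndarray) -> np.ndarray:
    """Time-domain resolution window R(t), R(0) = 1.

    Gaussian energy profile of FWHM Γ → Gaussian in time with
    R(t) = exp(−σ_E² t²/(2ħ²)); Lorentzian → exp(−Γ|t|/(2ħ));
    pseudo-Voigt → η-weighted sum of the two.
    """
    t = np.abs(np.asarray(t_grid, dtype=float))
    sigma_e = res.fwhm * FWHM_TO_SIGMA
    gauss = np.exp(-0.5 * (sigma_e * t / HBAR_UEV_PS) ** 2)
    lorentz = np.exp(-res.fwhm * t / (2.0 * HBAR_UEV_PS))
    if res.shape == "gaussian":
        return gauss
    if res.shape == "lorentzian":
        return lorentz
    if res.shape == "pseudo_voigt":
        return res.eta * lorentz + (1.0 - res.eta) * gauss
    raise ValueError(f"unknown resolution shape {res.shape!r}")


def elastic_intensity(
    isf: ISF, res: ResolutionSpec, mode: str = "peak_height"
) -> np.ndarray:
    """Per-Q elastic intensity (arbitrary common units).

    'peak_height': S(Q, ω=0) ∝ ∫ I(Q,t)·R(t) dt (cosine transform at
    zero frequency of the symmetric extension).
    'integrated': ∫₋w^{+w} S(Q,ω) dω ∝ ∫ I(Q,t)·R(t)·sinc(w t/ħ) dt
    with w the integration half-width.
    """
    t = isf.t_grid
    r = resolution_window(res, t)
    if r[-1] > 0.01:
        warnings.warn(
            "t-grid too short for the resolution window "
            f"(R(t_max) = {r[-1]:.3f} > 0.01); elastic intensity may be biased"
        )
    integrand = isf.values * r[None, :]
    if mode == "peak_height":
        return np.trapezoid(integrand, t, axis=1)
    if mode == "integrated":
        if res.integration_half_width is None:
            raise ValueError("integrated mode needs an integration_half_width")
        w_omega = res.integration_half_width / HBAR_UEV_PS  # 1/ps
        kernel = np.sinc(w_omega * t / np.pi)
        return np.trapezoid(integrand * kernel[None, :], t, axis=1)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Debye–Waller fitting


def dw_fit(
    scan: ElasticScan, q_fit_range: tuple[float, float] = (0.4, 1.8)
) -> DWFitResult:
    """Per-temperature log-linear Debye–Waller fit with floating intercept.

    ln[I(Q,T)/I(Q,T_base)] = a(T) − Q²⟨u²(T)⟩/3 by least squares on Q²
    within ``q_fit_range``.
    """
    q = scan.q_grid
    in_range = (q >= q_fit_range[0]) & (q <= q_fit_range[1])
    if int(in_range.sum()) < 3:
        raise ValueError("need at least 3 Q points inside the fit range")
    base = scan.base_column()
    if np.any(scan.intensities[in_range] <= 0) or np.any(base[in_range] <= 0):
        raise ValueError("non-positive elastic intensity inside the fit range")
    q2 = q[in_range] ** 2
    design = np.column_stack([np.ones_like(q2), q2])
    n_t = len(scan.temperatures)
    u2 = np.empty(n_t)
    intercept = np.empty(n_t)
    resid = np.empty(n_t)
    for j in range(n_t):
        y = np.log(scan.intensities[in_range, j] / base[in_range])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        u2[j] = -3.0 * coef[1]
        intercept[j] = np.exp(coef[0])
        resid[j] = float(np.sqrt(np.mean((design @ coef - y) ** 2)))
    ga = np.max(q2) * u2 / 3.0
    return DWFitResult(
        temperatures=np.asarray(scan.temperatures, dtype=float),
        u2=u2,
        intercept=intercept,
        fit_q2_range=(q_fit_range[0] ** 2, q_fit_range[1] ** 2),
        residual_rms=resid,
        ga_flag=ga,
    )


def scan_pipeline(
    systems: list[tuple[Trajectory, AtomTable]],
    res: ResolutionSpec,
    q_grid: np.ndarray | None = None,
    *,
    weighting: str = "protein_H",
    mode: str = "peak_height",
    max_lag: float | None = None,
    origin_stride: int = 10,
    q_fit_range: tuple[float, float] = (0.4, 1.8),
) -> tuple[MSDvsT, DWFitResult, ElasticScan]:
    """Full virtual elastic scan: ISF → elastic intensity → DW fit.

    Intensities are normalised per Q at the lowest temperature; the
    fitted ⟨u²(T)⟩ series is returned as a neutron-derived MSD(T).
    """
    if q_grid is None:
        q_grid = default_q_grid()
    order = np.argsort([t.temperature for t, _ in systems])
    temps = []
    cols = []
    for i in order:
        traj, atoms = systems[i]
        sel = neutron_weights(atoms, weighting)
        isf = intermediate_scattering(
            traj, sel, q_grid, max_lag=max_lag, origin_stride=origin_stride
        )
        cols.append(elastic_intensity(isf, res, mode=mode))
        temps.append(traj.temperature)
    scan = ElasticScan(
        q_grid=np.asarray(q_grid, dtype=float),
        temperatures=np.asarray(temps),
        intensities=np.column_stack(cols),
        t_base=temps[0],
        mode=mode,
    )
    fit = dw_fit(scan, q_fit_range)
    series = MSDvsT(
        temperatures=fit.temperatures,
        msd_t=fit.u2,
        errors=np.zeros_like(fit.u2),
        window=(0.0, 0.0),
        selection_label=f"u2({weighting})",
    )
    return series, fit, scan


# ---------------------------------------------------------------------------
# tabulated experimental scans


def write_elastic_scan(scan: ElasticScan, path) -> None:
    from .io import write_tsv

    rows = []
    for i, q in enumerate(scan.q_grid):
        for j, t in enumerate(scan.temperatures):
            rows.append((q, t, scan.intensities[i, j]))
    write_tsv(
        path,
        pd.DataFrame(rows, columns=["Q", "T", "intensity"]),
        meta={"mode": scan.mode, "t_base": scan.t_base},
    )


def load_elastic_scan(path, t_base: float | None = None, mode: str | None = None) -> ElasticScan:
    """Read a Q/T/intensity table (TSV with optional '#' metadata)."""
    from .io import read_tsv

    df, meta = read_tsv(path)
    missing = {"Q", "T", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"elastic-scan table lacks columns: {sorted(missing)}")
    if df.duplicated(subset=["Q", "T"]).any():
        raise ValueError("duplicate (Q, T) entries in elastic-scan table")
    t_base = float(meta.get("t_base", np.nan)) if t_base is None else t_base
    mode = mode or meta.get("mode", "integrated")
    qs = np.sort(df["Q"].unique())
    ts = np.sort(df["T"].unique())
    if np.isnan(t_base):
        t_base = float(ts[0])
    if not np.any(np.isclose(ts, t_base)):
        raise ValueError(f"base temperature T_base={t_base} K has no row in the table")
    grid = df.pivot(index="Q", columns="T", values="intensity")
    if grid.isna().any().any():
        raise ValueError("incomplete (Q, T) grid in elastic-scan table")
    return ElasticScan(
        q_grid=qs,
        temperatures=ts,
        intensities=grid.loc[qs, ts].to_numpy(),
        t_base=t_base,
        mode=mode,
    )
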
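"""End-to-end virtual-experiment workflow and scenario comparison.

`run_synth` writes the two-scenario temperature series (trajectories in
multi-frame XYZ plus a YAML ground-truth manifest), `run_analyse` runs
every analysis stage on a trajectory set and emits one TSV per
figure-level observable, and `run_compare` derives hydrated/dry ratios,
piecewise-linear transition temperatures and residue mobility classes.
Every output file header carries the config hash, seed and package
version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AtomTable, Trajectory
from .io import config_hash, write_manifest, write_tsv, write_xyz
from .methyl import decompose
from .msd import (
    blocking_error,
    compute_msd,
    mobility_change,
    msd_by_subset,
    per_residue_msd,
    powerlaw_fit,
)
from .neutron import INSTRUMENTS, ResolutionSpec, default_q_grid, scan_pipeline
from .rdf import profile_overlap, subset_rdf_report
from .synthetic import SeriesConfig, gen_temperature_series
from .water import arrhenius_fit, correlation_from_states, hbond_correlation

log = logging.getLogger("hydradyn")

__all__ = ["RunConfig", "run_synth", "run_analyse", "run_compare", "piecewise_breakpoints"]


@dataclass
class RunConfig:
    """Reproducibility contract: everything a run needs, in one record."""

    instrument: str = "OSIRIS"
    resolution: ResolutionSpec | None = None  # overrides the preset
    n_q: int = 15
    msd_window: tuple[float, float] = (6000.0, 8000.0)
    decomposition_lag: float = 1000.0
    rdf_bin_width: float = 0.05  # nm
    hbond_max_oo: float = 3.5  # Å
    hbond_max_angle: float = 30.0  # degrees
    seed: int = 0
    series: SeriesConfig = field(default_factory=SeriesConfig)
    isf_origin_stride: int = 10
    isf_max_lag: float = 400.0  # ps

    @property
    def res_spec(self) -> ResolutionSpec:
        if self.resolution is not None:
            return self.resolution
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument preset {self.instrument!r}")
        return INSTRUMENTS[self.instrument]

    def meta(self) -> dict:
        payload = {
            "instrument": self.instrument,
            "n_q": self.n_q,
            "msd_window": list(self.msd_window),
            "decomposition_lag": self.decomposition_lag,
            "rdf_bin_width": self.rdf_bin_width,
            "seed": self.seed,
            "series_T": list(self.series.temperatures),
        }
        return {
            "package": f"hydradyn {__version__}",
            "config_hash": config_hash(payload),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        series = SeriesConfig(**raw.pop("series", {}))
        if "msd_window" in raw:
            raw["msd_window"] = tuple(raw["msd_window"])
        return cls(series=series, **raw)


# ---------------------------------------------------------------------------


def run_synth(config: RunConfig, outdir: str | Path) -> dict:
    """Generate and write both scenario series; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, **config.meta(), "scenarios": {}}
    for scenario in ("lyophilised", "hydrated"):
        systems, truth = gen_temperature_series(scenario, config.series, config.seed)
        files = []
        for traj, table in systems:
            name = f"{scenario}_T{traj.temperature:g}.xyz"
            write_xyz(traj, table, outdir / name)
            files.append(
                {"file": name, "T": traj.temperature, "timestep": traj.timestep,
                 "n_frames": traj.n_frames}
            )
        truth_public = {
            k: v for k, v in truth.items() if k != "per_temperature"
        }
        truth_public["per_temperature"] = [
            {k: v for k, v in row.items() if k != "hbond_states"}
            for row in truth["per_temperature"]
        ]
        manifest["scenarios"][scenario] = {"files": files, "truth": truth_public}
    write_manifest(outdir / "manifest.yaml", manifest)
    log.info("wrote %d trajectory files to %s", 2 * len(config.series.temperatures), outdir)
    return manifest


def analyse_series(
    systems: Sequence[tuple[Trajectory, AtomTable]],
    config: RunConfig,
    hbond_states: Sequence[np.ndarray | None] | None = None,
) -> dict:
    """All analysis stages on one scenario's temperature series.

    Returns a bundle of DataFrames: neutron-derived u²(T), direct-space
    subset MSD_t(T), methyl decomposition vs T, radial profiles at the
    top temperature, and (when waters are present) hydration-water
    kinetics with an Arrhenius fit.
    """
    bundle: dict = {"partial": False}
    temps = [t.temperature for t, _ in systems]

    # neutron route: u2(T) from the virtual elastic scan
    series_u2, fit, _scan = scan_pipeline(
        [(t, a) for t, a in systems],
        config.res_spec,
        default_q_grid(config.n_q),
        mode="peak_height",
        max_lag=config.isf_max_lag,
        origin_stride=config.isf_origin_stride,
    )
    bundle["u2_vs_T"] = fit.to_frame()

    # direct space: subset MSD_t(T)
    rows = []
    for traj, atoms in systems:
        subsets = msd_by_subset(traj, atoms, window=config.msd_window)
        row = {"T": traj.temperature}
        for label, (v, e) in subsets.items():
            row[label] = v
            row[f"{label}_err"] = e
        rows.append(row)
    bundle["msd_t_subsets"] = pd.DataFrame(rows)

    # methyl decomposition at fixed lag
    rows = []
    for traj, atoms in systems:
        try:
            comp = decompose(traj, atoms, lag=config.decomposition_lag)
        except ValueError as exc:
            log.warning("decomposition skipped at T=%g: %s", traj.temperature, exc)
            bundle["partial"] = True
            continue
        rows.append(
            {"T": traj.temperature, "lag_ps": comp.lag, "total": comp.total,
             "rotational": comp.rotational, "non_rotational": comp.non_rotational,
             "cross": comp.cross_term}
        )
    bundle["methyl_decomposition"] = pd.DataFrame(rows)

    # radial profiles at the top temperature
    traj_top, atoms_top = systems[int(np.argmax(temps))]
    try:
        profiles = subset_rdf_report(traj_top, atoms_top, bin_width=config.rdf_bin_width)
        bundle["rdf_profiles"] = {p.selection_label: p for p in profiles}
    except ValueError as exc:
        log.warning("RDF stage skipped: %s", exc)
        bundle["partial"] = True

    # hydration-water kinetics (skipped when no waters)
    has_water = any(np.any(a.water) for _, a in systems)
    if has_water:
        taus = {}
        exponents = {}
        for i, (traj, atoms) in enumerate(systems):
            states = hbond_states[i] if hbond_states is not None else None
            try:
                if states is not None:
                    corr = correlation_from_states(
                        states, traj.timestep, temperature=traj.temperature
                    )
                else:
                    corr = hbond_correlation(traj, atoms)
            except ValueError as exc:
                log.warning("H-bond stage skipped at T=%g: %s", traj.temperature, exc)
                continue
            if corr.tau_defined:
                taus[traj.temperature] = corr.tau_h
            if np.any(atoms.water_O):
                curve = compute_msd(traj, atoms.water_O)
                hi = min(1000.0, curve.lag_times[-1])
                try:
                    _, beta = powerlaw_fit(curve, (5.0, hi))
                    exponents[traj.temperature] = beta
                except ValueError:
                    pass
        bundle["water_tau"] = pd.Series(taus, name="tau_ps").rename_axis("T")
        bundle["water_beta"] = pd.Series(exponents, name="beta").rename_axis("T")
        try:
            bundle["arrhenius"] = arrhenius_fit(bundle["water_tau"])
        except ValueError as exc:
            log.warning("Arrhenius fit skipped: %s", exc)
    else:
        log.info("no water in this series; water-kinetics stage skipped")
    return bundle


def run_analyse(
    config: RunConfig,
    systems: Sequence[tuple[Trajectory, AtomTable]],
    outdir: str | Path | None = None,
    hbond_states=None,
    label: str = "series",
) -> dict:
    """Analyse one scenario and optionally write the TSV bundle."""
    bundle = analyse_series(systems, config, hbond_states)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = config.meta()
        write_tsv(outdir / f"{label}_u2_vs_T.tsv", bundle["u2_vs_T"], meta)
        write_tsv(outdir / f"{label}_msd_t_subsets.tsv", bundle["msd_t_subsets"], meta)
        write_tsv(outdir / f"{label}_methyl_decomposition.tsv",
                  bundle["methyl_decomposition"], meta)
        if "rdf_profiles" in bundle:
            frames = []
            for name, p in bundle["rdf_profiles"].items():
                df = p.to_frame()
                df.insert(0, "selection", name)
                frames.append(df)
            write_tsv(outdir / f"{label}_rdf.tsv", pd.concat(frames), meta)
        if "water_tau" in bundle:
            write_tsv(outdir / f"{label}_water_tau.tsv",
                      bundle["water_tau"].reset_index(), meta)
    return bundle


# ---------------------------------------------------------------------------
# comparison


def piecewise_breakpoints(
    temps: np.ndarray,
    values: np.ndarray,
    n_breaks: int = 2,
    grid: np.ndarray | None = None,
) -> list[float]:
    """Continuous piecewise-linear least-squares breakpoint estimates.

    Fits y(T) with basis {1, T, (T−b)₊ per break} over a grid of
    candidate break locations and returns the combination with the
    smallest residual sum of squares.
    """
    t = np.asarray(temps, dtype=float)
    y = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.arange(t.min() + 20.0, t.max() - 10.0, 5.0)
    best, best_sse = None, np.inf

    def sse_for(breaks: tuple[float, ...]) -> float:
        cols = [np.ones_like(t), t] + [np.clip(t - b, 0.0, None) for b in breaks]
        a = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        r = a @ coef - y
        return float(r @ r)

    if n_breaks == 1:
        for b in grid:
            s = sse_for((b,))
            if s < best_sse:
                best, best_sse = [b], s
    elif n_breaks == 2:
        for i, b1 in enumerate(grid):
            for b2 in grid[i + 1 :]:
                if b2 - b1 < 30.0:
                    continue  # segments need support
                s = sse_for((b1, b2))
                if s < best_sse:
                    best, best_sse = [b1, b2], s
    else:
        raise ValueError("n_breaks must be 1 or 2")
    return [float(b) for b in best]


def run_compare(bundle_hydrated: dict, bundle_dry: dict) -> dict:
    """Hydrated/dry ratios, transition breakpoints and mobility classes."""
    mh = bundle_hydrated["msd_t_subsets"].set_index("T")
    md = bundle_dry["msd_t_subsets"].set_index("T")
    if not mh.index.equals(md.index):
        raise ValueError("temperature grids differ between scenarios")
    report: dict = {}
    report["msd_ratio"] = (mh["all_H"] / md["all_H"]).rename("hydrated_over_dry")
    t_top = float(mh.index.max())
    report["top_T_ratio"] = float(report["msd_ratio"].loc[t_top])

    # transition temperatures from the hydrated all-H curve
    report["breakpoints_hydrated"] = piecewise_breakpoints(
        mh.index.to_numpy(), mh["all_H"].to_numpy(), n_breaks=2
    )
    # methyl activation from the methyl-H curve of the dry scenario
    mm = bundle_dry["msd_t_subsets"].set_index("T")
    if "methyl_H" in mm:
        report["methyl_onset"] = piecewise_breakpoints(
            mm.index.to_numpy(), mm["methyl_H"].to_numpy(), n_breaks=1,
            grid=np.arange(mm.index.min() + 20.0, 200.0, 5.0),
        )[0]

    if "per_residue_hydrated" in bundle_hydrated and "per_residue_dry" in bundle_dry:
        report["mobility"] = mobility_change(
            bundle_hydrated["per_residue_hydrated"], bundle_dry["per_residue_dry"]
        )
    profiles = bundle_hydrated.get("rdf_profiles", {})
    if "water_O" in profiles:
        # within-bundle grids are shared: water vs residue-subset overlap
        report["rdf_overlap"] = {
            name: profile_overlap(profiles["water_O"], p)
            for name, p in sorted(profiles.items())
            if name != "water_O"
        }
    return report
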
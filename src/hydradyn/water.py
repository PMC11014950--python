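"""Hydration-water observables: hydrogen-bond kinetics and Arrhenius fit.

A water–water hydrogen bond is declared when the O···O distance is
within a cutoff (default 3.5 Å) and the H–donor-O–acceptor-O angle is
within a cone (default 30°), testing both waters as donor.  The
intermittent bond correlation C_H(t) = ⟨h(0)h(t)⟩/⟨h⟩ runs over every
pair that is ever bonded; its relaxation time τ_H is where C_H decays
to 1/e (log-linear interpolation).  Plotting ln τ_H against 1/T and
fitting a line gives the Arrhenius activation energy E_a = slope · R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .core import AtomTable, Trajectory
from .units import R_KJ_PER_MOL_K

__all__ = [
    "HBondCriterion",
    "HBondCorrelation",
    "ArrheniusFit",
    "detect_hbonds",
    "hbond_correlation",
    "correlation_from_states",
    "arrhenius_fit",
    "replica_aggregate",
]


@dataclass(frozen=True)
class HBondCriterion:
    max_oo_distance: float = 3.5  # Å
    max_hda_angle: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.max_oo_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.max_hda_angle < 90.0:
            raise ValueError("angle cutoff must lie in (0, 90) degrees")


@dataclass
class HBondCorrelation:
    times: np.ndarray  # ps
    c_h: np.ndarray  # [0, 1]
    tau_h: float | None  # ps; None when C_H never reaches 1/e
    criterion: HBondCriterion | None = None
    temperature: float = 0.0

    @property
    def tau_defined(self) -> bool:
        return self.tau_h is not None


@dataclass
class ArrheniusFit:
    e_a: float  # kJ/mol
    tau0: float  # ps
    e_a_error: float
    t_range: tuple[float, float]
    n_points: int
    r_gas: float = field(default=R_KJ_PER_MOL_K)


def _water_molecules(atoms: AtomTable) -> tuple[np.ndarray, np.ndarray]:
    """(oxygen_indices, hydrogen_indices (n_water, 2)) per water molecule."""
    w = atoms.water
    if not np.any(w):
        raise ValueError("no water molecules in the system")
    o_idx = []
    h_idx = []
    for sub, res in dict.fromkeys(
        zip(atoms.subunit_id[w].tolist(), atoms.residue_index[w].tolist())
    ):
        mask = w & (atoms.subunit_id == sub) & (atoms.residue_index == res)
        os = np.flatnonzero(mask & (atoms.element == "O"))
        hs = np.flatnonzero(mask & atoms.is_hydrogen)
        if len(os) != 1 or len(hs) != 2:
            raise ValueError(
                f"malformed water {sub}:{res}: {len(os)} O and {len(hs)} H"
            )
        o_idx.append(os[0])
        h_idx.append(hs)
    return np.array(o_idx), np.array(h_idx)


def detect_hbonds(
    coords: np.ndarray,
    atoms: AtomTable,
    criterion: HBondCriterion = HBondCriterion(),
) -> list[tuple[int, int]]:
    """Water–water bonds in one frame as sorted (water_i, water_j) pairs.

    Indices refer to water molecules in residue order.  Both donor
    directions are tested; a pair is bonded if either direction
    satisfies distance and angle.
    """
    o_idx, h_idx = _water_molecules(atoms)
    o_pos = coords[o_idx]
    tree = cKDTree(o_pos)
    pairs = tree.query_pairs(criterion.max_oo_distance, output_type="ndarray")
    cos_max = np.cos(np.deg2rad(criterion.max_hda_angle))
    bonds = []
    for i, j in pairs:
        bonded = False
        for donor, acceptor in ((i, j), (j, i)):
            oa = o_pos[acceptor] - o_pos[donor]
            oa_n = oa / np.linalg.norm(oa)
            for h in h_idx[donor]:
                oh = coords[h] - o_pos[donor]
                cosang = float(np.dot(oh, oa) / (np.linalg.norm(oh) * np.linalg.norm(oa)))
                if cosang >= cos_max:
                    bonded = True
                    break
            if bonded:
                break
        if bonded:
            bonds.append((int(min(i, j)), int(max(i, j))))
    return sorted(bonds)


def correlation_from_states(
    states: np.ndarray,
    timestep: float,
    max_lag: float | None = None,
    origin_stride: int = 1,
    temperature: float = 0.0,
    criterion: HBondCriterion | None = None,
) -> HBondCorrelation:
    """Intermittent C_H(t) from a (n_frames, n_pairs) bond indicator.

    C_H(t) = Σ h(t₀)h(t₀+t) / Σ h(t₀) over pairs ever bonded and all
    (strided) origins; exactly 1 at t = 0.
    """
    h = np.asarray(states, dtype=float)
    ever = h.any(axis=0)
    if not ever.any():
        raise ValueError("no hydrogen bond was ever formed")
    h = h[:, ever]
    n = h.shape[0]
    n_lags = n // 2 if max_lag is None else min(int(round(max_lag / timestep)) + 1, n)
    c = np.empty(n_lags)
    for lag in range(n_lags):
        origins = np.arange(0, n - lag, origin_stride)
        num = float(np.sum(h[origins] * h[origins + lag]))
        den = float(np.sum(h[origins]))
        c[lag] = num / den if den > 0 else 0.0
    times = np.arange(n_lags) * timestep
    tau = _tau_at_inv_e(times, c)
    return HBondCorrelation(
        times=times, c_h=c, tau_h=tau, criterion=criterion, temperature=temperature
    )


def _tau_at_inv_e(times: np.ndarray, c: np.ndarray) -> float | None:
    """First crossing of 1/e, interpolated linearly in ln C."""
    target = np.exp(-1.0)
    below = np.flatnonzero(c <= target)
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(times[0])
    c0, c1 = c[i - 1], max(c[i], 1e-300)
    f = (np.log(c0) - (-1.0)) / (np.log(c0) - np.log(c1))
    return float(times[i - 1] + f * (times[i] - times[i - 1]))


def hbond_correlation(
    traj: Trajectory,
    atoms: AtomTable,
    criterion: HBondCriterion = HBondCriterion(),
    max_lag: float | None = None,
    origin_stride: int = 1,
) -> HBondCorrelation:
    """Detect bonds per frame, then correlate the indicator."""
    o_idx, _ = _water_molecules(atoms)
    n_w = len(o_idx)
    pair_col: dict[tuple[int, int], int] = {}
    frames_bonds = []
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.positions[f], atoms, criterion)
        for b in bonds:
            if b not in pair_col:
                pair_col[b] = len(pair_col)
        frames_bonds.append(bonds)
    if not pair_col:
        raise ValueError("no hydrogen bond was ever formed")
    states = np.zeros((traj.n_frames, len(pair_col)), dtype=bool)
    for f, bonds in enumerate(frames_bonds):
        for b in bonds:
            states[f, pair_col[b]] = True
    return correlation_from_states(
        states,
        traj.timestep,
        max_lag=max_lag,
        origin_stride=origin_stride,
        temperature=traj.temperature,
        criterion=criterion,
    )


def arrhenius_fit(
    tau_by_t: pd.Series | dict[float, float],
    t_range: tuple[float, float] = (200.0, 290.0),
) -> ArrheniusFit:
    """E_a (kJ/mol) from least squares of ln τ_H against 1/T."""
    s = pd.Series(dict(tau_by_t)) if not isinstance(tau_by_t, pd.Series) else tau_by_t
    s = s.dropna()
    s = s[(s.index >= t_range[0]) & (s.index <= t_range[1])]
    if (s <= 0).any():
        raise ValueError("τ_H must be positive")
    if len(s) < 3:
        raise ValueError(f"Arrhenius fit needs ≥ 3 temperatures in {t_range}, got {len(s)}")
    inv_t = 1.0 / s.index.to_numpy(dtype=float)
    ln_tau = np.log(s.to_numpy(dtype=float))
    res = stats.linregress(inv_t, ln_tau)
    return ArrheniusFit(
        e_a=float(res.slope * R_KJ_PER_MOL_K),
        tau0=float(np.exp(res.intercept)),
        e_a_error=float(res.stderr * R_KJ_PER_MOL_K),
        t_range=t_range,
        n_points=len(s),
    )


def replica_aggregate(values) -> tuple[float, float]:
    """Mean and sample standard deviation over independent replicas."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicas")
    return float(v.mean()), float(v.std(ddof=1))
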
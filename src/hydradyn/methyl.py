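"""Rotational / non-rotational decomposition of methyl-hydrogen MSD.

At a fixed lag (default 1 ns) the methyl-hydrogen displacement is split
into a rotational part — the displacement of the hydrogen position
relative to its methyl carbon, d(t) = r_H(t) − r_C(t), which captures
three-site jumps and any C3-axis reorientation — and a non-rotational
part, the displacement of the carbon itself (the intrinsic mobility of
the group).  The two do not add exactly because displacement is
quadratic; the residual cross term 2⟨Δd·Δr_C⟩ is reported explicitly
so that total = rotational + non_rotational + cross holds as algebra.
All three estimators share one origin set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomTable, Trajectory

__all__ = ["MethylMSDComponents", "rotational_msd", "nonrotational_msd", "decompose"]


@dataclass
class MethylMSDComponents:
    lag: float  # ps
    total: float
    rotational: float
    non_rotational: float
    cross_term: float
    temperature: float

    def __post_init__(self) -> None:
        resid = self.total - (self.rotational + self.non_rotational + self.cross_term)
        if abs(resid) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("components do not sum to the total")


def _methyl_pairs(atoms: AtomTable) -> tuple[np.ndarray, np.ndarray]:
    """(hydrogen_indices, matching_carbon_indices) ordered per group."""
    h_idx = []
    c_idx = []
    gids = np.unique(atoms.methyl_group_id[atoms.methyl_group_id >= 0])
    if gids.size == 0:
        raise ValueError("no classified methyl groups in the atom table")
    for gid in gids:
        members = atoms.methyl_group_id == gid
        c = int(np.flatnonzero(members & atoms.is_methyl_C)[0])
        for h in np.flatnonzero(members & atoms.is_methyl_H):
            h_idx.append(int(h))
            c_idx.append(c)
    return np.array(h_idx), np.array(c_idx)


def _lag_frames(traj: Trajectory, lag: float) -> int:
    m = int(round(lag / traj.timestep))
    if m < 1 or m >= traj.n_frames:
        raise ValueError(
            f"lag {lag} ps outside trajectory span "
            f"(0, {(traj.n_frames - 1) * traj.timestep}] ps"
        )
    return m


def _mean_sq_disp(arr: np.ndarray, m: int, origin_stride: int) -> float:
    origins = np.arange(0, arr.shape[0] - m, origin_stride)
    d = arr[origins + m] - arr[origins]
    return float(np.einsum("omc,omc->", d, d) / (d.shape[0] * d.shape[1]))


def rotational_msd(
    traj: Trajectory, atoms: AtomTable, lag: float = 1000.0, origin_stride: int = 1
) -> float:
    """MSD of the carbon-relative hydrogen vector at the given lag (Ų)."""
    m = _lag_frames(traj, lag)
    h_idx, c_idx = _methyl_pairs(atoms)
    rel = traj.positions[:, h_idx, :] - traj.positions[:, c_idx, :]
    return _mean_sq_disp(rel, m, origin_stride)


def nonrotational_msd(
    traj: Trajectory, atoms: AtomTable, lag: float = 1000.0, origin_stride: int = 1
) -> float:
    """MSD of the methyl carbon atoms at the given lag (Ų)."""
    m = _lag_frames(traj, lag)
    c_only = np.flatnonzero(atoms.is_methyl_C)
    if c_only.size == 0:
        raise ValueError("no methyl carbons in the atom table")
    return _mean_sq_disp(traj.positions[:, c_only, :], m, origin_stride)


def decompose(
    traj: Trajectory, atoms: AtomTable, lag: float = 1000.0, origin_stride: int = 1
) -> MethylMSDComponents:
    """Total / rotational / non-rotational methyl-H MSD at one lag.

    All three quantities use the same origins, and the carbon MSD is
    averaged per hydrogen (each H paired with its own carbon), so the
    identity total = rot + nonrot + cross is exact.
    """
    m = _lag_frames(traj, lag)
    h_idx, c_idx = _methyl_pairs(atoms)
    origins = np.arange(0, traj.n_frames - m, origin_stride)

    r_h = traj.positions[:, h_idx, :]
    r_c = traj.positions[:, c_idx, :]
    dh = r_h[origins + m] - r_h[origins]
    dc = r_c[origins + m] - r_c[origins]
    drel = dh - dc
    norm = dh.shape[0] * dh.shape[1]
    total = float(np.einsum("omc,omc->", dh, dh) / norm)
    rot = float(np.einsum("omc,omc->", drel, drel) / norm)
    nonrot = float(np.einsum("omc,omc->", dc, dc) / norm)
    cross = total - rot - nonrot
    return MethylMSDComponents(
        lag=m * traj.timestep,
        total=total,
        rotational=rot,
        non_rotational=nonrot,
        cross_term=cross,
        temperature=traj.temperature,
    )
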
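"""Radial density profiles relative to the assembly centre of mass.

For a hollow, vacuum-suspended assembly there is no bulk density to
normalise against, so the "RDF" here is the shell-volume-normalised
radial number density n(r) = count / (4πr²Δr), frame-averaged, with the
mass-weighted COM of a reference selection (the whole protein by
default) as origin.  Radii are reported in nm.  The cavity radius is
the innermost radius where the density first rises above a small
fraction of its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtomTable, Trajectory
from .units import ANGSTROM_PER_NM

__all__ = [
    "RDFProfile",
    "com_rdf",
    "cavity_radius",
    "subset_rdf_report",
    "profile_overlap",
    "standard_subsets",
]


@dataclass
class RDFProfile:
    r_bins: np.ndarray  # bin centres, nm
    density: np.ndarray  # counts · nm⁻³
    bin_width: float  # nm
    selection_label: str = ""
    temperature: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("negative density")
        widths = np.diff(self.r_bins)
        if widths.size and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")

    @property
    def counts(self) -> np.ndarray:
        """Frame-averaged per-bin counts (density × shell volume)."""
        return self.density * 4.0 * np.pi * self.r_bins**2 * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r_bins, "density": self.density})


def com_rdf(
    traj: Trajectory,
    atoms: AtomTable,
    selection: np.ndarray,
    reference_selection: np.ndarray | None = None,
    bin_width: float = 0.05,
    r_max: float | None = None,
    label: str = "",
) -> RDFProfile:
    """Radial number density of ``selection`` about the reference COM.

    ``bin_width`` and the returned grid are in nm; the COM is recomputed
    per frame from the mass-weighted reference selection (protein by
    default).
    """
    selection = np.asarray(selection)
    if reference_selection is None:
        reference_selection = atoms.protein
    if not np.any(selection) or not np.any(reference_selection):
        raise ValueError("empty selection")
    masses = atoms.mass[reference_selection]
    if masses.sum() <= 0:
        raise ValueError("reference selection has zero mass")

    if r_max is None:
        # generous upper bound from the first frame
        com0 = np.average(
            traj.positions[0, reference_selection], axis=0, weights=masses
        )
        d0 = np.linalg.norm(traj.positions[0, selection] - com0, axis=1)
        r_max = (d0.max() / ANGSTROM_PER_NM) * 1.25 + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for f in range(traj.n_frames):
        com = np.average(
            traj.positions[f, reference_selection], axis=0, weights=masses
        )
        d = np.linalg.norm(traj.positions[f, selection] - com, axis=1) / ANGSTROM_PER_NM
        hist += np.histogram(d, bins=edges)[0]
    hist /= traj.n_frames
    centres = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centres**2 * bin_width
    return RDFProfile(
        r_bins=centres,
        density=hist / shell,
        bin_width=bin_width,
        selection_label=label,
        temperature=traj.temperature,
    )


def cavity_radius(profile: RDFProfile, threshold_fraction: float = 0.05) -> float:
    """Innermost radius (nm) where density first exceeds the threshold.

    The threshold is ``threshold_fraction`` of the profile maximum;
    the crossing is linearly interpolated between bin centres.
    """
    d = profile.density
    peak = d.max()
    if peak <= 0:
        raise ValueError("all-zero radial profile")
    thr = threshold_fraction * peak
    above = np.flatnonzero(d > thr)
    i = above[0]
    if i == 0:  # density present from the first bin: no cavity
        return 0.0
    r0, r1 = profile.r_bins[i - 1], profile.r_bins[i]
    d0, d1 = d[i - 1], d[i]
    return float(r0 + (thr - d0) / (d1 - d0) * (r1 - r0))


def standard_subsets(atoms: AtomTable) -> dict[str, np.ndarray]:
    """Residue-level methyl / non-methyl partition plus water oxygens.

    Residue-to-subset assignment is by whole residue: every atom of a
    methyl-bearing residue counts as 'methyl_residues'.
    """
    from .templates import METHYL_RESIDUES

    is_methyl_res = np.array(
        [str(r).upper() in METHYL_RESIDUES for r in atoms.residue_name]
    )
    out = {
        "methyl_residues": atoms.protein & is_methyl_res,
        "non_methyl_residues": atoms.protein & ~is_methyl_res,
    }
    if np.any(atoms.water_O):
        out["water_O"] = atoms.water_O
    return out


def subset_rdf_report(
    traj: Trajectory,
    atoms: AtomTable,
    subsets: dict[str, np.ndarray] | None = None,
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> list[RDFProfile]:
    """One COM-referenced profile per subset, on a shared r-grid."""
    if subsets is None:
        subsets = standard_subsets(atoms)
    for name, mask in subsets.items():
        if not np.any(mask):
            raise ValueError(f"subset {name!r} selects no atoms")
    if r_max is None:
        ref = atoms.protein
        masses = atoms.mass[ref]
        com0 = np.average(traj.positions[0, ref], axis=0, weights=masses)
        r_max = 0.0
        for mask in subsets.values():
            d0 = np.linalg.norm(traj.positions[0, mask] - com0, axis=1)
            r_max = max(r_max, d0.max() / ANGSTROM_PER_NM)
        r_max = r_max * 1.25 + bin_width
    return [
        com_rdf(traj, atoms, mask, bin_width=bin_width, r_max=r_max, label=name)
        for name, mask in subsets.items()
    ]


def profile_overlap(p1: RDFProfile, p2: RDFProfile) -> float:
    """Overlap coefficient Σ min(n̂₁, n̂₂) of unit-normalised profiles.

    Profiles are converted to per-bin probability masses (density ×
    shell volume, normalised to one) before taking the bin-wise min;
    identical shapes give 1, disjoint supports 0.
    """
    if len(p1.r_bins) != len(p2.r_bins) or not np.allclose(p1.r_bins, p2.r_bins):
        raise ValueError("profiles are not on a shared r-grid")
    w1, w2 = p1.counts, p2.counts
    if w1.sum() <= 0 or w2.sum() <= 0:
        raise ValueError("cannot normalise an empty profile")
    return float(np.minimum(w1 / w1.sum(), w2 / w2.sum()).sum())
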
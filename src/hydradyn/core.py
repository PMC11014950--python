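"""Domain types, structure/trajectory ingestion and composition bookkeeping.

The two central containers are :class:`Trajectory` (a dense
``(n_frames, n_atoms, 3)`` coordinate array in Å with a timestep in ps
and a temperature label) and :class:`AtomTable` (per-atom metadata:
element, residue, subunit, protein/water/ion role, methyl and
exchangeable-hydrogen flags).  Structure and trajectory files are read
through MDAnalysis; nothing here modifies coordinates (in particular no
centre-of-mass removal is applied on load).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .templates import (
    ION_NAMES,
    METHYL_CARBONS,
    METHYL_RESIDUES,
    WATER_RESNAMES,
)
from .units import D2O_MOLAR_MASS

__all__ = [
    "Trajectory",
    "AtomTable",
    "SystemComposition",
    "load_structure",
    "load_trajectory",
    "infer_bonds",
    "classify_methyls",
    "classify_exchangeable",
    "methyl_hydrogen_fraction",
    "composition_summary",
    "composition_from_counts",
]

_ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "ZN": 65.38, "FE": 55.845,
}


# ---------------------------------------------------------------------------
# containers


@dataclass
class Trajectory:
    """Time-ordered coordinate frames of one system.

    positions : (n_frames, n_atoms, 3) float64, Å
    timestep  : frame spacing, ps
    temperature : thermostat label, K
    box       : optional (3,) orthorhombic box lengths, Å
    unwrapped : True when coordinates are continuous (no PBC jumps);
                MSD estimators refuse wrapped trajectories.
    """

    positions: np.ndarray
    timestep: float
    temperature: float
    box: np.ndarray | None = None
    unwrapped: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.timestep <= 0:
            raise ValueError(f"timestep must be positive, got {self.timestep}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.timestep

    def slice_atoms(self, mask: np.ndarray) -> "Trajectory":
        return replace(self, positions=self.positions[:, mask, :])


@dataclass
class AtomTable:
    """Per-atom metadata aligned with trajectory columns.

    ``methyl_group_id`` is -1 for atoms outside any CH₃ group; each
    group id maps to exactly one carbon and three hydrogens.
    """

    element: np.ndarray
    mass: np.ndarray
    name: np.ndarray
    residue_name: np.ndarray
    residue_index: np.ndarray
    subunit_id: np.ndarray
    role: np.ndarray  # 'protein' | 'water' | 'ion'
    is_hydrogen: np.ndarray
    is_methyl_H: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_methyl_C: np.ndarray = field(default=None)  # type: ignore[assignment]
    methyl_group_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_exchangeable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.element)
        self.element = np.asarray(self.element, dtype=object)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        self.name = np.asarray(self.name, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.subunit_id = np.asarray(self.subunit_id, dtype=np.int64)
        self.role = np.asarray(self.role, dtype=object)
        self.is_hydrogen = np.asarray(self.is_hydrogen, dtype=bool)
        for attr, fill in (
            ("is_methyl_H", False),
            ("is_methyl_C", False),
            ("is_exchangeable", False),
        ):
            v = getattr(self, attr)
            setattr(
                self,
                attr,
                np.full(n, fill) if v is None else np.asarray(v, dtype=bool),
            )
        if self.methyl_group_id is None:
            self.methyl_group_id = np.full(n, -1, dtype=np.int64)
        else:
            self.methyl_group_id = np.asarray(self.methyl_group_id, dtype=np.int64)
        for attr in (
            "mass", "name", "residue_name", "residue_index", "subunit_id",
            "role", "is_hydrogen", "is_methyl_H", "is_methyl_C",
            "methyl_group_id", "is_exchangeable",
        ):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"field {attr} length mismatch")
        self.validate()

    def __len__(self) -> int:
        return len(self.element)

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    # convenience masks ----------------------------------------------------
    @property
    def protein(self) -> np.ndarray:
        return self.role == "protein"

    @property
    def water(self) -> np.ndarray:
        return self.role == "water"

    @property
    def ion(self) -> np.ndarray:
        return self.role == "ion"

    @property
    def protein_H(self) -> np.ndarray:
        return self.protein & self.is_hydrogen

    @property
    def methyl_H(self) -> np.ndarray:
        return self.is_methyl_H

    @property
    def non_methyl_H(self) -> np.ndarray:
        return self.protein_H & ~self.is_methyl_H

    @property
    def water_O(self) -> np.ndarray:
        return self.water & (self.element == "O")

    def validate(self) -> None:
        if np.any(self.is_methyl_H & ~self.is_hydrogen):
            raise ValueError("is_methyl_H set on a non-hydrogen atom")
        if np.any(self.is_methyl_H & (self.role != "protein")):
            raise ValueError("is_methyl_H set outside the protein")
        if np.any(self.is_exchangeable & ~self.is_hydrogen):
            raise ValueError("is_exchangeable set on a non-hydrogen atom")
        gids = self.methyl_group_id[self.methyl_group_id >= 0]
        for gid in np.unique(gids):
            members = self.methyl_group_id == gid
            n_c = int(np.sum(members & self.is_methyl_C))
            n_h = int(np.sum(members & self.is_methyl_H))
            if n_c != 1 or n_h != 3:
                raise ValueError(
                    f"methyl group {gid} has {n_c} carbons and {n_h} hydrogens"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": self.element,
                "mass": self.mass,
                "name": self.name,
                "residue_name": self.residue_name,
                "residue_index": self.residue_index,
                "subunit_id": self.subunit_id,
                "role": self.role,
                "is_hydrogen": self.is_hydrogen,
                "is_methyl_H": self.is_methyl_H,
                "is_methyl_C": self.is_methyl_C,
                "methyl_group_id": self.methyl_group_id,
                "is_exchangeable": self.is_exchangeable,
            }
        )

    def subset(self, mask: np.ndarray) -> "AtomTable":
        mask = np.asarray(mask)
        return AtomTable(
            element=self.element[mask],
            mass=self.mass[mask],
            name=self.name[mask],
            residue_name=self.residue_name[mask],
            residue_index=self.residue_index[mask],
            subunit_id=self.subunit_id[mask],
            role=self.role[mask],
            is_hydrogen=self.is_hydrogen[mask],
            is_methyl_H=self.is_methyl_H[mask],
            is_methyl_C=self.is_methyl_C[mask],
            methyl_group_id=self.methyl_group_id[mask],
            is_exchangeable=self.is_exchangeable[mask],
        )


@dataclass
class SystemComposition:
    """Counts and hydration bookkeeping of one simulated system."""

    n_subunits: int
    residues_per_subunit: int
    n_water: int
    n_ions: int
    total_atoms: int
    subunit_mass: float  # Da
    water_molar_mass: float = D2O_MOLAR_MASS
    h: float = 0.0  # g water per g protein
    waters_per_residue: float = 0.0

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


# ---------------------------------------------------------------------------
# structure / trajectory ingestion


def _guess_element(name: str, resname: str) -> str:
    name = name.strip()
    if resname.upper() in ION_NAMES or name.upper() in ION_NAMES:
        return name.upper().rstrip("+-0123456789")
    # PDB convention: element is the first letter once leading digits are
    # stripped; two-letter organic elements do not occur in proteins/water
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _roles_from_names(resnames: np.ndarray, names: np.ndarray) -> np.ndarray:
    roles = np.full(len(resnames), "protein", dtype=object)
    for i, (rn, an) in enumerate(zip(resnames, names)):
        rn_u = str(rn).upper()
        if rn_u in WATER_RESNAMES:
            roles[i] = "water"
        elif rn_u in ION_NAMES or (rn_u == str(an).upper() and rn_u in ION_NAMES):
            roles[i] = "ion"
    return roles


def _table_from_universe(u) -> AtomTable:
    ag = u.atoms
    names = np.array([a.name for a in ag], dtype=object)
    resnames = np.array([a.resname for a in ag], dtype=object)
    try:
        elements = np.array([str(e).upper() for e in ag.elements], dtype=object)
        if any(e in ("", "X") for e in elements):
            raise AttributeError
    except Exception:
        elements = np.array(
            [_guess_element(n, r) for n, r in zip(names, resnames)], dtype=object
        )
    masses = np.array(
        [_ELEMENT_MASSES.get(e, _ELEMENT_MASSES.get(e[:1], 0.0)) for e in elements]
    )
    resids = np.array([a.resid for a in ag], dtype=np.int64)
    segids = [getattr(a, "chainID", "") or getattr(a, "segid", "") for a in ag]
    uniq = {s: i for i, s in enumerate(dict.fromkeys(segids))}
    subunits = np.array([uniq[s] for s in segids], dtype=np.int64)
    roles = _roles_from_names(resnames, names)
    is_h = np.array([e in ("H", "D") for e in elements])
    return AtomTable(
        element=elements,
        mass=masses,
        name=names,
        residue_name=resnames,
        residue_index=resids,
        subunit_id=subunits,
        role=roles,
        is_hydrogen=is_h,
    )


def _parse_biomt(path: Path) -> dict[str, list[np.ndarray]]:
    """REMARK 350 biomolecule operators: {assembly_id: [4x4 matrices]}."""
    ops: dict[str, list[np.ndarray]] = {}
    current = None
    rows: dict[int, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("REMARK 350"):
                continue
            if "BIOMOLECULE:" in line:
                current = line.split("BIOMOLECULE:")[1].strip()
                ops[current] = []
                rows = {}
            elif line[13:18] == "BIOMT" and current is not None:
                axis = int(line[18]) - 1  # 1..3
                serial = int(line[19:23])
                vals = [float(x) for x in line[23:].split()]
                rows.setdefault(serial, [None, None, None])  # type: ignore[arg-type]
                rows[serial][axis] = vals
                if axis == 2 and all(r is not None for r in rows[serial]):
                    m = np.eye(4)
                    for ax in range(3):
                        m[ax, :3] = rows[serial][ax][:3]
                        m[ax, 3] = rows[serial][ax][3]
                    ops[current].append(m)
    return ops


def load_structure(
    path: str | Path,
    assembly: str | None = None,
    *,
    allow_empty_protein: bool = False,
):
    """Read a PDB file into a one-frame :class:`Trajectory` + :class:`AtomTable`.

    ``assembly=None`` keeps the asymmetric unit; ``assembly="1"`` applies
    the REMARK 350 BIOMT operators of biomolecule 1, replicating every
    chain per operator (each copy becomes its own subunit).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    table = _table_from_universe(u)
    coords = u.atoms.positions.astype(np.float64)

    if assembly is not None:
        ops = _parse_biomt(path)
        if str(assembly) not in ops or not ops[str(assembly)]:
            raise ValueError(
                f"assembly {assembly!r} not present in {path.name}; "
                f"available: {sorted(ops)}"
            )
        mats = ops[str(assembly)]
        n = len(table)
        new_coords = []
        tables = []
        for k, m in enumerate(mats):
            xyz = coords @ m[:3, :3].T + m[:3, 3]
            new_coords.append(xyz)
            t = table.subset(np.ones(n, dtype=bool))
            t.subunit_id = t.subunit_id + k * (table.subunit_id.max() + 1)
            tables.append(t)
        coords = np.concatenate(new_coords, axis=0)
        table = _concat_tables(tables)

    if not allow_empty_protein and not np.any(table.protein):
        raise ValueError(
            f"{path.name} contains zero protein atoms "
            "(pass allow_empty_protein=True to accept)"
        )
    traj = Trajectory(
        positions=coords[None, :, :], timestep=1.0, temperature=300.0, unwrapped=True
    )
    return traj, table


def _concat_tables(tables: Sequence[AtomTable]) -> AtomTable:
    cat = lambda attr: np.concatenate([getattr(t, attr) for t in tables])
    return AtomTable(
        element=cat("element"),
        mass=cat("mass"),
        name=cat("name"),
        residue_name=cat("residue_name"),
        residue_index=cat("residue_index"),
        subunit_id=cat("subunit_id"),
        role=cat("role"),
        is_hydrogen=cat("is_hydrogen"),
        is_methyl_H=cat("is_methyl_H"),
        is_methyl_C=cat("is_methyl_C"),
        methyl_group_id=cat("methyl_group_id"),
        is_exchangeable=cat("is_exchangeable"),
    )


def load_trajectory(
    path: str | Path,
    topology: AtomTable | str | Path,
    *,
    timestep: float | None = None,
    temperature: float = 300.0,
    unwrapped: bool = True,
) -> Trajectory:
    """Read a trajectory file (XYZ, DCD, ... anything MDAnalysis reads).

    ``topology`` is either an :class:`AtomTable` (atom count checked) or a
    structure file path.  Coordinates are taken verbatim — no wrapping,
    unwrapping or COM removal.
    """
    import MDAnalysis as mda

    path = Path(path)
    if isinstance(topology, (str, Path)):
        _, table = load_structure(topology, allow_empty_protein=True)
    else:
        table = topology
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(len(table), trajectory=True)
        u.load_new(str(path))
        n_file = u.trajectory.n_atoms if hasattr(u.trajectory, "n_atoms") else len(u.atoms)
        if n_file != len(table):
            raise ValueError(
                f"atom-count mismatch: trajectory has {n_file} atoms, "
                f"topology has {len(table)}"
            )
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64)
        dt_file = getattr(u.trajectory, "dt", None)
    dt = timestep if timestep is not None else (dt_file or 1.0)
    return Trajectory(
        positions=frames,
        timestep=float(dt),
        temperature=temperature,
        unwrapped=unwrapped,
    )


# ---------------------------------------------------------------------------
# classification


def infer_bonds(
    coords: np.ndarray, table: AtomTable, *, h_cutoff: float = 1.25
) -> np.ndarray:
    """Hydrogen—heavy-atom bonds by proximity.

    Each hydrogen is bonded to the nearest heavy atom within
    ``h_cutoff`` Å (robust for idealised H placement).  Returns an
    (n_bonds, 2) array of (hydrogen_index, heavy_index).
    """
    coords = np.asarray(coords, dtype=float)
    heavy_idx = np.flatnonzero(~table.is_hydrogen)
    h_idx = np.flatnonzero(table.is_hydrogen)
    if len(heavy_idx) == 0 or len(h_idx) == 0:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(coords[heavy_idx])
    dist, nearest = tree.query(coords[h_idx], k=1)
    keep = dist <= h_cutoff
    return np.column_stack([h_idx[keep], heavy_idx[nearest[keep]]]).astype(np.int64)


def classify_methyls(
    table: AtomTable,
    bonds: np.ndarray | None = None,
    coords: np.ndarray | None = None,
) -> AtomTable:
    """Flag CH₃ carbons and hydrogens of Ala/Val/Leu/Ile/Thr/Met.

    ``bonds`` is an (n, 2) array of (hydrogen, heavy) index pairs; when
    absent it is inferred from ``coords`` by proximity.  A candidate
    methyl carbon with a hydrogen count other than three is skipped with
    a warning.
    """
    if bonds is None:
        if coords is None:
            raise ValueError("need either bonds or coordinates to classify methyls")
        bonds = infer_bonds(coords, table)
    h_of_heavy: dict[int, list[int]] = {}
    for h, heavy in np.asarray(bonds, dtype=np.int64):
        h_of_heavy.setdefault(int(heavy), []).append(int(h))

    out = table.subset(np.ones(len(table), dtype=bool))
    out.is_methyl_H[:] = False
    out.is_methyl_C[:] = False
    out.methyl_group_id[:] = -1
    gid = 0
    for c in np.flatnonzero((out.element == "C") & out.protein):
        key = (str(out.residue_name[c]).upper(), str(out.name[c]).upper())
        if key not in METHYL_CARBONS:
            continue
        hs = h_of_heavy.get(int(c), [])
        if len(hs) != 3:
            warnings.warn(
                f"methyl carbon {out.name[c]} of {out.residue_name[c]} "
                f"{out.residue_index[c]} has {len(hs)} bonded hydrogens; skipped"
            )
            continue
        out.is_methyl_C[c] = True
        out.methyl_group_id[c] = gid
        for h in hs:
            out.is_methyl_H[h] = True
            out.methyl_group_id[h] = gid
        gid += 1
    out.validate()
    return out


def classify_exchangeable(
    table: AtomTable,
    bonds: np.ndarray | None = None,
    coords: np.ndarray | None = None,
) -> AtomTable:
    """Flag hydrogens bonded to N, O or S as exchangeable."""
    if bonds is None:
        if coords is None:
            raise ValueError("need either bonds or coordinates")
        bonds = infer_bonds(coords, table)
    out = table.subset(np.ones(len(table), dtype=bool))
    out.is_exchangeable[:] = False
    for h, heavy in np.asarray(bonds, dtype=np.int64):
        if out.element[heavy] in ("N", "O", "S"):
            out.is_exchangeable[h] = True
    out.validate()
    return out


def methyl_hydrogen_fraction(table: AtomTable) -> float:
    """Percentage of methyl hydrogens among all protein hydrogens."""
    n_h = int(np.sum(table.protein_H))
    if n_h == 0:
        raise ValueError("no protein hydrogens in the system")
    return 100.0 * int(np.sum(table.is_methyl_H)) / n_h


# ---------------------------------------------------------------------------
# composition


def composition_from_counts(
    *,
    n_subunits: int,
    residues_per_subunit: int,
    n_water: int,
    n_ions: int,
    subunit_mass: float,
    water_molar_mass: float = D2O_MOLAR_MASS,
    total_atoms: int | None = None,
    protein_atoms: int | None = None,
) -> SystemComposition:
    """Composition bookkeeping from explicit counts.

    h = n_water · M_water / (n_subunits · subunit_mass); waters per
    residue = n_water / (n_subunits · residues_per_subunit).  When both
    ``total_atoms`` and ``protein_atoms`` are given the identity
    protein + 3·water + ions = total is enforced.
    """
    protein_mass = n_subunits * subunit_mass
    if protein_mass <= 0:
        raise ValueError("zero protein mass")
    if total_atoms is not None and protein_atoms is not None:
        expected = protein_atoms + 3 * n_water + n_ions
        if expected != total_atoms:
            raise ValueError(
                "inconsistent atom totals: "
                f"protein {protein_atoms} + 3×water {n_water} + ions {n_ions} "
                f"= {expected} ≠ total {total_atoms}"
            )
    if total_atoms is None:
        total_atoms = (protein_atoms or 0) + 3 * n_water + n_ions
    n_res = n_subunits * residues_per_subunit
    return SystemComposition(
        n_subunits=n_subunits,
        residues_per_subunit=residues_per_subunit,
        n_water=n_water,
        n_ions=n_ions,
        total_atoms=int(total_atoms),
        subunit_mass=subunit_mass,
        water_molar_mass=water_molar_mass,
        h=n_water * water_molar_mass / protein_mass,
        waters_per_residue=(n_water / n_res) if n_res else 0.0,
    )


def composition_summary(
    table: AtomTable,
    subunit_mass: float | None = None,
    water_molar_mass: float = D2O_MOLAR_MASS,
) -> SystemComposition:
    """Derive a :class:`SystemComposition` from an :class:`AtomTable`."""
    protein = table.protein
    if not np.any(protein):
        raise ValueError("zero protein atoms")
    sub_ids = np.unique(table.subunit_id[protein])
    n_subunits = len(sub_ids)
    # residues per subunit from the first subunit
    first = protein & (table.subunit_id == sub_ids[0])
    residues_per_subunit = len(np.unique(table.residue_index[first]))
    n_water = int(np.sum(table.water)) // 3
    n_ions = int(np.sum(table.ion))
    if subunit_mass is None:
        subunit_mass = float(np.sum(table.mass[protein])) / n_subunits
    return composition_from_counts(
        n_subunits=n_subunits,
        residues_per_subunit=residues_per_subunit,
        n_water=n_water,
        n_ions=n_ions,
        subunit_mass=subunit_mass,
        water_molar_mass=water_molar_mass,
        total_atoms=len(table),
        protein_atoms=int(np.sum(protein)),
    )
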
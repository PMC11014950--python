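"""Plain-text structure/trajectory writers and tabular output.

Two trajectory formats are emitted: a multi-frame XYZ dialect (element
symbol + three coordinates in Å, one block per frame — readable by
MDAnalysis and most viewers) and, through MDAnalysis, the binary DCD
format.  A YAML manifest records generator ground truth and seeds next
to every written trajectory set.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import AtomTable, Trajectory

_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_xyz(traj: Trajectory, table: AtomTable, path: str | Path) -> Path:
    """Multi-frame XYZ with %.3f coordinates (round-trips to 1e-3 Å)."""
    path = Path(path)
    n = traj.n_atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"frame {f} t={f * traj.timestep:.3f} ps T={traj.temperature:g} K\n")
            for el, (x, y, z) in zip(table.element, traj.positions[f]):
                fh.write(f"{el:<2s} {x:12.3f} {y:12.3f} {z:12.3f}\n")
    return path


def write_pdb(table: AtomTable, coords: np.ndarray, path: str | Path) -> Path:
    """Single-frame PDB (ATOM/HETATM records only)."""
    path = Path(path)
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for i in range(len(table)):
            rec = "ATOM  " if table.role[i] == "protein" else "HETATM"
            chain = _CHAINS[int(table.subunit_id[i]) % len(_CHAINS)]
            name = str(table.name[i])
            name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = coords[i]
            fh.write(
                f"{rec}{(i % 99999) + 1:5d} {name_f} {str(table.residue_name[i])[:3]:<3s} "
                f"{chain}{int(table.residue_index[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{str(table.element[i])[:2]:>2s}\n"
            )
        fh.write("END\n")
    return path


def write_dcd(traj: Trajectory, path: str | Path) -> Path:
    """Binary DCD trajectory via MDAnalysis."""
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[f].astype(np.float32)
            w.write(u.atoms)
    return path


def write_manifest(path: str | Path, payload: Mapping[str, Any]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=False)
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_tsv(
    path: str | Path, df: pd.DataFrame, meta: Mapping[str, Any] | None = None
) -> Path:
    """TSV with '# key: value' header lines for run provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def config_hash(payload: Mapping[str, Any]) -> str:
    blob = yaml.safe_dump(_plain(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
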
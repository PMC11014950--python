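"""Shared fixtures: tiny hand-built structures with known topology."""

from __future__ import annotations

import numpy as np
import pytest

from hydradyn.core import AtomTable

# idealised alanine with explicit hydrogens; H within 1.25 Å of its heavy atom
ALA_ATOMS = [
    # name, element, xyz
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.50, 0.86, 0.00)),
    ("CA", "C", (1.45, 0.00, 0.00)),
    ("HA", "H", (0.95, 0.55, -0.85)),
    ("CB", "C", (2.00, -1.30, 0.50)),
    ("HB1", "H", (3.00, -1.30, 0.80)),
    ("HB2", "H", (1.30, -2.00, 0.80)),
    ("HB3", "H", (2.00, -1.90, -0.30)),
    ("C", "C", (2.20, 1.20, 0.00)),
    ("O", "O", (3.40, 1.20, 0.20)),
]

GLY_ATOMS = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.50, 0.86, 0.00)),
    ("CA", "C", (1.45, 0.00, 0.00)),
    ("HA2", "H", (1.45, 1.05, 0.30)),
    ("HA3", "H", (1.45, -0.60, 0.90)),
    ("C", "C", (2.20, 1.20, 0.00)),
    ("O", "O", (3.40, 1.20, 0.20)),
]

# valine side chain fragment: CB-H plus two methyls
VAL_ATOMS = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.50, 0.86, 0.00)),
    ("CA", "C", (1.45, 0.00, 0.00)),
    ("HA", "H", (0.95, 0.55, -0.85)),
    ("CB", "C", (2.10, -1.35, 0.00)),
    ("HB", "H", (1.60, -2.25, 0.30)),
    ("CG1", "C", (3.55, -1.30, 0.55)),
    ("HG11", "H", (4.10, -0.55, 0.05)),
    ("HG12", "H", (4.05, -2.25, 0.40)),
    ("HG13", "H", (3.50, -1.10, 1.60)),
    ("CG2", "C", (2.15, -1.80, -1.45)),
    ("HG21", "H", (1.15, -1.85, -1.85)),
    ("HG22", "H", (2.65, -1.10, -2.10)),
    ("HG23", "H", (2.65, -2.75, -1.55)),
    ("C", "C", (2.20, 1.20, 0.00)),
    ("O", "O", (3.40, 1.20, 0.20)),
]

# serine: hydroxyl + amide hydrogens exchangeable
SER_ATOMS = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.50, 0.86, 0.00)),
    ("CA", "C", (1.45, 0.00, 0.00)),
    ("HA", "H", (0.95, 0.55, -0.85)),
    ("CB", "C", (2.10, -1.35, 0.00)),
    ("HB2", "H", (1.60, -2.20, 0.40)),
    ("HB3", "H", (2.20, -1.55, -1.05)),
    ("OG", "O", (3.40, -1.30, 0.60)),
    ("HG", "H", (3.90, -2.10, 0.50)),
    ("C", "C", (2.20, 1.20, 0.00)),
    ("O", "O", (3.40, 1.20, 0.20)),
]

LEU_ATOMS = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.50, 0.86, 0.00)),
    ("CA", "C", (1.45, 0.00, 0.00)),
    ("HA", "H", (0.95, 0.55, -0.85)),
    ("CB", "C", (2.10, -1.35, 0.00)),
    ("HB2", "H", (1.60, -2.20, 0.40)),
    ("HB3", "H", (2.20, -1.55, -1.05)),
    ("CG", "C", (3.50, -1.30, 0.65)),
    ("HG", "H", (3.40, -1.00, 1.70)),
    ("CD1", "C", (4.50, -0.35, -0.05)),
    ("HD11", "H", (4.60, 0.55, 0.55)),
    ("HD12", "H", (5.45, -0.30, 0.50)),
    ("HD13", "H", (4.70, -0.75, -1.05)),
    ("CD2", "C", (4.10, -2.70, 0.70)),
    ("HD21", "H", (3.40, -3.40, 1.15)),
    ("HD22", "H", (5.00, -2.70, 1.30)),
    ("HD23", "H", (4.35, -3.05, -0.30)),
    ("C", "C", (2.20, 1.20, 0.00)),
    ("O", "O", (3.40, 1.20, 0.20)),
]

WATER_ATOMS = [
    ("OW", "O", (0.0, 0.0, 0.0)),
    ("HW1", "H", (0.96, 0.0, 0.0)),
    ("HW2", "H", (-0.28, 0.92, 0.0)),
]

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def build_residues(residues, waters=0, water_offset=20.0):
    """(AtomTable, coords) from [(resname, atom_list), ...] plus waters."""
    names, elements, resnames, resids, roles, xyz = [], [], [], [], [], []
    for i, (resname, atoms) in enumerate(residues):
        for name, el, pos in atoms:
            names.append(name)
            elements.append(el)
            resnames.append(resname)
            resids.append(i + 1)
            roles.append("protein")
            xyz.append(np.asarray(pos) + np.array([6.0 * i, 0.0, 0.0]))
    n_res = len(residues)
    for w in range(waters):
        for name, el, pos in WATER_ATOMS:
            names.append(name)
            elements.append(el)
            resnames.append("HOH")
            resids.append(n_res + 1 + w)
            roles.append("water")
            xyz.append(np.asarray(pos) + np.array([water_offset + 5.0 * w, 10.0, 0.0]))
    elements = np.array(elements, dtype=object)
    table = AtomTable(
        element=elements,
        mass=np.array([_MASSES[e] for e in elements]),
        name=np.array(names, dtype=object),
        residue_name=np.array(resnames, dtype=object),
        residue_index=np.array(resids),
        subunit_id=np.zeros(len(names), dtype=int),
        role=np.array(roles, dtype=object),
        is_hydrogen=elements == "H",
    )
    return table, np.array(xyz, dtype=float)


@pytest.fixture
def ala_water_pdb(tmp_path):
    """PDB of one alanine + 3 waters with a 2-copy BIOMT assembly."""
    from hydradyn.io import write_pdb

    table, coords = build_residues([("ALA", ALA_ATOMS)], waters=3)
    path = tmp_path / "ala.pdb"
    write_pdb(table, coords, path)
    body = path.read_text()
    biomt = (
        "REMARK 350 BIOMOLECULE: 1\n"
        "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000\n"
        "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000\n"
        "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000\n"
        "REMARK 350   BIOMT1   2  1.000000  0.000000  0.000000       50.00000\n"
        "REMARK 350   BIOMT2   2  0.000000  1.000000  0.000000        0.00000\n"
        "REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000\n"
    )
    path.write_text(biomt + body)
    return path
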
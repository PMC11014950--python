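"""Structure ingestion, atom classification and composition bookkeeping."""

import numpy as np
import pytest

from hydradyn.core import (
    AtomTable,
    classify_exchangeable,
    classify_methyls,
    composition_from_counts,
    composition_summary,
    infer_bonds,
    load_structure,
    load_trajectory,
    methyl_hydrogen_fraction,
)
from hydradyn.templates import methyl_fraction_from_sequence, sequence_hydrogen_counts

from conftest import (
    ALA_ATOMS,
    GLY_ATOMS,
    LEU_ATOMS,
    SER_ATOMS,
    VAL_ATOMS,
    build_residues,
)


class TestLoadStructure:
    def test_asymmetric_unit(self, ala_water_pdb):
        traj, table = load_structure(ala_water_pdb)
        assert traj.n_frames == 1
        assert int(np.sum(table.protein)) == len(ALA_ATOMS)
        assert int(np.sum(table.water)) == 9  # 3 waters x 3 atoms

    def test_assembly_expansion_doubles_atoms(self, ala_water_pdb):
        traj1, t1 = load_structure(ala_water_pdb)
        traj2, t2 = load_structure(ala_water_pdb, assembly="1")
        assert len(t2) == 2 * len(t1)
        assert len(np.unique(t2.subunit_id)) == 2
        # second copy translated by +50 in x
        shift = traj2.positions[0, len(t1) :, 0] - traj2.positions[0, : len(t1), 0]
        assert np.allclose(shift, 50.0, atol=1e-3)

    def test_missing_assembly_raises(self, ala_water_pdb):
        with pytest.raises(ValueError, match="assembly"):
            load_structure(ala_water_pdb, assembly="9")

    def test_waters_only_requires_flag(self, tmp_path):
        from hydradyn.io import write_pdb

        table, coords = build_residues([], waters=3)
        path = tmp_path / "w.pdb"
        write_pdb(table, coords, path)
        with pytest.raises(ValueError, match="zero protein"):
            load_structure(path)
        _, t = load_structure(path, allow_empty_protein=True)
        assert int(np.sum(t.water)) == 9
        assert not np.any(t.protein)


class TestLoadTrajectory:
    def test_xyz_round_trip(self, tmp_path):
        from hydradyn.io import write_xyz
        from hydradyn.synthetic import HarmonicSpec, gen_harmonic

        traj, table, _ = gen_harmonic(HarmonicSpec(6, 0.1), 300.0, 25, 5.0, seed=3)
        path = tmp_path / "t.xyz"
        write_xyz(traj, table, path)
        back = load_trajectory(path, table, timestep=5.0)
        assert back.n_frames == 25
        assert back.timestep == 5.0
        # format precision is 3 decimals
        assert np.abs(back.positions - traj.positions).max() < 1e-3

    def test_atom_count_mismatch_raises(self, tmp_path):
        from hydradyn.io import write_xyz
        from hydradyn.synthetic import HarmonicSpec, gen_harmonic

        traj, table, _ = gen_harmonic(HarmonicSpec(6, 0.1), 300.0, 5, 5.0, seed=3)
        path = tmp_path / "t.xyz"
        write_xyz(traj, table, path)
        other, _, _ = gen_harmonic(HarmonicSpec(9, 0.1), 300.0, 5, 5.0, seed=3)
        _, wrong_table, _ = gen_harmonic(HarmonicSpec(9, 0.1), 300.0, 5, 5.0, seed=3)
        with pytest.raises(Exception, match="atoms"):
            load_trajectory(path, wrong_table)


class TestClassification:
    def test_valine_two_methyls(self):
        table, coords = build_residues([("VAL", VAL_ATOMS)])
        out = classify_methyls(table, coords=coords)
        assert int(np.sum(out.is_methyl_C)) == 2
        assert int(np.sum(out.is_methyl_H)) == 6
        # each group has one carbon and three hydrogens (validated on build)
        assert len(np.unique(out.methyl_group_id[out.methyl_group_id >= 0])) == 2

    def test_glycine_no_methyls(self):
        table, coords = build_residues([("GLY", GLY_ATOMS)])
        out = classify_methyls(table, coords=coords)
        assert int(np.sum(out.is_methyl_H)) == 0

    def test_ala_leu_dipeptide(self):
        table, coords = build_residues([("ALA", ALA_ATOMS), ("LEU", LEU_ATOMS)])
        out = classify_methyls(table, coords=coords)
        assert int(np.sum(out.is_methyl_C)) == 3
        assert int(np.sum(out.is_methyl_H)) == 9

    def test_broken_methyl_skipped_with_warning(self):
        table, coords = build_residues([("ALA", ALA_ATOMS)])
        # remove one methyl hydrogen -> CB has only 2 bonded H
        keep = table.name != "HB3"
        with pytest.warns(UserWarning, match="skipped"):
            out = classify_methyls(table.subset(keep), coords=coords[keep])
        assert int(np.sum(out.is_methyl_H)) == 0

    def test_exchangeable_serine(self):
        table, coords = build_residues([("SER", SER_ATOMS)])
        out = classify_exchangeable(table, coords=coords)
        # amide H + hydroxyl HG
        assert set(out.name[out.is_exchangeable]) == {"H", "HG"}

    def test_methyl_H_not_exchangeable(self):
        table, coords = build_residues([("ALA", ALA_ATOMS)])
        out = classify_exchangeable(table, coords=coords)
        assert set(out.name[out.is_exchangeable]) == {"H"}

    def test_partition_methyl_plus_nonmethyl(self):
        table, coords = build_residues([("VAL", VAL_ATOMS), ("SER", SER_ATOMS)])
        out = classify_methyls(table, coords=coords)
        assert np.array_equal(out.methyl_H | out.non_methyl_H, out.protein_H)
        assert not np.any(out.methyl_H & out.non_methyl_H)

    def test_methyl_fraction_valine(self):
        table, coords = build_residues([("VAL", VAL_ATOMS)])
        out = classify_methyls(table, coords=coords)
        # 6 methyl H of 9 total H
        assert methyl_hydrogen_fraction(out) == pytest.approx(100 * 6 / 9)

    def test_zero_protein_h_raises(self):
        table, _ = build_residues([], waters=2)
        with pytest.raises(ValueError, match="hydrogens"):
            methyl_hydrogen_fraction(table)


class TestBondInference:
    def test_h_assigned_to_nearest_heavy(self):
        table, coords = build_residues([("ALA", ALA_ATOMS)])
        bonds = infer_bonds(coords, table)
        names = {str(table.name[h]): str(table.name[c]) for h, c in bonds}
        assert names["HB1"] == "CB" and names["HA"] == "CA" and names["H"] == "N"


class TestComposition:
    def test_zero_waters(self):
        c = composition_from_counts(
            n_subunits=1, residues_per_subunit=10, n_water=0, n_ions=0,
            subunit_mass=1000.0, protein_atoms=100,
        )
        assert c.h == 0.0 and c.waters_per_residue == 0.0

    def test_h_linear_in_waters(self):
        vals = [
            composition_from_counts(
                n_subunits=2, residues_per_subunit=5, n_water=n, n_ions=0,
                subunit_mass=5000.0, protein_atoms=50,
            ).h
            for n in (10, 20, 40)
        ]
        assert vals[1] == pytest.approx(2 * vals[0])
        assert vals[2] == pytest.approx(4 * vals[0])

    def test_inconsistent_totals_diagnostic(self):
        with pytest.raises(ValueError, match="inconsistent"):
            composition_from_counts(
                n_subunits=1, residues_per_subunit=1, n_water=2, n_ions=1,
                subunit_mass=100.0, protein_atoms=10, total_atoms=99,
            )

    def test_from_atom_table(self):
        table, coords = build_residues([("ALA", ALA_ATOMS)], waters=3)
        c = composition_summary(table, subunit_mass=71.079 + 18.015)
        assert c.n_water == 3
        assert c.total_atoms == len(table)
        assert c.waters_per_residue == pytest.approx(3.0)


class TestSequenceTemplates:
    def test_glycine_chain_has_no_methyls(self):
        assert methyl_fraction_from_sequence(["GGGGG"]) == 0.0

    def test_serine_exchangeable_count(self):
        # internal Ser: backbone HN + hydroxyl; charged termini add 2
        c = sequence_hydrogen_counts(["S"], charged_termini=False)
        assert c.exchangeable == 2
        c2 = sequence_hydrogen_counts(["S"], charged_termini=True)
        assert c2.exchangeable == 4

    def test_disulfides_remove_thiol_h(self):
        free = sequence_hydrogen_counts(["CC"], charged_termini=False)
        bridged = sequence_hydrogen_counts(["CC"], charged_termini=False, n_disulfides=2)
        assert free.total - bridged.total == 2
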
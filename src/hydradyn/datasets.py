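"""Reference system compositions and sequences shipped with the package.

Four amorphous-protein systems are described: horse spleen apoferritin
(a hollow 24-mer, 170 modelled residues per subunit, subunit mass
18,500 Da) and the bovine insulin dimer (2 × 51 residues, dimer mass
11,555.07 Da), each in a lyophilised (h ≈ 0.05) and a weakly hydrated
state.  The counts feed the hydration-level bookkeeping
(h = g D₂O per g protein) in :mod:`hydradyn.core`.

Sequences: the insulin dimer chains are the exact bovine sequences; the
apoferritin L-chain file is a SYNTHETIC stand-in reconstructed from
public sequence knowledge (see its FASTA header) used for
sequence-level hydrogen bookkeeping when no hydrogenated structure is
available.  Insulin carries three disulfide bridges per monomer.
"""

from __future__ import annotations

from importlib import resources

from .core import SystemComposition, composition_from_counts
from .templates import methyl_fraction_from_sequence

__all__ = [
    "SYSTEM_COUNTS",
    "composition",
    "insulin_dimer_chains",
    "apoferritin_subunit_chain",
    "insulin_methyl_fraction",
    "apoferritin_methyl_fraction",
]

#: per-system atom bookkeeping (counts; masses in Da)
SYSTEM_COUNTS: dict[str, dict] = {
    "apo_h005": dict(
        n_subunits=24, residues_per_subunit=170, n_water=1257, n_ions=168,
        subunit_mass=18_500.0, total_atoms=69_051,
    ),
    "apo_h031": dict(
        n_subunits=24, residues_per_subunit=170, n_water=6844, n_ions=168,
        subunit_mass=18_500.0, total_atoms=85_812,
    ),
    "ins_h005": dict(
        n_subunits=2, residues_per_subunit=51, n_water=29, n_ions=4,
        subunit_mass=11_555.07 / 2.0, total_atoms=1_641,
    ),
    "ins_h025": dict(
        n_subunits=2, residues_per_subunit=51, n_water=145, n_ions=4,
        subunit_mass=11_555.07 / 2.0, total_atoms=1_989,
    ),
}


def composition(name: str, **overrides) -> SystemComposition:
    """Composition summary of one named reference system."""
    if name not in SYSTEM_COUNTS:
        raise KeyError(f"unknown system {name!r}; have {sorted(SYSTEM_COUNTS)}")
    counts = SYSTEM_COUNTS[name]
    # protein atom count follows from the conservation identity
    protein_atoms = counts["total_atoms"] - 3 * counts["n_water"] - counts["n_ions"]
    return composition_from_counts(
        **counts, protein_atoms=protein_atoms, **overrides
    )


def _read_fasta(name: str) -> list[str]:
    from Bio import SeqIO

    ref = resources.files("hydradyn.data") / name
    with resources.as_file(ref) as path:
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def insulin_dimer_chains() -> list[str]:
    """Four chains (A, B, A, B) of the bovine insulin dimer."""
    return _read_fasta("insulin_dimer.fasta")


def apoferritin_subunit_chain() -> str:
    """Synthetic stand-in L-chain sequence of the apoferritin subunit."""
    return _read_fasta("apoferritin_l_chain_synthetic.fasta")[0]


def insulin_methyl_fraction() -> float:
    """Methyl-H percentage of insulin dimer hydrogens (6 disulfides)."""
    return methyl_fraction_from_sequence(insulin_dimer_chains(), n_disulfides=6)


def apoferritin_methyl_fraction() -> float:
    """Methyl-H percentage of apoferritin hydrogens (per subunit)."""
    return methyl_fraction_from_sequence([apoferritin_subunit_chain()])
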
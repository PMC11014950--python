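"""Per-residue hydrogen inventories and methyl-group definitions.

Standard amino-acid topology at neutral pH for a chain-internal
residue: Asp/Glu deprotonated, Lys/Arg protonated, His neutral (one
ring NH), Cys reduced (SH present).  Counts are used when a structure
lacks explicit hydrogens, e.g. crystal structures, so that hydrogen
bookkeeping (methyl fractions, exchangeable fractions) can still be
done from sequence alone.

Methyl groups carried by the standard amino acids:
Ala Cβ; Val Cγ1, Cγ2; Leu Cδ1, Cδ2; Ile Cγ2, Cδ1; Thr Cγ2; Met Cε.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

#: residues that carry at least one CH₃ group
METHYL_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "THR", "MET"})

#: (residue, carbon atom name) pairs whose carbon is a methyl carbon
METHYL_CARBONS = frozenset(
    {
        ("ALA", "CB"),
        ("VAL", "CG1"),
        ("VAL", "CG2"),
        ("LEU", "CD1"),
        ("LEU", "CD2"),
        ("ILE", "CG2"),
        ("ILE", "CD1"),
        ("ILE", "CD"),  # CHARMM naming for Ile Cδ
        ("THR", "CG2"),
        ("MET", "CE"),
    }
)

#: residue names treated as water in structure files
WATER_RESNAMES = frozenset({"HOH", "SOL", "TIP3", "WAT", "SPC", "TIP4", "H2O"})

#: monatomic ion residue/atom names
ION_NAMES = frozenset(
    {"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "MG2+", "CA", "CA2+", "ZN", "ZN2+", "SOD", "CLA"}
)


class ResidueHydrogens(NamedTuple):
    """Hydrogen inventory of one chain-internal residue."""

    total: int        # all H including backbone HN and HA
    methyl: int       # H on CH₃ carbons
    exchangeable: int  # H bonded to N, O or S (includes backbone HN)


#: keyed by one-letter code
RESIDUE_HYDROGENS: dict[str, ResidueHydrogens] = {
    "A": ResidueHydrogens(5, 3, 1),
    "R": ResidueHydrogens(13, 0, 6),
    "N": ResidueHydrogens(6, 0, 3),
    "D": ResidueHydrogens(4, 0, 1),
    "C": ResidueHydrogens(5, 0, 2),
    "Q": ResidueHydrogens(8, 0, 3),
    "E": ResidueHydrogens(6, 0, 1),
    "G": ResidueHydrogens(3, 0, 1),
    "H": ResidueHydrogens(7, 0, 2),
    "I": ResidueHydrogens(11, 6, 1),
    "L": ResidueHydrogens(11, 6, 1),
    "K": ResidueHydrogens(13, 0, 4),
    "M": ResidueHydrogens(9, 3, 1),
    "F": ResidueHydrogens(9, 0, 1),
    "P": ResidueHydrogens(7, 0, 0),
    "S": ResidueHydrogens(5, 0, 2),
    "T": ResidueHydrogens(7, 3, 2),
    "W": ResidueHydrogens(10, 0, 2),
    "Y": ResidueHydrogens(9, 0, 2),
    "V": ResidueHydrogens(9, 6, 1),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common His tautomer/protonation variants
    "HSD": "H", "HSE": "E", "HSP": "H", "HID": "H", "HIE": "H", "HIP": "H",
}


class ChainHydrogenCounts(NamedTuple):
    total: int
    methyl: int
    exchangeable: int


def sequence_hydrogen_counts(
    chains: Iterable[str],
    *,
    charged_termini: bool = True,
    n_disulfides: int = 0,
) -> ChainHydrogenCounts:
    """Hydrogen bookkeeping for one or more peptide chains.

    Parameters
    ----------
    chains
        One-letter sequences, one per chain.
    charged_termini
        If True each chain has an N-terminal NH₃⁺ (two extra H relative
        to the internal amide) and a C-terminal carboxylate (no extra H).
    n_disulfides
        Number of cystine bridges in the whole assembly; each removes
        one thiol hydrogen (also removed from the exchangeable count).
    """
    total = methyl = exch = 0
    for chain in chains:
        for aa in chain.upper():
            try:
                h = RESIDUE_HYDROGENS[aa]
            except KeyError as exc:
                raise ValueError(f"unknown residue code {aa!r}") from exc
            total += h.total
            methyl += h.methyl
            exch += h.exchangeable
        if charged_termini:
            total += 2
            exch += 2
    total -= n_disulfides
    exch -= n_disulfides
    if total < 0:
        raise ValueError("more disulfides than thiol hydrogens")
    return ChainHydrogenCounts(total, methyl, exch)


def methyl_fraction_from_sequence(
    chains: Iterable[str], *, charged_termini: bool = True, n_disulfides: int = 0
) -> float:
    """Percentage of methyl hydrogens among all protein hydrogens."""
    c = sequence_hydrogen_counts(
        chains, charged_termini=charged_termini, n_disulfides=n_disulfides
    )
    if c.total == 0:
        raise ValueError("sequence has no hydrogens")
    return 100.0 * c.methyl / c.total
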
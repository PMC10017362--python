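"""Residue mass tables and elementary peptide mass arithmetic.

Two conventions are maintained side by side throughout the package:
monoisotopic masses (most-abundant-isotope composition) and average
masses (isotope-abundance-weighted). Published product tables mix the
two conventions, so every species is reported in both.
"""

from __future__ import annotations

import math

#: Monoisotopic residue masses (Da) for the 20 standard amino acids,
#: as the dehydrated residue (i.e. the in-chain monomer).
MONO_RESIDUE: dict[str, float] = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}

#: Average residue masses (Da), standard IUPAC-abundance values.
AVG_RESIDUE: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MONO = 18.010565
WATER_AVG = 18.0153

HYDROGEN_MONO = 1.0078250319
HYDROGEN_AVG = 1.00794

STANDARD_RESIDUES = frozenset(MONO_RESIDUE)


class NonstandardResidueError(ValueError):
    """Sequence contains a symbol outside the 20 standard one-letter codes."""


def validate_sequence(sequence: str) -> None:
    """Reject any symbol outside the 20 standard residues, naming its position."""
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_RESIDUES:
            raise NonstandardResidueError(
                f"nonstandard residue {aa!r} at position {i}"
            )


def residue_sum(sequence: str, *, monoisotopic: bool) -> float:
    table = MONO_RESIDUE if monoisotopic else AVG_RESIDUE
    validate_sequence(sequence)
    return sum(table[aa] for aa in sequence)


def linear_mass(sequence: str, *, monoisotopic: bool) -> float:
    """Mass of a linear peptide: residue masses plus one terminal water."""
    water = WATER_MONO if monoisotopic else WATER_AVG
    return residue_sum(sequence, monoisotopic=monoisotopic) + water


def cyclic_mass(sequence: str, *, monoisotopic: bool) -> float:
    """Mass of a head-to-tail backbone macrocycle: residue masses, no water."""
    return residue_sum(sequence, monoisotopic=monoisotopic)


def disulfide_correction(n_disulfides: int, *, monoisotopic: bool) -> float:
    """Mass removed by ``n_disulfides`` S-S bonds (two hydrogens each)."""
    h = HYDROGEN_MONO if monoisotopic else HYDROGEN_AVG
    return 2.0 * h * n_disulfides


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (mass-table convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
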
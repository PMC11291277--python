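"""Monoisotopic masses, elemental compositions and isotope abundances.

All residue masses are derived from elemental compositions and CODATA/IUPAC
monoisotopic atom masses so that peptide masses and isotope envelopes are
mutually consistent by construction.
"""

from __future__ import annotations

# Monoisotopic atom masses (Da) of the principal isotope.
MONOISOTOPIC_ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Aggregated isotope abundance vectors per nominal +1 neutron step,
# normalized; index 0 is the principal isotope (IUPAC 2013 representative
# values). O17/S33 are folded into the +1 slot, O18/S34 into +2, S36 into +4.
ELEMENT_ISOTOPE_ABUNDANCES = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}

# Residue (amino-acid minus water) elemental compositions, 20 canonical.
RESIDUE_COMPOSITION = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

PROTON_MASS = 1.007276
WATER_MASS = 2 * MONOISOTOPIC_ELEMENT_MASS["H"] + MONOISOTOPIC_ELEMENT_MASS["O"]

# Mass shifts of the two post-translational modifications handled here.
HYDROXYLATION_SHIFT = 15.994915          # +O on proline
DEAMIDATION_SHIFT = 0.984016             # N/Q: -NH +O
ISOTOPE_SPACING = 1.00336                # average C13-dominated neutron step


def _residue_mass(composition: dict[str, int]) -> float:
    return sum(MONOISOTOPIC_ELEMENT_MASS[el] * n for el, n in composition.items())


MONOISOTOPIC_RESIDUE_MASS = {
    aa: _residue_mass(comp) for aa, comp in RESIDUE_COMPOSITION.items()
}


def peptide_composition(
    sequence: str, n_hydroxylations: int = 0, n_deamidations: int = 0
) -> dict[str, int]:
    """Elemental composition of a peptide with water and modifications.

    Deamidation swaps NH for O; hydroxylation adds O.
    """
    comp: dict[str, int] = {"H": 2, "O": 1}
    for pos, aa in enumerate(sequence):
        try:
            residue = RESIDUE_COMPOSITION[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {pos + 1}") from None
        for el, n in residue.items():
            comp[el] = comp.get(el, 0) + n
    comp["O"] = comp.get("O", 0) + n_hydroxylations + n_deamidations
    comp["N"] -= n_deamidations
    comp["H"] -= n_deamidations
    return comp
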
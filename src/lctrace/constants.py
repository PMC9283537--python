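"""Pinned physical constants for all m/z arithmetic.

Monoisotopic atomic masses (Da) and terrestrial isotopic abundances from the
NIST/CODATA compilations. Keeping the table inside the package (rather than
deferring to an external library) makes every printed m/z in reports and tests
bit-stable across environments.
"""

from __future__ import annotations

# CODATA
ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466621

# NIST monoisotopic masses of the most abundant (lightest, for these elements)
# isotope. Covers the biological elements plus common adduct atoms.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Si": 27.9769265325,
    "Se": 79.9165213,
    "B": 11.0093054,
    "Li": 7.01600455,
    "Mg": 23.985041700,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Cu": 62.9295975,
    "Mn": 54.9380451,
    "Co": 58.9331950,
}

# Heavy-minus-light mass differences for the tracer isotopes (Da/atom).
ISOTOPE_MASS_SHIFT: dict[str, float] = {
    "13C": 13.0033548378 - 12.0,          # 1.0033548378
    "15N": 15.0001088989 - 14.0030740048,  # 0.9970348941
}

# Terrestrial isotopic abundances (IUPAC representative values).
ISOTOPE_ABUNDANCE: dict[str, tuple[float, float]] = {
    # isotope -> (heavy abundance, light abundance)
    "13C": (0.0107, 0.9893),
    "15N": (0.00364, 0.99636),
}

# Element carrying each tracer isotope.
ISOTOPE_ELEMENT: dict[str, str] = {"13C": "C", "15N": "N"}


def natural_abundance_ratio(isotope: str) -> float:
    """Heavy/light abundance ratio for one atom of the isotope's element."""
    heavy, light = ISOTOPE_ABUNDANCE[isotope]
    return heavy / light


def dump_constants() -> dict:
    """Machine-readable dump of the pinned constants table."""
    return {
        "electron_mass": ELECTRON_MASS,
        "proton_mass": PROTON_MASS,
        "monoisotopic_mass": dict(MONOISOTOPIC_MASS),
        "isotope_mass_shift": dict(ISOTOPE_MASS_SHIFT),
        "isotope_abundance": {k: list(v)
                              for k, v in ISOTOPE_ABUNDANCE.items()},
    }
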
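"""Molecular formulas, adduct m/z, tracer mass shifts and MRM transitions.

This is the mass basis of the whole pipeline: monoisotopic masses of target
compounds, singly charged adduct ions ([M+H]+, [M+Na]+ in positive mode;
[M-H]-, [M+Cl]-, [M+HCOO]- in negative mode), the per-atom mass increment of
the 13C and 15N tracers, and nominal heavy/light transition pairs for
triple-quadrupole (MRM) assays.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .constants import (
    ELECTRON_MASS,
    ISOTOPE_ELEMENT,
    ISOTOPE_MASS_SHIFT,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    natural_abundance_ratio,
)

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "LabelScheme",
    "CompoundSpec",
    "ADDUCTS",
    "POSITIVE_ADDUCTS",
    "NEGATIVE_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "label_mass_shift",
    "isotopologue_mz_series",
    "heavy_transition",
    "natural_isotope_fraction",
    "nominal_mz",
]

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map; the empty formula has mass exactly zero."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def hill(self) -> str:
        """Canonical Hill notation: C, then H, then other elements A-Z."""
        parts: list[str] = []
        order = [el for el in ("C", "H") if self[el] > 0]
        order += sorted(el for el, n in self.counts.items()
                        if el not in ("C", "H") and n > 0)
        for el in order:
            n = self[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C6H14N2O2"``.

    Raises :class:`FormulaError` naming the offending token for malformed
    input or unknown element symbols.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed token at {text[pos:]!r}")
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed token at {text[pos:]!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of standard monoisotopic atomic masses in Da (additive by element)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ionization adduct with its signed mass delta (Da).

    Mass deltas include the electron mass so that 4-decimal m/z values are
    correct for ppm-level matching, not only for 2-decimal presentation.
    """

    name: str
    charge_sign: int
    mass_delta: float


ADDUCTS: dict[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", +1, PROTON_MASS),
    "M+Na": AdductSpec("M+Na", +1, MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS),
    "M-H": AdductSpec("M-H", -1, -PROTON_MASS),
    "M+Cl": AdductSpec("M+Cl", -1, MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS),
    "M+HCOO": AdductSpec(
        "M+HCOO",
        -1,
        MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["C"]
        + 2 * MONOISOTOPIC_MASS["O"] + ELECTRON_MASS,
    ),
}

POSITIVE_ADDUCTS = ("M+H", "M+Na")
NEGATIVE_ADDUCTS = ("M-H", "M+Cl", "M+HCOO")


def _resolve_adduct(adduct: AdductSpec | str) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of the singly charged adduct ion of a neutral of given mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    spec = _resolve_adduct(adduct)
    if abs(spec.charge_sign) != 1:
        raise ValueError("only singly charged species are supported")
    return neutral_mass + spec.mass_delta


@dataclass(frozen=True)
class LabelScheme:
    """A tracer isotope and how many atoms of it a species carries."""

    isotope: str
    n_atoms: int

    def __post_init__(self) -> None:
        if self.isotope not in ISOTOPE_MASS_SHIFT:
            raise KeyError(
                f"unknown isotope {self.isotope!r}; "
                f"supported: {sorted(ISOTOPE_MASS_SHIFT)}"
            )
        if self.n_atoms < 0:
            raise ValueError("label atom count must be >= 0")

    @property
    def per_atom_shift(self) -> float:
        return ISOTOPE_MASS_SHIFT[self.isotope]


def label_mass_shift(scheme: LabelScheme | tuple[str, int]) -> float:
    """Total mass shift in Da: n_atoms x (heavy - light) isotope mass."""
    if isinstance(scheme, tuple):
        scheme = LabelScheme(*scheme)
    return scheme.n_atoms * scheme.per_atom_shift


@dataclass(frozen=True)
class CompoundSpec:
    """A target-list entry: identity, formula, labelable atoms and adducts."""

    id: str
    name: str
    formula: MolecularFormula
    labelable: dict[str, int]
    adducts: tuple[str, ...] = POSITIVE_ADDUCTS
    compound_class: str = "other"

    CLASSES = (
        "lysine", "degradation", "modified", "carnitine-pathway",
        "peptide", "acylcarnitine", "other",
    )

    def __post_init__(self) -> None:
        if self.compound_class not in self.CLASSES:
            raise ValueError(
                f"unknown compound class {self.compound_class!r}; "
                f"allowed: {self.CLASSES}"
            )
        for isotope, n in self.labelable.items():
            element = ISOTOPE_ELEMENT[isotope]
            if n > self.formula[element]:
                raise ValueError(
                    f"{self.id}: {isotope} labelable count {n} exceeds "
                    f"{element} count {self.formula[element]} in formula"
                )

    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


def isotopologue_mz_series(
    c: CompoundSpec, adduct: AdductSpec | str, isotope: str
) -> list[tuple[int, float]]:
    """(label_count, m/z) for label counts 0..max, strictly increasing in m/z."""
    if isotope not in c.labelable:
        raise KeyError(
            f"compound {c.id!r} has no labelable map entry for {isotope!r}"
        )
    base = adduct_mz(c.neutral_mass(), adduct)
    step = ISOTOPE_MASS_SHIFT[isotope]
    return [(k, base + k * step) for k in range(c.labelable[isotope] + 1)]


def nominal_mz(mz: float) -> int:
    """Unit-resolution (QQQ) m/z: round half away from zero."""
    return int(math.floor(mz + 0.5)) if mz >= 0 else -int(math.floor(-mz + 0.5))


def heavy_transition(
    light_precursor: float,
    light_fragment: float,
    precursor_labels: int,
    fragment_labels: int,
    isotope: str,
) -> tuple[int, int]:
    """Nominal heavy MRM pair from a light precursor->fragment transition.

    The precursor and fragment are each shifted by their own label count;
    a fragment cannot carry more labels than its precursor.
    """
    if fragment_labels > precursor_labels:
        raise ValueError(
            "fragment cannot carry more labels than its precursor "
            f"({fragment_labels} > {precursor_labels})"
        )
    step = ISOTOPE_MASS_SHIFT[isotope]
    return (
        nominal_mz(light_precursor + precursor_labels * step),
        nominal_mz(light_fragment + fragment_labels * step),
    )


def natural_isotope_fraction(f: MolecularFormula, isotope: str) -> float:
    """Expected +1-heavy/monoisotopic intensity ratio from natural abundance.

    Linear (single-substitution) approximation: n_atoms x heavy/light
    abundance ratio of the isotope's element.
    """
    element = ISOTOPE_ELEMENT[isotope]
    return f[element] * natural_abundance_ratio(isotope)
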
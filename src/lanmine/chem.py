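"""Exact molecular-formula and monoisotopic-mass arithmetic for peptides.

All downstream stages (precursor mining, MS1 linking, fragment annotation,
desulfurization simulation) route their mass bookkeeping through this module.
Masses are monoisotopic throughout; the atomic mass table is fixed so that
every ppm figure the package reports is reproducible bit-for-bit.

Conventions
-----------
* Deuterium is its own element symbol ``D`` (not an isotope annotation on H).
* Charged species are protonated: m/z = (M + z * m_p) / z with the
  electron-corrected proton mass 1.007276 Da.
* ppm error is signed, 1e6 * (observed - theoretical) / theoretical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

__all__ = [
    "MolecularFormula",
    "ModificationSet",
    "MassValue",
    "RESIDUE_FORMULAS",
    "DERIVED_RESIDUE_FORMULAS",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "METHYLENE",
    "H2",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "peptide_formula",
    "apply_modifications",
    "revert_modifications",
    "mz_from_neutral",
    "neutral_from_mz",
    "ppm_error",
]

# IUPAC monoisotopic atomic masses (Da).  D = deuterium, tracked separately
# from H so that NaBD4 labelling arithmetic stays element-wise.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "D": 2.0141018,
}

#: Electron-corrected proton mass (Da); the charge carrier for [M + zH]^z+.
PROTON_MASS = 1.007276

_ALLOWED = set(MONOISOTOPIC_MASS)
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula text or infeasible formula arithmetic."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map with element-wise group arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    element negative raises :class:`FormulaError` (the modification is
    chemically infeasible on that species).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in _ALLOWED:
                raise FormulaError(f"unknown element symbol {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            new = merged.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction drives {el} negative "
                    f"({merged.get(el, 0)} - {n})"
                )
            merged[el] = new
        return MolecularFormula(merged)

    def __mul__(self, k: int) -> "MolecularFormula":
        if k < 0:
            raise FormulaError("scalar multiple must be non-negative")
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    @property
    def mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MolecularFormula({format_formula(self)!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``C57H71N13O15S2``.

    Counts default to 1; unknown element symbols and stray characters are
    rejected with the offending token named.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable token {text[pos:m.start()]!r} in {text!r}"
            )
        el, num = m.group(1), m.group(2)
        if el not in _ALLOWED:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparseable token {text[pos:]!r} in {text!r}")
    return MolecularFormula(counts)


def format_formula(f: MolecularFormula) -> str:
    """Canonical Hill-order writer: C, H, then remaining symbols A-Z."""
    parts = []
    for el in ("C", "H"):
        if el in f.counts:
            n = f.counts[el]
            parts.append(el + (str(n) if n != 1 else ""))
    for el in sorted(set(f.counts) - {"C", "H"}):
        n = f.counts[el]
        parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts) or "(empty)"


WATER = parse_formula("H2O")
METHYLENE = parse_formula("CH2")
H2 = parse_formula("H2")

# Internal (dehydrated) residue formulas for the 20 standard amino acids.
RESIDUE_FORMULAS: Mapping[str, MolecularFormula] = {
    "G": parse_formula("C2H3NO"),
    "A": parse_formula("C3H5NO"),
    "S": parse_formula("C3H5NO2"),
    "P": parse_formula("C5H7NO"),
    "V": parse_formula("C5H9NO"),
    "T": parse_formula("C4H7NO2"),
    "C": parse_formula("C3H5NOS"),
    "L": parse_formula("C6H11NO"),
    "I": parse_formula("C6H11NO"),
    "N": parse_formula("C4H6N2O2"),
    "D": parse_formula("C4H5NO3"),
    "Q": parse_formula("C5H8N2O2"),
    "K": parse_formula("C6H12N2O"),
    "E": parse_formula("C5H7NO3"),
    "M": parse_formula("C5H9NOS"),
    "H": parse_formula("C6H7N3O"),
    "F": parse_formula("C9H9NO"),
    "R": parse_formula("C6H12N4O"),
    "Y": parse_formula("C9H9NO2"),
    "W": parse_formula("C11H10N2O"),
}

# Post-translationally derived residue states reachable from the standard
# residues by defined deltas:
#   Dha = Ser - H2O (dehydroalanine), Dhb = Thr - H2O (dehydrobutyrine),
#   Abu = Thr - O   (2-aminobutyric acid, MeLan desulfurization product),
#   ring-opened Cys -> Ala (= Cys - S); deuterated Ala/Abu carry one H -> D.
DERIVED_RESIDUE_FORMULAS: Mapping[str, MolecularFormula] = {
    "Dha": RESIDUE_FORMULAS["S"] - WATER,
    "Dhb": RESIDUE_FORMULAS["T"] - WATER,
    "Abu": RESIDUE_FORMULAS["T"] - parse_formula("O"),
    "Ala": RESIDUE_FORMULAS["A"],
    "Ala(d1)": RESIDUE_FORMULAS["A"] - parse_formula("H") + parse_formula("D"),
    "Abu(d1)": RESIDUE_FORMULAS["T"]
    - parse_formula("O")
    - parse_formula("H")
    + parse_formula("D"),
    # donor residue after Cgamma-S fragmentation: side-chain O replaced by S
    "Ser(+S-O)": RESIDUE_FORMULAS["S"] - parse_formula("O") + parse_formula("S"),
    "Thr(+S-O)": RESIDUE_FORMULAS["T"] - parse_formula("O") + parse_formula("S"),
}


@dataclass(frozen=True)
class MassValue:
    """A mass in Da, tagged monoisotopic or nominal (integer)."""

    value: float
    kind: str = "monoisotopic"

    def __post_init__(self) -> None:
        if self.kind not in ("monoisotopic", "nominal"):
            raise ValueError(f"unknown mass kind {self.kind!r}")
        if self.kind == "nominal" and self.value != round(self.value):
            raise ValueError("nominal mass must be an integer")

    def __float__(self) -> float:
        return float(self.value)

    @classmethod
    def nominal_from_monoisotopic(cls, value: float) -> "MassValue":
        return cls(float(round(value)), "nominal")


@dataclass(frozen=True)
class ModificationSet:
    """Counted post-translational modifications on a core peptide.

    * dehydration: -H2O on Ser/Thr (the lanthipeptide hallmark)
    * methylation: +CH2 (justified only when the gene cluster carries a
      methyltransferase)
    * dehydrogenation: -H2 (e.g. a disulfide crosslink)
    * extra: arbitrary named (label, formula, sign) deltas, sign +1 or -1
    """

    n_dehydration: int = 0
    n_methylation: int = 0
    n_dehydrogenation: int = 0
    extra: Tuple[Tuple[str, MolecularFormula, int], ...] = ()

    def __post_init__(self) -> None:
        for name, n in (
            ("n_dehydration", self.n_dehydration),
            ("n_methylation", self.n_methylation),
            ("n_dehydrogenation", self.n_dehydrogenation),
        ):
            if n < 0:
                raise ValueError(f"{name} must be >= 0, got {n}")
        for label, f, sign in self.extra:
            if sign not in (1, -1):
                raise ValueError(f"extra delta {label!r}: sign must be +/-1")

    @property
    def total(self) -> int:
        """Total modification count (ranking key for MS1 matches)."""
        return (
            self.n_dehydration
            + self.n_methylation
            + self.n_dehydrogenation
            + len(self.extra)
        )

    def delta_mass(self) -> float:
        """Net monoisotopic mass shift of the whole set (Da, signed)."""
        d = -self.n_dehydration * WATER.mass
        d += self.n_methylation * METHYLENE.mass
        d -= self.n_dehydrogenation * H2.mass
        for _, f, sign in self.extra:
            d += sign * f.mass
        return d

    def describe(self) -> str:
        bits = []
        if self.n_dehydration:
            bits.append(f"-{self.n_dehydration}H2O")
        if self.n_methylation:
            bits.append(f"+{self.n_methylation}CH2")
        if self.n_dehydrogenation:
            bits.append(f"-{self.n_dehydrogenation}H2")
        bits.extend(
            f"{'+' if sign > 0 else '-'}{label}" for label, _, sign in self.extra
        )
        return " ".join(bits) or "unmodified"


def monoisotopic_mass(f: MolecularFormula) -> MassValue:
    """Monoisotopic mass of a formula as sum of fixed-table atomic masses."""
    return MassValue(f.mass, "monoisotopic")


def peptide_formula(
    sequence: str,
    table: Mapping[str, MolecularFormula] = RESIDUE_FORMULAS,
) -> MolecularFormula:
    """Neutral formula of a linear peptide with free termini.

    Sum of internal residue formulas plus one water for the H/OH termini.
    Unknown letters raise with the offending 1-based position named.
    """
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total = total + table[aa]
        except KeyError:
            raise FormulaError(
                f"unknown residue {aa!r} at position {i + 1} in {sequence!r}"
            ) from None
    return total


def apply_modifications(
    f: MolecularFormula, mods: ModificationSet
) -> MolecularFormula:
    """Apply a modification set to a neutral formula (element-wise sums).

    Raises :class:`FormulaError` when any delta would drive an element count
    negative (the modification set is infeasible on this species).
    """
    out = f
    if mods.n_dehydration:
        out = out - mods.n_dehydration * WATER
    if mods.n_methylation:
        out = out + mods.n_methylation * METHYLENE
    if mods.n_dehydrogenation:
        out = out - mods.n_dehydrogenation * H2
    for _, delta, sign in mods.extra:
        out = out + delta if sign > 0 else out - delta
    return out


def revert_modifications(
    f: MolecularFormula, mods: ModificationSet
) -> MolecularFormula:
    """Exact inverse of :func:`apply_modifications`."""
    out = f
    if mods.n_dehydration:
        out = out + mods.n_dehydration * WATER
    if mods.n_methylation:
        out = out - mods.n_methylation * METHYLENE
    if mods.n_dehydrogenation:
        out = out + mods.n_dehydrogenation * H2
    for _, delta, sign in mods.extra:
        out = out - delta if sign > 0 else out + delta
    return out


def mz_from_neutral(mass: float, z: int) -> float:
    """m/z of the protonated [M + zH]^z+ ion of a neutral mass."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (float(mass) + z * PROTON_MASS) / z


def neutral_from_mz(mz: float, z: int) -> float:
    """Neutral monoisotopic mass back-calculated from an [M + zH]^z+ peak."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return float(mz) * z - z * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error in parts-per-million: 1e6 (obs - theo)/theo."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical
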
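"""Molecular formula arithmetic and mass-difference matching.

Every network layer in this package ultimately reasons about neutral
monoisotopic masses: mass-difference edges are pairwise precursor
differences matched against a list of biochemical transformations, and
annotation propagation adds or subtracts the transformation's formula
from a seed formula.  This module provides the formula container, the
parser, monoisotopic mass and ion m/z computation, and the ppm matcher.

Element monoisotopic masses come from the NIST table shipped with
pyteomics; ion m/z is electron-inclusive (anions gain electron mass),
which is required to reproduce measured negative-mode values such as
m/z 171.0064 for deprotonated glycerol 3-phosphate [C3H8O6P]-.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from pyteomics import mass as _pymass

__all__ = [
    "MolecularFormula",
    "Transformation",
    "TransformationList",
    "FormulaError",
    "InfeasibleTransformation",
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "apply_transformation",
    "match_mass_difference",
    "bundled_transformations",
]

#: monoisotopic mass (u) per element symbol, from the NIST table.
ELEMENT_MASSES: dict[str, float] = {
    el: data[0][0]
    for el, data in _pymass.nist_mass.items()
    if re.fullmatch(r"[A-Z][a-z]?", el) and data[0][0] > 0
}

#: electron rest mass in u (CODATA).
ELECTRON_MASS: float = _pymass.nist_mass["e*"][0][0]


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


class InfeasibleTransformation(ValueError):
    """Subtracting a transformation would drive an element count negative."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element -> count map with arithmetic and Hill-order printing.

    Zero-count elements are dropped on construction, so two formulas are
    equal iff they denote the same composition.  Addition and subtraction
    are element-wise; subtraction raises :class:`InfeasibleTransformation`
    if any count would become negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"invalid count {n!r} for element {el}")
            if n > 0:
                cleaned[el] = n
        object.__setattr__(self, "counts", dict(cleaned))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise InfeasibleTransformation(
                    f"cannot remove {other} from {self}: element {el} "
                    f"count would be {left}"
                )
            merged[el] = left
        return MolecularFormula(merged)

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    def contains(self, other: "MolecularFormula") -> bool:
        """True if ``other`` can be subtracted without going negative."""
        return all(self.counts.get(el, 0) >= n for el, n in other.counts.items())

    # -- mass ---------------------------------------------------------
    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    # -- printing -----------------------------------------------------
    def __str__(self) -> str:
        els = self.counts
        if "C" in els:
            order = ["C"] + (["H"] if "H" in els else [])
            order += sorted(e for e in els if e not in ("C", "H"))
        else:
            order = sorted(els)
        return "".join(f"{e}{els[e] if els[e] != 1 else ''}" for e in order)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MolecularFormula({str(self)!r})"

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __bool__(self) -> bool:
        return bool(self.counts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string such as ``"C6H10O5"`` or ``"HPO3"``.

    Implicit count 1 is allowed.  Charges, isotopes, parentheses and
    adduct notation are not part of the dialect; charge is always a
    separate parameter (see :func:`ion_mz`).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise FormulaError(f"malformed formula {text!r}: unknown element {el!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in u; the empty formula has mass 0."""
    return sum(n * ELEMENT_MASSES[el] for el, n in f.counts.items())


def ion_mz(f: MolecularFormula, charge: int) -> float:
    """m/z of an ion whose formula (charge carriers included) is ``f``.

    Electrons are subtracted for cations and added for anions:
    ``(M - z * m_e) / |z|``.  The measured negative-mode values in this
    field are only reproduced with the electron term included.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    return (monoisotopic_mass(f) - charge * ELECTRON_MASS) / abs(charge)


@dataclass(frozen=True)
class Transformation:
    """A named biochemical mass difference (unsigned).

    ``delta_mass`` is always derived from ``delta_formula``; the sign of
    a transformation (gain vs loss) is resolved only at propagation time
    from which endpoint of an edge carries the seed.
    """

    name: str
    delta_formula: MolecularFormula
    delta_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        computed = monoisotopic_mass(self.delta_formula)
        if self.delta_mass and abs(self.delta_mass - computed) > 1e-6:
            raise ValueError(
                f"transformation {self.name}: stored delta_mass "
                f"{self.delta_mass} disagrees with formula mass {computed}"
            )
        object.__setattr__(self, "delta_mass", computed)


class TransformationList:
    """Ordered collection of :class:`Transformation` with unique names."""

    def __init__(self, transformations: Iterable[Transformation] = ()):
        self._items: list[Transformation] = list(transformations)
        names = [t.name for t in self._items]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate transformation names: {dupes}")

    def __iter__(self) -> Iterator[Transformation]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __getitem__(self, key: int | str) -> Transformation:
        if isinstance(key, str):
            for t in self._items:
                if t.name == key:
                    return t
            raise KeyError(key)
        return self._items[key]

    def names(self) -> list[str]:
        return [t.name for t in self._items]

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransformationList":
        """Load from a CSV with columns ``name, formula``.

        ``delta_mass`` is recomputed from the formula at load; a
        ``delta_mass`` column, if present, is validated against it.
        """
        items = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"name", "formula"} <= set(
                reader.fieldnames
            ):
                raise ValueError(
                    f"{path}: transformation CSV needs columns 'name' and 'formula'"
                )
            for row in reader:
                f = parse_formula(row["formula"])
                stored = float(row["delta_mass"]) if row.get("delta_mass") else 0.0
                items.append(Transformation(row["name"].strip(), f, stored))
        return cls(items)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "formula", "delta_mass"])
            for t in self:
                writer.writerow([t.name, str(t.delta_formula), f"{t.delta_mass:.6f}"])


def apply_transformation(
    f: MolecularFormula, t: Transformation, sign: int
) -> MolecularFormula:
    """Add (+1) or subtract (-1) a transformation's formula delta."""
    if sign == 1:
        return f + t.delta_formula
    if sign == -1:
        return f - t.delta_formula
    raise ValueError("sign must be +1 or -1")


def match_mass_difference(
    delta_mz: float,
    ref_mz: float,
    transformations: TransformationList | Iterable[Transformation],
    ppm: float,
) -> list[Transformation]:
    """All transformations matching ``delta_mz`` within a ppm window.

    The absolute tolerance is ``ppm * 1e-6 * ref_mz`` where ``ref_mz``
    is the heavier feature's m/z (the error of a difference of two
    measured m/z scales with the measured values, and anchoring on the
    heavier one is the conservative choice).  Several transformations
    may match one difference; all are returned in list order.
    """
    if delta_mz < 0:
        raise ValueError("delta_mz must be non-negative")
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    tol = ppm * 1e-6 * ref_mz
    return [t for t in transformations if abs(delta_mz - t.delta_mass) <= tol]


def bundled_transformations(which: str = "gpnae") -> TransformationList:
    """One of the two transformation lists shipped with the package.

    ``"gpnae"`` (27 entries) targets glycerophospho-N-acyl-ethanolamide
    metabolism; ``"ascaroside_mogl"`` (21 entries) targets ascaroside and
    modular-glucoside metabolism.  Both are plain CSVs and meant to be
    replaced by user lists for other chemistries.
    """
    fname = {
        "gpnae": "transformations_gpnae.csv",
        "ascaroside_mogl": "transformations_ascaroside_mogl.csv",
    }.get(which)
    if fname is None:
        raise ValueError(f"unknown bundled list {which!r}")
    ref = resources.files("molnetprop") / "data" / fname
    with resources.as_file(ref) as p:
        return TransformationList.from_csv(p)
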
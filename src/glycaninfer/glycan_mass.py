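"""Monoisotopic mass calculus for free and derivatized glycans and their ions.

Glycans are modeled as multisets of glycosidically linked residues (the
monosaccharide minus one water); a free glycan of n residues therefore weighs
the sum of its residue masses plus one water.  Reducing-end derivatization
(here, condensation with two molecules of 1-phenyl-3-methyl-5-pyrazolone,
"bis-PMP") adds the label masses and removes one water.  All masses are
monoisotopic and in daltons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

from pyteomics import mass as _ptmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "PMP_LABEL_MASS",
    "ResidueSpec",
    "ResidueRegistry",
    "GlycanComposition",
    "DerivatizationScheme",
    "IonSpec",
    "BIS_PMP",
    "M_PLUS_H",
    "default_registry",
    "residue_mass",
    "neutral_glycan_mass",
    "derivatized_mass",
    "ion_mz",
]

#: Monoisotopic mass of a proton (Da).
PROTON_MASS = 1.007276466812
#: Monoisotopic mass of water (Da); one water condenses per glycosidic bond.
WATER_MASS = _ptmass.calculate_mass(formula="H2O")
#: Monoisotopic mass of one PMP molecule, C10H10N2O (Da).
PMP_LABEL_MASS = _ptmass.calculate_mass(formula="C10H10N2O")

_ADDUCT_MASSES = {
    "H": PROTON_MASS,
    "Na": 22.98922070,
    "K": 38.96315810,
    "NH4": 18.03382555,
}


class UnknownResidueError(KeyError):
    """A residue code was not found in the registry."""

    def __init__(self, code: str, known: Iterable[str]):
        self.code = code
        self.known = sorted(known)
        super().__init__(
            f"unknown residue code {code!r}; known codes: {', '.join(self.known)}"
        )


@dataclass(frozen=True)
class ResidueSpec:
    """A glycosidically linked monosaccharide residue.

    ``formula`` is the elemental composition of the *residue* (monosaccharide
    minus one water); ``residue_mass`` defaults to the monoisotopic mass of
    that formula and, when given explicitly, must agree with it to 1e-4 Da.
    ``class_label`` is the chemical class used by adjacency inference
    (e.g. "hexose", "N-acetylhexosamine", "sulfoquinovose").
    """

    code: str
    formula: str
    class_label: str
    residue_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        formula_mass = _ptmass.calculate_mass(formula=self.formula)
        if self.residue_mass == 0.0:
            object.__setattr__(self, "residue_mass", formula_mass)
        elif abs(self.residue_mass - formula_mass) > 1e-4:
            raise ValueError(
                f"residue {self.code}: stated mass {self.residue_mass} differs "
                f"from formula {self.formula} mass {formula_mass:.6f} by more "
                "than 1e-4 Da"
            )
        if self.residue_mass <= 0:
            raise ValueError(f"residue {self.code}: mass must be positive")


class ResidueRegistry:
    """An ordered, code-unique collection of :class:`ResidueSpec`."""

    def __init__(self, residues: Iterable[ResidueSpec]):
        self._by_code: Dict[str, ResidueSpec] = {}
        for spec in residues:
            if spec.code in self._by_code:
                raise ValueError(f"duplicate residue code {spec.code!r}")
            self._by_code[spec.code] = spec

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self) -> Iterator[ResidueSpec]:
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> Tuple[str, ...]:
        return tuple(self._by_code)

    def get(self, code: str) -> ResidueSpec:
        try:
            return self._by_code[code]
        except KeyError:
            raise UnknownResidueError(code, self._by_code) from None

    def mass(self, code: str) -> float:
        return self.get(code).residue_mass

    def class_of(self, code: str) -> str:
        return self.get(code).class_label

    def extended(self, residues: Iterable[ResidueSpec]) -> "ResidueRegistry":
        """A new registry with ``residues`` added or overriding by code."""
        merged = dict(self._by_code)
        for spec in residues:
            merged[spec.code] = spec
        return ResidueRegistry(merged.values())


_DEFAULT_RESIDUES = (
    ResidueSpec("Hex", "C6H10O5", "hexose"),
    ResidueSpec("HexNAc", "C8H13NO5", "N-acetylhexosamine"),
    ResidueSpec("dHex", "C6H10O4", "deoxyhexose"),
    ResidueSpec("Pent", "C5H8O4", "pentose"),
    ResidueSpec("HexA", "C6H8O6", "hexuronic acid"),
    # Sulfoquinovose (6-deoxy-6-sulfohexose), the ~226 Da sulfonated sugar
    # found in Sulfolobus N-glycans.
    ResidueSpec("QuiS", "C6H10O7S", "sulfoquinovose"),
)


def default_registry() -> ResidueRegistry:
    """The built-in residue registry: Hex, HexNAc, dHex, Pent, HexA, QuiS."""
    return ResidueRegistry(_DEFAULT_RESIDUES)


_COMP_TOKEN = re.compile(r"([A-Za-z]+?)(\d+)")


@dataclass(frozen=True)
class GlycanComposition:
    """A multiset of residue codes with non-negative counts.

    The compact string notation concatenates code and count, e.g.
    ``"QuiS1Hex4HexNAc2"``.  Zero-count entries are dropped.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for code, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {code}")
            if n > 0:
                cleaned[code] = int(n)
        object.__setattr__(self, "counts", dict(sorted(cleaned.items())))

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse compact notation like ``"QuiS1Hex4HexNAc2"`` (case-sensitive)."""
        text = text.strip()
        if not text:
            return cls({})
        if not re.fullmatch(r"(?:[A-Za-z]+?\d+)+", text):
            raise ValueError(f"cannot parse composition string {text!r}")
        counts: Dict[str, int] = {}
        for m in _COMP_TOKEN.finditer(text):
            code, n = m.group(1), int(m.group(2))
            counts[code] = counts.get(code, 0) + n
        return cls(counts)

    def __str__(self) -> str:
        return "".join(f"{c}{n}" for c, n in self.counts.items())

    def __hash__(self) -> int:
        return hash(tuple(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return self.counts == other.counts

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, code: str) -> int:
        return self.counts.get(code, 0)

    def merge(self, other: "GlycanComposition") -> "GlycanComposition":
        """Multiset union (counts add)."""
        counts = dict(self.counts)
        for code, n in other.counts.items():
            counts[code] = counts.get(code, 0) + n
        return GlycanComposition(counts)

    def contains(self, sub: "GlycanComposition") -> bool:
        """Multiset inclusion: every residue of ``sub`` is available here."""
        return all(self.get(code) >= n for code, n in sub.counts.items())

    def subtract(self, sub: "GlycanComposition") -> "GlycanComposition":
        if not self.contains(sub):
            raise ValueError(f"{self} does not contain {sub}")
        return GlycanComposition(
            {code: self.get(code) - sub.get(code) for code in self.counts}
        )

    def sub_multisets(
        self, *, include_empty: bool = False, proper: bool = False
    ) -> Iterator["GlycanComposition"]:
        """Iterate distinct sub-multisets (count vectors bounded by this one)."""
        codes = list(self.counts)

        def rec(i: int, acc: Dict[str, int]) -> Iterator[GlycanComposition]:
            if i == len(codes):
                yield GlycanComposition(dict(acc))
                return
            code = codes[i]
            for n in range(self.counts[code] + 1):
                if n:
                    acc[code] = n
                yield from rec(i + 1, acc)
                acc.pop(code, None)

        for sub in rec(0, {}):
            if not include_empty and not sub:
                continue
            if proper and sub == self:
                continue
            yield sub


@dataclass(frozen=True)
class DerivatizationScheme:
    """Reducing-end labeling chemistry.

    ``n_labels`` label molecules condense with the reducing end, losing
    ``condensation_loss`` Da (one water for PMP chemistry).  The net mass
    delta is ``n_labels * label_mass - condensation_loss``.
    """

    name: str = "bis-PMP"
    n_labels: int = 2
    label_mass: float = PMP_LABEL_MASS
    condensation_loss: float = WATER_MASS

    @property
    def mass_delta(self) -> float:
        return self.n_labels * self.label_mass - self.condensation_loss

    @classmethod
    def none(cls) -> "DerivatizationScheme":
        """The identity scheme (underivatized glycan)."""
        return cls(name="none", n_labels=0, label_mass=0.0, condensation_loss=0.0)


#: Two PMP molecules condensing with the reducing end, losing one water.
BIS_PMP = DerivatizationScheme()


@dataclass(frozen=True)
class IonSpec:
    """An adduct/charge specification; default singly protonated positive mode."""

    adduct: str = "H"
    charge: int = 1
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.adduct not in _ADDUCT_MASSES:
            raise ValueError(
                f"unknown adduct {self.adduct!r}; known: {sorted(_ADDUCT_MASSES)}"
            )
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity}")

    @property
    def adduct_mass(self) -> float:
        return _ADDUCT_MASSES[self.adduct]

    def mz(self, neutral_mass: float) -> float:
        sign = 1.0 if self.polarity == "positive" else -1.0
        return (neutral_mass + sign * self.charge * self.adduct_mass) / self.charge


#: The default [M+H]+ ion.
M_PLUS_H = IonSpec()


def residue_mass(code: str, registry: Optional[ResidueRegistry] = None) -> float:
    """Monoisotopic mass of one glycosidic residue (Da)."""
    registry = registry or default_registry()
    return registry.mass(code)


def neutral_glycan_mass(
    comp: GlycanComposition, registry: Optional[ResidueRegistry] = None
) -> float:
    """Mass of the free (underivatized) glycan: residue masses plus one water."""
    registry = registry or default_registry()
    return sum(n * registry.mass(code) for code, n in comp.counts.items()) + WATER_MASS


def derivatized_mass(
    comp: GlycanComposition,
    scheme: DerivatizationScheme = BIS_PMP,
    registry: Optional[ResidueRegistry] = None,
) -> float:
    """Mass of the labeled glycan: free glycan plus the scheme's mass delta."""
    return neutral_glycan_mass(comp, registry) + scheme.mass_delta


def ion_mz(neutral_mass: float, ion: IonSpec = M_PLUS_H) -> float:
    """m/z of the ionized species; [M+H]+ adds one proton."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return ion.mz(neutral_mass)
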
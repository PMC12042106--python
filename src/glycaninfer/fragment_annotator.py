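"""Explain MS2 peaks of a reducing-end-labeled glycan.

For a derivatized glycan fragmented at glycosidic bonds the observable ions
are:

* the intact precursor;
* Y ions — fragments retaining the labeled reducing end: sub-composition
  plus one water plus the label delta, plus the adduct;
* B ions — non-reducing oxocarbenium fragments: sum of residue masses plus
  a proton (no water, no label);
* neutral losses — precursor minus one uncharged terminal residue.

A precursor-minus-one-residue mass is numerically identical to the Y ion of
the complementary sub-composition; such matches carry the neutral-loss label
(the lost residue as sub-composition), which is the informative reading for
ladder-style interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .glycan_mass import (
    BIS_PMP,
    M_PLUS_H,
    DerivatizationScheme,
    GlycanComposition,
    IonSpec,
    ResidueRegistry,
    default_registry,
    derivatized_mass,
    ion_mz,
)

__all__ = [
    "Peak",
    "Spectrum",
    "TheoreticalFragment",
    "FragmentAnnotation",
    "AnnotationResult",
    "theoretical_fragments",
    "annotate_spectrum",
    "delta_ladder",
    "DEFAULT_ANNOTATION_TOLERANCE",
]

#: Default peak-matching tolerance (Da); printed 2-decimal m/z values
#: reproduce within 0.01 Da.
DEFAULT_ANNOTATION_TOLERANCE = 0.02

# Tie-break rank at equal |mass error|: label-retaining assignments first.
_SERIES_RANK = {"precursor": 0, "Y": 1, "B": 2, "neutral-loss": 3}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """An MS2 peak list with its precursor and chemistry context."""

    precursor_mz: float
    peaks: List[Peak] = field(default_factory=list)
    ion: IonSpec = M_PLUS_H
    scheme: DerivatizationScheme = BIS_PMP
    title: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mzs(self) -> List[float]:
        return [p.mz for p in self.peaks]


@dataclass(frozen=True)
class TheoreticalFragment:
    """One entry of the candidate fragment universe.

    For the neutral-loss series ``subcomp`` is the *lost* residue multiset;
    for precursor/Y/B it is the composition carried by the fragment.
    """

    series: str
    subcomp: GlycanComposition
    theoretical_mz: float


@dataclass(frozen=True)
class FragmentAnnotation:
    peak: Peak
    series: str
    subcomp: GlycanComposition
    theoretical_mz: float
    mass_error: float  # observed - theoretical, Da


@dataclass
class AnnotationResult:
    """Best annotation per matched peak plus diagnostics."""

    comp: GlycanComposition
    annotations: List[FragmentAnnotation]
    unmatched: List[Peak]
    universe: List[TheoreticalFragment]
    tolerance: float

    def candidates_for(self, peak: Peak) -> List[FragmentAnnotation]:
        """All in-tolerance annotations for one peak, best first."""
        cands = [
            FragmentAnnotation(peak, f.series, f.subcomp, f.theoretical_mz,
                               peak.mz - f.theoretical_mz)
            for f in self.universe
            if abs(peak.mz - f.theoretical_mz) <= self.tolerance
        ]
        cands.sort(key=_annotation_rank)
        return cands


def _annotation_rank(a: FragmentAnnotation) -> Tuple:
    return (abs(a.mass_error), _SERIES_RANK[a.series], str(a.subcomp))


def theoretical_fragments(
    comp: GlycanComposition,
    scheme: DerivatizationScheme = BIS_PMP,
    ion: IonSpec = M_PLUS_H,
    registry: Optional[ResidueRegistry] = None,
) -> List[TheoreticalFragment]:
    """The single-cleavage fragment universe of ``comp``.

    Emits the precursor, every Y ion of a non-empty sub-multiset (except
    those equal to the precursor minus one residue, which appear as
    neutral-loss entries), every B ion of a non-empty proper sub-multiset,
    and a neutral-loss entry per distinct residue.  Deduplicated by
    (series, sub-composition) and sorted by m/z.
    """
    if not comp:
        raise ValueError("composition must be non-empty")
    registry = registry or default_registry()
    precursor_mz = ion_mz(derivatized_mass(comp, scheme, registry), ion)
    proton_like = ion.adduct_mass  # oxocarbenium B ions carry the adduct charge

    out = {("precursor", comp): precursor_mz}
    if comp.total >= 2:
        for r in comp.counts:
            lost = GlycanComposition({r: 1})
            out[("neutral-loss", lost)] = precursor_mz - registry.mass(r)
    for sub in comp.sub_multisets():
        complement = comp.subtract(sub)
        # precursor-minus-one-residue Y masses are labeled neutral-loss above
        if complement.total != 1:
            out.setdefault(
                ("Y", sub), ion_mz(derivatized_mass(sub, scheme, registry), ion)
            )
        if sub != comp:
            b_mz = (
                sum(n * registry.mass(c) for c, n in sub.counts.items())
                + proton_like
            )
            out.setdefault(("B", sub), b_mz)
    frags = [TheoreticalFragment(s, c, mz) for (s, c), mz in out.items()]
    frags.sort(key=lambda f: (f.theoretical_mz, _SERIES_RANK[f.series], str(f.subcomp)))
    return frags


def annotate_spectrum(
    spec: Spectrum,
    comp: GlycanComposition,
    tolerance: float = DEFAULT_ANNOTATION_TOLERANCE,
    registry: Optional[ResidueRegistry] = None,
) -> AnnotationResult:
    """Match each peak to its best in-tolerance theoretical fragment.

    Best = smallest |mass error|, ties broken precursor > Y > B >
    neutral-loss, then by sub-composition string.  Unmatched peaks are
    reported in the result's diagnostics.
    """
    registry = registry or default_registry()
    universe = theoretical_fragments(comp, spec.scheme, spec.ion, registry)
    theo_precursor = ion_mz(derivatized_mass(comp, spec.scheme, registry), spec.ion)
    if abs(theo_precursor - spec.precursor_mz) > max(tolerance, 0.5):
        warnings.warn(
            f"composition {comp} (theoretical precursor {theo_precursor:.4f}) is "
            f"far from the spectrum precursor {spec.precursor_mz:.4f}",
            stacklevel=2,
        )
    annotations: List[FragmentAnnotation] = []
    unmatched: List[Peak] = []
    for peak in spec.peaks:
        best: Optional[FragmentAnnotation] = None
        for f in universe:
            err = peak.mz - f.theoretical_mz
            if abs(err) > tolerance:
                continue
            cand = FragmentAnnotation(peak, f.series, f.subcomp, f.theoretical_mz, err)
            if best is None or _annotation_rank(cand) < _annotation_rank(best):
                best = cand
        if best is None:
            unmatched.append(peak)
        else:
            annotations.append(best)
    return AnnotationResult(comp, annotations, unmatched, universe, tolerance)


def delta_ladder(
    spec: Spectrum,
    tolerance: float = DEFAULT_ANNOTATION_TOLERANCE,
    registry: Optional[ResidueRegistry] = None,
) -> List[Tuple[Peak, Peak, str]]:
    """Peak pairs whose m/z difference equals one residue mass.

    Returns ``(higher peak, lower peak, residue code)`` for every unordered
    peak pair and residue code with ``|Δm/z − residue mass| ≤ tolerance``;
    each pair appears at most once per residue code.
    """
    registry = registry or default_registry()
    peaks = sorted(spec.peaks, key=lambda p: p.mz)
    out: List[Tuple[Peak, Peak, str]] = []
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            delta = peaks[j].mz - peaks[i].mz
            for spec_r in registry:
                if abs(delta - spec_r.residue_mass) <= tolerance:
                    out.append((peaks[j], peaks[i], spec_r.code))
    out.sort(key=lambda t: (t[0].mz, t[1].mz, t[2]))
    return out
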
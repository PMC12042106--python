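"""Enumerate monosaccharide compositions matching an observed precursor m/z.

Given a precursor m/z, a derivatization scheme, and an adduct, the solver
searches all residue count vectors within per-residue and total bounds whose
theoretical m/z falls within tolerance, sorted by absolute mass error.  The
search is depth-first over residue codes in lexicographic order with
branch-and-bound pruning on the remaining mass; within the stated bounds it
is complete (every matching count vector is returned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

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

__all__ = ["SolverQuery", "CompositionCandidate", "enumerate_compositions",
           "filter_by_fragments"]


@dataclass(frozen=True)
class SolverQuery:
    """A precursor-matching query.

    Exactly one of ``tolerance_da`` (absolute, Da) or ``tolerance_ppm``
    (relative) must be set.  ``bounds`` caps the count of each residue code
    (default 10 for every code); ``max_total`` caps the total residue count.
    """

    target_mz: float
    scheme: DerivatizationScheme = BIS_PMP
    ion: IonSpec = M_PLUS_H
    tolerance_da: Optional[float] = 0.30
    tolerance_ppm: Optional[float] = None
    bounds: Union[int, Mapping[str, int]] = 10
    max_total: int = 15

    def __post_init__(self) -> None:
        if (self.tolerance_da is None) == (self.tolerance_ppm is None):
            raise ValueError("set exactly one of tolerance_da or tolerance_ppm")
        tol = self.tolerance_da if self.tolerance_da is not None else self.tolerance_ppm
        if tol <= 0:
            raise ValueError(f"tolerance must be positive, got {tol}")
        if self.target_mz <= 0:
            raise ValueError("target_mz must be positive")
        if self.max_total < 0:
            raise ValueError("max_total must be non-negative")

    @property
    def tolerance_in_da(self) -> float:
        if self.tolerance_da is not None:
            return self.tolerance_da
        return self.tolerance_ppm * 1e-6 * self.target_mz

    def bound_for(self, code: str) -> int:
        if isinstance(self.bounds, Mapping):
            return max(0, int(self.bounds.get(code, 0)))
        return max(0, int(self.bounds))


@dataclass(frozen=True)
class CompositionCandidate:
    """A composition whose theoretical m/z matches the query target."""

    comp: GlycanComposition
    theoretical_mz: float
    mass_error: float  # observed - theoretical, Da

    def __str__(self) -> str:
        return (f"{self.comp or 'empty'} "
                f"(m/z {self.theoretical_mz:.4f}, err {self.mass_error:+.4f})")


def _candidate(query: SolverQuery, registry: ResidueRegistry,
               counts: Dict[str, int]) -> CompositionCandidate:
    comp = GlycanComposition(dict(counts))
    theo = ion_mz(derivatized_mass(comp, query.scheme, registry), query.ion)
    return CompositionCandidate(comp, theo, query.target_mz - theo)


def enumerate_compositions(
    query: SolverQuery, registry: Optional[ResidueRegistry] = None
) -> List[CompositionCandidate]:
    """All compositions within tolerance and bounds, by |mass error| ascending.

    Ties are broken by fewer total residues, then by the lexicographic
    sequence of residue codes, so output order is fully reproducible.
    """
    registry = registry or default_registry()
    tol_da = query.tolerance_in_da
    charge = query.ion.charge
    # Residue-sum mass implied by the target m/z (strip adduct, water, labels).
    sign = 1.0 if query.ion.polarity == "positive" else -1.0
    neutral_target = query.target_mz * charge - sign * charge * query.ion.adduct_mass
    from .glycan_mass import WATER_MASS  # local to avoid polluting module ns

    residue_sum_target = neutral_target - WATER_MASS - query.scheme.mass_delta
    tol_neutral = tol_da * charge

    codes = sorted(registry.codes)
    masses = [registry.mass(c) for c in codes]
    min_mass = min(masses) if masses else 0.0

    results: List[CompositionCandidate] = []
    counts: Dict[str, int] = {}

    def dfs(i: int, acc_mass: float, acc_total: int) -> None:
        remaining = residue_sum_target - acc_mass
        if remaining < -tol_neutral:
            return  # overshoot beyond tolerance; adding residues only worsens it
        if i == len(codes):
            if abs(remaining) <= tol_neutral:
                results.append(_candidate(query, registry, counts))
            return
        # Even filling every remaining slot with the heaviest residue cannot
        # reach the target: prune.
        slots_left = query.max_total - acc_total
        if slots_left >= 0 and masses and remaining - slots_left * max(masses[i:], default=0.0) > tol_neutral:
            return
        code, m = codes[i], masses[i]
        cap = min(query.bound_for(code), query.max_total - acc_total)
        n = 0
        while n <= cap and acc_mass + n * m - residue_sum_target <= tol_neutral:
            if n:
                counts[code] = n
            dfs(i + 1, acc_mass + n * m, acc_total + n)
            counts.pop(code, None)
            n += 1

    dfs(0, 0.0, 0)

    results.sort(
        key=lambda c: (
            abs(c.mass_error),
            c.comp.total,
            tuple(sorted(c.comp.counts.items())),
        )
    )
    return results


def filter_by_fragments(
    candidates: Sequence[CompositionCandidate],
    required_subcompositions: Sequence[GlycanComposition],
) -> List[CompositionCandidate]:
    """Keep candidates containing every required sub-composition (multiset
    inclusion) — the fragment-evidence constraint on the precursor assignment."""
    return [
        c
        for c in candidates
        if all(c.comp.contains(sub) for sub in required_subcompositions)
    ]
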
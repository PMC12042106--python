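"""Key-residue conservation across homologues in a multiple alignment.

Given an aligned set of protein sequences and a reference-anchored list of
catalytic positions (e.g. F66, D69, D70, Y640, W1033 of a viral tailspike's
endo-mannanase-like domain), classify every sequence at every key column as
conserved (identical letter), substituted, or gap, and report which
sequences are conserved at all positions.  Positions are 1-based in the
*ungapped* reference, matching "Phe66"-style residue nomenclature;
conservation means strict identity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

__all__ = [
    "KeyResidueSet",
    "ConservationReport",
    "map_reference_positions",
    "check_key_residues",
]

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO")
_RESIDUE_TOKEN = re.compile(r"^([A-Za-z])(\d+)$")


@dataclass(frozen=True)
class KeyResidueSet:
    """Reference-anchored key positions: (1-based ungapped position, letter)."""

    reference_id: str
    positions: Tuple[Tuple[int, str], ...]

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.positions]
        if pos != sorted(set(pos)):
            raise ValueError("positions must be sorted and unique")
        for p, letter in self.positions:
            if p < 1:
                raise ValueError(f"position {p} must be >= 1")
            if letter.upper() not in _AA_LETTERS:
                raise ValueError(f"invalid amino-acid letter {letter!r}")

    @classmethod
    def parse(cls, reference_id: str, text: str) -> "KeyResidueSet":
        """Parse a compact list like ``"F66,D69,D70,Y640,W1033"``."""
        positions: List[Tuple[int, str]] = []
        for tok in text.split(","):
            m = _RESIDUE_TOKEN.match(tok.strip())
            if not m:
                raise ValueError(f"cannot parse key residue {tok!r} (expected e.g. F66)")
            positions.append((int(m.group(2)), m.group(1).upper()))
        positions.sort()
        return cls(reference_id, tuple(positions))


@dataclass
class ConservationReport:
    """Per-sequence status vector over the key positions.

    Statuses are ``"conserved"``, ``"substituted:X"`` (X the observed
    letter), or ``"gap"``.
    """

    keyset: KeyResidueSet
    columns: Tuple[int, ...]  # 1-based alignment columns of the key positions
    per_sequence: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    @property
    def fully_conserved_ids(self) -> List[str]:
        return [
            sid
            for sid, vec in self.per_sequence.items()
            if all(s == "conserved" for s in vec)
        ]


def _validate_alignment(alignment: Mapping[str, str]) -> None:
    if not alignment:
        raise ValueError("alignment is empty")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")


def map_reference_positions(
    alignment: Mapping[str, str], reference_id: str
) -> Dict[int, int]:
    """1-based ungapped reference position -> 1-based alignment column."""
    _validate_alignment(alignment)
    if reference_id not in alignment:
        raise KeyError(
            f"reference {reference_id!r} not in alignment "
            f"(ids: {', '.join(list(alignment)[:10])}...)"
        )
    mapping: Dict[int, int] = {}
    pos = 0
    for col, letter in enumerate(alignment[reference_id], start=1):
        if letter != "-":
            pos += 1
            mapping[pos] = col
    return mapping


def check_key_residues(
    alignment: Mapping[str, str], keyset: KeyResidueSet
) -> ConservationReport:
    """Classify every sequence at every key column relative to the reference."""
    _validate_alignment(alignment)
    mapping = map_reference_positions(alignment, keyset.reference_id)
    ref = alignment[keyset.reference_id]
    columns: List[int] = []
    for pos, expected in keyset.positions:
        if pos not in mapping:
            raise ValueError(
                f"key position {pos} exceeds reference ungapped length {len(mapping)}"
            )
        col = mapping[pos]
        observed = ref[col - 1].upper()
        if observed != expected.upper():
            warnings.warn(
                f"reference letter at position {pos} is {observed}, expected "
                f"{expected} — key-residue coordinates may be stale",
                stacklevel=2,
            )
        columns.append(col)

    report = ConservationReport(keyset, tuple(columns))
    expected_letters = [ref[c - 1].upper() for c in columns]
    for sid, seq in alignment.items():
        vec: List[str] = []
        for col, exp in zip(columns, expected_letters):
            letter = seq[col - 1].upper()
            if letter == "-":
                vec.append("gap")
            elif letter == exp:
                vec.append("conserved")
            else:
                vec.append(f"substituted:{letter}")
        report.per_sequence[sid] = tuple(vec)
    return report
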
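"""HPAEC-PAD chromatogram annotation and before/after-treatment diffing.

Pulsed amperometric detection identifies sugars only by retention time, so
the module's vocabulary is deliberately modest: detect peaks, assign them to
user-supplied retention-time standards, and report which peaks appear,
disappear, or shift between two conditions (e.g. an N-glycan substrate
before and after incubation with virions or glycosidases).  Retention times
are instrument-specific and always come from the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "RetentionStandard",
    "DetectedPeak",
    "ChangeReport",
    "detect_peaks",
    "match_standards",
    "diff_conditions",
    "DEFAULT_RT_TOLERANCE",
    "DEFAULT_MIN_HEIGHT_FRAC",
]

#: Default retention-time matching tolerance (minutes).
DEFAULT_RT_TOLERANCE = 0.2
#: Default peak threshold as a fraction of the trace maximum.
DEFAULT_MIN_HEIGHT_FRAC = 0.05


@dataclass
class Chromatogram:
    """A detector trace: strictly increasing retention times (minutes) and
    finite signal (arbitrary units)."""

    times: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("retention times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RetentionStandard:
    analyte: str
    rt: float
    rt_tolerance: float = DEFAULT_RT_TOLERANCE

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("standard retention time must be positive")
        if self.rt_tolerance <= 0:
            raise ValueError("rt tolerance must be positive")


@dataclass(frozen=True)
class DetectedPeak:
    apex_rt: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.area <= 0:
            raise ValueError("peak height and area must be positive")


@dataclass
class ChangeReport:
    """Differences between two chromatograms.

    ``consumed``: peaks present only before; ``produced``: only after;
    ``matched``: (before, after) pairs within tolerance; ``shifts``:
    consumed/produced pairs that are mutually nearest — candidate retention
    shifts of one analyte (PAD cannot prove identity, so these are flags,
    not assignments).
    """

    consumed: List[DetectedPeak] = field(default_factory=list)
    produced: List[DetectedPeak] = field(default_factory=list)
    matched: List[Tuple[DetectedPeak, DetectedPeak]] = field(default_factory=list)
    shifts: List[Tuple[DetectedPeak, DetectedPeak]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.consumed and not self.produced

    def summary(self) -> str:
        lines = []
        for b, a in self.matched:
            lines.append(f"unchanged: {b.apex_rt:.2f} min -> {a.apex_rt:.2f} min")
        for p in self.consumed:
            lines.append(f"consumed:  {p.apex_rt:.2f} min (height {p.height:.3g})")
        for p in self.produced:
            lines.append(f"produced:  {p.apex_rt:.2f} min (height {p.height:.3g})")
        for b, a in self.shifts:
            lines.append(f"shift?     {b.apex_rt:.2f} min -> {a.apex_rt:.2f} min")
        return "\n".join(lines) if lines else "no changes"


def detect_peaks(
    chrom: Chromatogram, min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC
) -> List[DetectedPeak]:
    """Local maxima above ``min_height_frac`` of the trace maximum.

    Apex at the sample maximum; area by trapezoid between the flanking
    local minima (or trace ends).  Returns peaks sorted by apex retention
    time; a flat or non-positive trace yields no peaks.
    """
    if len(chrom) < 3:
        raise ValueError("need at least 3 trace points")
    y = chrom.signal
    ymax = float(y.max())
    if ymax <= 0 or np.allclose(y, y[0]):
        return []
    idx, _ = find_peaks(y, height=min_height_frac * ymax)
    peaks: List[DetectedPeak] = []
    for i in idx:
        lo = i
        while lo > 0 and y[lo - 1] < y[lo]:
            lo -= 1
        hi = i
        while hi < len(y) - 1 and y[hi + 1] < y[hi]:
            hi += 1
        area = float(np.trapezoid(y[lo : hi + 1], chrom.times[lo : hi + 1]))
        if area <= 0:
            continue
        peaks.append(DetectedPeak(float(chrom.times[i]), float(y[i]), area))
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def match_standards(
    peaks: Sequence[DetectedPeak],
    standards: Sequence[RetentionStandard],
) -> List[Tuple[DetectedPeak, Optional[str]]]:
    """Assign each peak to the nearest standard within that standard's
    tolerance; each standard claims at most one peak (closest wins, ties to
    the earlier-eluting peak).  Unassignable peaks map to ``None``."""
    pairs = []
    for pi, p in enumerate(peaks):
        for s in standards:
            d = abs(p.apex_rt - s.rt)
            if d <= s.rt_tolerance:
                pairs.append((d, p.apex_rt, s.analyte, pi))
    pairs.sort()
    assigned: dict = {}
    used_standards = set()
    for _, _, analyte, pi in pairs:
        if pi in assigned or analyte in used_standards:
            continue
        assigned[pi] = analyte
        used_standards.add(analyte)
    return [(p, assigned.get(pi)) for pi, p in enumerate(peaks)]


def _greedy_rt_match(
    a: Sequence[DetectedPeak], b: Sequence[DetectedPeak], tol: float
) -> List[Tuple[int, int]]:
    cand = [
        (abs(pa.apex_rt - pb.apex_rt), ia, ib)
        for ia, pa in enumerate(a)
        for ib, pb in enumerate(b)
        if abs(pa.apex_rt - pb.apex_rt) <= tol
    ]
    cand.sort()
    used_a, used_b, out = set(), set(), []
    for _, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        out.append((ia, ib))
    return out


def _mutual_nearest(
    a: Sequence[DetectedPeak], b: Sequence[DetectedPeak]
) -> List[Tuple[int, int]]:
    out = []
    for ia, pa in enumerate(a):
        if not b:
            break
        ib = min(range(len(b)), key=lambda j: abs(b[j].apex_rt - pa.apex_rt))
        back = min(range(len(a)), key=lambda i: abs(a[i].apex_rt - b[ib].apex_rt))
        if back == ia:
            out.append((ia, ib))
    return out


def diff_conditions(
    before: Chromatogram,
    after: Chromatogram,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
    min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC,
) -> ChangeReport:
    """Call substrate disappearance, product appearance, and candidate peak
    shifts between two traces."""
    pb = detect_peaks(before, min_height_frac)
    pa = detect_peaks(after, min_height_frac)
    matched_idx = _greedy_rt_match(pb, pa, rt_tolerance)
    used_b = {ia for ia, _ in matched_idx}
    used_a = {ib for _, ib in matched_idx}
    consumed = [p for i, p in enumerate(pb) if i not in used_b]
    produced = [p for i, p in enumerate(pa) if i not in used_a]
    shifts = [
        (consumed[ia], produced[ib]) for ia, ib in _mutual_nearest(consumed, produced)
    ]
    return ChangeReport(
        consumed=consumed,
        produced=produced,
        matched=[(pb[ia], pa[ib]) for ia, ib in matched_idx],
        shifts=shifts,
    )
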
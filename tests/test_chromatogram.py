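"""Peak detection, standards matching, and condition diffing tests.

Retention times in these fixtures are synthetic constructions; an
HPAEC-PAD instrument's actual retention times are user input.
"""

import numpy as np
import pytest

from glycaninfer.chromatogram import (
    Chromatogram,
    DetectedPeak,
    RetentionStandard,
    detect_peaks,
    diff_conditions,
    match_standards,
)
from glycaninfer.synthetic_data import ChromSimConfig, ChromSpecies, simulate_chromatogram


def _gaussians(species, noise_sd=0.0, seed=0):
    chrom, _ = simulate_chromatogram(
        ChromSimConfig(species=tuple(species), noise_sd=noise_sd, seed=seed)
    )
    return chrom


def test_single_gaussian_detected_at_apex():
    chrom = _gaussians([ChromSpecies("x", 7.2, 100.0, 0.05)])
    peaks = detect_peaks(chrom)
    assert len(peaks) == 1
    assert peaks[0].apex_rt == pytest.approx(7.2, abs=0.01)


def test_two_resolved_gaussians_in_rt_order():
    chrom = _gaussians([ChromSpecies("a", 9.5, 50.0, 0.05),
                        ChromSpecies("b", 7.2, 100.0, 0.05)])
    peaks = detect_peaks(chrom)
    assert [round(p.apex_rt, 1) for p in peaks] == [7.2, 9.5]


def test_noisy_four_species_trace_yields_four_peaks():
    species = [ChromSpecies(n, rt, 80.0, 0.06)
               for n, rt in [("a", 4.0), ("b", 6.0), ("c", 9.0), ("d", 11.5)]]
    chrom = _gaussians(species, noise_sd=0.5, seed=42)
    assert len(detect_peaks(chrom)) == 4


def test_flat_trace_yields_nothing():
    t = np.linspace(0, 10, 101)
    assert detect_peaks(Chromatogram(t, np.ones_like(t))) == []
    with pytest.raises(ValueError, match="3 trace points"):
        detect_peaks(Chromatogram(np.array([0.0, 1.0]), np.array([0.0, 1.0])))


def test_gaussian_area_recovered():
    chrom = _gaussians([ChromSpecies("x", 7.2, 100.0, 0.05)])
    (peak,) = detect_peaks(chrom)
    assert peak.area == pytest.approx(100.0 * 0.05 * np.sqrt(2 * np.pi), rel=0.02)


def test_apex_within_one_sampling_interval():
    interval = 0.02
    chrom, _ = simulate_chromatogram(
        ChromSimConfig(
            species=(ChromSpecies("a", 5.005, 10.0, 0.1),
                     ChromSpecies("b", 8.377, 20.0, 0.1)),
            sampling_interval=interval,
        )
    )
    peaks = detect_peaks(chrom)
    assert len(peaks) == 2
    for peak, true_rt in zip(peaks, (5.005, 8.377)):
        assert abs(peak.apex_rt - true_rt) <= interval


STANDARDS = [
    RetentionStandard("GlcNAc", 4.0),
    RetentionStandard("Gal", 5.0),
    RetentionStandard("Glc", 6.0),
    RetentionStandard("Man", 9.0),
]


def test_hydrolysate_fixture_assigns_three_of_four_standards():
    """A synthetic hydrolysate with GlcNAc, Glc and Man present but no Gal:
    three peaks assigned, the Gal standard left unclaimed."""
    chrom = _gaussians(
        [ChromSpecies("GlcNAc", 4.0, 80.0, 0.05),
         ChromSpecies("Glc", 6.0, 60.0, 0.05),
         ChromSpecies("Man", 9.0, 70.0, 0.05)],
        noise_sd=0.2, seed=3,
    )
    assignments = match_standards(detect_peaks(chrom), STANDARDS)
    named = {a for _, a in assignments if a}
    assert named == {"GlcNAc", "Glc", "Man"}


def test_match_standards_empty_and_tie_break():
    assert match_standards([], STANDARDS) == []
    early = DetectedPeak(5.9, 10.0, 1.0)
    late = DetectedPeak(6.1, 10.0, 1.0)
    assignments = dict(
        (p.apex_rt, a)
        for p, a in match_standards([early, late], [RetentionStandard("Glc", 6.0)])
    )
    assert assignments[5.9] == "Glc" and assignments[6.1] is None


def test_match_standards_stable_under_uniform_shift():
    peaks = [DetectedPeak(4.05, 10.0, 1.0), DetectedPeak(8.95, 20.0, 1.0)]
    base = [a for _, a in match_standards(peaks, STANDARDS)]
    shift = 1.7
    shifted_peaks = [DetectedPeak(p.apex_rt + shift, p.height, p.area) for p in peaks]
    shifted_standards = [
        RetentionStandard(s.analyte, s.rt + shift, s.rt_tolerance) for s in STANDARDS
    ]
    assert [a for _, a in match_standards(shifted_peaks, shifted_standards)] == base


def test_diff_identical_traces_is_empty():
    chrom = _gaussians([ChromSpecies("x", 7.2, 100.0, 0.05)])
    report = diff_conditions(chrom, chrom)
    assert report.is_empty and len(report.matched) == 1


def test_diff_is_antisymmetric():
    a = _gaussians([ChromSpecies("x", 7.2, 100.0, 0.05)])
    b = _gaussians([ChromSpecies("y", 8.3, 60.0, 0.05)])
    fwd = diff_conditions(a, b)
    rev = diff_conditions(b, a)
    assert [p.apex_rt for p in fwd.consumed] == [p.apex_rt for p in rev.produced]
    assert [p.apex_rt for p in fwd.produced] == [p.apex_rt for p in rev.consumed]


def test_injected_gaussian_appears_as_single_product():
    before = _gaussians([ChromSpecies("x", 7.2, 100.0, 0.05)])
    after = _gaussians([ChromSpecies("x", 7.2, 100.0, 0.05),
                        ChromSpecies("new", 11.0, 40.0, 0.05)])
    report = diff_conditions(before, after)
    assert not report.consumed
    assert [round(p.apex_rt, 1) for p in report.produced] == [11.0]


def test_virion_hydrolysis_fixture_reports_shift_and_product():
    """Substrate at 7.2 min consumed; products at 8.3 min (mutual-nearest
    shift candidate) and at the mannose standard's retention time."""
    before = _gaussians([ChromSpecies("glycan", 7.2, 100.0, 0.05)], 0.1, seed=5)
    after = _gaussians([ChromSpecies("oligo", 8.3, 60.0, 0.05),
                        ChromSpecies("Man", 9.0, 40.0, 0.05)], 0.1, seed=6)
    report = diff_conditions(before, after)
    assert [round(p.apex_rt, 1) for p in report.consumed] == [7.2]
    assert [round(p.apex_rt, 1) for p in report.produced] == [8.3, 9.0]
    assert [(round(b.apex_rt, 1), round(a.apex_rt, 1)) for b, a in report.shifts] == [
        (7.2, 8.3)
    ]
    man_products = match_standards(report.produced, STANDARDS)
    assert ("Man" in [a for _, a in man_products])


def test_chromatogram_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        Chromatogram(np.array([1.0, 1.0, 2.0]), np.zeros(3))
    with pytest.raises(ValueError, match="finite"):
        Chromatogram(np.array([1.0, 2.0, 3.0]), np.array([0.0, np.inf, 0.0]))
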
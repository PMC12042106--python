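"""Simulators with known ground truth for every inference stage.

Spectra are generated the way single-glycosidic-cleavage fragmentation of a
reducing-end-labeled glycan works: each tree edge cut yields the Y ion of
the root-side component and the B ion of the leaf-side subtree, plus the
intact precursor.  Gaussian m/z jitter, fragment dropout, and uniform decoy
peaks model instrument imperfection.  Chromatograms are sums of Gaussians
on a uniform time grid with additive noise; alignments are a reference plus
homologues with a planted subset conserved at the key positions.  Every
simulator is a deterministic function of its config (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram
from .conservation import KeyResidueSet
from .fragment_annotator import Peak, Spectrum
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
from .topology_inference import GlycanTopology

__all__ = [
    "SpectrumSimConfig",
    "ChromSimConfig",
    "ChromSpecies",
    "simulate_spectrum",
    "simulate_chromatogram",
    "simulate_alignment",
    "ssv19_fixture_topology",
    "random_topology",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def ssv19_fixture_topology() -> GlycanTopology:
    """A plausible heptasaccharide emulating the SSV19 host N-glycan.

    Linear chain HexNAc-HexNAc-QuiS-Hex-Hex-Hex-Hex (reducing end first):
    the HexNAc2 core carries sulfoquinovose, which in turn carries the
    hexose arm, so single cleavages yield root-side fragments HexNAc2 and
    HexNAc2 QuiS1.  This is one topology consistent with the fragment
    evidence, synthetic and documented as an emulation — not a structure
    determination.
    """
    nodes = ("HexNAc", "HexNAc", "QuiS", "Hex", "Hex", "Hex", "Hex")
    parents = (None, 0, 1, 2, 3, 4, 5)
    return GlycanTopology(nodes, parents)


def random_topology(
    n_nodes: int,
    rng: np.random.Generator,
    codes: Sequence[str] = ("Hex", "HexNAc", "dHex", "Pent", "HexA", "QuiS"),
    n_residue_types: int = 3,
    max_children: int = 4,
) -> GlycanTopology:
    """A random recursive tree labeled from a small residue alphabet.

    Each tree draws its labels from a random subset of ``n_residue_types``
    codes (default 3) — natural oligosaccharides of this size are built
    from a handful of residue classes, and the bound also keeps exhaustive
    tree enumeration over the resulting composition tractable.
    """
    alphabet = list(rng.choice(list(codes),
                               size=min(n_residue_types, len(codes)),
                               replace=False))
    nodes = tuple(str(rng.choice(alphabet)) for _ in range(n_nodes))
    parents: List[Optional[int]] = [None]
    counts = [0] * n_nodes
    for i in range(1, n_nodes):
        eligible = [j for j in range(i) if counts[j] < max_children]
        p = int(rng.choice(eligible))
        parents.append(p)
        counts[p] += 1
    return GlycanTopology(nodes, tuple(parents))


@dataclass(frozen=True)
class SpectrumSimConfig:
    topology: GlycanTopology
    scheme: DerivatizationScheme = BIS_PMP
    ion: IonSpec = M_PLUS_H
    mz_jitter_sd: float = 0.005
    n_decoy_peaks: int = 0
    decoy_mz_range: Tuple[float, float] = (150.0, 2000.0)
    fragment_coverage: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_coverage <= 1.0:
            raise ValueError("fragment_coverage must be in [0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be non-negative")


def _true_fragments(
    topo: GlycanTopology,
    scheme: DerivatizationScheme,
    ion: IonSpec,
    registry: ResidueRegistry,
) -> List[Tuple[str, GlycanComposition, float]]:
    """(series, composition, theoretical m/z) for the precursor and every
    single-edge cut; deduplicated by (series, composition)."""
    full = topo.composition()
    precursor_mz = ion_mz(derivatized_mass(full, scheme, registry), ion)
    seen = {("precursor", full): precursor_mz}
    for _, child in topo.edges():
        leaf_side = topo.subtree_composition(child)
        root_side = full.subtract(leaf_side)
        seen.setdefault(
            ("Y", root_side),
            ion_mz(derivatized_mass(root_side, scheme, registry), ion),
        )
        b_mz = (
            sum(n * registry.mass(c) for c, n in leaf_side.counts.items())
            + ion.adduct_mass
        )
        seen.setdefault(("B", leaf_side), b_mz)
    return [(s, c, mz) for (s, c), mz in seen.items()]


def simulate_spectrum(
    cfg: SpectrumSimConfig, registry: Optional[ResidueRegistry] = None
) -> Tuple[Spectrum, pd.DataFrame]:
    """Simulate an MS2 spectrum of a labeled glycan plus its truth table.

    The truth table has one row per theoretical fragment (series, subcomp,
    mz_true, emitted, mz_observed) and one per decoy peak.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)
    frags = _true_fragments(cfg.topology, cfg.scheme, cfg.ion, registry)
    precursor_mz = frags[0][2]

    rows = []
    peaks: List[Peak] = []
    for series, comp, mz_true in frags:
        emitted = series == "precursor" or rng.random() < cfg.fragment_coverage
        mz_obs = np.nan
        if emitted:
            mz_obs = mz_true + rng.normal(0.0, cfg.mz_jitter_sd)
            intensity = float(10 ** rng.uniform(3.0, 4.0))
            peaks.append(Peak(mz_obs, intensity))
        rows.append(
            {
                "series": series,
                "subcomp": str(comp),
                "mz_true": mz_true,
                "emitted": emitted,
                "mz_observed": mz_obs,
                "is_decoy": False,
            }
        )
    lo, hi = cfg.decoy_mz_range
    for _ in range(cfg.n_decoy_peaks):
        mz = float(rng.uniform(lo, min(hi, precursor_mz)))
        peaks.append(Peak(mz, float(10 ** rng.uniform(3.0, 4.0))))
        rows.append(
            {
                "series": "decoy",
                "subcomp": "",
                "mz_true": np.nan,
                "emitted": True,
                "mz_observed": mz,
                "is_decoy": True,
            }
        )
    spectrum = Spectrum(
        precursor_mz=precursor_mz,
        peaks=peaks,
        ion=cfg.ion,
        scheme=cfg.scheme,
        title=f"synthetic:{cfg.topology.to_text()}",
    )
    return spectrum, pd.DataFrame(rows)


@dataclass(frozen=True)
class ChromSpecies:
    name: str
    rt: float
    height: float
    width: float  # Gaussian sd, minutes

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class ChromSimConfig:
    species: Tuple[ChromSpecies, ...] = ()
    sampling_interval: float = 0.01  # minutes
    noise_sd: float = 0.0
    t_start: float = 0.0
    t_end: float = 15.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


def simulate_chromatogram(cfg: ChromSimConfig) -> Tuple[Chromatogram, pd.DataFrame]:
    """Sum-of-Gaussians trace plus the ground-truth species table."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.t_start, cfg.t_end + cfg.sampling_interval / 2,
                  cfg.sampling_interval)
    y = np.zeros_like(t)
    rows = []
    for sp in cfg.species:
        y += sp.height * np.exp(-0.5 * ((t - sp.rt) / sp.width) ** 2)
        rows.append(
            {
                "name": sp.name,
                "rt": sp.rt,
                "height": sp.height,
                "width": sp.width,
                "area": sp.height * sp.width * np.sqrt(2 * np.pi),
            }
        )
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    return Chromatogram(t, y, label=cfg.label), pd.DataFrame(
        rows, columns=["name", "rt", "height", "width", "area"]
    )


def simulate_alignment(
    n_sequences: int,
    keyset: KeyResidueSet,
    n_conserved: int,
    mutation_rate: float = 0.05,
    gap_rate: float = 0.02,
    seed: int = 0,
    length: Optional[int] = None,
) -> Tuple[Dict[str, str], Dict[str, bool]]:
    """A reference plus homologues with a planted conserved subset.

    Exactly ``n_conserved`` homologues match the reference at every key
    position; the rest are substituted at one or more key positions.  The
    reference itself is ungapped and is not counted in ``n_conserved``.
    Returns (alignment, truth) where truth maps homologue id -> fully
    conserved at all key positions.
    """
    if n_conserved > n_sequences:
        raise ValueError("n_conserved cannot exceed n_sequences")
    rng = np.random.default_rng(seed)
    max_pos = max(p for p, _ in keyset.positions)
    L = length if length is not None else max_pos + 20
    if L < max_pos:
        raise ValueError(f"length {L} shorter than last key position {max_pos}")

    ref = [str(rng.choice(list(_AA20))) for _ in range(L)]
    for pos, letter in keyset.positions:
        ref[pos - 1] = letter.upper()
    key_cols = {pos - 1 for pos, _ in keyset.positions}

    conserved_flags = [True] * n_conserved + [False] * (n_sequences - n_conserved)
    rng.shuffle(conserved_flags)

    alignment: Dict[str, str] = {keyset.reference_id: "".join(ref)}
    truth: Dict[str, bool] = {}
    for i, keep in enumerate(conserved_flags):
        sid = f"homologue_{i + 1:03d}"
        seq = list(ref)
        for j in range(L):
            if j in key_cols:
                continue
            r = rng.random()
            if r < gap_rate:
                seq[j] = "-"
            elif r < gap_rate + mutation_rate:
                seq[j] = str(rng.choice([a for a in _AA20 if a != seq[j]]))
        if not keep:
            n_hits = 1 + int(rng.integers(0, len(key_cols)))
            hit_cols = rng.choice(sorted(key_cols), size=n_hits, replace=False)
            for j in hit_cols:
                seq[int(j)] = str(rng.choice([a for a in _AA20 if a != ref[int(j)]]))
        alignment[sid] = "".join(seq)
        truth[sid] = keep
    return alignment, truth
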
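"""Readers and writers for the formats the analysis stages touch.

MGF peak lists go through pyteomics; aligned FASTA through Biopython;
chromatograms, standards tables, and reports are plain CSV (comma-separated,
header row, '.' decimal, UTF-8).  Registry and scheme overrides come from a
small YAML config.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .chromatogram import Chromatogram, RetentionStandard, DEFAULT_RT_TOLERANCE
from .fragment_annotator import Peak, Spectrum
from .glycan_mass import (
    BIS_PMP,
    DerivatizationScheme,
    ResidueRegistry,
    ResidueSpec,
    default_registry,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_chromatogram",
    "write_chromatogram",
    "read_standards",
    "read_alignment",
    "write_alignment",
    "load_registry_config",
    "load_scheme_config",
]

PathLike = Union[str, Path]


def read_spectrum(
    path: PathLike,
    format: Optional[str] = None,
    precursor_mz: Optional[float] = None,
) -> Spectrum:
    """Read one spectrum from MGF (PEPMASS as precursor) or two-column CSV.

    For CSV the precursor is not part of the file and must be supplied via
    ``precursor_mz``.  The format is inferred from the extension when not
    given.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        with _mgf.read(str(path)) as reader:
            entries = list(reader)
        if not entries:
            raise ValueError(f"{path}: no spectra found")
        entry = entries[0]
        pepmass = entry["params"].get("pepmass")
        if pepmass is None and precursor_mz is None:
            raise ValueError(
                f"{path}: MGF block lacks PEPMASS; pass precursor_mz explicitly"
            )
        prec = precursor_mz if precursor_mz is not None else float(pepmass[0])
        mzs = np.asarray(entry["m/z array"], dtype=float)
        intens = np.asarray(entry["intensity array"], dtype=float)
        if len(mzs) == 0:
            warnings.warn(f"{path}: empty peak block", stacklevel=2)
        peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, intens)]
        title = str(entry["params"].get("title", ""))
        return Spectrum(precursor_mz=prec, peaks=peaks, title=title)
    if fmt == "csv":
        if precursor_mz is None:
            raise ValueError(
                "CSV peak lists carry no precursor; pass precursor_mz "
                "(CLI flag --precursor-mz)"
            )
        df = _read_csv(path, expected=("mz", "intensity"))
        peaks = [Peak(float(r.mz), float(r.intensity)) for r in df.itertuples()]
        return Spectrum(precursor_mz=precursor_mz, peaks=peaks, title=path.stem)
    raise ValueError(f"unsupported spectrum format {fmt!r} (use mgf or csv)")


def write_spectrum(spec: Spectrum, path: PathLike, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        entry = {
            "m/z array": np.array([p.mz for p in spec.peaks]),
            "intensity array": np.array([p.intensity for p in spec.peaks]),
            "params": {
                "title": spec.title or "spectrum",
                "pepmass": (spec.precursor_mz,),
                "charge": f"{spec.ion.charge}+",
            },
        }
        with open(path, "w") as fh:
            _mgf.write([entry], fh)
        return
    if fmt == "csv":
        pd.DataFrame(
            {"mz": [p.mz for p in spec.peaks],
             "intensity": [p.intensity for p in spec.peaks]}
        ).to_csv(path, index=False)
        return
    raise ValueError(f"unsupported spectrum format {fmt!r} (use mgf or csv)")


def _read_csv(path: Path, expected: Tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text suffices
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected header {list(expected)}"
        )
    return df


def read_chromatogram(path: PathLike, label: str = "") -> Chromatogram:
    """Two-column CSV: rt (minutes), signal."""
    path = Path(path)
    df = _read_csv(path, expected=("rt", "signal"))
    return Chromatogram(
        df["rt"].to_numpy(float), df["signal"].to_numpy(float),
        label=label or path.stem,
    )


def write_chromatogram(chrom: Chromatogram, path: PathLike) -> None:
    pd.DataFrame({"rt": chrom.times, "signal": chrom.signal}).to_csv(
        path, index=False
    )


def read_standards(path: PathLike) -> List[RetentionStandard]:
    """CSV with columns analyte, rt and optional rt_tolerance (minutes)."""
    path = Path(path)
    df = _read_csv(path, expected=("analyte", "rt"))
    out = []
    for r in df.itertuples():
        tol = getattr(r, "rt_tolerance", None)
        if tol is None or (isinstance(tol, float) and np.isnan(tol)):
            tol = DEFAULT_RT_TOLERANCE
        out.append(RetentionStandard(str(r.analyte), float(r.rt), float(tol)))
    return out


def read_alignment(path: PathLike) -> Dict[str, str]:
    """Aligned FASTA -> ordered id->sequence mapping; validates rectangular
    shape and id uniqueness."""
    path = Path(path)
    alignment: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in alignment:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        alignment[rec.id] = str(rec.seq).upper()
    if not alignment:
        raise ValueError(f"{path}: no sequences found")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(
            f"{path}: ragged alignment (row lengths {sorted(lengths)}); "
            "input must be aligned FASTA"
        )
    return alignment


def write_alignment(alignment: Dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid, seq in alignment.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_registry_config(path: PathLike) -> ResidueRegistry:
    """Extend the default registry from a YAML config.

    Schema::

        residues:
          - code: Xyl
            formula: C5H8O4
            class: pentose

    Entries override defaults with the same code.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {"residues", "schemes"}
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    extra = []
    for entry in data.get("residues", []) or []:
        bad = set(entry) - {"code", "formula", "class", "residue_mass"}
        if bad:
            raise ValueError(f"unknown residue config keys {sorted(bad)}")
        extra.append(
            ResidueSpec(
                code=str(entry["code"]),
                formula=str(entry["formula"]),
                class_label=str(entry.get("class", entry["code"])),
                residue_mass=float(entry.get("residue_mass", 0.0)),
            )
        )
    return default_registry().extended(extra)


def load_scheme_config(path: PathLike, name: str) -> DerivatizationScheme:
    """Look up a derivatization scheme by name from the YAML config.

    Schema::

        schemes:
          - name: mono-PMP
            n_labels: 1
            label_formula: C10H10N2O
            condensation_loss: 18.010565
    """
    from pyteomics import mass as _ptmass

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for entry in data.get("schemes", []) or []:
        if entry.get("name") == name:
            label_mass = (
                _ptmass.calculate_mass(formula=entry["label_formula"])
                if "label_formula" in entry
                else float(entry["label_mass"])
            )
            return DerivatizationScheme(
                name=name,
                n_labels=int(entry["n_labels"]),
                label_mass=label_mass,
                condensation_loss=float(entry.get("condensation_loss", 18.010565)),
            )
    if name == "bis-PMP":
        return BIS_PMP
    raise ValueError(f"scheme {name!r} not found in {path}")
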
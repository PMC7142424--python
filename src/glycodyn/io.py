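"""Readers and writers for the pipeline's plain-text interchange formats.

Feature tables travel as two CSVs (wide feature x sample intensities plus a
sample-metadata file; see :mod:`glycodyn.feature_table`), expert ratings as
a two-column CSV, and MS/MS spectra as MGF (via pyteomics).  All round
trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .feature_table import FeatureTable

__all__ = [
    "Spectrum",
    "read_feature_table",
    "write_feature_table",
    "read_ratings",
    "read_spectra",
    "write_spectra",
]


@dataclass
class Spectrum:
    """A precursor with its fragment m/z (and optional intensity) lists."""

    title: str
    precursor_mz: float
    charge: int
    fragment_mzs: List[float]
    fragment_intensities: Optional[List[float]] = None


def read_feature_table(features_path: str | Path, samples_path: str | Path) -> FeatureTable:
    return FeatureTable.from_csv(features_path, samples_path)


def write_feature_table(
    table: FeatureTable, features_path: str | Path, samples_path: str | Path
) -> None:
    table.to_csv(features_path, samples_path)


def read_ratings(path: str | Path) -> pd.Series:
    """Expert ratings CSV: columns ``feature_id`` and ``rating`` in {0, 1}."""
    df = pd.read_csv(path)
    for col in ("feature_id", "rating"):
        if col not in df.columns:
            raise ValueError(f"ratings CSV is missing mandatory column {col!r}")
    bad = set(df["rating"].dropna().unique()) - {0, 1}
    if bad:
        raise ValueError(f"ratings must be 0 or 1; found {sorted(bad)}")
    return df.set_index("feature_id")["rating"].astype(int)


def read_spectra(path: str | Path) -> List[Spectrum]:
    """Read an MGF file (PEPMASS = precursor m/z, CHARGE sign = polarity)."""
    out: List[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            pep = params.get("pepmass")
            mz0 = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            charge = 0
            if params.get("charge"):
                charge = int(params["charge"][0])
            out.append(
                Spectrum(
                    title=str(params.get("title", f"spectrum {i}")),
                    precursor_mz=mz0,
                    charge=charge,
                    fragment_mzs=[float(x) for x in spec["m/z array"]],
                    fragment_intensities=[float(x) for x in spec["intensity array"]],
                )
            )
    return out


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        inten = (
            s.fragment_intensities
            if s.fragment_intensities is not None
            else [100.0] * len(s.fragment_mzs)
        )
        entries.append(
            {
                "m/z array": np.asarray(s.fragment_mzs, dtype=float),
                "intensity array": np.asarray(inten, dtype=float),
                "params": {
                    "title": s.title,
                    "pepmass": s.precursor_mz,
                    "charge": s.charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
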
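"""The central feature x sample container for the longitudinal pipeline.

A :class:`FeatureTable` couples three pandas frames:

``features``
    one row per LC-MS feature: ``mz``, ``rt_min``, optional ``width_min``,
    and (after deisotoping) ``is_isotope`` / ``isotope_of``;
``intensities``
    the feature x sample matrix (non-negative, NaN = missing);
``samples``
    per-sample metadata: ``class_`` in {HEX, NCHEX, MB}, ``phase`` in
    {T0, S, SI, COLON}, ``time_h`` on a common hour axis, ``replicate``.

Time axis: the colonic grid is 2, 4, 6, 10, 14, 18, 22, 24, 32, 40, 48 and
72 h after colon onset (hour 0); the pre-colon points sit at T0 = -3 h,
S (gastric) = -2 h and SI (small intestine) = -1 h — ordinal placements,
since the protocol states no stage durations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CLASSES", "PHASES", "COLON_TIMES_H", "PRECOLON_TIMES_H", "FeatureTable"]

CLASSES = ("HEX", "NCHEX", "MB")
PHASES = ("T0", "S", "SI", "COLON")
COLON_TIMES_H = (2.0, 4.0, 6.0, 10.0, 14.0, 18.0, 22.0, 24.0, 32.0, 40.0, 48.0, 72.0)
PRECOLON_TIMES_H = {"T0": -3.0, "S": -2.0, "SI": -1.0}

_FEATURE_COLUMNS = ("mz", "rt_min")
_SAMPLE_COLUMNS = ("class_", "phase", "time_h", "replicate")


@dataclass
class FeatureTable:
    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        for col in _FEATURE_COLUMNS:
            if col not in self.features.columns:
                raise ValueError(f"features frame is missing mandatory column {col!r}")
        for col in _SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples frame is missing mandatory column {col!r}")
        bad = set(self.samples["class_"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown sample class values: {sorted(bad)}")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share the same feature index")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("intensity columns must match the sample index")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ValueError("intensities must be non-negative")
        if (self.features["mz"] <= 0).any() or (self.features["rt_min"] < 0).any():
            raise ValueError("feature m/z must be > 0 and rt_min >= 0")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy(), self.samples.copy())

    def subset(self, feature_ids: Iterable) -> "FeatureTable":
        idx = pd.Index(feature_ids)
        return FeatureTable(
            self.features.loc[idx].copy(),
            self.intensities.loc[idx].copy(),
            self.samples.copy(),
        )

    def without_isotopes(self) -> "FeatureTable":
        if "is_isotope" not in self.features.columns:
            return self.copy()
        keep = self.features.index[~self.features["is_isotope"].astype(bool)]
        return self.subset(keep)

    def class_columns(self, class_: str, phase: Optional[str] = None) -> pd.Index:
        mask = self.samples["class_"] == class_
        if phase is not None:
            mask &= self.samples["phase"] == phase
        return self.samples.index[mask]

    # ------------------------------------------------------------------
    def to_csv(self, features_path: str | Path, samples_path: str | Path) -> None:
        """Write the documented two-file CSV schema (lossless round-trip)."""
        wide = self.features.join(self.intensities)
        wide.to_csv(features_path, index_label="id")
        self.samples.rename(columns={"class_": "class"}).to_csv(
            samples_path, index_label="sample"
        )

    @classmethod
    def from_csv(cls, features_path: str | Path, samples_path: str | Path) -> "FeatureTable":
        samples = pd.read_csv(samples_path)
        if "sample" not in samples.columns:
            raise ValueError("samples CSV is missing mandatory column 'sample'")
        samples = samples.set_index("sample")
        if "class" not in samples.columns:
            raise ValueError("samples CSV is missing mandatory column 'class'")
        samples = samples.rename(columns={"class": "class_"})
        for col in _SAMPLE_COLUMNS:
            if col not in samples.columns:
                raise ValueError(f"samples CSV is missing mandatory column {col!r}")

        wide = pd.read_csv(features_path)
        if "id" not in wide.columns:
            raise ValueError("features CSV is missing mandatory column 'id'")
        wide = wide.set_index("id")
        for col in _FEATURE_COLUMNS:
            if col not in wide.columns:
                raise ValueError(f"features CSV is missing mandatory column {col!r}")
        meta_cols = [c for c in wide.columns if c not in samples.index]
        missing_samples = [s for s in samples.index if s not in wide.columns]
        if missing_samples:
            raise ValueError(
                f"features CSV lacks intensity columns for samples: {missing_samples[:5]}"
            )
        return cls(wide[meta_cols], wide[list(samples.index)], samples)
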
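"""Aligned LC-MS feature tables and the experimental design.

A :class:`FeatureTable` couples three pieces of data:

* a feature frame (``id``, ``mz``, ``rt`` in minutes, ``ion_mode``),
* a design frame (``sample_id``, ``treatment``, ``time_h``,
  ``replicate``, ``batch``),
* an intensity matrix (features x samples, area-under-curve units)
  where missing measurements are ``NaN`` — kept distinct from zero so
  the noise-flooring step can be audited.

CSV round-trips preserve every field. The reader accepts a column
mapping so matrices with differently named metadata columns can be
ingested without editing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ION_MODES",
    "TREATMENTS",
    "FeatureTableError",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "group_means",
]

ION_MODES = ("positive", "negative")
TREATMENTS = ("control", "unlabeled_tracer", "labeled_tracer")

FEATURE_COLUMNS = ("id", "mz", "rt", "ion_mode")
DESIGN_COLUMNS = ("sample_id", "treatment", "time_h", "replicate", "batch")


class FeatureTableError(ValueError):
    """Validation failure in a feature table or design."""


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with metadata and design.

    ``intensities`` is indexed by feature id with one column per
    sample id; NaN means "not measured". ``floored`` / ``normalized``
    record which preprocessing steps have been applied.
    """

    features: pd.DataFrame
    design: pd.DataFrame
    intensities: pd.DataFrame
    floored: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------

    def validate(self) -> None:
        feats, design, mat = self.features, self.design, self.intensities
        for col in FEATURE_COLUMNS:
            if col not in feats.columns:
                raise FeatureTableError(f"feature frame missing column {col!r}")
        for col in DESIGN_COLUMNS:
            if col not in design.columns:
                raise FeatureTableError(f"design frame missing column {col!r}")
        ids = feats["id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise FeatureTableError(f"duplicate feature ids: {dupes}")
        bad_mode = set(feats["ion_mode"]) - set(ION_MODES)
        if bad_mode:
            raise FeatureTableError(f"unknown ion modes: {sorted(bad_mode)}")
        bad_trt = set(design["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise FeatureTableError(f"unknown treatments: {sorted(bad_trt)}")
        if (feats["mz"] <= 0).any():
            raise FeatureTableError("all m/z values must be positive")
        rt = feats["rt"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rt)) or (rt < 0).any():
            raise FeatureTableError("retention times must be finite and >= 0")
        key = design[["treatment", "time_h", "replicate"]]
        if key.duplicated().any():
            raise FeatureTableError(
                "duplicate (treatment, time_h, replicate) entries in design"
            )
        if list(mat.index) != list(ids):
            raise FeatureTableError("intensity rows do not match feature ids")
        if list(mat.columns) != list(design["sample_id"].astype(str)):
            raise FeatureTableError("intensity columns do not match design samples")
        vals = mat.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative intensities are not allowed")

    # -- convenience ------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    def feature_ids(self, ion_mode: Optional[str] = None) -> list[str]:
        feats = self.features
        if ion_mode is not None:
            feats = feats[feats["ion_mode"] == ion_mode]
        return feats["id"].astype(str).tolist()

    def mode_counts(self) -> Dict[str, int]:
        counts = self.features["ion_mode"].value_counts().to_dict()
        return {mode: int(counts.get(mode, 0)) for mode in ION_MODES}

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(),
            self.design.copy(),
            self.intensities.copy(),
            floored=self.floored,
            normalized=self.normalized,
        )

    def samples_for(self, treatment: str) -> list[str]:
        """Sample ids of one treatment ordered by (time_h, replicate)."""
        sub = self.design[self.design["treatment"] == treatment]
        sub = sub.sort_values(["time_h", "replicate"])
        return sub["sample_id"].astype(str).tolist()


def read_feature_table(
    matrix_path: str | Path,
    design_path: str | Path,
    sep: str = ",",
    column_map: Optional[Mapping[str, str]] = None,
) -> FeatureTable:
    """Read an aligned matrix CSV/TSV and its design CSV/TSV.

    The matrix must carry the metadata columns id, mz, rt, ion_mode
    (renameable through ``column_map``, mapping file column -> dialect
    column) followed by one intensity column per sample. Empty cells
    are recorded as missing, not zero.
    """
    raw = pd.read_csv(matrix_path, sep=sep)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in FEATURE_COLUMNS if c not in raw.columns]
    if missing:
        raise FeatureTableError(
            f"matrix {matrix_path} missing metadata columns {missing}"
        )
    design = pd.read_csv(design_path, sep=sep)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FeatureTableError(
            f"design {design_path} missing columns {missing}"
        )
    design = design.copy()
    design["sample_id"] = design["sample_id"].astype(str)

    sample_cols = [c for c in raw.columns if c not in FEATURE_COLUMNS]
    known = set(design["sample_id"])
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise FeatureTableError(
            f"matrix sample columns absent from design: {unknown}"
        )
    features = raw[list(FEATURE_COLUMNS)].copy()
    features["id"] = features["id"].astype(str)
    # align design order to the matrix's column order
    design = design.set_index("sample_id").loc[sample_cols].reset_index()
    mat = raw[sample_cols].copy()
    for col in sample_cols:
        try:
            mat[col] = pd.to_numeric(mat[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FeatureTableError(
                f"non-numeric intensity in column {col!r}: {exc}"
            ) from None
    mat.index = features["id"]
    mat.index.name = None
    return FeatureTable(features.reset_index(drop=True), design, mat)


def write_feature_table(
    table: FeatureTable,
    matrix_path: str | Path,
    design_path: str | Path,
    sep: str = ",",
) -> None:
    """Write the documented CSV dialect; missing stays an empty cell."""
    out = table.features.copy()
    mat = table.intensities.reset_index(drop=True)
    out = pd.concat([out, mat], axis=1)
    out.to_csv(matrix_path, sep=sep, index=False)
    table.design.to_csv(design_path, sep=sep, index=False)


def group_means(table: FeatureTable) -> pd.DataFrame:
    """Per-feature mean intensity of every (treatment, time_h) group.

    Returns a frame indexed by feature id with a (treatment, time_h)
    MultiIndex on columns. Every group in the design must have at
    least one sample; NaN intensities propagate (preprocess first if a
    floored table is wanted).
    """
    design = table.design
    groups = design.groupby(["treatment", "time_h"], sort=True)
    cols = {}
    for (trt, t), sub in groups:
        sample_ids = sub["sample_id"].astype(str).tolist()
        if not sample_ids:
            raise FeatureTableError(f"empty group ({trt}, {t})")
        cols[(trt, float(t))] = table.intensities[sample_ids].mean(axis=1)
    result = pd.DataFrame(cols)
    result.columns = pd.MultiIndex.from_tuples(
        result.columns, names=["treatment", "time_h"]
    )
    return result
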
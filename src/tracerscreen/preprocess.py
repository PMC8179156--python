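"""Noise flooring and internal-standard normalization.

The untargeted pipeline floors every intensity below the noise level
(and every missing cell) to exactly that level, then divides each
sample column by the intensity of the spiked internal standard of the
same ion mode in that sample — lidocaine (m/z 235.1805) for positive
ions, 10-camphorsulfonic acid (m/z 231.0697) for negative ions. The
targeted variant uses a noise level of 10.

Flooring is idempotent; normalization is guarded against being applied
twice via the table's ``normalized`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, FeatureTableError, ION_MODES

__all__ = [
    "PreprocessConfig",
    "floor_noise",
    "normalize_internal_standard",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Flooring/normalization parameters.

    noise_floor: intensity below which (and missing) values are set to
        the floor; 500 for the untargeted matrices, 10 for targeted.
    is_positive_mz / is_negative_mz: internal-standard m/z per mode.
    is_match_tol_da: window for locating the IS feature by m/z.
    """

    noise_floor: float = 500.0
    is_positive_mz: float = 235.1805
    is_negative_mz: float = 231.0697
    is_match_tol_da: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be positive")
        if self.is_match_tol_da <= 0:
            raise ValueError("is_match_tol_da must be positive")


def floor_noise(table: FeatureTable, config: PreprocessConfig | None = None) -> FeatureTable:
    """Set every intensity below the noise floor, and every missing
    cell, to exactly the floor; leave other values untouched."""
    config = config or PreprocessConfig()
    out = table.copy()
    mat = out.intensities.to_numpy(dtype=float)
    mat = np.where(np.isnan(mat) | (mat < config.noise_floor), config.noise_floor, mat)
    out.intensities = pd.DataFrame(
        mat, index=table.intensities.index, columns=table.intensities.columns
    )
    out.floored = True
    return out


def find_internal_standard(
    table: FeatureTable, ion_mode: str, config: PreprocessConfig
) -> str:
    """Feature id of the internal standard in one ion mode.

    Located by m/z within ``is_match_tol_da``; ties are broken by the
    highest total intensity (logged).
    """
    target = {
        "positive": config.is_positive_mz,
        "negative": config.is_negative_mz,
    }[ion_mode]
    feats = table.features
    mask = (feats["ion_mode"] == ion_mode) & (
        (feats["mz"] - target).abs() <= config.is_match_tol_da
    )
    hits = feats[mask]
    if hits.empty:
        raise FeatureTableError(
            f"no internal-standard feature within {config.is_match_tol_da} Da "
            f"of m/z {target} in {ion_mode} mode"
        )
    if len(hits) > 1:
        totals = table.intensities.loc[hits["id"].astype(str)].sum(axis=1)
        chosen = str(totals.idxmax())
        logger.warning(
            "%d features match IS m/z %.4f in %s mode; keeping %s (highest total intensity)",
            len(hits), target, ion_mode, chosen,
        )
        return chosen
    return str(hits["id"].iloc[0])


def normalize_internal_standard(
    table: FeatureTable, config: PreprocessConfig | None = None
) -> FeatureTable:
    """Divide every feature of a mode by that mode's IS, per sample.

    The IS feature's own normalized row is all ones. Samples whose IS
    intensity sits at the noise floor are flagged with a warning (the
    division is still performed).
    """
    config = config or PreprocessConfig()
    if table.normalized:
        raise FeatureTableError(
            "table is already internal-standard normalized; refusing to normalize twice"
        )
    out = table.copy()
    mat = out.intensities
    for mode in ION_MODES:
        ids = table.feature_ids(mode)
        if not ids:
            continue
        is_id = find_internal_standard(table, mode, config)
        is_row = mat.loc[is_id]
        at_floor = is_row[is_row <= config.noise_floor]
        for sample in at_floor.index:
            logger.warning(
                "internal standard %s at/below noise floor in sample %s", is_id, sample
            )
        mat.loc[ids] = mat.loc[ids].div(is_row, axis=1)
    out.intensities = mat
    out.normalized = True
    return out


def preprocess(
    table: FeatureTable,
    config: PreprocessConfig | None = None,
    normalize: bool = True,
) -> FeatureTable:
    """Floor then (optionally) normalize, in that order."""
    config = config or PreprocessConfig()
    out = floor_noise(table, config)
    if normalize:
        out = normalize_internal_standard(out, config)
    return out
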
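"""Tracer co-behavior screen (criteria 1, 5, 6).

Finds features whose abundance responds to the tracer feeding in the
same way under both the unlabeled and the labeled tracer — e.g. a
conjugation substrate being depleted, or a downstream product
accumulating — regardless of whether the feature itself carries the
label.

Criteria, applied to a noise-floored table:

1. highest group mean strictly above twice the noise level;
5. the global maximum OR minimum group mean belongs to a tracer
   treatment (unlabeled or labeled); ties in that extremum disqualify;
6. Spearman's rank correlation between the unlabeled-tracer and
   labeled-tracer intensity vectors is strictly greater than 0.4,
   while the correlations of the control vector with each tracer
   vector are both at most 0.2.

Correlation vectors hold one entry per sample of a treatment, matched
across treatments by (time point, replicate) — 12 points in the
3-replicate x 4-time-point design. A group-mean mode (4 points per
treatment) is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, FeatureTableError, group_means
from .pair_screen import ScreenConfig

__all__ = [
    "CobehaviorThresholds",
    "CobehaviorRecord",
    "spearman_rho",
    "passes_correlation",
    "criterion_extremum",
    "screen_cobehavior",
]

logger = logging.getLogger(__name__)


class ConstantVectorError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class CobehaviorThresholds:
    """rho_tracers must exceed ``high`` strictly; both control
    correlations must be <= ``low``."""

    high: float = 0.4
    low: float = 0.2
    vector_mode: str = "replicate"  # or "group_mean"

    def __post_init__(self) -> None:
        if self.vector_mode not in ("replicate", "group_mean"):
            raise ValueError("vector_mode must be replicate or group_mean")


@dataclass(frozen=True)
class CobehaviorRecord:
    """A feature passing criteria 1, 5 and 6."""

    feature_id: str
    ion_mode: str
    direction: str  # "max_in_tracer" or "min_in_tracer"
    rho_tracers: float
    rho_control_unlabeled: float
    rho_control_labeled: float


def passes_correlation(
    rho_tracers: float,
    rho_control_unlabeled: float,
    rho_control_labeled: float,
    thresholds: CobehaviorThresholds | None = None,
) -> bool:
    """Criterion 6's comparisons: the tracer correlation must be
    strictly greater than ``high`` and both control correlations at
    most ``low`` (boundary values 0.4 fail and 0.2 pass)."""
    t = thresholds or CobehaviorThresholds()
    return (
        rho_tracers > t.high
        and rho_control_unlabeled <= t.low
        and rho_control_labeled <= t.low
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks).

    Raises :class:`ConstantVectorError` when either vector is
    constant, where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("Spearman rho undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def criterion_extremum(
    feature_id: str, table: FeatureTable,
    means: Optional[pd.DataFrame] = None,
) -> Tuple[bool, Optional[str]]:
    """Criterion 5: global max or min group mean in a tracer group.

    Ties in the extremum disqualify that extremum (flat profiles are
    noise). Direction reports which extremum qualified; when both do,
    the maximum wins.
    """
    if means is None:
        means = group_means(table)
    row = means.loc[feature_id]
    tracer = {"unlabeled_tracer", "labeled_tracer"}

    def owner(extreme_value) -> Optional[str]:
        winners = row.index[row == extreme_value]
        if len(winners) != 1:
            return None
        return str(winners[0][0])

    if owner(row.max()) in tracer:
        return True, "max_in_tracer"
    if owner(row.min()) in tracer:
        return True, "min_in_tracer"
    return False, None


def _treatment_matrix(
    table: FeatureTable, treatment: str, vector_mode: str
) -> np.ndarray:
    """Feature x point intensity matrix for one treatment, points
    ordered by (time, replicate) or by time for group means."""
    if vector_mode == "group_mean":
        means = group_means(table)
        cols = [c for c in means.columns if c[0] == treatment]
        cols.sort(key=lambda c: c[1])
        return means[cols].to_numpy(dtype=float)
    samples = table.samples_for(treatment)
    return table.intensities[samples].to_numpy(dtype=float)


def _check_complete_design(table: FeatureTable) -> None:
    design = table.design
    layouts = {}
    for trt, sub in design.groupby("treatment"):
        layouts[trt] = tuple(sorted(zip(sub["time_h"], sub["replicate"])))
    if len(set(layouts.values())) != 1:
        raise FeatureTableError(
            "incomplete design: treatments do not share the same "
            f"(time, replicate) layout: {layouts}"
        )


def screen_cobehavior(
    table: FeatureTable,
    thresholds: CobehaviorThresholds | None = None,
    config: ScreenConfig | None = None,
) -> List[CobehaviorRecord]:
    """Features passing criteria 1, 5 and 6, in deterministic order
    (ion mode, then m/z)."""
    thresholds = thresholds or CobehaviorThresholds()
    config = config or ScreenConfig()
    if not table.floored:
        raise ValueError("screen_cobehavior requires a noise-floored table")
    if table.n_features == 0:
        return []
    _check_complete_design(table)

    means = group_means(table)
    max_mean = means.max(axis=1)

    mats = {
        trt: _treatment_matrix(table, trt, thresholds.vector_mode)
        for trt in ("control", "unlabeled_tracer", "labeled_tracer")
    }

    feats = table.features.sort_values(["ion_mode", "mz"], ascending=[False, True])
    # ion modes ordered positive first
    feats = pd.concat([
        feats[feats["ion_mode"] == "positive"],
        feats[feats["ion_mode"] == "negative"],
    ])
    row_of = {fid: i for i, fid in enumerate(table.features["id"].astype(str))}

    records: List[CobehaviorRecord] = []
    for _, feat in feats.iterrows():
        fid = str(feat["id"])
        if not (max_mean.loc[fid] > config.intensity_threshold):
            continue
        ok5, direction = criterion_extremum(fid, table, means)
        if not ok5:
            continue
        i = row_of[fid]
        try:
            rho_t = spearman_rho(mats["unlabeled_tracer"][i], mats["labeled_tracer"][i])
            rho_cu = spearman_rho(mats["control"][i], mats["unlabeled_tracer"][i])
            rho_cl = spearman_rho(mats["control"][i], mats["labeled_tracer"][i])
        except ConstantVectorError:
            continue
        if passes_correlation(rho_t, rho_cu, rho_cl, thresholds):
            records.append(CobehaviorRecord(
                feature_id=fid,
                ion_mode=str(feat["ion_mode"]),
                direction=direction,
                rho_tracers=rho_t,
                rho_control_unlabeled=rho_cu,
                rho_control_labeled=rho_cl,
            ))
    logger.info("co-behavior screen: %d records", len(records))
    return records


def records_to_frame(records: List[CobehaviorRecord]) -> pd.DataFrame:
    """Record list as a flat frame (the ``screen-cobehavior`` CSV)."""
    return pd.DataFrame([r.__dict__ for r in records], columns=[
        "feature_id", "ion_mode", "direction", "rho_tracers",
        "rho_control_unlabeled", "rho_control_labeled",
    ])
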
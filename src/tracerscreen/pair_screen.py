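"""Isotopologue-pair screen (criteria 1-4).

Detects (unlabeled, labeled) feature pairs produced by feeding a
deuterated tracer: two co-eluting features of one ion mode separated
by the mass shift of 2, 3, 5 or 10 deuterium atoms, where the lighter
member peaks under the unlabeled tracer and the heavier under the
labeled tracer.

Criteria, applied to a noise-floored table:

1. a feature's highest (treatment, time) group mean exceeds twice the
   noise level (strict) — applied to both members;
2. the observed m/z difference matches an allowed label shift within
   +/-20 ppm of the query (lighter member's) m/z;
3. retention times agree within +/-0.05 min (inclusive);
4. the group-mean argmax of the lighter member lies in an
   unlabeled-tracer group and that of the heavier member in a
   labeled-tracer group; ties in the argmax disqualify.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .chem import DEUTERIUM_PRINTED, LabelShiftSpec, label_delta
from .feature_table import FeatureTable, group_means

__all__ = [
    "ScreenConfig",
    "PairCandidate",
    "criterion_intensity",
    "criterion_mass_shift",
    "criterion_coelution",
    "criterion_treatment_max",
    "screen_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Pair-screen thresholds.

    intensity_multiplier: criterion-1 threshold as a multiple of the
        noise floor (strict inequality).
    shift_spec: allowed label shifts; defaults to the reported
        deuterium table {2: 2.0126, 3: 3.0189, 5: 5.0314, 10: 10.0628}.
    delta_ppm_tol: mass-difference tolerance in ppm of the query m/z.
    rt_tol_min: co-elution tolerance in minutes (inclusive).
    treatment_max_mode: "group_mean" compares group means (default,
        consistent with criterion 1); "per_sample_max" compares single
        samples.
    """

    noise_floor: float = 500.0
    intensity_multiplier: float = 2.0
    shift_spec: LabelShiftSpec = DEUTERIUM_PRINTED
    delta_ppm_tol: float = 20.0
    rt_tol_min: float = 0.05
    treatment_max_mode: str = "group_mean"

    def __post_init__(self) -> None:
        for name in ("noise_floor", "intensity_multiplier", "delta_ppm_tol", "rt_tol_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.treatment_max_mode not in ("group_mean", "per_sample_max"):
            raise ValueError("treatment_max_mode must be group_mean or per_sample_max")

    @property
    def intensity_threshold(self) -> float:
        return self.intensity_multiplier * self.noise_floor


@dataclass(frozen=True)
class PairCandidate:
    """An (unlabeled, labeled) pair passing criteria 1-4."""

    unlabeled_id: str
    labeled_id: str
    n_label: int
    observed_delta: float
    delta_ppm_error: float
    rt_diff: float
    ion_mode: str


# -- per-feature / per-pair criteria --------------------------------

def criterion_intensity(
    feature_id: str, table: FeatureTable, config: ScreenConfig,
    means: Optional[pd.DataFrame] = None,
) -> bool:
    """Criterion 1: any group mean strictly above multiplier x floor."""
    if means is None:
        means = group_means(table)
    return bool(means.loc[feature_id].max() > config.intensity_threshold)


def criterion_mass_shift(
    mz_unlabeled: float, mz_labeled: float, config: ScreenConfig
) -> Tuple[bool, Optional[int]]:
    """Criterion 2: does the m/z gap match an allowed label shift?

    Tolerance is ``delta_ppm_tol`` ppm of the query (unlabeled) m/z.
    Returns the smallest matching label count.
    """
    if mz_labeled <= mz_unlabeled:
        return False, None
    observed = mz_labeled - mz_unlabeled
    tol = config.delta_ppm_tol * 1e-6 * mz_unlabeled
    for n in sorted(config.shift_spec.allowed_counts):
        if abs(observed - label_delta(config.shift_spec, n)) <= tol:
            return True, n
    return False, None


def criterion_coelution(rt_a: float, rt_b: float, config: ScreenConfig) -> bool:
    """Criterion 3: |RT difference| <= tolerance, boundary inclusive."""
    return abs(rt_a - rt_b) <= config.rt_tol_min


def _argmax_treatment(
    feature_id: str, table: FeatureTable, config: ScreenConfig,
    means: Optional[pd.DataFrame] = None,
) -> Optional[str]:
    """Treatment owning the feature's unique maximal group mean (or
    sample, in per_sample_max mode); None when the argmax is tied."""
    if config.treatment_max_mode == "per_sample_max":
        row = table.intensities.loc[feature_id]
        top = row.max()
        winners = row.index[row == top]
        if len(winners) != 1:
            return None
        sample = winners[0]
        design = table.design.set_index("sample_id")
        return str(design.loc[str(sample), "treatment"])
    if means is None:
        means = group_means(table)
    row = means.loc[feature_id]
    top = row.max()
    winners = row.index[row == top]
    if len(winners) != 1:
        return None
    return str(winners[0][0])  # (treatment, time_h) tuple


def criterion_treatment_max(
    unlabeled_id: str, labeled_id: str, table: FeatureTable,
    config: ScreenConfig | None = None,
    means: Optional[pd.DataFrame] = None,
) -> bool:
    """Criterion 4: unlabeled member peaks under the unlabeled tracer,
    labeled member under the labeled tracer (any time point)."""
    config = config or ScreenConfig()
    return (
        _argmax_treatment(unlabeled_id, table, config, means) == "unlabeled_tracer"
        and _argmax_treatment(labeled_id, table, config, means) == "labeled_tracer"
    )


# -- full screen ----------------------------------------------------

def screen_pairs(
    table: FeatureTable,
    config: ScreenConfig | None = None,
    rejection_counts: Optional[Counter] = None,
) -> List[PairCandidate]:
    """All pairs satisfying criteria 1-4, per ion mode.

    Expects a noise-floored table (raises otherwise). Output is
    deterministic: sorted by ion mode, unlabeled m/z, then labeled
    m/z. ``rejection_counts``, when supplied, accumulates per-criterion
    rejection tallies for diagnostics.
    """
    config = config or ScreenConfig()
    if not table.floored:
        raise ValueError("screen_pairs requires a noise-floored table")
    if table.n_features == 0:
        return []
    means = group_means(table)
    ids_all = table.features["id"].astype(str).to_numpy()
    max_mean = means.to_numpy().max(axis=1)
    passes1 = max_mean > config.intensity_threshold

    # unique-argmax treatment per feature, vectorized over group means
    argmax_trt = np.array([
        _argmax_treatment(fid, table, config, means) for fid in ids_all
    ], dtype=object)

    pairs: List[PairCandidate] = []
    tally = rejection_counts if rejection_counts is not None else Counter()
    deltas = config.shift_spec.deltas()

    for mode in ("positive", "negative"):
        sel = (table.features["ion_mode"] == mode).to_numpy()
        if not sel.any():
            continue
        order = np.argsort(table.features.loc[sel, "mz"].to_numpy(), kind="stable")
        idx = np.flatnonzero(sel)[order]
        mz = table.features["mz"].to_numpy(dtype=float)[idx]
        rt = table.features["rt"].to_numpy(dtype=float)[idx]
        ids = ids_all[idx]
        ok1 = passes1[idx]
        trt = argmax_trt[idx]

        seen: set[Tuple[int, int]] = set()
        for n in sorted(deltas):
            d = deltas[n]
            tol = config.delta_ppm_tol * 1e-6 * mz
            lo = np.searchsorted(mz, mz + d - tol, side="left")
            hi = np.searchsorted(mz, mz + d + tol, side="right")
            for i in range(len(mz)):
                for j in range(lo[i], hi[i]):
                    if j == i or (i, j) in seen:
                        continue
                    seen.add((i, j))
                    if not (ok1[i] and ok1[j]):
                        tally["criterion1"] += 1
                        continue
                    if not criterion_coelution(rt[i], rt[j], config):
                        tally["criterion3"] += 1
                        continue
                    if not (trt[i] == "unlabeled_tracer" and trt[j] == "labeled_tracer"):
                        tally["criterion4"] += 1
                        continue
                    observed = mz[j] - mz[i]
                    pairs.append(PairCandidate(
                        unlabeled_id=str(ids[i]),
                        labeled_id=str(ids[j]),
                        n_label=n,
                        observed_delta=float(observed),
                        delta_ppm_error=float(1e6 * abs(observed - d) / mz[i]),
                        rt_diff=float(rt[j] - rt[i]),
                        ion_mode=mode,
                    ))

    pairs.sort(key=_pair_sort_key(table))
    logger.info("pair screen: %d pairs; rejections %s", len(pairs), dict(tally))
    return pairs


def _pair_sort_key(table: FeatureTable):
    mz_of = dict(zip(table.features["id"].astype(str), table.features["mz"]))
    mode_rank = {"positive": 0, "negative": 1}
    def key(p: PairCandidate):
        return (mode_rank[p.ion_mode], mz_of[p.unlabeled_id], mz_of[p.labeled_id])
    return key


def pairs_to_frame(pairs: List[PairCandidate]) -> pd.DataFrame:
    """Pair list as a flat frame (the CSV dialect of ``screen-pairs``)."""
    return pd.DataFrame([p.__dict__ for p in pairs], columns=[
        "unlabeled_id", "labeled_id", "n_label", "observed_delta",
        "delta_ppm_error", "rt_diff", "ion_mode",
    ])
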
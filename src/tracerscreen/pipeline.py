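"""End-to-end screening pipeline and its funnel summary.

Wires the stages together — floor, (optionally) normalize, pair
screen, pair consolidation, co-behavior screen, co-behavior
consolidation, annotation — and reports a machine-readable summary of
per-stage counts per ion mode, so a run can be compared directly with
a published funnel (features read -> pairs -> consolidated pairs;
co-behavior records -> consolidated records).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .annotate import AnnotationHit, CompoundRecord, annotate_mz, bundled_library
from .cobehavior import CobehaviorRecord, CobehaviorThresholds, screen_cobehavior
from .cobehavior import records_to_frame as cobehavior_frame
from .consolidate import (
    ConsolidatedRecord,
    consolidate,
    entries_from_feature_ids,
    entries_from_pairs,
)
from .consolidate import records_to_frame as consolidated_frame
from .feature_table import FeatureTable
from .pair_screen import PairCandidate, ScreenConfig, pairs_to_frame, screen_pairs
from .preprocess import PreprocessConfig, floor_noise, normalize_internal_standard

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated stage parameters.

    The screens evaluate intensities on the floored, pre-normalization
    table by default (the noise level is stated in raw counts);
    ``screen_on_normalized`` switches them to the IS-normalized table
    for sensitivity analysis. ``normalize`` controls whether the
    normalization stage runs at all.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    cobehavior: CobehaviorThresholds = field(default_factory=CobehaviorThresholds)
    consolidate_mass_tol_da: float = 0.01
    consolidate_rt_tol_min: float = 0.05
    annotate_tol_da: float = 0.01
    normalize: bool = True
    screen_on_normalized: bool = False


@dataclass
class PipelineResult:
    table: FeatureTable
    pairs: List[PairCandidate]
    consolidated_pairs: List[ConsolidatedRecord]
    cobehavior: List[CobehaviorRecord]
    consolidated_cobehavior: List[ConsolidatedRecord]
    annotations: Dict[str, List[AnnotationHit]]
    rejections: Counter
    summary: Dict[str, object]


def run_pipeline(
    table: FeatureTable,
    config: PipelineConfig | None = None,
    compounds: Optional[List[CompoundRecord]] = None,
) -> PipelineResult:
    """Run every stage on an aligned feature table."""
    config = config or PipelineConfig()
    floored = floor_noise(table, config.preprocess)
    screen_table = floored
    if config.normalize and table.n_features > 0:
        normalized = normalize_internal_standard(floored, config.preprocess)
        if config.screen_on_normalized:
            screen_table = normalized

    rejections: Counter = Counter()
    pairs = screen_pairs(screen_table, config.screen, rejections)
    cons_pairs = consolidate(
        entries_from_pairs(pairs, screen_table),
        mass_tol_da=config.consolidate_mass_tol_da,
        rt_tol_min=config.consolidate_rt_tol_min,
    )
    cob = screen_cobehavior(screen_table, config.cobehavior, config.screen)
    cons_cob = consolidate(
        entries_from_feature_ids([r.feature_id for r in cob], screen_table),
        mass_tol_da=config.consolidate_mass_tol_da,
        rt_tol_min=config.consolidate_rt_tol_min,
    )

    if compounds is None:
        compounds = bundled_library()
    mz_of = dict(zip(table.features["id"].astype(str), table.features["mz"]))
    mode_of = dict(zip(table.features["id"].astype(str), table.features["ion_mode"]))
    annotations: Dict[str, List[AnnotationHit]] = {}
    for rec in cons_pairs:
        fid = rec.representative.split("|")[0]  # unlabeled member of the pair
        annotations[rec.representative] = annotate_mz(
            mz_of[fid], mode_of[fid], compounds, config.annotate_tol_da)
    for rec in cons_cob:
        fid = rec.representative
        annotations.setdefault(fid, annotate_mz(
            mz_of[fid], mode_of[fid], compounds, config.annotate_tol_da))

    mode_counts = table.mode_counts()
    summary = {
        "n_features": {"positive": mode_counts["positive"],
                       "negative": mode_counts["negative"]},
        "n_pairs": _per_mode([p.ion_mode for p in pairs]),
        "n_consolidated_pairs": len(cons_pairs),
        "n_cobehavior": _per_mode([r.ion_mode for r in cob]),
        "n_consolidated_cobehavior": len(cons_cob),
        "n_annotated": sum(1 for hits in annotations.values() if hits),
        "rejections": dict(rejections),
    }
    logger.info("pipeline summary: %s", summary)
    return PipelineResult(
        table=screen_table, pairs=pairs, consolidated_pairs=cons_pairs,
        cobehavior=cob, consolidated_cobehavior=cons_cob,
        annotations=annotations, rejections=rejections, summary=summary,
    )


def _per_mode(modes: List[str]) -> Dict[str, int]:
    return {
        "positive": sum(1 for m in modes if m == "positive"),
        "negative": sum(1 for m in modes if m == "negative"),
    }


def write_results(result: PipelineResult, out_dir: str | Path) -> Dict[str, Path]:
    """Write stage CSVs plus a JSON summary; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs": out / "pairs.csv",
        "consolidated_pairs": out / "consolidated_pairs.csv",
        "cobehavior": out / "cobehavior.csv",
        "consolidated_cobehavior": out / "consolidated_cobehavior.csv",
        "annotations": out / "annotations.csv",
        "summary": out / "summary.json",
    }
    pairs_to_frame(result.pairs).to_csv(paths["pairs"], index=False)
    consolidated_frame(result.consolidated_pairs).to_csv(
        paths["consolidated_pairs"], index=False)
    cobehavior_frame(result.cobehavior).to_csv(paths["cobehavior"], index=False)
    consolidated_frame(result.consolidated_cobehavior).to_csv(
        paths["consolidated_cobehavior"], index=False)
    rows = []
    for rec_id, hits in result.annotations.items():
        if not hits:
            rows.append({"record": rec_id, "compound": "", "adduct": "",
                         "mass_error_da": ""})
        for h in hits:
            rows.append({"record": rec_id, "compound": h.compound.name,
                         "adduct": h.adduct, "mass_error_da": h.mass_error_da})
    pd.DataFrame(rows, columns=["record", "compound", "adduct", "mass_error_da"]).to_csv(
        paths["annotations"], index=False)
    paths["summary"].write_text(json.dumps(result.summary, indent=2) + "\n")
    return paths
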
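"""Seeded generator of tracer-feeding feature tables with ground truth.

Emulates the statistical structure of an untargeted LC-MS tracer
study: three treatments (solvent control, unlabeled tracer, labeled
tracer) x four time points (3, 9, 24, 48 h) x three replicates, two
ion modes, a spiked internal standard per mode, a 500-count noise
floor, and log-normal (multiplicative) intensity noise.

Planted truths are recoverable by construction and decoys are
unrecoverable by construction:

* planted isotopologue pairs draw their m/z gap within half the
  screen's ppm tolerance of an allowed deuterium shift and co-elute
  within half the RT tolerance; the labeled member is above floor only
  under the labeled tracer, the unlabeled member only under the
  unlabeled tracer;
* decoy pairs violate exactly one criterion by at least twice its
  tolerance (mass-gap near-misses, RT misses, wrong-treatment peaks);
* co-behaving features share a time profile under both tracer
  treatments (rising, peaking at 24 h, or dipping at 9 h) with flat
  controls whose rank correlation with the tracer profile is bounded
  below the screen's control cap by seeded resampling;
* background features share one (time, replicate) profile across all
  three treatments, so their control correlation is high and the
  co-behavior screen rejects them; a post-draw audit nudges any
  accidental mass/RT coincidence among non-planted features and
  flattens any residual screen false positive.

The result is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import DEUTERIUM_PRINTED, PROTON_MASS, LabelShiftSpec, label_delta
from .cobehavior import CobehaviorThresholds, screen_cobehavior
from .feature_table import FeatureTable, TREATMENTS
from .pair_screen import ScreenConfig, screen_pairs
from .preprocess import PreprocessConfig, floor_noise

__all__ = ["SimulationConfig", "GroundTruth", "PlantedPair", "DecoyPair", "generate"]

_SHAPES = {
    "peak24": np.array([0.15, 0.40, 1.00, 0.60]),
    "late": np.array([0.05, 0.15, 0.50, 1.00]),
    "rise": np.array([0.10, 0.30, 0.60, 1.00]),
    "dip9": np.array([1.00, 0.25, 0.60, 0.90]),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults emulate the study conditions."""

    seed: int = 0
    n_features_pos: int = 1200
    n_features_neg: int = 800
    n_planted_pairs_pos: int = 13
    n_planted_pairs_neg: int = 7
    n_cobehave_up: int = 8          # includes adduct-triplet members
    n_cobehave_down: int = 7
    n_adduct_triplets: int = 2      # each = 3 "up" features of one metabolite
    n_decoy_ppm: int = 80           # pairs with mass-gap near-miss
    n_decoy_rt: int = 60            # pairs with RT miss
    n_decoy_control: int = 60       # pairs peaking in the wrong treatment
    time_points_h: Tuple[float, ...] = (3.0, 9.0, 24.0, 48.0)
    n_replicates: int = 3
    noise_floor: float = 500.0
    is_positive_mz: float = 235.1805
    is_negative_mz: float = 231.0697
    shift_spec: LabelShiftSpec = DEUTERIUM_PRINTED
    delta_ppm_tol: float = 20.0
    rt_tol_min: float = 0.05
    baseline_log10_mean: float = 3.3
    baseline_log10_sd: float = 0.6
    replicate_log10_sd: float = 0.02    # within-cell, treatment-specific noise
    profile_log10_sd: float = 0.30      # shared (time, replicate) structure
    planted_jitter_frac: float = 0.5    # planted gap error, fraction of tol
    planted_rt_jitter_frac: float = 0.4
    decoy_offset_min: float = 2.0       # decoy violation, multiples of tol
    decoy_offset_max: float = 4.0
    missing_rate: float = 0.02          # background cells only

    def __post_init__(self) -> None:
        for name in ("n_features_pos", "n_features_neg", "n_planted_pairs_pos",
                     "n_planted_pairs_neg", "n_cobehave_up", "n_cobehave_down",
                     "n_adduct_triplets", "n_decoy_ppm", "n_decoy_rt",
                     "n_decoy_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.planted_jitter_frac < 1 and 0 < self.planted_rt_jitter_frac < 1):
            raise ValueError(
                "planted jitters must be strictly inside the screen tolerances"
            )
        if self.decoy_offset_min <= 1.0:
            raise ValueError(
                "contradictory config: decoy offsets must exceed the screen "
                "tolerance (decoy_offset_min > 1)"
            )
        if self.decoy_offset_max < self.decoy_offset_min:
            raise ValueError("decoy_offset_max < decoy_offset_min")
        if 3 * self.n_adduct_triplets > self.n_cobehave_up:
            raise ValueError("adduct-triplet members exceed n_cobehave_up")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class PlantedPair:
    unlabeled_id: str
    labeled_id: str
    n_label: int
    ion_mode: str


@dataclass(frozen=True)
class DecoyPair:
    unlabeled_id: str
    labeled_id: str
    kind: str  # "ppm_near_miss" | "rt_miss" | "control_max"
    ion_mode: str


@dataclass
class GroundTruth:
    """The generator's ledger of what was planted where."""

    pairs: List[PlantedPair]
    cobehaving: List[Tuple[str, str]]          # (feature_id, direction)
    decoys: List[DecoyPair]
    adduct_triplets: List[Tuple[str, str, str]]
    internal_standards: Dict[str, str]         # ion mode -> feature id

    def pair_set(self) -> set:
        return {(p.unlabeled_id, p.labeled_id) for p in self.pairs}

    def decoy_feature_ids(self) -> set:
        return {f for d in self.decoys for f in (d.unlabeled_id, d.labeled_id)}

    def cobehaving_ids(self) -> set:
        return {fid for fid, _ in self.cobehaving}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append({"kind": "planted_pair", "id_a": p.unlabeled_id,
                         "id_b": p.labeled_id, "detail": str(p.n_label),
                         "ion_mode": p.ion_mode})
        for fid, direction in self.cobehaving:
            rows.append({"kind": "cobehaving", "id_a": fid, "id_b": "",
                         "detail": direction, "ion_mode": ""})
        for d in self.decoys:
            rows.append({"kind": f"decoy_{d.kind}", "id_a": d.unlabeled_id,
                         "id_b": d.labeled_id, "detail": "", "ion_mode": d.ion_mode})
        for t in self.adduct_triplets:
            rows.append({"kind": "adduct_triplet", "id_a": t[0], "id_b": t[1],
                         "detail": t[2], "ion_mode": ""})
        for mode, fid in self.internal_standards.items():
            rows.append({"kind": "internal_standard", "id_a": fid, "id_b": "",
                         "detail": "", "ion_mode": mode})
        return pd.DataFrame(rows, columns=["kind", "id_a", "id_b", "detail", "ion_mode"])


# ------------------------------------------------------------------


class _Builder:
    """Accumulates features/rows while generating."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.design = _make_design(config)
        self.sample_ids = self.design["sample_id"].tolist()
        self.n_samples = len(self.sample_ids)
        self.sample_meta = list(zip(
            self.design["treatment"], self.design["time_h"], self.design["replicate"],
        ))
        self.time_index = {t: i for i, t in enumerate(config.time_points_h)}
        self.ids: List[str] = []
        self.mz: List[float] = []
        self.rt: List[float] = []
        self.mode: List[str] = []
        self.rows: List[np.ndarray] = []
        self._counter = {"positive": 0, "negative": 0}

    def new_id(self, mode: str) -> str:
        self._counter[mode] += 1
        prefix = "P" if mode == "positive" else "N"
        return f"{prefix}{self._counter[mode]:04d}"

    def add(self, mode: str, mz: float, rt: float, row: np.ndarray) -> str:
        fid = self.new_id(mode)
        self.ids.append(fid)
        self.mz.append(mz)
        self.rt.append(rt)
        self.mode.append(mode)
        self.rows.append(row)
        return fid

    # -- intensity row builders -------------------------------------

    def below_floor(self) -> np.ndarray:
        """Values strictly below the floor (floored to a constant)."""
        return self.rng.uniform(0.2, 0.9, self.n_samples) * self.config.noise_floor

    def treatment_profile(self, treatment: str, shape: np.ndarray,
                          amplitude: float) -> np.ndarray:
        """Row peaking only under one treatment; below floor elsewhere."""
        row = self.below_floor()
        for k, (trt, t, _rep) in enumerate(self.sample_meta):
            if trt == treatment:
                row[k] = amplitude * shape[self.time_index[t]] * self._noise()
        return row

    def tracer_shared_profile(self, shape: np.ndarray, amplitude: float,
                              control_level: float) -> np.ndarray:
        """Row following ``shape`` under both tracers, flat control."""
        row = np.empty(self.n_samples)
        for k, (trt, t, _rep) in enumerate(self.sample_meta):
            if trt == "control":
                row[k] = control_level * 10 ** self.rng.normal(0, 0.08)
            else:
                row[k] = amplitude * shape[self.time_index[t]] * self._noise()
        return row

    def background_profile(self, amplitude: float) -> np.ndarray:
        """Shared (time, replicate) structure across all treatments."""
        cfg = self.config
        cell = {}
        for t in cfg.time_points_h:
            for r in range(1, cfg.n_replicates + 1):
                cell[(t, r)] = 10 ** self.rng.normal(0, cfg.profile_log10_sd)
        row = np.empty(self.n_samples)
        for k, (_trt, t, rep) in enumerate(self.sample_meta):
            row[k] = amplitude * cell[(t, rep)] * self._noise()
        return row

    def _noise(self) -> float:
        return 10 ** self.rng.normal(0, self.config.replicate_log10_sd)


def _make_design(config: SimulationConfig) -> pd.DataFrame:
    code = {"control": "C", "unlabeled_tracer": "U", "labeled_tracer": "L"}
    rows = []
    for trt in TREATMENTS:
        for t in config.time_points_h:
            for rep in range(1, config.n_replicates + 1):
                rows.append({
                    "sample_id": f"{code[trt]}_t{t:g}_r{rep}",
                    "treatment": trt,
                    "time_h": t,
                    "replicate": rep,
                    "batch": "b1",
                })
    return pd.DataFrame(rows)


def _tracer_vectors(b: _Builder, row: np.ndarray) -> Dict[str, np.ndarray]:
    """(time, replicate)-ordered vectors per treatment for a row."""
    order = {}
    for trt in TREATMENTS:
        idx = [k for k, (t, _, _) in enumerate(b.sample_meta) if t == trt]
        idx.sort(key=lambda k: (b.sample_meta[k][1], b.sample_meta[k][2]))
        order[trt] = row[idx]
    return order


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    from scipy import stats
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(stats.spearmanr(x, y).statistic)


def generate(config: SimulationConfig | None = None) -> Tuple[FeatureTable, GroundTruth]:
    """Build a feature table plus its ground-truth ledger.

    Deterministic for a fixed seed: the same config yields an
    identical table.
    """
    config = config or SimulationConfig()
    b = _Builder(config)
    truth = GroundTruth([], [], [], [], {})

    mode_budget = {"positive": config.n_features_pos, "negative": config.n_features_neg}

    def charge(mode: str, n: int = 1) -> None:
        mode_budget[mode] -= n
        if mode_budget[mode] < 0:
            raise ValueError(
                f"feature budget for {mode} mode exhausted; increase n_features"
            )

    # internal standards: background-like drift so they co-behave with control
    for mode, is_mz, is_rt in (("positive", config.is_positive_mz, 1.20),
                               ("negative", config.is_negative_mz, 1.40)):
        charge(mode)
        amp = 10 ** b.rng.normal(4.0, 0.05)
        row = amp * np.array([10 ** b.rng.normal(0, 0.05) for _ in range(b.n_samples)])
        fid = b.add(mode, is_mz, is_rt, row)
        truth.internal_standards[mode] = fid

    shapes_up = ["peak24", "late", "rise"]

    # planted isotopologue pairs
    counts = sorted(config.shift_spec.allowed_counts)
    plan = [("positive", config.n_planted_pairs_pos), ("negative", config.n_planted_pairs_neg)]
    k = 0
    for mode, n_pairs in plan:
        for _ in range(n_pairs):
            charge(mode, 2)
            n = counts[k % len(counts)]
            shape = _SHAPES[shapes_up[k % len(shapes_up)]]
            k += 1
            mz_u = b.rng.uniform(150.0, 800.0)
            rt = b.rng.uniform(0.5, 14.0)
            tol = config.delta_ppm_tol * 1e-6 * mz_u
            gap = label_delta(config.shift_spec, n) + b.rng.uniform(-1, 1) * (
                config.planted_jitter_frac * tol)
            rt_l = rt + b.rng.uniform(-1, 1) * (
                config.planted_rt_jitter_frac * config.rt_tol_min)
            amp = 10 ** b.rng.uniform(3.8, 4.7)
            uid = b.add(mode, mz_u, rt,
                        b.treatment_profile("unlabeled_tracer", shape, amp))
            lid = b.add(mode, mz_u + gap, rt_l,
                        b.treatment_profile("labeled_tracer", shape,
                                            amp * 10 ** b.rng.uniform(-0.1, 0.1)))
            truth.pairs.append(PlantedPair(uid, lid, n, mode))

    # decoy pairs: each violates exactly one criterion by >= 2x tolerance
    decoy_plan = (
        [("ppm_near_miss", config.n_decoy_ppm),
         ("rt_miss", config.n_decoy_rt),
         ("control_max", config.n_decoy_control)]
    )
    k = 0
    for kind, n_decoys in decoy_plan:
        for i in range(n_decoys):
            mode = "positive" if (mode_budget["positive"] * 2 >= mode_budget["negative"] * 3) else "negative"
            charge(mode, 2)
            n = counts[k % len(counts)]
            shape = _SHAPES[shapes_up[k % len(shapes_up)]]
            k += 1
            mz_u = b.rng.uniform(150.0, 800.0)
            rt = b.rng.uniform(0.5, 14.0)
            tol = config.delta_ppm_tol * 1e-6 * mz_u
            gap = label_delta(config.shift_spec, n) + b.rng.uniform(-1, 1) * (
                config.planted_jitter_frac * tol)
            rt_l = rt + b.rng.uniform(-1, 1) * (
                config.planted_rt_jitter_frac * config.rt_tol_min)
            if kind == "ppm_near_miss":
                sign = 1 if b.rng.random() < 0.5 else -1
                gap = label_delta(config.shift_spec, n) + sign * b.rng.uniform(
                    config.decoy_offset_min, config.decoy_offset_max) * tol
            elif kind == "rt_miss":
                sign = 1 if b.rng.random() < 0.5 else -1
                rt_l = rt + sign * b.rng.uniform(
                    config.decoy_offset_min, config.decoy_offset_max) * config.rt_tol_min
                rt_l = max(rt_l, 0.0)
            amp = 10 ** b.rng.uniform(3.8, 4.7)
            labeled_treatment = "control" if kind == "control_max" else "labeled_tracer"
            uid = b.add(mode, mz_u, rt,
                        b.treatment_profile("unlabeled_tracer", shape, amp))
            lid = b.add(mode, mz_u + gap, rt_l,
                        b.treatment_profile(labeled_treatment, shape,
                                            amp * 10 ** b.rng.uniform(-0.1, 0.1)))
            truth.decoys.append(DecoyPair(uid, lid, kind, mode))

    # co-behaving features (adduct triplets first, then independents)
    def make_cobehaver(mode: str, mz: float, rt: float, direction: str,
                       shape: np.ndarray, amp: float, control_level: float) -> str:
        charge(mode)
        low_cap = 0.2 - 0.05
        high_floor = 0.4 + 0.1
        for _attempt in range(200):
            row = b.tracer_shared_profile(shape, amp, control_level)
            floored = np.maximum(row, config.noise_floor)
            vecs = _tracer_vectors(b, floored)
            rho_t = _spearman(vecs["unlabeled_tracer"], vecs["labeled_tracer"])
            rho_cu = _spearman(vecs["control"], vecs["unlabeled_tracer"])
            rho_cl = _spearman(vecs["control"], vecs["labeled_tracer"])
            if rho_t >= high_floor and abs(rho_cu) <= low_cap and abs(rho_cl) <= low_cap:
                fid = b.add(mode, mz, rt, row)
                truth.cobehaving.append((fid, direction))
                return fid
        raise RuntimeError("could not draw a compliant co-behaving profile")

    n_up_left = config.n_cobehave_up
    for _ in range(config.n_adduct_triplets):
        M = b.rng.uniform(300.0, 600.0)
        rt = b.rng.uniform(0.5, 14.0)
        shape = _SHAPES[shapes_up[b.rng.integers(len(shapes_up))]]
        amp = 10 ** b.rng.uniform(4.1, 4.6)
        ids = (
            make_cobehaver("positive", M + PROTON_MASS, rt, "max_in_tracer",
                           shape, amp, 10 ** b.rng.uniform(3.1, 3.4)),
            make_cobehaver("positive", 2 * M + PROTON_MASS,
                           rt + b.rng.uniform(-0.01, 0.01), "max_in_tracer",
                           shape, amp * 0.3, 10 ** b.rng.uniform(2.9, 3.2)),
            make_cobehaver("negative", M - PROTON_MASS,
                           rt + b.rng.uniform(-0.01, 0.01), "max_in_tracer",
                           shape, amp * 0.6, 10 ** b.rng.uniform(3.0, 3.3)),
        )
        truth.adduct_triplets.append(ids)
        n_up_left -= 3

    toggle = ["positive", "negative"]
    for i in range(n_up_left):
        mode = toggle[i % 2]
        make_cobehaver(mode, b.rng.uniform(120.0, 900.0), b.rng.uniform(0.5, 14.0),
                       "max_in_tracer", _SHAPES[shapes_up[i % len(shapes_up)]],
                       10 ** b.rng.uniform(4.0, 4.6), 10 ** b.rng.uniform(3.1, 3.4))
    for i in range(config.n_cobehave_down):
        mode = toggle[i % 2]
        base = 10 ** b.rng.uniform(3.6, 4.0)
        make_cobehaver(mode, b.rng.uniform(120.0, 900.0), b.rng.uniform(0.5, 14.0),
                       "min_in_tracer", _SHAPES["dip9"], base, base * 1.05)

    # background features fill the remaining budget
    for mode in ("positive", "negative"):
        while mode_budget[mode] > 0:
            charge(mode)
            amp = 10 ** b.rng.normal(config.baseline_log10_mean, config.baseline_log10_sd)
            b.add(mode, b.rng.uniform(100.0, 1000.0), b.rng.uniform(0.5, 14.0),
                  b.background_profile(amp))

    table = _assemble(b, truth)
    table = _audit_mass_coincidences(table, truth, config)
    table = _audit_screen_false_positives(table, truth, config)
    return table, truth


def _assemble(b: _Builder, truth: GroundTruth) -> FeatureTable:
    config = b.config
    features = pd.DataFrame({
        "id": b.ids, "mz": b.mz, "rt": b.rt, "ion_mode": b.mode,
    })
    mat = np.vstack(b.rows)
    # missing cells on background features only (keeps planted truths exact)
    protected = (
        {p.unlabeled_id for p in truth.pairs} | {p.labeled_id for p in truth.pairs}
        | truth.decoy_feature_ids() | truth.cobehaving_ids()
        | set(truth.internal_standards.values())
    )
    if config.missing_rate > 0:
        mask = b.rng.random(mat.shape) < config.missing_rate
        rows_protected = np.array([fid in protected for fid in b.ids])
        mask[rows_protected, :] = False
        mat = np.where(mask, np.nan, mat)
    intensities = pd.DataFrame(mat, index=features["id"], columns=b.sample_ids)
    intensities.index.name = None
    return FeatureTable(features, b.design.copy(), intensities)


def _intended_pairs(truth: GroundTruth) -> Dict[str, set]:
    """feature id -> set of ids it is intentionally paired with."""
    links: Dict[str, set] = {}
    for p in truth.pairs:
        links.setdefault(p.unlabeled_id, set()).add(p.labeled_id)
        links.setdefault(p.labeled_id, set()).add(p.unlabeled_id)
    for d in truth.decoys:
        links.setdefault(d.unlabeled_id, set()).add(d.labeled_id)
        links.setdefault(d.labeled_id, set()).add(d.unlabeled_id)
    return links


def _audit_mass_coincidences(
    table: FeatureTable, truth: GroundTruth, config: SimulationConfig,
    max_rounds: int = 10,
) -> FeatureTable:
    """Nudge accidental label-shift/RT coincidences between features
    that were not planted as a pair (guard band: 2x each tolerance)."""
    links = _intended_pairs(truth)
    deltas = list(config.shift_spec.deltas().values())
    feats = table.features
    # never move the internal standards (preprocess finds them by m/z)
    # or adduct-triplet members (their m/z encodes the shared neutral mass)
    immovable = set(truth.internal_standards.values())
    for t in truth.adduct_triplets:
        immovable |= set(t)
    for _round in range(max_rounds):
        collisions: List[Tuple[str, str]] = []
        for mode in ("positive", "negative"):
            sub = feats[feats["ion_mode"] == mode]
            order = sub.sort_values("mz")
            mz = order["mz"].to_numpy()
            rt = order["rt"].to_numpy()
            ids = order["id"].to_numpy()
            for d in deltas:
                tol = 2.0 * config.delta_ppm_tol * 1e-6 * mz
                lo = np.searchsorted(mz, mz + d - tol, side="left")
                hi = np.searchsorted(mz, mz + d + tol, side="right")
                for i in range(len(mz)):
                    for j in range(lo[i], hi[i]):
                        if j == i:
                            continue
                        if abs(rt[i] - rt[j]) > 2.0 * config.rt_tol_min:
                            continue
                        if ids[j] in links.get(ids[i], ()):
                            continue
                        collisions.append((ids[i], ids[j]))
        if not collisions:
            break
        # shift one offender per collision (with its intended partner,
        # preserving the planted gap). Both sides of a handled collision
        # are locked for the round so reciprocal collisions between two
        # planted pairs cannot shift both pairs in lockstep.
        locked: set = set()
        for a, c in collisions:
            group_a = {a, *links.get(a, ())}
            group_c = {c, *links.get(c, ())}
            if (group_a | group_c) & locked:
                continue
            target_group = group_c if not (group_c & immovable) else group_a
            if target_group & immovable:
                continue  # both sides immovable; left as-is (screens reject them)
            for fid in target_group:
                feats.loc[feats["id"] == fid, "mz"] += 0.35
            locked |= group_a | group_c
    else:
        raise RuntimeError("mass-coincidence audit did not converge")
    table.features = feats
    return table


def _audit_screen_false_positives(
    table: FeatureTable, truth: GroundTruth, config: SimulationConfig,
    max_rounds: int = 5,
) -> FeatureTable:
    """Flatten any non-planted feature that still slips through either
    screen: its tracer columns are replaced by its control profile with
    tiny per-treatment scale offsets, which pins all three rank
    correlations near one and removes any tracer-specific argmax."""
    screen_cfg = ScreenConfig(
        noise_floor=config.noise_floor,
        shift_spec=config.shift_spec,
        delta_ppm_tol=config.delta_ppm_tol,
        rt_tol_min=config.rt_tol_min,
    )
    truth_pairs = truth.pair_set()
    truth_cb = truth.cobehaving_ids()
    protected = (
        {p.unlabeled_id for p in truth.pairs} | {p.labeled_id for p in truth.pairs}
        | truth_cb
    )
    col_of_trt = {
        trt: [s for s, t in zip(table.design["sample_id"], table.design["treatment"]) if t == trt]
        for trt in TREATMENTS
    }
    for _round in range(max_rounds):
        floored = floor_noise(table, PreprocessConfig(noise_floor=config.noise_floor))
        offenders: set = set()
        for p in screen_pairs(floored, screen_cfg):
            if (p.unlabeled_id, p.labeled_id) not in truth_pairs:
                for fid in (p.unlabeled_id, p.labeled_id):
                    if fid not in protected:
                        offenders.add(fid)
        for r in screen_cobehavior(floored, CobehaviorThresholds(), screen_cfg):
            if r.feature_id not in truth_cb and r.feature_id not in protected:
                offenders.add(r.feature_id)
        if not offenders:
            return table
        for fid in offenders:
            ctrl = table.intensities.loc[fid, col_of_trt["control"]].to_numpy(dtype=float)
            ctrl = np.where(np.isnan(ctrl), config.noise_floor, ctrl)
            table.intensities.loc[fid, col_of_trt["control"]] = ctrl * 1.002
            table.intensities.loc[fid, col_of_trt["unlabeled_tracer"]] = ctrl
            table.intensities.loc[fid, col_of_trt["labeled_tracer"]] = ctrl * 0.998
    raise RuntimeError("screen false-positive audit did not converge")


def write_simulation(
    table: FeatureTable, truth: GroundTruth, out_dir: str | Path
) -> Dict[str, Path]:
    """Write matrix, design and ground-truth CSVs; returns the paths."""
    from .feature_table import write_feature_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.csv",
        "design": out / "design.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_feature_table(table, paths["matrix"], paths["design"])
    truth.to_frame().to_csv(paths["ground_truth"], index=False)
    return paths
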
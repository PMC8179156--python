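"""Cross-mode / cross-adduct consolidation of screened records.

One metabolite can surface as several features — [M+H]+ and [2M+H]+
in positive mode, [M-H]- in negative mode. Entries whose neutral-mass
hypotheses agree within a Da tolerance and whose retention times agree
within an RT tolerance are linked, and connected components are merged
into one record represented by the most intense member. This is the
step that reduces 42+13 first-screen pairs to 26 and 50+31 co-behavior
records to 67 in the original screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .chem import neutral_mass_from_mz
from .pair_screen import PairCandidate
from .feature_table import FeatureTable

__all__ = [
    "ConsolidationEntry",
    "ConsolidatedRecord",
    "neutral_hypotheses",
    "consolidate",
    "entries_from_pairs",
    "entries_from_feature_ids",
]

logger = logging.getLogger(__name__)

#: Adduct hypotheses assumed per ion mode (singly charged).
MODE_HYPOTHESES = {
    "positive": ("[M+H]+", "[2M+H]+"),
    "negative": ("[M-H]-",),
}


def neutral_hypotheses(mz: float, ion_mode: str) -> Dict[str, float]:
    """Candidate neutral masses for a measured m/z under the adduct
    forms assumed for its ion mode."""
    try:
        adducts = MODE_HYPOTHESES[ion_mode]
    except KeyError:
        raise ValueError(f"unknown ion mode {ion_mode!r}") from None
    return {name: neutral_mass_from_mz(mz, name) for name in adducts}


@dataclass(frozen=True)
class ConsolidationEntry:
    """One screened record entering consolidation.

    For a pair, ``mz`` and ``rt`` are those of the unlabeled member
    and ``labeled_mz`` that of the labeled member (used for the
    consistency check); ``max_intensity`` is the entry's maximal
    intensity, which elects the representative.
    """

    entry_id: str
    mz: float
    rt: float
    ion_mode: str
    max_intensity: float
    labeled_mz: Optional[float] = None


@dataclass(frozen=True)
class ConsolidatedRecord:
    """A merged group of entries, led by its most intense member."""

    representative: str
    members: Tuple[str, ...]
    neutral_mass_estimates: Dict[str, float]
    rt: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        if len(self.members) < 1:
            raise ValueError("a record needs at least one member")


def _linked(a: ConsolidationEntry, b: ConsolidationEntry,
            mass_tol_da: float, rt_tol_min: float) -> bool:
    if abs(a.rt - b.rt) > rt_tol_min:
        return False
    ha = neutral_hypotheses(a.mz, a.ion_mode).values()
    hb = neutral_hypotheses(b.mz, b.ion_mode).values()
    return any(abs(x - y) <= mass_tol_da for x in ha for y in hb)


def consolidate(
    entries: Sequence[ConsolidationEntry],
    mass_tol_da: float = 0.01,
    rt_tol_min: float = 0.05,
) -> List[ConsolidatedRecord]:
    """Merge entries into connected components of the agreement graph.

    Two entries are linked when any of their neutral-mass hypotheses
    agree within ``mass_tol_da`` and their RTs within ``rt_tol_min``
    (RT gating applies across ion modes — same chromatographic run).
    The representative is the member with the highest max intensity;
    ties break toward lower m/z, then lexicographically smaller id
    (logged). Output is sorted by representative m/z.
    """
    entries = list(entries)
    n = len(entries)
    if n == 0:
        return []
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if _linked(entries[i], entries[j], mass_tol_da, rt_tol_min):
                rows += [i, j]
                cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)

    records: List[ConsolidatedRecord] = []
    for comp in range(n_comp):
        members = [entries[i] for i in np.flatnonzero(labels == comp)]
        rep = min(members, key=lambda e: (-e.max_intensity, e.mz, e.entry_id))
        if len(members) > 1:
            tied = [e for e in members if e.max_intensity == rep.max_intensity]
            if len(tied) > 1:
                logger.info(
                    "representative tie among %s resolved to %s (lower m/z, then id)",
                    [e.entry_id for e in tied], rep.entry_id,
                )
            _check_labeled_consistency(members, mass_tol_da)
        records.append(ConsolidatedRecord(
            representative=rep.entry_id,
            members=tuple(sorted(e.entry_id for e in members)),
            neutral_mass_estimates=neutral_hypotheses(rep.mz, rep.ion_mode),
            rt=rep.rt,
        ))
    records.sort(key=lambda r: (r.rt, min(r.neutral_mass_estimates.values()), r.representative))
    return records


def _check_labeled_consistency(
    members: Sequence[ConsolidationEntry], mass_tol_da: float
) -> None:
    """For merged pairs, the labeled members must also be explainable
    by one neutral mass; warn when they are not."""
    labeled = [e for e in members if e.labeled_mz is not None]
    for i in range(len(labeled)):
        for j in range(i + 1, len(labeled)):
            a, b = labeled[i], labeled[j]
            ha = neutral_hypotheses(a.labeled_mz, a.ion_mode).values()
            hb = neutral_hypotheses(b.labeled_mz, b.ion_mode).values()
            if not any(abs(x - y) <= mass_tol_da for x in ha for y in hb):
                logger.warning(
                    "labeled members of %s and %s do not merge consistently",
                    a.entry_id, b.entry_id,
                )


def entries_from_pairs(
    pairs: Sequence[PairCandidate], table: FeatureTable
) -> List[ConsolidationEntry]:
    """Consolidation entries for screened pairs: linkage on the
    unlabeled member, intensity = max over both members' samples."""
    feats = table.features.set_index(table.features["id"].astype(str))
    out = []
    for p in pairs:
        mz = float(feats.loc[p.unlabeled_id, "mz"])
        rt = float(feats.loc[p.unlabeled_id, "rt"])
        intensity = float(
            max(table.intensities.loc[p.unlabeled_id].max(),
                table.intensities.loc[p.labeled_id].max())
        )
        out.append(ConsolidationEntry(
            entry_id=f"{p.unlabeled_id}|{p.labeled_id}",
            mz=mz, rt=rt, ion_mode=p.ion_mode,
            max_intensity=intensity,
            labeled_mz=float(feats.loc[p.labeled_id, "mz"]),
        ))
    return out


def entries_from_feature_ids(
    feature_ids: Sequence[str], table: FeatureTable
) -> List[ConsolidationEntry]:
    """Consolidation entries for single screened features (the
    co-behavior records)."""
    feats = table.features.set_index(table.features["id"].astype(str))
    out = []
    for fid in feature_ids:
        out.append(ConsolidationEntry(
            entry_id=str(fid),
            mz=float(feats.loc[fid, "mz"]),
            rt=float(feats.loc[fid, "rt"]),
            ion_mode=str(feats.loc[fid, "ion_mode"]),
            max_intensity=float(table.intensities.loc[fid].max()),
        ))
    return out


def records_to_frame(records: List[ConsolidatedRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "representative": r.representative,
            "n_members": len(r.members),
            "members": ";".join(r.members),
            "rt": r.rt,
            **{f"neutral_mass_{k}": v for k, v in r.neutral_mass_estimates.items()},
        })
    return pd.DataFrame(rows)
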
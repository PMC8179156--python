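"""Exact-mass annotation against a compound library.

A measured m/z is matched to library compounds through the precursor
adduct of its ion mode ([M+H]+ for positive, [M-H]- for negative)
with an absolute Da tolerance (default 0.01 Da). A small curated
library of isothiocyanate-processing intermediates and glucosinolates
ships with the package; any user CSV with columns ``name,formula``
(optional ``synonyms``) can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .chem import MolecularFormula, adduct_mz, monoisotopic_mass

__all__ = [
    "CompoundRecord",
    "AnnotationHit",
    "load_compound_library",
    "bundled_library",
    "annotate_mz",
]

PRECURSOR_ADDUCT = {"positive": "[M+H]+", "negative": "[M-H]-"}


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound with its derived neutral monoisotopic mass."""

    name: str
    formula: MolecularFormula
    neutral_mass: float
    source: str = "user"

    @classmethod
    def from_formula(cls, name: str, formula: str, source: str = "user") -> "CompoundRecord":
        f = MolecularFormula.parse(formula)
        return cls(name=name, formula=f, neutral_mass=monoisotopic_mass(f), source=source)


@dataclass(frozen=True)
class AnnotationHit:
    compound: CompoundRecord
    adduct: str
    theoretical_mz: float
    mass_error_da: float


def load_compound_library(path: str | Path, source: Optional[str] = None) -> List[CompoundRecord]:
    """Read a compound CSV (columns: name, formula[, synonyms])."""
    df = pd.read_csv(path)
    for col in ("name", "formula"):
        if col not in df.columns:
            raise ValueError(f"compound library {path} missing column {col!r}")
    tag = source or str(path)
    return [
        CompoundRecord.from_formula(str(row["name"]), str(row["formula"]), source=tag)
        for _, row in df.iterrows()
    ]


def bundled_library() -> List[CompoundRecord]:
    """The curated library shipped with the package."""
    ref = resources.files("tracerscreen.data") / "compounds.csv"
    with resources.as_file(ref) as path:
        return load_compound_library(path, source="bundled")


def annotate_mz(
    mz: float,
    ion_mode: str,
    compounds: Optional[Sequence[CompoundRecord]] = None,
    tol_da: float = 0.01,
) -> List[AnnotationHit]:
    """Library compounds whose precursor-adduct m/z lies within
    ``tol_da`` of the query, sorted by absolute mass error."""
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    try:
        adduct = PRECURSOR_ADDUCT[ion_mode]
    except KeyError:
        raise ValueError(f"unknown ion mode {ion_mode!r}") from None
    if compounds is None:
        compounds = bundled_library()
    hits = []
    for c in compounds:
        theo = adduct_mz(c.formula, adduct)
        err = mz - theo
        if abs(err) <= tol_da:
            hits.append(AnnotationHit(c, adduct, theo, err))
    hits.sort(key=lambda h: (abs(h.mass_error_da), h.compound.name))
    return hits
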
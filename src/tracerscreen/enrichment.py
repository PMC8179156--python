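"""Isotope-enrichment fractions and tracer sulfur-budget arithmetic.

Small, exact helpers for the bookkeeping around a labeling study:
the labeled fraction of a metabolite from its monoisotopic and
heavy-isotope channel intensities, the per-plant tracer dose, and the
percentage of the supplied label recovered in measured pools.

No natural-abundance correction is applied to the labeled fraction;
the two channel intensities are taken as given (they come from
designated MS/MS fragment-ion pairs chosen upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "TracerDose",
    "labeled_fraction",
    "dose_per_plant",
    "recovery_percent",
]


@dataclass(frozen=True)
class TracerDose:
    """A tracer application: concentration (uM) x volume (mL) shared
    by ``n_plants`` seedlings."""

    concentration_um: float
    volume_ml: float
    n_plants: int

    def __post_init__(self) -> None:
        if self.concentration_um <= 0 or self.volume_ml <= 0:
            raise ValueError("concentration and volume must be positive")
        if self.n_plants <= 0:
            raise ValueError("n_plants must be a positive count")


def labeled_fraction(i_mono: float, i_labeled: float) -> float:
    """Heavy-channel intensity over total (labeled + monoisotopic).

    Scale-invariant; raises when both channels are zero (undefined).
    """
    if i_mono < 0 or i_labeled < 0:
        raise ValueError("channel intensities must be non-negative")
    total = i_mono + i_labeled
    if total == 0:
        raise ValueError("labeled fraction undefined when both channels are zero")
    return i_labeled / total


def dose_per_plant(dose: TracerDose) -> float:
    """Tracer amount per plant in nmol (uM x mL = nmol)."""
    return dose.concentration_um * dose.volume_ml / dose.n_plants


def recovery_percent(retained_nmol: Sequence[float], dose_per_plant_nmol: float) -> float:
    """Percent of the per-plant dose recovered across measured pools."""
    if dose_per_plant_nmol <= 0:
        raise ValueError("dose must be positive")
    if any(r < 0 for r in retained_nmol):
        raise ValueError("retained amounts must be non-negative")
    return 100.0 * sum(retained_nmol) / dose_per_plant_nmol
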
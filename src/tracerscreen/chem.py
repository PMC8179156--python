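"""Monoisotopic mass arithmetic for small-molecule LC-MS work.

Provides molecular-formula parsing and mass summation, adduct m/z
computation ([M+H]+, [M-H]-, [2M+H]+ and user-defined singly charged
adducts), isotope-label mass shifts (deuterium, sulfur-34) and ppm
error arithmetic.

Atomic masses are embedded as constants (CODATA 2018 / AME2020 rounded
to 8 decimal places) so results are identical on every platform.
Heavy-isotope labels are treated as distinct element symbols (``2H``,
``34S``) so a labeled composition can be written explicitly, e.g.
``C12H18[2H]5NO10S3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "Adduct",
    "ADDUCTS",
    "LabelShiftSpec",
    "DEUTERIUM_PRINTED",
    "DEUTERIUM_COMPUTED",
    "SULFUR34",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_mass_from_mz",
    "label_delta",
    "ppm_error",
]

#: Monoisotopic atomic masses in Da. Light isotopes from CODATA 2018,
#: heavy labels from AME2020; 8 decimals.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207100,
    "P": 30.97376163,
    "2H": 2.01410178,   # deuterium
    "34S": 33.96786701,  # sulfur-34
}

#: Mass of a proton (H minus one electron), Da.
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(
    r"\[(?P<iso>\d+)(?P<isoel>[A-Z][a-z]?)\](?P<ison>\d*)"
    r"|(?P<el>[A-Z][a-z]?)(?P<n>\d*)"
)


class UnsupportedElementError(ValueError):
    """Raised for an element symbol absent from the mass table."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. C16H28N4O7S3.

    ``element_counts`` maps symbols (including the label symbols ``2H``
    and ``34S``) to positive integer counts. An empty composition is
    invalid.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise ValueError("empty molecular formula is invalid")
        for symbol, count in self.element_counts.items():
            if symbol not in MONOISOTOPIC_MASS:
                raise UnsupportedElementError(
                    f"unsupported element symbol {symbol!r}"
                )
            if not isinstance(count, int) or count < 1:
                raise ValueError(
                    f"count for {symbol} must be a positive integer, got {count!r}"
                )
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse ``C16H28N4O7S3`` style text; ``D`` and ``[2H]`` both
        denote deuterium, ``[34S]`` sulfur-34."""
        counts: Dict[str, int] = {}
        pos = 0
        text = text.strip()
        if not text:
            raise ValueError("empty molecular formula is invalid")
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if m is None:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            if m.group("iso"):
                symbol = f"{m.group('iso')}{m.group('isoel')}"
                n = int(m.group("ison") or 1)
            else:
                symbol = m.group("el")
                if symbol == "D":
                    symbol = "2H"
                n = int(m.group("n") or 1)
            counts[symbol] = counts.get(symbol, 0) + n
            pos = m.end()
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for symbol, n in other.element_counts.items():
            counts[symbol] = counts.get(symbol, 0) + n
        return MolecularFormula(counts)

    def __str__(self) -> str:
        parts = []
        for symbol in sorted(self.element_counts):
            n = self.element_counts[symbol]
            token = f"[{symbol}]" if symbol[0].isdigit() else symbol
            parts.append(f"{token}{n if n > 1 else ''}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic mass."""
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    return sum(
        count * MONOISOTOPIC_MASS[symbol]
        for symbol, count in formula.element_counts.items()
    )


@dataclass(frozen=True)
class Adduct:
    """A singly charged adduct relating neutral mass M to measured m/z.

    m/z = multimer * M + proton_delta, with proton_delta = +p for
    protonated and -p for deprotonated species.
    """

    name: str
    charge_sign: int        # +1 or -1
    multimer: int           # M count: 1 for [M+H]+, 2 for [2M+H]+
    proton_delta: float     # signed Da added to multimer * M

    def __post_init__(self) -> None:
        if self.charge_sign not in (-1, 1):
            raise ValueError("only singly charged adducts are supported")
        if self.multimer < 1:
            raise ValueError("multimer count must be >= 1")


ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, 1, +PROTON_MASS),
    "[M-H]-": Adduct("[M-H]-", -1, 1, -PROTON_MASS),
    "[2M+H]+": Adduct("[2M+H]+", +1, 2, +PROTON_MASS),
}


def _resolve_adduct(adduct: Adduct | str) -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(formula: MolecularFormula | str, adduct: Adduct | str) -> float:
    """Theoretical m/z of a singly charged adduct of ``formula``."""
    a = _resolve_adduct(adduct)
    return a.multimer * monoisotopic_mass(formula) + a.proton_delta


def neutral_mass_from_mz(mz: float, adduct: Adduct | str) -> float:
    """Invert :func:`adduct_mz`: neutral mass hypothesis for a measured m/z."""
    a = _resolve_adduct(adduct)
    return (mz - a.proton_delta) / a.multimer


@dataclass(frozen=True)
class LabelShiftSpec:
    """Mass shifts caused by incorporating n heavy-isotope atoms.

    ``printed_deltas`` may override the computed ``n * per_atom_delta``
    with externally reported shift values (it must stay within 200 ppm
    of the computed product, a sanity bound on transcription errors).
    """

    label: str                      # e.g. "2H" or "34S"
    per_atom_delta: float           # Da per substituted atom
    allowed_counts: frozenset[int]
    printed_deltas: Optional[Mapping[int, float]] = None

    def __post_init__(self) -> None:
        if self.per_atom_delta <= 0:
            raise ValueError("per_atom_delta must be positive")
        object.__setattr__(self, "allowed_counts", frozenset(self.allowed_counts))
        if self.printed_deltas is not None:
            for n, value in self.printed_deltas.items():
                computed = n * self.per_atom_delta
                if abs(value - computed) / computed > 200e-6:
                    raise ValueError(
                        f"printed delta {value} for n={n} deviates >200 ppm "
                        f"from computed {computed:.5f}"
                    )
            object.__setattr__(self, "printed_deltas", dict(self.printed_deltas))

    def deltas(self) -> Dict[int, float]:
        """All allowed (count, shift) values."""
        return {n: label_delta(self, n) for n in sorted(self.allowed_counts)}


_D_PER_ATOM = MONOISOTOPIC_MASS["2H"] - MONOISOTOPIC_MASS["H"]
_S34_PER_ATOM = MONOISOTOPIC_MASS["34S"] - MONOISOTOPIC_MASS["S"]

#: Deuterium shifts as reported for the 4MSB-d5 screen (2/3/5/10 atoms).
DEUTERIUM_PRINTED = LabelShiftSpec(
    label="2H",
    per_atom_delta=_D_PER_ATOM,
    allowed_counts=frozenset({2, 3, 5, 10}),
    printed_deltas={2: 2.0126, 3: 3.0189, 5: 5.0314, 10: 10.0628},
)

#: Same counts, shifts computed from the isotope mass table.
DEUTERIUM_COMPUTED = LabelShiftSpec(
    label="2H",
    per_atom_delta=_D_PER_ATOM,
    allowed_counts=frozenset({2, 3, 5, 10}),
)

#: Sulfur-34 shifts (+2 and +4 Da isotopes).
SULFUR34 = LabelShiftSpec(
    label="34S",
    per_atom_delta=_S34_PER_ATOM,
    allowed_counts=frozenset({1, 2}),
)


def label_delta(spec: LabelShiftSpec, n: int) -> float:
    """Mass shift in Da for n labeled atoms under ``spec``."""
    if n not in spec.allowed_counts:
        raise ValueError(
            f"label count {n} not in allowed counts {sorted(spec.allowed_counts)}"
        )
    if spec.printed_deltas is not None and n in spec.printed_deltas:
        return spec.printed_deltas[n]
    return n * spec.per_atom_delta


def ppm_error(observed: float, expected: float, reference_mz: float) -> float:
    """Absolute mass error in parts per million of ``reference_mz``."""
    if reference_mz <= 0:
        raise ValueError("reference_mz must be positive")
    return 1e6 * abs(observed - expected) / reference_mz
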
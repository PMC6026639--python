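"""Residue scales, calibration constants, and display rounding.

The aggregation-propensity values (``a3v``) are the experimentally derived
AGGRESCAN scale; hydropathy is Kyte–Doolittle; amphipathicity uses the
Eisenberg consensus hydrophobicity scale; the charge model defaults to the
EMBOSS pKa set.  All tables are data transcribed from their primary
publications, not fitted here, with two documented exceptions: the terminal
window pad and the normalization baseline of :class:`PropensityScale`, which
calibrate the windowed score against the reference AGGRESCAN webserver
output (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

# Intrinsic per-residue aggregation propensities (a3v), AGGRESCAN scale
# (Conchillo-Sole et al., derived from the in-vivo amyloid propensity data
# of Sanchez de Groot et al.).  Higher = more aggregation-prone.
A3V: Mapping[str, float] = {
    "I": 1.822,
    "F": 1.754,
    "V": 1.594,
    "L": 1.380,
    "Y": 1.159,
    "W": 1.037,
    "M": 0.910,
    "C": 0.604,
    "A": -0.036,
    "T": -0.159,
    "S": -0.294,
    "P": -0.334,
    "G": -0.535,
    "K": -0.931,
    "H": -1.033,
    "Q": -1.037,
    "R": -1.240,
    "N": -1.302,
    "E": -1.412,
    "D": -1.836,
}

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8,
    "R": -4.5,
    "N": -3.5,
    "D": -3.5,
    "C": 2.5,
    "Q": -3.5,
    "E": -3.5,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "L": 3.8,
    "K": -3.9,
    "M": 1.9,
    "F": 2.8,
    "P": -1.6,
    "S": -0.8,
    "T": -0.7,
    "V": 4.2,
    "W": -0.9,
    "Y": -1.3,
}

# Eisenberg consensus hydrophobicity, used for the hydrophobic moment.
EISENBERG: Mapping[str, float] = {
    "A": 0.62,
    "R": -2.53,
    "N": -0.78,
    "D": -0.90,
    "C": 0.29,
    "Q": -0.85,
    "E": -0.74,
    "G": 0.48,
    "H": -0.40,
    "I": 1.38,
    "L": 1.06,
    "K": -1.50,
    "M": 0.64,
    "F": 1.19,
    "P": 0.12,
    "S": -0.18,
    "T": -0.05,
    "V": 1.08,
    "W": 0.81,
    "Y": 0.26,
}

# AGGRESCAN window-length rule: sequence length -> odd window size.
_WINDOW_TIERS: tuple[tuple[int, int], ...] = (
    (75, 5),
    (175, 7),
    (300, 9),
)
_WINDOW_MAX = 11


def window_size_for_length(length: int) -> int:
    """Odd sliding-window size prescribed for a given sequence length."""
    if length < 1:
        raise ValueError(f"sequence length must be >= 1, got {length}")
    for upper, w in _WINDOW_TIERS:
        if length <= upper:
            return w
    return _WINDOW_MAX


@dataclass(frozen=True)
class PropensityScale:
    """Per-residue aggregation propensities plus windowing/normalization rules.

    ``terminal_pad`` is the propensity assigned to the virtual positions a
    centered window overhangs beyond the termini; ``baseline`` is subtracted
    per residue when the windowed sum is normalized to 100 residues.  Both
    are calibration constants of the scale, fixed once against published
    reference scores for IAPP peptides (see docs/methods.md); they are not
    free parameters of an analysis.
    """

    values: Mapping[str, float] = field(default_factory=lambda: dict(A3V))
    hot_spot_threshold: float = -0.02
    min_hot_spot_length: int = 5
    terminal_pad: float = -0.3094
    baseline: float = 0.02695

    def __post_init__(self) -> None:
        missing = STANDARD_20 - set(self.values)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")
        for aa, v in self.values.items():
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite propensity for {aa!r}")

    def window_size(self, length: int) -> int:
        return window_size_for_length(length)

    def value(self, residue: str, position: int | None = None) -> float:
        try:
            return self.values[residue]
        except KeyError:
            where = f" at position {position}" if position is not None else ""
            raise ValueError(
                f"residue {residue!r}{where} has no propensity value"
            ) from None


STANDARD_20 = frozenset(A3V)

# EMBOSS pKa set for the Henderson-Hasselbalch charge model.
EMBOSS_PKA_NTERM = 8.6
EMBOSS_PKA_CTERM = 3.6
EMBOSS_PKA_SIDECHAINS: Mapping[str, float] = {
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}
BASIC_SIDECHAINS = frozenset("KRH")
ACIDIC_SIDECHAINS = frozenset("DECY")


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def display_na4vss(x: float) -> float:
    """Na4vSS as printed in reports: half-up to 1 decimal."""
    return round_half_up(x, 1)


def display_gravy(x: float) -> float:
    """GRAVY as printed in reports: half-up to 3 decimals, then to 2.

    The double rounding reproduces the reference tabulations exactly; a
    single 2-decimal rounding differs for values such as -0.2946
    (-0.295 -> -0.30 versus -0.29).
    """
    return round_half_up(round_half_up(x, 3), 2)
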
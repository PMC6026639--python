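"""Peptide sequences and point-substitution variants.

Everything downstream (propensity scoring, physicochemical profiling,
catalog statistics, design scans) consumes :class:`PeptideSequence` and
:class:`VariantSpec`.  Positions are 1-based throughout, matching the
standard mutation notation (``F23R`` = wild residue F, position 23,
substitute R); substitutions never change sequence length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Invalid residue content or inconsistent sequence operation."""


class VariantParseError(ValueError):
    """Malformed variant notation."""


@dataclass(frozen=True)
class PeptideSequence:
    """An identified peptide as an uppercase one-letter residue string."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty residue string")
        bad = [
            (i, c)
            for i, c in enumerate(self.residues, start=1)
            if c not in STANDARD_RESIDUES
        ]
        if bad:
            pos, c = bad[0]
            raise SequenceError(
                f"sequence {self.id!r}: non-standard residue {c!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self):
            raise SequenceError(
                f"sequence {self.id!r}: position {position} outside 1..{len(self)}"
            )
        return self.residues[position - 1]


_VARIANT_RE = re.compile(r"^([A-Za-z])_?(\d+)_?([A-Za-z])$")


@dataclass(frozen=True, order=True)
class VariantSpec:
    """A single-residue substitution: wild residue, 1-based position, substitute."""

    position: int
    wild: str = field(compare=False)
    substitute: str = field(compare=False)

    def __post_init__(self) -> None:
        for name, c in (("wild", self.wild), ("substitute", self.substitute)):
            if c not in STANDARD_RESIDUES:
                raise VariantParseError(f"unknown {name} residue letter {c!r}")
        if self.wild == self.substitute:
            raise VariantParseError(
                f"wild residue equals substitute in {self.wild}{self.position}{self.substitute}"
            )
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")

    @property
    def notation(self) -> str:
        """Canonical separator-free form, e.g. ``F23R``."""
        return f"{self.wild}{self.position}{self.substitute}"

    def inverse(self) -> "VariantSpec":
        """The substitution that undoes this one at the same position."""
        return VariantSpec(self.position, self.substitute, self.wild)


def parse_variant_notation(text: str) -> VariantSpec:
    """Parse ``F23R`` / ``F_23_R`` style notation into a :class:`VariantSpec`."""
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"cannot parse variant notation {text!r}")
    wild, pos, sub = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return VariantSpec(pos, wild, sub)


def apply_variants(
    reference: PeptideSequence, variants: Iterable[VariantSpec]
) -> PeptideSequence:
    """Apply point substitutions to a reference sequence.

    Positions must be pairwise distinct and each variant's wild residue must
    match the reference at its position.  The returned id records the applied
    variants sorted by position (``refid|V17D+F23R``); an empty variant list
    returns a sequence identical to the reference.
    """
    vs = sorted(variants)
    seen: set[int] = set()
    chars = list(reference.residues)
    for v in vs:
        if v.position in seen:
            raise SequenceError(
                f"duplicate substitution position {v.position} "
                f"applied to {reference.id!r}"
            )
        seen.add(v.position)
        found = reference.residue_at(v.position)
        if found != v.wild:
            raise SequenceError(
                f"wild-residue mismatch at position {v.position} of "
                f"{reference.id!r}: expected {v.wild!r}, found {found!r}"
            )
        chars[v.position - 1] = v.substitute
    if not vs:
        return PeptideSequence(reference.id, reference.residues, reference.description)
    label = "+".join(v.notation for v in vs)
    return PeptideSequence(
        f"{reference.id}|{label}", "".join(chars), reference.description
    )


def variant_label(variants: Sequence[VariantSpec]) -> str:
    """Canonical ``+``-joined label of a variant set, sorted by position."""
    return "+".join(v.notation for v in sorted(variants))
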
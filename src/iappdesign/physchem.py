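"""Sequence-level physicochemical descriptors.

GRAVY (mean Kyte-Doolittle hydropathy), Henderson-Hasselbalch net charge
as a function of pH, isoelectric point by bisection, and the Eisenberg
hydrophobic moment.  The charge model treats cysteines as free thiols and
both termini as ionizable; pKa values default to the EMBOSS set and are
injectable for other conventions.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Mapping

from .scales import (
    ACIDIC_SIDECHAINS,
    BASIC_SIDECHAINS,
    EISENBERG,
    EMBOSS_PKA_CTERM,
    EMBOSS_PKA_NTERM,
    EMBOSS_PKA_SIDECHAINS,
    KYTE_DOOLITTLE,
)
from .sequences import PeptideSequence


@dataclass(frozen=True)
class ChargeModel:
    """pKa values for the termini and the ionizable side chains."""

    pka_nterm: float = EMBOSS_PKA_NTERM
    pka_cterm: float = EMBOSS_PKA_CTERM
    pka_sidechains: Mapping[str, float] = field(
        default_factory=lambda: dict(EMBOSS_PKA_SIDECHAINS)
    )

    def __post_init__(self) -> None:
        for name, v in [("N-terminus", self.pka_nterm), ("C-terminus", self.pka_cterm)]:
            if not 0 < v < 14:
                raise ValueError(f"pKa of {name} outside (0, 14): {v}")
        for aa, v in self.pka_sidechains.items():
            if not 0 < v < 14:
                raise ValueError(f"pKa of side chain {aa!r} outside (0, 14): {v}")
            if aa not in BASIC_SIDECHAINS | ACIDIC_SIDECHAINS:
                raise ValueError(f"residue {aa!r} is not an ionizable side chain")


def gravy(seq: PeptideSequence) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value."""
    return sum(KYTE_DOOLITTLE[c] for c in seq.residues) / len(seq)


def net_charge(
    seq: PeptideSequence, ph: float, model: ChargeModel | None = None
) -> float:
    """Net charge at a given pH, in elementary-charge units.

    Henderson-Hasselbalch sum over basic groups (N-terminal amine, K, R, H)
    minus acidic groups (C-terminal carboxyl, D, E, C, Y).
    """
    if not 0 <= ph <= 14:
        raise ValueError(f"pH outside [0, 14]: {ph}")
    if model is None:
        model = ChargeModel()

    def basic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def acidic(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    z = basic(model.pka_nterm) + acidic(model.pka_cterm)
    for c in seq.residues:
        pka = model.pka_sidechains.get(c)
        if pka is None:
            continue
        z += basic(pka) if c in BASIC_SIDECHAINS else acidic(pka)
    return z


def isoelectric_point(
    seq: PeptideSequence, model: ChargeModel | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH and changes sign over the
    interval (positive at pH 0, negative at pH 14), so the root exists and
    is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, model) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobic_moment(seq: PeptideSequence, angle_deg: float = 100.0) -> float:
    """Eisenberg hydrophobic moment per residue, muH.

    Magnitude of the vector sum of per-residue Eisenberg hydrophobicities
    placed at successive rotations of ``angle_deg`` (100 for an alpha helix,
    180 for a beta strand), divided by the sequence length.
    """
    delta = math.radians(angle_deg)
    total = sum(
        EISENBERG[c] * cmath.exp(1j * n * delta)
        for n, c in enumerate(seq.residues)
    )
    return abs(total) / len(seq)


@dataclass(frozen=True)
class PhysChemProfile:
    """Bundle of the descriptors for one sequence at a reference pH."""

    sequence_id: str
    length: int
    gravy: float
    charge: float
    ph: float
    pi: float
    hydrophobic_moment: float
    moment_angle_deg: float


def physchem_profile(
    seq: PeptideSequence,
    ph: float = 7.0,
    model: ChargeModel | None = None,
    moment_angle_deg: float = 100.0,
) -> PhysChemProfile:
    return PhysChemProfile(
        sequence_id=seq.id,
        length=len(seq),
        gravy=gravy(seq),
        charge=net_charge(seq, ph, model),
        ph=ph,
        pi=isoelectric_point(seq, model),
        hydrophobic_moment=hydrophobic_moment(seq, moment_angle_deg),
        moment_angle_deg=moment_angle_deg,
    )
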
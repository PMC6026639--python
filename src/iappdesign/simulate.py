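"""Synthetic cross-species sequence panels and packaged reference peptides.

The generator emulates the statistical structure the catalog analysis
assumes: a panel of equal-length homologues of a reference peptide, where
each position independently carries position-specific substitution
probabilities.  It reproduces, in expectation, the substitution-frequency
structure of the packaged 240-species IAPP table -- a hypervariable 17-31
segment, invariant positions (2, 12, 16), and one nonstandard (``X``)
record -- while making no attempt to model phylogenetic covariation
between sites or between sequences.

Sampling is deterministic given (seed, config); the RNG algorithm is
pinned in the config metadata so regenerated fixtures are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import (
    HUMAN_IAPP,
    PANEL_SIZE,
    SequencePanel,
    VariantCatalog,
    load_species_table,
)
from .sequences import PeptideSequence, VariantSpec, apply_variants

RNG_ALGORITHM = "numpy-default-rng(PCG64)"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Position-independent substitution model for panel generation.

    ``substitutions`` maps 1-based position -> ordered list of
    (substitute residue, probability); the residual mass at each position
    stays the reference residue.  Conserved positions simply carry no
    substitution mass.
    """

    reference: PeptideSequence
    n: int
    substitutions: dict[int, tuple[tuple[str, float], ...]] = field(
        default_factory=dict
    )
    rng_algorithm: str = RNG_ALGORITHM

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"panel size must be >= 1, got {self.n}")
        if self.rng_algorithm != RNG_ALGORITHM:
            raise ConfigError(
                f"unsupported RNG algorithm {self.rng_algorithm!r}; "
                f"this version generates with {RNG_ALGORITHM!r}"
            )
        for pos, subs in self.substitutions.items():
            if not 1 <= pos <= len(self.reference):
                raise ConfigError(f"substitution position {pos} outside reference")
            mass = 0.0
            for aa, p in subs:
                if aa == self.reference.residue_at(pos):
                    raise ConfigError(
                        f"position {pos}: substitute equals reference residue"
                    )
                if p < 0:
                    raise ConfigError(f"position {pos}: negative probability")
                mass += p
            if mass > 1.0 + 1e-12:
                raise ConfigError(
                    f"position {pos}: substitution probabilities sum to "
                    f"{mass:.6f} > 1"
                )


def generate_panel(config: SimulationConfig, seed: int) -> SequencePanel:
    """Draw ``config.n`` member sequences, sampling each position independently.

    Deterministic for a fixed (config, seed).
    """
    rng = np.random.default_rng(seed)
    L = len(config.reference)
    ref_chars = list(config.reference.residues)
    # alphabet per position: reference residue first, then substitutes
    columns: list[np.ndarray] = []
    for pos in range(1, L + 1):
        subs = config.substitutions.get(pos, ())
        residual = 1.0 - sum(p for _, p in subs)
        letters = [ref_chars[pos - 1]] + [aa for aa, _ in subs]
        probs = np.array([residual] + [p for _, p in subs])
        probs = probs / probs.sum()
        draws = rng.choice(len(letters), size=config.n, p=probs)
        columns.append(np.array(letters, dtype=object)[draws])
    members = []
    for i in range(config.n):
        residues = "".join(col[i] for col in columns)
        members.append(
            PeptideSequence(
                f"{config.reference.id}_sim{i + 1:04d}",
                residues,
            )
            if set(residues) <= set("ACDEFGHIKLMNPQRSTVWY")
            else _nonstandard_member(f"{config.reference.id}_sim{i + 1:04d}", residues)
        )
    return SequencePanel(
        reference=config.reference,
        members=tuple(members),
        provenance=f"synthetic panel, seed={seed}, {config.rng_algorithm}",
    )


class _NonstandardPeptide(PeptideSequence):
    """Panel member carrying a nonstandard residue (e.g. X); flagged, not scored."""

    def __post_init__(self) -> None:  # relax the alphabet check to allow X
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")


def _nonstandard_member(seq_id: str, residues: str) -> PeptideSequence:
    return _NonstandardPeptide(seq_id, residues)


def table1_config(
    n: int = PANEL_SIZE, catalog: VariantCatalog | None = None
) -> SimulationConfig:
    """Config whose substitution probabilities mirror the packaged table.

    Each substitute's probability is its occurrence count divided by the
    panel size (240 by default); the nonstandard ``X`` record keeps its
    mass and is sampled as the literal X so occurrence totals can
    reproduce the published 1,640.
    """
    if catalog is None:
        catalog = load_species_table()
    subs: dict[int, tuple[tuple[str, float], ...]] = {}
    merged: dict[int, dict[str, int]] = {}
    for source in (catalog.entries, catalog.nonstandard):
        for pos, d in source.items():
            merged.setdefault(pos, {}).update(d)
    for pos in sorted(merged):
        subs[pos] = tuple(
            (aa, count / PANEL_SIZE) for aa, count in sorted(merged[pos].items())
        )
    return SimulationConfig(reference=catalog.reference, n=n, substitutions=subs)


# -- config (de)serialization ------------------------------------------


def write_config_json(config: SimulationConfig, path: str | Path) -> None:
    payload = {
        "reference": {
            "id": config.reference.id,
            "residues": config.reference.residues,
            "description": config.reference.description,
        },
        "n": config.n,
        "rng_algorithm": config.rng_algorithm,
        "substitutions": {
            str(pos): [[aa, p] for aa, p in subs]
            for pos, subs in sorted(config.substitutions.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_config_json(path: str | Path) -> SimulationConfig:
    payload = json.loads(Path(path).read_text())
    ref = PeptideSequence(
        payload["reference"]["id"],
        payload["reference"]["residues"],
        payload["reference"].get("description", ""),
    )
    subs = {
        int(pos): tuple((aa, float(p)) for aa, p in entries)
        for pos, entries in payload["substitutions"].items()
    }
    return SimulationConfig(
        reference=ref,
        n=int(payload["n"]),
        substitutions=subs,
        rng_algorithm=payload.get("rng_algorithm", RNG_ALGORITHM),
    )


# -- packaged reference peptides ---------------------------------------

#: Human-to-rat substitutions, all within the 18-29 segment.
RAT_SUBSTITUTIONS = ("H18R", "F23L", "A25P", "I26V", "S28P", "S29P")

#: Pramlintide carries the three rat prolines on the human backbone.
PRAMLINTIDE_SUBSTITUTIONS = ("A25P", "S28P", "S29P")


def builtin_sequences() -> dict[str, PeptideSequence]:
    """The reference peptide set used throughout the package.

    hIAPP (37-mer), rat IAPP and pramlintide (derived from hIAPP by their
    defining substitutions), the N-terminal 1-20 fragment, the C-terminal
    23-37 fragment and its F23R variant, and the amyloid-beta 25-35
    aggregative core used as a control.
    """
    from .sequences import parse_variant_notation

    h = PeptideSequence("hIAPP", HUMAN_IAPP, "human islet amyloid polypeptide")
    rat = apply_variants(h, [parse_variant_notation(v) for v in RAT_SUBSTITUTIONS])
    rat = PeptideSequence("rIAPP", rat.residues, "rat islet amyloid polypeptide")
    pram = apply_variants(
        h, [parse_variant_notation(v) for v in PRAMLINTIDE_SUBSTITUTIONS]
    )
    pram = PeptideSequence("pramlintide", pram.residues, "amylin analog")
    return {
        "hIAPP": h,
        "rIAPP": rat,
        "pramlintide": pram,
        "N_native": PeptideSequence(
            "N_native", HUMAN_IAPP[0:20], "hIAPP 1-20, N-terminal native"
        ),
        "C_native": PeptideSequence(
            "C_native", HUMAN_IAPP[22:37], "hIAPP 23-37, C-terminal native"
        ),
        "F23R_fragment": PeptideSequence(
            "F23R_fragment", "R" + HUMAN_IAPP[23:37], "hIAPP 23-37 with F23R"
        ),
        "abeta_core": PeptideSequence(
            "abeta_core", "GSNKGAIIGLM", "amyloid-beta 25-35 aggregative core"
        ),
    }
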
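"""Windowed aggregation-propensity scoring (AGGRESCAN-style).

Each residue gets an intrinsic propensity ``a3v``; a sliding window of
length-dependent size (5 for peptides up to 75 residues) averages these
into the profile ``a4v``; windows overhanging the termini are completed
with the scale's terminal pad value.  The sequence-level score

    Na4vSS = 100 * (mean(a4v) - baseline)

is the windowed sum normalized to 100 residues; more negative means less
aggregation-prone.  Hot spots are maximal runs of at least five consecutive
residues whose a4v exceeds the hot-spot threshold, with prolines excluded
(a proline breaks a run and never belongs to a hot spot) -- candidate
aggregation nuclei in the amyloid sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .scales import PropensityScale
from .sequences import PeptideSequence


@dataclass(frozen=True)
class AggregationProfile:
    """Per-residue propensity profile and summary score of one sequence."""

    sequence_id: str
    residues: str
    a3v: tuple[float, ...]
    a4v: tuple[float, ...]
    hot_spots: tuple[tuple[int, int], ...]
    na4vss: float

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def n_hot_spots(self) -> int:
        return len(self.hot_spots)

    @property
    def hot_spot_residue_count(self) -> int:
        """Total number of residues covered by hot spots."""
        return sum(end - start + 1 for start, end in self.hot_spots)

    def in_hot_spot(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.hot_spots)


def a3v_values(seq: PeptideSequence, scale: PropensityScale) -> list[float]:
    """Intrinsic propensity of every residue, in sequence order."""
    return [scale.value(c, i) for i, c in enumerate(seq.residues, start=1)]


def a4v_profile(seq: PeptideSequence, scale: PropensityScale) -> list[float]:
    """Window-averaged propensity at every position.

    Position ``i`` averages a3v over the window of size ``w`` centered at
    ``i``; the ``w`` positions always include any virtual slots beyond the
    termini, which carry the scale's terminal pad value.
    """
    a3 = a3v_values(seq, scale)
    w = scale.window_size(len(a3))
    half = w // 2
    ext = [scale.terminal_pad] * half + a3 + [scale.terminal_pad] * half
    return [sum(ext[i : i + w]) / w for i in range(len(a3))]


def na4vss(seq: PeptideSequence, scale: PropensityScale) -> float:
    """Normalized windowed propensity score (per 100 residues)."""
    a4 = a4v_profile(seq, scale)
    return 100.0 * (sum(a4) / len(a4) - scale.baseline)


def find_hot_spots(
    residues: str, a4v: Sequence[float], scale: PropensityScale
) -> list[tuple[int, int]]:
    """Maximal proline-free runs of >= 5 positions with a4v above threshold.

    Returns closed 1-based intervals, sorted and disjoint by construction.
    """
    spots: list[tuple[int, int]] = []
    run_start: int | None = None
    for pos, (c, v) in enumerate(zip(residues, a4v), start=1):
        if c != "P" and v > scale.hot_spot_threshold:
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None and pos - run_start >= scale.min_hot_spot_length:
                spots.append((run_start, pos - 1))
            run_start = None
    if run_start is not None and len(residues) - run_start + 1 >= scale.min_hot_spot_length:
        spots.append((run_start, len(residues)))
    return spots


def score_sequence(
    seq: PeptideSequence, scale: PropensityScale | None = None
) -> AggregationProfile:
    """Full propensity characterization: a3v, a4v, hot spots, Na4vSS."""
    if scale is None:
        scale = PropensityScale()
    a3 = a3v_values(seq, scale)
    a4 = a4v_profile(seq, scale)
    spots = find_hot_spots(seq.residues, a4, scale)
    score = 100.0 * (sum(a4) / len(a4) - scale.baseline)
    return AggregationProfile(
        sequence_id=seq.id,
        residues=seq.residues,
        a3v=tuple(a3),
        a4v=tuple(a4),
        hot_spots=tuple(spots),
        na4vss=score,
    )


def write_profile_tsv(profile: AggregationProfile, path: str | Path) -> None:
    """Per-residue profile as TSV: position, residue, a3v, a4v, in_hot_spot."""
    lines = ["position\tresidue\ta3v\ta4v\tin_hot_spot"]
    for i, (c, v3, v4) in enumerate(
        zip(profile.residues, profile.a3v, profile.a4v), start=1
    ):
        flag = "1" if profile.in_hot_spot(i) else "0"
        lines.append(f"{i}\t{c}\t{v3:.6f}\t{v4:.6f}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")
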
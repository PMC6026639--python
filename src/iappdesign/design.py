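"""De-novo sequence design by exhaustive substitution scanning.

Every catalog variant (or combination of ``k`` variants at pairwise
distinct positions) is substituted into the reference, each candidate is
scored with the windowed propensity engine and GRAVY, classified against
the reference score, and flagged for hot-spot deletion.  Ranking is by
ascending Na4vSS (most aggregation-suppressing first); ties break by first
variant position, then substitute letter, making reports byte-reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .aggrescan import AggregationProfile, score_sequence
from .catalog import VariantCatalog
from .physchem import gravy
from .scales import PropensityScale, display_gravy, display_na4vss
from .sequences import PeptideSequence, VariantSpec, apply_variants, variant_label

#: Refuse multi-scans that would enumerate more combinations than this.
DEFAULT_COMBINATION_BUDGET = 2_000_000


class DesignError(ValueError):
    """Invalid scan request or undefined summary."""


@dataclass(frozen=True)
class ScanRecord:
    """One scored candidate sequence of a scan."""

    variants: tuple[VariantSpec, ...]
    sequence: PeptideSequence
    na4vss: float
    gravy: float
    delta_na4vss: float
    n_hot_spots: int
    hot_spot_residue_count: int
    hotspot_deleted: bool

    @property
    def label(self) -> str:
        return variant_label(self.variants)

    @property
    def classification(self) -> str:
        """"lower" iff strictly below the reference score (full precision)."""
        return "lower" if self.delta_na4vss < 0 else "higher"


@dataclass(frozen=True)
class ScanTable:
    """Ranked scan results plus the reference characterization."""

    reference: PeptideSequence
    reference_profile: AggregationProfile
    reference_gravy: float
    records: tuple[ScanRecord, ...]
    k: int

    def __len__(self) -> int:
        return len(self.records)


def _sort_key(rec: ScanRecord):
    first = rec.variants[0] if rec.variants else None
    return (
        rec.na4vss,
        first.position if first else 0,
        first.substitute if first else "",
        rec.label,
    )


def _build_records(
    reference: PeptideSequence,
    ref_profile: AggregationProfile,
    ref_gravy: float,
    combos: Iterable[tuple[VariantSpec, ...]],
    scale: PropensityScale,
) -> list[ScanRecord]:
    records = []
    for combo in combos:
        seq = apply_variants(reference, combo)
        prof = score_sequence(seq, scale)
        records.append(
            ScanRecord(
                variants=tuple(sorted(combo)),
                sequence=seq,
                na4vss=prof.na4vss,
                gravy=gravy(seq),
                delta_na4vss=prof.na4vss - ref_profile.na4vss,
                n_hot_spots=prof.n_hot_spots,
                hot_spot_residue_count=prof.hot_spot_residue_count,
                hotspot_deleted=prof.hot_spot_residue_count
                < ref_profile.hot_spot_residue_count,
            )
        )
    records.sort(key=_sort_key)
    return records


def single_scan(
    reference: PeptideSequence,
    catalog: VariantCatalog,
    scale: PropensityScale | None = None,
) -> ScanTable:
    """Score every scorable catalog variant substituted into the reference.

    Nonstandard-residue records (e.g. ``X``) are skipped with a warning;
    they have no propensity value.
    """
    if scale is None:
        scale = PropensityScale()
    if catalog.reference.residues != reference.residues:
        raise DesignError(
            f"catalog reference {catalog.reference.id!r} does not match "
            f"scan reference {reference.id!r}"
        )
    n_skipped = sum(len(s) for s in catalog.nonstandard.values())
    if n_skipped:
        warnings.warn(
            f"skipping {n_skipped} nonstandard-residue variant(s) with no "
            "propensity value",
            stacklevel=2,
        )
    ref_profile = score_sequence(reference, scale)
    ref_gravy = gravy(reference)
    records = _build_records(
        reference,
        ref_profile,
        ref_gravy,
        ((v,) for v in catalog.scorable_variants()),
        scale,
    )
    return ScanTable(reference, ref_profile, ref_gravy, tuple(records), k=1)


def multi_scan(
    reference: PeptideSequence,
    catalog: VariantCatalog,
    k: int,
    candidate_pool: Sequence[VariantSpec] | None = None,
    scale: PropensityScale | None = None,
    combination_budget: int = DEFAULT_COMBINATION_BUDGET,
) -> ScanTable:
    """Score every ``k``-combination of pool variants at distinct positions.

    The pool defaults to all scorable catalog variants.  Combinations whose
    members share a position are excluded (a position can only be
    substituted once).  Enumeration is exhaustive; a request whose
    combination count exceeds ``combination_budget`` raises
    :class:`DesignError` rather than truncating silently.
    """
    if scale is None:
        scale = PropensityScale()
    if k < 2:
        raise DesignError(f"multi_scan requires k >= 2, got {k}")
    if catalog.reference.residues != reference.residues:
        raise DesignError(
            f"catalog reference {catalog.reference.id!r} does not match "
            f"scan reference {reference.id!r}"
        )
    pool = list(candidate_pool) if candidate_pool is not None else catalog.scorable_variants()
    n_positions = len({v.position for v in pool})
    if k > n_positions:
        raise DesignError(
            f"k={k} exceeds the {n_positions} distinct variant positions in the pool"
        )
    import math

    if math.comb(len(pool), k) > combination_budget:
        raise DesignError(
            f"{math.comb(len(pool), k)} combinations exceed the budget of "
            f"{combination_budget}; restrict the candidate pool"
        )
    combos = (
        combo
        for combo in itertools.combinations(pool, k)
        if len({v.position for v in combo}) == k
    )
    ref_profile = score_sequence(reference, scale)
    ref_gravy = gravy(reference)
    records = _build_records(reference, ref_profile, ref_gravy, combos, scale)
    return ScanTable(reference, ref_profile, ref_gravy, tuple(records), k=k)


def classify_vs_reference(table: ScanTable, threshold: float) -> tuple[int, int]:
    """Count and integer percentage of records strictly below ``threshold``.

    Comparison is strict (<) on full-precision scores; the percentage is
    rounded half-up to the nearest integer.
    """
    if not table.records:
        raise DesignError("classification undefined for an empty scan table")
    n_lower = sum(1 for r in table.records if r.na4vss < threshold)
    from .scales import round_half_up

    pct = int(round_half_up(100.0 * n_lower / len(table.records), 0))
    return n_lower, pct


def hotspot_deletion_flags(
    table: ScanTable, reference_profile: AggregationProfile
) -> list[bool]:
    """Per-record flag: strictly fewer hot-spot residues than the reference.

    Records already carry this flag relative to the table's own reference;
    this recomputes it against an explicit profile (e.g. a different
    reference characterization).
    """
    ref_cover = reference_profile.hot_spot_residue_count
    return [rec.hot_spot_residue_count < ref_cover for rec in table.records]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Raises :class:`DesignError` for unequal lengths, fewer than 3 pairs, or
    a constant vector (where the coefficient is undefined).
    """
    if len(x) != len(y):
        raise DesignError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise DesignError("Pearson correlation needs at least 3 pairs")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise DesignError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def scan_correlation(table: ScanTable) -> float:
    """Pearson correlation of (Na4vSS, GRAVY) across the scan records."""
    return pearson(
        [r.na4vss for r in table.records], [r.gravy for r in table.records]
    )


def write_scan_tsv(
    table: ScanTable,
    path: str | Path,
    annotations: dict[str, dict[str, str]] | None = None,
) -> None:
    """Ranked scan report as TSV.

    Columns: rank, variants, sequence, na4vss, delta_na4vss, gravy,
    n_hot_spots, hotspot_deleted, class; optional annotation columns are
    merged by variant label, with ``.`` for missing cells.  Na4vSS and
    GRAVY cells use the documented display roundings; delta is full
    precision.
    """
    ann_cols: list[str] = []
    if annotations:
        seen: list[str] = []
        for row in annotations.values():
            for c in row:
                if c not in seen:
                    seen.append(c)
        ann_cols = seen
    header = [
        "rank",
        "variants",
        "sequence",
        "na4vss",
        "delta_na4vss",
        "gravy",
        "n_hot_spots",
        "hotspot_deleted",
        "class",
        *ann_cols,
    ]
    lines = ["\t".join(header)]
    for rank, rec in enumerate(table.records, start=1):
        row = [
            str(rank),
            rec.label or ".",
            rec.sequence.residues,
            f"{display_na4vss(rec.na4vss):.1f}",
            f"{rec.delta_na4vss:.6f}",
            f"{display_gravy(rec.gravy):.2f}",
            str(rec.n_hot_spots),
            "1" if rec.hotspot_deleted else "0",
            rec.classification,
        ]
        ann = (annotations or {}).get(rec.label, {})
        row.extend(ann.get(c, ".") for c in ann_cols)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """Annotation table keyed by variant label (e.g. pasta, organisms)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    cols = lines[0].split("\t")
    if cols[0] != "variant":
        raise DesignError(f"{path}: first column must be 'variant'")
    out: dict[str, dict[str, str]] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        out[cells[0]] = dict(zip(cols[1:], cells[1:]))
    return out
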
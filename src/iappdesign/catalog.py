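"""Per-position variant catalogs and their summary statistics.

A :class:`VariantCatalog` records, for every position of a reference
peptide, the substitute residues observed across a panel of homologous
sequences together with occurrence counts -- the data model behind a
cross-species substitution table.  Nonstandard residues (``X``) occurring
in panels are kept in a separate bucket: they contribute to occurrence
totals but are never scored.

Two catalog sources are supported: computing one from an aligned,
gap-free, equal-length sequence panel, and loading the packaged
cross-species substitution table for human IAPP (240 species).  The
packaged table records per-position substitute lists and per-position
occurrence totals; per-substitute counts within a position are apportioned
uniformly (largest shares to the earliest listed substitutes), which
preserves every position-level sum exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .sequences import STANDARD_RESIDUES, PeptideSequence, VariantSpec

#: Human IAPP (amylin), 37 residues.
HUMAN_IAPP = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

#: Panel size behind the packaged substitution table.
PANEL_SIZE = 240


class CatalogError(ValueError):
    """Inconsistent catalog data or panel input."""


@dataclass(frozen=True)
class SequencePanel:
    """An aligned, gap-free panel of equal-length sequences plus reference."""

    reference: PeptideSequence
    members: tuple[PeptideSequence, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        for m in self.members:
            if len(m) != len(self.reference):
                raise CatalogError(
                    f"panel member {m.id!r} has length {len(m)}, "
                    f"reference {self.reference.id!r} has {len(self.reference)}"
                )


@dataclass
class VariantCatalog:
    """Observed substitutions per position with occurrence counts.

    ``entries`` maps 1-based position -> {substitute residue: count}.
    Substitutes equal to the reference residue are forbidden; counts are
    positive.  ``nonstandard`` holds the same structure for non-standard
    residue records (e.g. ``X``), which count toward occurrence totals but
    are excluded from scoring and scanning.
    """

    reference: PeptideSequence
    entries: dict[int, dict[str, int]] = field(default_factory=dict)
    nonstandard: dict[int, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, subs in self.entries.items():
            ref = self.reference.residue_at(pos)
            for aa, count in subs.items():
                if aa == ref:
                    raise CatalogError(
                        f"position {pos}: substitute equals reference residue {ref!r}"
                    )
                if aa not in STANDARD_RESIDUES:
                    raise CatalogError(
                        f"position {pos}: nonstandard substitute {aa!r} in "
                        "standard entries"
                    )
                if count < 1:
                    raise CatalogError(
                        f"position {pos}: non-positive count for {aa!r}"
                    )

    # -- totals ---------------------------------------------------------

    def distinct_variants(self, include_nonstandard: bool = True) -> int:
        n = sum(len(s) for s in self.entries.values())
        if include_nonstandard:
            n += sum(len(s) for s in self.nonstandard.values())
        return n

    def total_occurrences(self, include_nonstandard: bool = True) -> int:
        n = sum(sum(s.values()) for s in self.entries.values())
        if include_nonstandard:
            n += sum(sum(s.values()) for s in self.nonstandard.values())
        return n

    def scorable_variants(self) -> list[VariantSpec]:
        """All standard-residue variants, sorted by position then substitute."""
        out: list[VariantSpec] = []
        for pos in sorted(self.entries):
            ref = self.reference.residue_at(pos)
            for aa in sorted(self.entries[pos]):
                out.append(VariantSpec(pos, ref, aa))
        return out


def catalog_totals(catalog: VariantCatalog) -> tuple[int, int]:
    """(number of distinct variants, total occurrence count)."""
    return catalog.distinct_variants(), catalog.total_occurrences()


def conserved_positions(catalog: VariantCatalog) -> list[int]:
    """Positions with no observed substitution, ascending."""
    occupied = {
        p
        for p, s in list(catalog.entries.items()) + list(catalog.nonstandard.items())
        if s
    }
    return [p for p in range(1, len(catalog.reference) + 1) if p not in occupied]


def region_concentration(
    catalog: VariantCatalog, start: int, end: int
) -> tuple[int, float]:
    """Occurrences within the closed interval [start, end] and their fraction.

    Raises :class:`CatalogError` for an empty catalog, where the fraction
    is undefined.
    """
    if not 1 <= start <= end <= len(catalog.reference):
        raise CatalogError(
            f"region {start}..{end} outside 1..{len(catalog.reference)}"
        )
    total = catalog.total_occurrences()
    if total == 0:
        raise CatalogError("region fraction undefined for an empty catalog")
    in_region = 0
    for source in (catalog.entries, catalog.nonstandard):
        for pos, subs in source.items():
            if start <= pos <= end:
                in_region += sum(subs.values())
    return in_region, in_region / total


def catalog_from_panel(panel: SequencePanel) -> VariantCatalog:
    """Tally every member residue that differs from the reference.

    The count of a (position, substitute) entry is the number of panel
    members carrying that residue there.  Invariant to member order.
    """
    ref = panel.reference
    entries: dict[int, dict[str, int]] = {}
    nonstandard: dict[int, dict[str, int]] = {}
    counters = [Counter() for _ in range(len(ref))]
    for m in panel.members:
        for i, c in enumerate(m.residues):
            if c != ref.residues[i]:
                counters[i][c] += 1
    for i, counter in enumerate(counters):
        pos = i + 1
        for aa, count in counter.items():
            bucket = entries if aa in STANDARD_RESIDUES else nonstandard
            bucket.setdefault(pos, {})[aa] = count
    return VariantCatalog(reference=ref, entries=entries, nonstandard=nonstandard)


# -- flat TSV interchange (one row per (position, substitute)) ----------


def write_catalog_tsv(catalog: VariantCatalog, path: str | Path) -> None:
    lines = ["position\tref_residue\tsubstitute\tcount"]
    merged: dict[int, dict[str, int]] = {}
    for source in (catalog.entries, catalog.nonstandard):
        for pos, subs in source.items():
            merged.setdefault(pos, {}).update(subs)
    for pos in sorted(merged):
        ref = catalog.reference.residue_at(pos)
        for aa in sorted(merged[pos]):
            lines.append(f"{pos}\t{ref}\t{aa}\t{merged[pos][aa]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_catalog_tsv(path: str | Path, reference: PeptideSequence) -> VariantCatalog:
    text = Path(path).read_text().rstrip("\n")
    lines = text.split("\n")
    header = "position\tref_residue\tsubstitute\tcount"
    if not lines or lines[0] != header:
        raise CatalogError(f"{path}: expected header {header!r}")
    entries: dict[int, dict[str, int]] = {}
    nonstandard: dict[int, dict[str, int]] = {}
    for ln in lines[1:]:
        pos_s, ref_aa, sub, count_s = ln.split("\t")
        pos, count = int(pos_s), int(count_s)
        if reference.residue_at(pos) != ref_aa:
            raise CatalogError(
                f"{path}: row at position {pos} states reference {ref_aa!r}, "
                f"sequence has {reference.residue_at(pos)!r}"
            )
        bucket = entries if sub in STANDARD_RESIDUES else nonstandard
        bucket.setdefault(pos, {})[sub] = count
    return VariantCatalog(reference=reference, entries=entries, nonstandard=nonstandard)


# -- the packaged cross-species substitution table ----------------------


def _apportion(total: int, k: int) -> list[int]:
    """Split ``total`` into ``k`` positive parts, largest first, sum-exact."""
    base, rem = divmod(total, k)
    return [base + 1 if i < rem else base for i in range(k)]


def load_species_table(
    path: str | Path | None = None,
) -> VariantCatalog:
    """Load the packaged per-position substitution table for human IAPP.

    The table stores, per position, the ordered substitute list and the
    total number of panel sequences carrying any substitution there; the
    per-substitute counts are apportioned uniformly across the listed
    substitutes (earliest listed get the remainder), keeping all
    position-level totals exact.  Rows are validated: the stated variant
    count must equal the number of substitute cells.
    """
    if path is None:
        source = resources.files("iappdesign.data").joinpath("variant_table.tsv")
        text = source.read_text()
        name = "variant_table.tsv"
    else:
        text = Path(path).read_text()
        name = str(path)
    lines = text.rstrip("\n").split("\n")
    header = "position\tref_residue\tsubstitutes\tn_variants\ttotal_count"
    if lines[0] != header:
        raise CatalogError(f"{name}: expected header {header!r}")
    reference_chars: dict[int, str] = {}
    rows: list[tuple[int, str, list[str], int]] = []
    for ln in lines[1:]:
        pos_s, ref_aa, subs_s, n_s, total_s = ln.split("\t")
        pos, n, total = int(pos_s), int(n_s), int(total_s)
        subs = [] if subs_s == "." else subs_s.split(",")
        if len(subs) != n:
            raise CatalogError(
                f"{name}: position {pos} states {n} variants but lists "
                f"{len(subs)} substitutes"
            )
        if (n == 0) != (total == 0):
            raise CatalogError(
                f"{name}: position {pos} has inconsistent zero counts"
            )
        reference_chars[pos] = ref_aa
        rows.append((pos, ref_aa, subs, total))
    residues = "".join(reference_chars[p] for p in sorted(reference_chars))
    reference = PeptideSequence("hIAPP", residues, "human islet amyloid polypeptide")
    entries: dict[int, dict[str, int]] = {}
    nonstandard: dict[int, dict[str, int]] = {}
    for pos, _ref_aa, subs, total in rows:
        if not subs:
            continue
        for aa, count in zip(subs, _apportion(total, len(subs))):
            bucket = entries if aa in STANDARD_RESIDUES else nonstandard
            bucket.setdefault(pos, {})[aa] = count
    return VariantCatalog(reference=reference, entries=entries, nonstandard=nonstandard)


def position_totals(catalog: VariantCatalog) -> Mapping[int, int]:
    """Occurrence total per position (standard + nonstandard records)."""
    totals: dict[int, int] = {}
    for source in (catalog.entries, catalog.nonstandard):
        for pos, subs in source.items():
            totals[pos] = totals.get(pos, 0) + sum(subs.values())
    return totals
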
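"""Readers and writers for the tabular formats the pipeline touches.

Every table is tab-separated UTF-8 with a header row, matching the way
TargetScan distributes its family-info and predicted-target files.  Two
target-table dialects are accepted and distinguished by header sniffing:

* the TargetScan "Predicted Targets" summary dialect (``Gene Symbol``,
  ``miRNA family``, ``Species ID``, ``Total num conserved sites``, ...);
* a simplified three-column dialect (``gene``, ``family``, ``count``)
  used by the synthetic generator and the test fixtures.

Identifiers are treated case-sensitively (TargetScan gene symbols are
case-significant) but surrounding whitespace is stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

RPM_TOTAL = 1_000_000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MirnaExpressionProfile:
    """Per-miRNA expression (reads per million) at two timepoints.

    ``timepoint_labels`` orders the timepoints as (earlier, later);
    ``values`` maps each miRNA id to its ``(rpm_early, rpm_late)`` pair.
    A profile is *complete* when it covers a whole library, in which case
    each timepoint's RPM values sum to one million (within 0.1%).
    """

    timepoint_labels: tuple[str, str]
    values: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for mirna, (early, late) in self.values.items():
            if early < 0 or late < 0:
                raise ValidationError(f"negative RPM for {mirna!r}")

    def __len__(self) -> int:
        return len(self.values)

    def mirnas(self) -> list[str]:
        return list(self.values)

    def totals(self) -> tuple[float, float]:
        early = sum(v[0] for v in self.values.values())
        late = sum(v[1] for v in self.values.values())
        return early, late

    def is_complete(self, rel_tol: float = 1e-3) -> bool:
        return all(abs(t - RPM_TOTAL) <= rel_tol * RPM_TOTAL for t in self.totals())


@dataclass(frozen=True)
class MirnaFamilyAnnotation:
    """Mapping from miRNAs to their conserved seed family.

    miRNAs without a conserved family are simply absent from
    ``member_map``.  ``universe`` is the set of all conserved family ids
    and may be a strict superset of the families seen in ``member_map``
    (the permutation null samples from the universe).
    """

    member_map: dict[str, str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        missing = set(self.member_map.values()) - self.universe
        if missing:
            raise ValidationError(
                f"families in member_map but not in universe: {sorted(missing)}"
            )

    def family_of(self, mirna: str) -> str | None:
        return self.member_map.get(mirna)


@dataclass(frozen=True)
class TargetIncidenceTable:
    """Gene x miRNA-family conserved 3'UTR site counts.

    Absence of a (gene, family) pair encodes zero sites; stored counts
    are always >= 1.
    """

    sites: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for gene, fams in self.sites.items():
            if not gene:
                raise ValidationError("empty gene id")
            for fam, count in fams.items():
                if not fam:
                    raise ValidationError(f"empty family id for gene {gene!r}")
                if count < 1:
                    raise ValidationError(
                        f"non-positive site count for ({gene!r}, {fam!r}): {count}"
                    )

    def genes(self) -> list[str]:
        return list(self.sites)

    def families_of(self, gene: str) -> frozenset[str]:
        return frozenset(self.sites.get(gene, {}))

    def site_count(self, gene: str, family: str) -> int:
        return self.sites.get(gene, {}).get(family, 0)


@dataclass(frozen=True)
class GeneExpressionTable:
    """Gene-level expression (FPKM) used only as an inclusion gate."""

    fpkm: dict[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.fpkm.items():
            if value < 0:
                raise ValidationError(f"negative FPKM for {gene!r}: {value}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.fpkm

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.fpkm.get(gene, default)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def _strip(value: str) -> str:
    return str(value).strip()


def _find_column(columns: Sequence[str], *needles: str) -> str | None:
    """Return the first column whose name contains any needle (case-folded)."""
    for needle in needles:
        for col in columns:
            if needle in col.casefold():
                return col
    return None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_mirna_expression(
    path: str | Path, timepoint_labels: tuple[str, str]
) -> MirnaExpressionProfile:
    """Read a miRNA RPM table.

    The first column carries miRNA ids; one column per entry of
    ``timepoint_labels`` carries the RPM values.  Extra columns are
    ignored.  Duplicate ids and negative RPMs are rejected.
    """
    frame = _read_tsv(path)
    for label in timepoint_labels:
        if label not in frame.columns:
            raise FormatError(f"{path}: missing RPM column {label!r}")
    id_col = frame.columns[0]
    values: dict[str, tuple[float, float]] = {}
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        mirna = _strip(record[id_col])
        if not mirna:
            raise ValidationError(f"{path}: empty miRNA id at row {row_number}")
        if mirna in values:
            raise ValidationError(f"{path}: duplicate miRNA id {mirna!r}")
        try:
            rpms = tuple(float(record[label]) for label in timepoint_labels)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-numeric RPM at row {row_number}"
            ) from exc
        if any(r < 0 for r in rpms):
            raise ValidationError(
                f"{path}: negative RPM for {mirna!r} at row {row_number}"
            )
        values[mirna] = rpms  # type: ignore[assignment]
    return MirnaExpressionProfile(tuple(timepoint_labels), values)


def read_family_annotation(
    path: str | Path, extra_universe: Iterable[str] = ()
) -> MirnaFamilyAnnotation:
    """Read a miRNA-family table in the TargetScan family-info dialect.

    Requires one column naming the family and one naming the miRNA
    (matched by substring: "family"; "mirbase"/"mirna"/"mir").  A miRNA
    assigned to two different families is rejected.  ``extra_universe``
    adds conserved families with no member in this file.
    """
    frame = _read_tsv(path)
    fam_col = _find_column(frame.columns, "family")
    if fam_col is None:
        raise FormatError(f"{path}: no family column found")
    others = [c for c in frame.columns if c != fam_col]
    mir_col = _find_column(others, "mirbase", "mirna", "mir")
    if mir_col is None:
        raise FormatError(f"{path}: no miRNA id column found")

    member_map: dict[str, str] = {}
    universe: set[str] = set(map(_strip, extra_universe))
    for _, row in frame.iterrows():
        mirna = _strip(row[mir_col])
        family = _strip(row[fam_col])
        if not family:
            continue
        universe.add(family)
        if not mirna:
            continue  # family listed without a member: universe-only
        if mirna in member_map and member_map[mirna] != family:
            raise ValidationError(
                f"{path}: {mirna!r} assigned to two families "
                f"({member_map[mirna]!r}, {family!r})"
            )
        member_map[mirna] = family
    return MirnaFamilyAnnotation(member_map, frozenset(universe))


_SIMPLE_TARGET_COLUMNS = ("gene", "family", "count")


def read_target_table(
    path: str | Path,
    conserved_only: bool = True,
    species_id: str | None = None,
) -> TargetIncidenceTable:
    """Read predicted 3'UTR target sites, aggregated to (gene, family) counts.

    Dialect is sniffed from the header: the simplified dialect has
    exactly the columns ``gene``/``family``/``count`` (any order); the
    TargetScan summary dialect has ``Gene Symbol`` and ``miRNA family``
    columns plus conserved / non-conserved site-count columns.  With
    ``conserved_only`` only conserved sites are counted.  Counts for the
    same (gene, family) on several rows are summed.
    """
    frame = _read_tsv(path)
    lowered = {c.casefold(): c for c in frame.columns}
    sites: dict[str, dict[str, int]] = {}

    def add(gene: str, family: str, count: int, row_number: int) -> None:
        if count <= 0:
            raise ValidationError(
                f"{path}: non-positive site count at row {row_number}"
            )
        sites.setdefault(gene, {})
        sites[gene][family] = sites[gene].get(family, 0) + count

    if all(c in lowered for c in _SIMPLE_TARGET_COLUMNS):
        gcol, fcol, ccol = (lowered[c] for c in _SIMPLE_TARGET_COLUMNS)
        for row_number, (_, row) in enumerate(frame.iterrows(), start=2):
            gene, family = _strip(row[gcol]), _strip(row[fcol])
            if not gene or not family:
                raise ValidationError(f"{path}: empty id at row {row_number}")
            try:
                count = int(row[ccol])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-integer count at row {row_number}"
                ) from exc
            add(gene, family, count, row_number)
        return TargetIncidenceTable(sites)

    gene_col = _find_column(frame.columns, "gene symbol")
    fam_col = _find_column(frame.columns, "mirna family", "family")
    if gene_col is None or fam_col is None:
        raise FormatError(
            f"{path}: unrecognized target-table dialect "
            f"(need gene/family/count or TargetScan summary columns)"
        )
    cons_col = _find_column(frame.columns, "total num conserved sites")
    noncons_col = _find_column(frame.columns, "total num nonconserved sites")
    if cons_col is None:
        raise FormatError(f"{path}: missing column 'Total num conserved sites'")
    species_col = _find_column(frame.columns, "species id")

    for row_number, (_, row) in enumerate(frame.iterrows(), start=2):
        if species_id is not None and species_col is not None:
            if _strip(row[species_col]) != species_id:
                continue
        gene, family = _strip(row[gene_col]), _strip(row[fam_col])
        if not gene or not family:
            raise ValidationError(f"{path}: empty id at row {row_number}")
        count = int(float(row[cons_col]))
        if not conserved_only and noncons_col is not None:
            count += int(float(row[noncons_col]))
        if count > 0:
            add(gene, family, count, row_number)
    return TargetIncidenceTable(sites)


def read_gene_fpkm(path: str | Path) -> GeneExpressionTable:
    """Read a two-column gene/FPKM table; duplicates and negatives rejected."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected at least gene and FPKM columns")
    gene_col, fpkm_col = frame.columns[0], frame.columns[1]
    fpkm: dict[str, float] = {}
    for row_number, (_, row) in enumerate(frame.iterrows(), start=2):
        gene = _strip(row[gene_col])
        if not gene:
            raise ValidationError(f"{path}: empty gene id at row {row_number}")
        if gene in fpkm:
            raise ValidationError(f"{path}: duplicate gene id {gene!r}")
        try:
            value = float(row[fpkm_col])
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-numeric FPKM at row {row_number}"
            ) from exc
        if value < 0:
            raise ValidationError(f"{path}: negative FPKM for {gene!r}")
        fpkm[gene] = value
    return GeneExpressionTable(fpkm)


# ---------------------------------------------------------------------------
# writers (deterministic column and row order; round-trip with the readers)
# ---------------------------------------------------------------------------

def write_mirna_expression(profile: MirnaExpressionProfile, path: str | Path) -> None:
    early_label, late_label = profile.timepoint_labels
    frame = pd.DataFrame(
        {
            "mirna": list(profile.values),
            early_label: [v[0] for v in profile.values.values()],
            late_label: [v[1] for v in profile.values.values()],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_family_annotation(annotation: MirnaFamilyAnnotation, path: str | Path) -> None:
    rows = sorted(annotation.member_map.items())
    frame = pd.DataFrame(
        {"mirna": [m for m, _ in rows], "family": [f for _, f in rows]}
    )
    frame.to_csv(path, sep="\t", index=False)
    orphans = sorted(annotation.universe - set(annotation.member_map.values()))
    if orphans:
        # Universe-only families have no natural row; record them with an
        # empty member so the reader's extra_universe is not needed.
        with open(path, "a", encoding="utf-8") as handle:
            for fam in orphans:
                handle.write(f"\t{fam}\n")


def write_target_table(table: TargetIncidenceTable, path: str | Path) -> None:
    rows = [
        (gene, family, count)
        for gene in sorted(table.sites)
        for family, count in sorted(table.sites[gene].items())
    ]
    frame = pd.DataFrame(rows, columns=["gene", "family", "count"])
    frame.to_csv(path, sep="\t", index=False)


def write_gene_fpkm(table: GeneExpressionTable, path: str | Path) -> None:
    rows = sorted(table.fpkm.items())
    frame = pd.DataFrame({"gene": [g for g, _ in rows], "fpkm": [v for _, v in rows]})
    frame.to_csv(path, sep="\t", index=False)


def write_shift_results(results, path: str | Path) -> None:
    """Write targeting-shift results (gene, delta, p_value, rank, iterations).

    Rows are ordered by rank then gene id so output is deterministic.
    """
    ordered = sorted(
        results, key=lambda r: (r.rank if r.rank is not None else 0, r.gene_id)
    )
    frame = pd.DataFrame(
        {
            "gene": [r.gene_id for r in ordered],
            "delta": [r.delta for r in ordered],
            "p_value": [repr(r.p_value) for r in ordered],
            "rank": [r.rank if r.rank is not None else "" for r in ordered],
            "iterations": [r.iterations_used for r in ordered],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_shift_results(path: str | Path):
    """Read back a shift-result table written by :func:`write_shift_results`."""
    from .targeting import TargetingShiftResult

    frame = _read_tsv(path)
    for col in ("gene", "delta", "p_value", "rank", "iterations"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    results = []
    for _, row in frame.iterrows():
        rank = _strip(row["rank"])
        results.append(
            TargetingShiftResult(
                gene_id=_strip(row["gene"]),
                delta=int(row["delta"]),
                p_value=float(row["p_value"]),
                iterations_used=int(row["iterations"]),
                rank=int(rank) if rank else None,
            )
        )
    return results


def write_counts(counts: Mapping[str, int | float], path: str | Path,
                 value_name: str = "count") -> None:
    rows = sorted(counts.items())
    frame = pd.DataFrame({"mirna": [m for m, _ in rows],
                          value_name: [v for _, v in rows]})
    frame.to_csv(path, sep="\t", index=False)
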
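"""Differential-miRNA gating between two timepoints.

A miRNA is called differentially expressed when it clears an absolute
expression gate (by default: at least 100 RPM at either timepoint) and
an at-least-two-fold change between the timepoints.  Fold changes use
the signed convention common in expression tables: late/early for
increases, -(early/late) for decreases, so the magnitude is always
>= 1 and the sign encodes direction.

Calls can then be restricted to miRNAs belonging to conserved seed
families and annotated with conserved 3'UTR site counts for genes of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .errors import ConfigError, ContractError, ZeroExpressionError
from .io_formats import (
    MirnaExpressionProfile,
    MirnaFamilyAnnotation,
    TargetIncidenceTable,
)

_GATE_MODES = ("either_timepoint", "early", "late", "both")


@dataclass(frozen=True)
class DiffExpConfig:
    min_rpm: float = 100.0
    min_fold: float = 2.0
    gate_mode: str = "either_timepoint"
    pseudocount: float = 0.0  # added to both RPMs before fold computation

    def __post_init__(self) -> None:
        if self.min_rpm <= 0:
            raise ConfigError("min_rpm must be > 0")
        if self.min_fold < 1:
            raise ConfigError("min_fold must be >= 1")
        if self.gate_mode not in _GATE_MODES:
            raise ConfigError(f"unknown gate_mode {self.gate_mode!r}")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")


@dataclass(frozen=True)
class DifferentialMirnaRecord:
    """One differential call: RPMs, signed fold, direction, annotations."""

    mirna_id: str
    rpm_early: float
    rpm_late: float
    signed_fold: float
    direction: str  # "up" | "down"
    family_id: str | None = None
    gene_site_counts: dict[str, int] | None = None


def signed_fold_change(
    rpm_early: float, rpm_late: float, pseudocount: float = 0.0
) -> float:
    """Signed fold change with magnitude >= 1.

    Returns late/early when expression rises (or is unchanged), else
    the negated reciprocal -(early/late).  A zero RPM (after the
    optional pseudocount) is an error rather than an infinite fold.
    """
    early = rpm_early + pseudocount
    late = rpm_late + pseudocount
    if early <= 0 or late <= 0:
        raise ZeroExpressionError(
            f"zero expression (early={rpm_early}, late={rpm_late}); "
            "pre-filter or supply a pseudocount"
        )
    return late / early if late >= early else -(early / late)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Presentation-layer rounding: half-up on the magnitude.

    Used only when printing folds/percentages; all computation keeps
    full precision.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    sign = -1.0 if value < 0 else 1.0
    magnitude = Decimal(repr(abs(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return sign * float(magnitude)


def _passes_expression_gate(
    rpm_early: float, rpm_late: float, config: DiffExpConfig
) -> bool:
    if config.gate_mode == "either_timepoint":
        return max(rpm_early, rpm_late) >= config.min_rpm
    if config.gate_mode == "early":
        return rpm_early >= config.min_rpm
    if config.gate_mode == "late":
        return rpm_late >= config.min_rpm
    return min(rpm_early, rpm_late) >= config.min_rpm  # "both"


def classify_differential(
    profile: MirnaExpressionProfile, config: DiffExpConfig = DiffExpConfig()
) -> list[DifferentialMirnaRecord]:
    """Emit a record for every miRNA passing the expression and fold gates.

    Output order follows the profile's input order; the emitted set is
    invariant to that order.
    """
    records: list[DifferentialMirnaRecord] = []
    for mirna, (rpm_early, rpm_late) in profile.values.items():
        if not _passes_expression_gate(rpm_early, rpm_late, config):
            continue
        fold = signed_fold_change(rpm_early, rpm_late, config.pseudocount)
        if abs(fold) < config.min_fold:
            continue
        records.append(
            DifferentialMirnaRecord(
                mirna_id=mirna,
                rpm_early=rpm_early,
                rpm_late=rpm_late,
                signed_fold=fold,
                direction="up" if fold > 0 else "down",
            )
        )
    return records


def restrict_to_conserved(
    records: Iterable[DifferentialMirnaRecord],
    annotation: MirnaFamilyAnnotation,
) -> list[DifferentialMirnaRecord]:
    """Keep records whose miRNA belongs to a conserved family; set family_id."""
    kept = []
    for record in records:
        family = annotation.family_of(record.mirna_id)
        if family is not None:
            kept.append(replace(record, family_id=family))
    return kept


def unique_family_sets(
    records: Iterable[DifferentialMirnaRecord],
) -> tuple[set[str], set[str]]:
    """Distinct families of up- and of down-regulated records.

    The two sets may intersect: a family is counted in both strata when
    one member rises while another falls.
    """
    up: set[str] = set()
    down: set[str] = set()
    for record in records:
        if record.family_id is None:
            raise ContractError(f"record {record.mirna_id!r} has no family_id")
        (up if record.direction == "up" else down).add(record.family_id)
    return up, down


def annotate_gene_sites(
    records: Iterable[DifferentialMirnaRecord],
    targets: TargetIncidenceTable,
    genes: Sequence[str],
) -> list[DifferentialMirnaRecord]:
    """Attach per-gene conserved site counts of each record's family.

    A gene absent from the table, or untargeted by the family, yields 0.
    """
    annotated = []
    for record in records:
        if record.family_id is None:
            raise ContractError(
                f"record {record.mirna_id!r} has no family_id; "
                "run restrict_to_conserved first"
            )
        counts = {g: targets.site_count(g, record.family_id) for g in genes}
        annotated.append(replace(record, gene_site_counts=counts))
    return annotated
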
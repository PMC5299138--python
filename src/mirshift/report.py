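"""Summary reports over differential calls, plus run manifests.

The counts mirror the headline numbers such analyses report: how many
miRNAs moved up or down, how many unique seed families that is, and for
genes of interest how many of the moved miRNAs have at least one
conserved site in the gene's 3'UTR.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .diffexp import DifferentialMirnaRecord, unique_family_sets
from .errors import ContractError
from .io_formats import MirnaExpressionProfile, TargetIncidenceTable


@dataclass(frozen=True)
class GeneTargetingCounts:
    n_up_mirnas_targeting: int
    n_down_mirnas_targeting: int


@dataclass(frozen=True)
class CountSummary:
    n_up: int
    n_down: int
    n_up_families: int
    n_down_families: int
    per_gene: dict[str, GeneTargetingCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_up_families": self.n_up_families,
            "n_down_families": self.n_down_families,
            "per_gene": {
                g: dataclasses.asdict(c) for g, c in self.per_gene.items()
            },
        }


def summarize_counts(
    records: Sequence[DifferentialMirnaRecord],
    targets: TargetIncidenceTable | None = None,
    genes: Sequence[str] = (),
) -> CountSummary:
    """Headline counts: up/down miRNAs, unique families, per-gene targeting.

    A miRNA "targets" a gene when its family has >= 1 conserved site in
    that gene's 3'UTR.  Records must carry family ids when genes are
    requested.
    """
    ups = [r for r in records if r.direction == "up"]
    downs = [r for r in records if r.direction == "down"]
    if records and all(r.family_id is not None for r in records):
        up_fams, down_fams = unique_family_sets(records)
    else:
        up_fams, down_fams = set(), set()

    per_gene: dict[str, GeneTargetingCounts] = {}
    if genes:
        if targets is None:
            raise ContractError("per-gene counts need a target table")
        for gene in genes:
            def hits(subset: list[DifferentialMirnaRecord]) -> int:
                n = 0
                for r in subset:
                    if r.family_id is None:
                        raise ContractError(
                            f"record {r.mirna_id!r} has no family_id"
                        )
                    if targets.site_count(gene, r.family_id) >= 1:
                        n += 1
                return n

            per_gene[gene] = GeneTargetingCounts(hits(ups), hits(downs))
    return CountSummary(
        n_up=len(ups),
        n_down=len(downs),
        n_up_families=len(up_fams),
        n_down_families=len(down_fams),
        per_gene=per_gene,
    )


def expression_share(
    profile: MirnaExpressionProfile,
    mirna_ids: Iterable[str],
    timepoint: str,
) -> float:
    """Percentage of the miRNA pool the named miRNAs occupy at a timepoint.

    RPMs are already per-million, so the share is sum(RPM) / 1e6 * 100
    regardless of how many miRNAs the profile lists.
    """
    if timepoint not in profile.timepoint_labels:
        raise ContractError(
            f"unknown timepoint {timepoint!r}; profile has "
            f"{profile.timepoint_labels}"
        )
    which = profile.timepoint_labels.index(timepoint)
    total = sum(
        profile.values[m][which] for m in mirna_ids if m in profile.values
    )
    return total / 1_000_000.0 * 100.0


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline invocation, written alongside its outputs.

    Re-running with an identical manifest (same subcommand, parameters,
    input digests and seed) reproduces the outputs bit-exactly; the
    timestamp is informational only.
    """

    subcommand: str
    parameters: dict
    input_digests: dict[str, str]
    seed: int | None = None
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def reproducibility_key(self) -> dict:
        """Everything that determines the outputs (timestamp excluded)."""
        return {
            "subcommand": self.subcommand,
            "parameters": self.parameters,
            "input_digests": self.input_digests,
            "seed": self.seed,
            "version": self.version,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True),
            encoding="utf-8",
        )


def manifest_for(
    subcommand: str,
    parameters: Mapping[str, object],
    input_paths: Mapping[str, str | Path],
    seed: int | None = None,
) -> RunManifest:
    digests = {
        name: file_digest(p) for name, p in input_paths.items() if Path(p).exists()
    }
    return RunManifest(
        subcommand=subcommand,
        parameters=dict(parameters),
        input_digests=digests,
        seed=seed,
    )
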
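"""Miniature small-RNA-seq quantifier: trim, filter, match, RPM.

Processes 50 bp single-end reads of adapter-ligated small RNAs into a
per-miRNA expression profile.  The stages are deliberately simple and
fully specified:

1. 3' adapter trimming: the read is cut at the leftmost position where
   a prefix of the adapter (length >= ``min_overlap``) aligns ungapped
   with a mismatch rate <= ``max_adapter_mismatch_rate``.
2. Quality/length filtering on the trimmed read.
3. Matching against mature miRNA sequences — ungapped, equal length
   only, at most ``max_mismatches`` substitutions.  Mature miRNAs are
   short (16-28 nt) so indel-free matching is adequate.
4. RPM normalization: counts scaled to reads per million *mapped*
   reads, i.e. the denominator is the miRNA-mapped total, not the raw
   library size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import ConfigError, NoMappedReadsError, ValidationError

_DNA = str.maketrans("uU", "tT")


@dataclass(frozen=True)
class FastqRead:
    """One sequencing read with Phred-scale per-base qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )


ReadSet = list[FastqRead]


@dataclass(frozen=True)
class MatureMirnaReference:
    """Mature miRNA sequences keyed by id, stored as DNA (T, not U)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for mirna, seq in self.entries.items():
            if not 16 <= len(seq) <= 28:
                raise ValidationError(
                    f"mature sequence for {mirna!r} has length {len(seq)}, "
                    "expected 16-28"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MatureMirnaReference":
        entries: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            mirna = record.id.strip()
            if mirna in entries:
                raise ValidationError(f"{path}: duplicate miRNA id {mirna!r}")
            entries[mirna] = str(record.seq).upper().translate(_DNA)
        return cls(entries)


@dataclass(frozen=True)
class QuantConfig:
    """Processing parameters; defaults follow common fastX/cutadapt practice."""

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
    min_overlap: int = 5
    max_adapter_mismatch_rate: float = 0.1
    min_quality: int = 20
    min_quality_fraction: float = 0.8
    min_len: int = 16
    max_len: int = 27
    max_mismatches: int = 0
    ambiguous_policy: str = "discard"

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches <= 2:
            raise ConfigError("max_mismatches must be in [0, 2]")
        if self.min_len < 15:
            raise ConfigError("min_len must be >= 15")
        if self.ambiguous_policy not in ("discard", "first_by_reference_order"):
            raise ConfigError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")
        if not 0.0 <= self.min_quality_fraction <= 1.0:
            raise ConfigError("min_quality_fraction must be in [0, 1]")


@dataclass
class QuantResult:
    """Counts per miRNA plus gate-by-gate read accounting."""

    counts: dict[str, int]
    mapped_total: int
    n_input: int = 0
    n_pass_filter: int = 0


def read_fastq(path: str | Path) -> ReadSet:
    """Load a Sanger/Phred+33 FASTQ file."""
    reads: ReadSet = []
    for record in SeqIO.parse(str(path), "fastq"):
        reads.append(
            FastqRead(
                id=record.id,
                sequence=str(record.seq).upper(),
                qualities=tuple(record.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(sequence: str, config: QuantConfig) -> str:
    """Cut ``sequence`` before the leftmost acceptable adapter match.

    At candidate position ``i`` the adapter prefix of length
    ``min(len(adapter), len(sequence) - i)`` is compared ungapped; the
    match is accepted when that overlap is >= ``min_overlap`` and its
    mismatch rate is <= ``max_adapter_mismatch_rate``.  Without a match
    the sequence is returned unchanged.
    """
    adapter = config.adapter.upper()
    n = len(sequence)
    for i in range(n):
        overlap = min(len(adapter), n - i)
        if overlap < config.min_overlap:
            break
        window = sequence[i : i + overlap]
        if _mismatches(window, adapter[:overlap]) <= (
            config.max_adapter_mismatch_rate * overlap
        ):
            return sequence[:i]
    return sequence


def quality_filter(read: FastqRead, config: QuantConfig) -> bool:
    """Keep/drop decision on an (already trimmed) read.

    Keep iff the fraction of bases at quality >= ``min_quality`` is
    >= ``min_quality_fraction`` (closed bounds), the length is inside
    [min_len, max_len], and — when mismatch-free matching is requested —
    the read contains no N.
    """
    n = len(read.sequence)
    if not config.min_len <= n <= config.max_len:
        return False
    good = sum(q >= config.min_quality for q in read.qualities)
    if good < config.min_quality_fraction * n:
        return False
    if config.max_mismatches == 0 and "N" in read.sequence:
        return False
    return True


def match_read(
    sequence: str, reference: MatureMirnaReference, config: QuantConfig
) -> str | None:
    """Assign a trimmed, filtered read to a mature miRNA, or ``None``.

    Candidates are reference entries of equal length within
    ``max_mismatches`` substitutions.  A unique candidate wins; multiple
    candidates fall to ``ambiguous_policy`` (``discard`` -> unmapped,
    ``first_by_reference_order`` -> first candidate in file order).
    """
    candidates = [
        mirna
        for mirna, ref_seq in reference.entries.items()
        if len(ref_seq) == len(sequence)
        and _mismatches(sequence, ref_seq) <= config.max_mismatches
    ]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    if config.ambiguous_policy == "first_by_reference_order":
        return candidates[0]
    return None


def quantify(
    reads: Sequence[FastqRead],
    reference: MatureMirnaReference,
    config: QuantConfig = QuantConfig(),
) -> QuantResult:
    """Run trim -> filter -> match over a read set and count per miRNA."""
    # exact-match index for the common zero-mismatch path
    by_sequence: dict[str, list[str]] = {}
    for mirna, seq in reference.entries.items():
        by_sequence.setdefault(seq, []).append(mirna)

    counts: Counter[str] = Counter()
    n_pass = 0
    for read in reads:
        trimmed_seq = trim_adapter(read.sequence, config)
        trimmed = FastqRead(
            read.id, trimmed_seq, read.qualities[: len(trimmed_seq)]
        )
        if not quality_filter(trimmed, config):
            continue
        n_pass += 1
        if config.max_mismatches == 0:
            hits = by_sequence.get(trimmed_seq, [])
            if len(hits) == 1:
                mirna = hits[0]
            elif hits and config.ambiguous_policy == "first_by_reference_order":
                mirna = hits[0]
            else:
                mirna = None
        else:
            mirna = match_read(trimmed_seq, reference, config)
        if mirna is not None:
            counts[mirna] += 1
    mapped_total = sum(counts.values())
    return QuantResult(
        counts=dict(counts),
        mapped_total=mapped_total,
        n_input=len(reads),
        n_pass_filter=n_pass,
    )


def rpm_normalize(
    counts: Mapping[str, int], mapped_total: int | None = None
) -> dict[str, float]:
    """Scale counts to reads per million mapped reads.

    The denominator defaults to the sum of the counts themselves (the
    mapped total); the normalized values always sum to one million.
    """
    if mapped_total is None:
        mapped_total = sum(counts.values())
    if mapped_total <= 0:
        raise NoMappedReadsError("no mapped reads: RPM undefined")
    return {m: c * 1_000_000.0 / mapped_total for m, c in counts.items()}
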
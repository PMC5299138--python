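"""Read processing: adapter trimming, filtering, matching, RPM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirshift.errors import NoMappedReadsError
from mirshift.quant import (
    FastqRead,
    MatureMirnaReference,
    QuantConfig,
    match_read,
    quality_filter,
    quantify,
    rpm_normalize,
    trim_adapter,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
CFG = QuantConfig(adapter=ADAPTER)
MIRNA21 = "ACGTACGTACGTACGTACGTA"  # 21 nt


def brute_force_trim(sequence, config):
    """Independent oracle: scan every offset, apply the same acceptance rule."""
    adapter = config.adapter.upper()
    for i in range(len(sequence)):
        overlap = min(len(adapter), len(sequence) - i)
        if overlap < config.min_overlap:
            break
        mism = sum(
            a != b for a, b in zip(sequence[i : i + overlap], adapter[:overlap])
        )
        if mism / overlap <= config.max_adapter_mismatch_rate:
            return sequence[:i]
    return sequence


class TestTrimAdapter:
    def test_full_adapter_after_mirna(self):
        assert trim_adapter(MIRNA21 + ADAPTER, CFG) == MIRNA21

    def test_no_adapter_unchanged(self):
        read = "A" * 50
        assert trim_adapter(read, CFG) == read

    def test_one_mismatch_in_twelve_accepted(self):
        # adapter truncated to 12 nt with 1 substitution: rate 0.083 <= 0.1
        mutated = "A" + ADAPTER[1:12]
        read = MIRNA21 + mutated
        assert trim_adapter(read, CFG) == brute_force_trim(read, CFG)
        assert trim_adapter(read, CFG) == MIRNA21

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_reads(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        read = "".join(rng.choice(list("ACGT"), n))
        if rng.random() < 0.5:  # embed a (possibly mutated) adapter
            insert = list(ADAPTER[: int(rng.integers(5, len(ADAPTER) + 1))])
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(0, len(insert)))
                insert[pos] = rng.choice(list("ACGT"))
            cut = int(rng.integers(0, n))
            read = read[:cut] + "".join(insert) + read[cut:]
            read = read[:50]
        assert trim_adapter(read, CFG) == brute_force_trim(read, CFG)


class TestQualityFilter:
    def _read(self, seq, quals):
        return FastqRead("r", seq, tuple(quals))

    def test_high_quality_kept(self):
        assert quality_filter(self._read("A" * 22, [40] * 22), CFG)

    def test_half_low_quality_dropped(self):
        quals = [2] * 11 + [40] * 11
        assert not quality_filter(self._read("A" * 22, quals), CFG)

    def test_boundary_fraction_exactly_met_is_kept(self):
        # 16 of 20 bases at exactly min_quality: fraction 0.8 == threshold
        quals = [CFG.min_quality] * 16 + [CFG.min_quality - 1] * 4
        assert quality_filter(self._read("A" * 20, quals), CFG)
        quals = [CFG.min_quality] * 15 + [CFG.min_quality - 1] * 5
        assert not quality_filter(self._read("A" * 20, quals), CFG)

    @pytest.mark.parametrize("length,kept", [(15, False), (16, True), (27, True), (28, False)])
    def test_length_gate_closed_bounds(self, length, kept):
        assert quality_filter(self._read("A" * length, [40] * length), CFG) is kept

    def test_n_base_dropped_when_mismatch_free(self):
        read = self._read("A" * 10 + "N" + "A" * 10, [40] * 21)
        assert not quality_filter(read, CFG)
        assert quality_filter(read, QuantConfig(adapter=ADAPTER, max_mismatches=1))


class TestMatchRead:
    REF = MatureMirnaReference(
        {
            "mir-a": "ACGTACGTACGTACGTACGTA",
            "mir-b": "TTTTACGTACGTACGTACGTA",
            "mir-c": "ACGTACGTACGTACGTACG",
        }
    )

    def test_exact_unique_match(self):
        assert match_read("ACGTACGTACGTACGTACG", self.REF, CFG) == "mir-c"

    def test_ambiguous_discarded(self):
        ref = MatureMirnaReference(
            {"m1": "A" * 20 + "C", "m2": "A" * 20 + "G"}
        )
        cfg = QuantConfig(adapter=ADAPTER, max_mismatches=1)
        assert match_read("A" * 20 + "T", ref, cfg) is None
        first = QuantConfig(
            adapter=ADAPTER, max_mismatches=1,
            ambiguous_policy="first_by_reference_order",
        )
        assert match_read("A" * 20 + "T", ref, first) == "m1"

    def test_single_mismatch_assignment_matches_hamming_oracle(self):
        cfg = QuantConfig(adapter=ADAPTER, max_mismatches=1)
        query = "ACGTACGTACGTACGTACGTT"  # distance 1 from mir-a, >=2 from rest
        distances = {
            m: sum(a != b for a, b in zip(query, s))
            for m, s in self.REF.entries.items()
            if len(s) == len(query)
        }
        expected = [m for m, d in distances.items() if d <= 1]
        assert expected == ["mir-a"]
        assert match_read(query, self.REF, cfg) == "mir-a"

    def test_length_mismatch_never_matches(self):
        assert match_read("ACGTACGTACGTACGTACGT", self.REF, CFG) is None


class TestQuantifyAndRpm:
    def test_zero_error_simulation_recovers_planted_counts(self):
        rng = np.random.default_rng(5)
        ref = MatureMirnaReference(
            {f"m{i}": "".join(rng.choice(list("ACGT"), 22)) for i in range(8)}
        )
        planted = {f"m{i}": int(rng.integers(1, 40)) for i in range(8)}
        reads = []
        for mirna, n in planted.items():
            template = (ref.entries[mirna] + ADAPTER)[:50]
            for j in range(n):
                reads.append(
                    FastqRead(f"{mirna}-{j}", template, (37,) * len(template))
                )
        result = quantify(reads, ref, CFG)
        assert result.counts == planted
        assert result.mapped_total == sum(planted.values())
        rpm = rpm_normalize(result.counts, result.mapped_total)
        assert sum(rpm.values()) == pytest.approx(1_000_000, rel=1e-3)

    def test_raising_max_mismatches_never_decreases_mapped_total(self):
        rng = np.random.default_rng(9)
        ref = MatureMirnaReference(
            {f"m{i}": "".join(rng.choice(list("ACGT"), 21)) for i in range(5)}
        )
        reads = []
        for i, (mirna, seq) in enumerate(ref.entries.items()):
            mutated = list((seq + ADAPTER)[:50])
            mutated[3] = "ACGT"[(("ACGT".index(mutated[3])) + 1) % 4]
            reads.append(
                FastqRead(f"r{i}", "".join(mutated), (37,) * len(mutated))
            )
        totals = [
            quantify(reads, ref, QuantConfig(adapter=ADAPTER, max_mismatches=k)).mapped_total
            for k in (0, 1, 2)
        ]
        assert totals == sorted(totals)
        assert totals[1] > totals[0]  # the planted mutations become mappable

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"a": 1, "b": 1}, {"a": 500000.0, "b": 500000.0}),
            ({"a": 3}, {"a": 1000000.0}),
            ({"a": 2, "b": 1, "c": 1}, {"a": 500000.0, "b": 250000.0, "c": 250000.0}),
        ],
    )
    def test_rpm_examples(self, counts, expected):
        assert rpm_normalize(counts) == expected

    @given(
        st.dictionaries(
            st.text(st.characters(min_codepoint=97, max_codepoint=122), min_size=1, max_size=5),
            st.integers(1, 10_000),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_rpm_always_sums_to_one_million(self, counts):
        assert sum(rpm_normalize(counts).values()) == pytest.approx(
            1_000_000, rel=1e-3
        )

    def test_no_mapped_reads_is_an_error(self):
        with pytest.raises(NoMappedReadsError):
            rpm_normalize({})
        with pytest.raises(NoMappedReadsError):
            rpm_normalize({"a": 0})
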
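"""Pre-processing: truncation, quality, adapters, complexity, cascade."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cladetrace.io import SampleConfig, SequenceRead
from cladetrace.preprocess import (
    REASON_AMBIGUOUS,
    REASON_LOW_COMPLEXITY,
    REASON_LOW_QUALITY,
    REASON_TOO_SHORT,
    STATUS_ADAPTER_FOUND,
    STATUS_ADAPTER_UNRECOGNIZED,
    STATUS_DISCARDED,
    is_low_complexity,
    passes_quality,
    preprocess_read,
    trim_adapter_cats,
    trim_adapter_nextflex,
    trim_adapter_truseq,
    truncate_read,
)
from cladetrace.synth import DEFAULT_ADAPTER, SynthSpec, generate_sample

ADAPTER = DEFAULT_ADAPTER
LET7 = "TGAGGTAGTAGGTTGTATAGTT"


def _read(seq, quals=None):
    return SequenceRead("r", seq, quals if quals is not None else [35] * len(seq))


class TestTruncate:
    @pytest.mark.parametrize("length,expected", [(75, 50), (22, 22), (50, 50)])
    def test_lengths(self, length, expected):
        out = truncate_read(_read("A" * length))
        assert len(out.seq) == len(out.quals) == expected


class TestQuality:
    def test_all_high(self):
        assert passes_quality(_read("A" * 10, [30] * 10))

    def test_over_half_low_fails(self):
        assert not passes_quality(_read("A" * 10, [10] * 6 + [30] * 4))

    def test_exactly_half_low_passes(self):
        # "more than 50%" is strict: exactly half below Q20 still passes
        assert passes_quality(_read("A" * 10, [10] * 5 + [30] * 5))

    def test_empty_read_fails(self):
        assert not passes_quality(_read(""))


class TestTruseqTrim:
    def test_clean_insert_recovered(self):
        insert, found = trim_adapter_truseq(LET7 + ADAPTER[:28], ADAPTER)
        assert (insert, found) == (LET7, True)

    def test_last_occurrence_wins(self):
        seed = ADAPTER[:8]
        seq = "ACGTC" + seed + "GTACGTACGTACGTACG" + seed + "TTTT"
        insert, found = trim_adapter_truseq(seq, ADAPTER)
        assert found and insert == "ACGTC" + seed + "GTACGTACGTACGTACG"

    def test_suffix_fallback_against_enumeration_oracle(self):
        """Partial-adapter trimming equals brute force over suffixes 1..7."""
        rng = random.Random(5)
        for _ in range(300):
            insert = "".join(rng.choices("ACGT", k=rng.randint(10, 30)))
            k = rng.randint(0, 7)
            seq = insert + ADAPTER[:k]
            if ADAPTER[:8] in seq:
                continue
            # oracle: longest suffix of seq equal to an adapter prefix
            best = 0
            for j in range(1, 8):
                if seq.endswith(ADAPTER[:j]):
                    best = j
            expected = seq[: len(seq) - best] if best else seq
            got, found = trim_adapter_truseq(seq, ADAPTER)
            assert not found
            assert got == expected

    def test_short_adapter_is_config_error(self):
        with pytest.raises(ValueError):
            trim_adapter_truseq("ACGT" * 10, "ACGTACG")


class TestNextflexTrim:
    def test_rule_composition(self):
        seq = "GGCA" + LET7 + "TCAG" + ADAPTER[:20]
        insert, found = trim_adapter_nextflex(seq, ADAPTER)
        assert (insert, found) == (LET7, True)

    def test_no_adapter_only_leading_removed(self):
        seq = "GGCA" + LET7
        insert, found = trim_adapter_nextflex(seq, ADAPTER)
        assert not found
        assert insert.startswith(LET7[:10])

    def test_zero_length_insert_yields_empty(self):
        # leading randoms + trailing randoms + adapter, no insert at all
        seq = "GGCA" + "TGCA" + ADAPTER[:12]
        insert, found = trim_adapter_nextflex(seq, ADAPTER)
        assert found and insert == ""


class TestCatsTrim:
    def test_polya_8mer_found(self):
        seq = "GCT" + LET7 + "A" * 12
        insert, found = trim_adapter_cats(seq)
        assert (insert, found) == (LET7, True)

    def test_trailing_partial_polya(self):
        seq = "GCT" + "TGAGGTAGTAGGTTGTATC" + "AAA"
        insert, found = trim_adapter_cats(seq)
        assert not found
        assert insert == "TGAGGTAGTAGGTTGTATC"

    def test_no_a_after_lead(self):
        seq = "GCT" + "TGCGGTCGTCGGTTGTCTC"
        insert, found = trim_adapter_cats(seq)
        assert (insert, found) == ("TGCGGTCGTCGGTTGTCTC", False)


class TestLowComplexity:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("A" * 18, True),
            ("AC" * 10, True),
            ("ACG" * 7, True),
            ("ACGACGA", True),  # truncated final unit
            (LET7, False),
        ],
    )
    def test_examples(self, seq, expected):
        assert is_low_complexity(seq) is expected

    def test_exhaustive_motif_oracle(self):
        """Implementation equals exhaustive check of all motifs length 1-3."""
        rng = random.Random(9)

        def oracle(s):
            for m in (1, 2, 3):
                if len(s) > m:
                    motif = s[:m]
                    if all(s[i] == motif[i % m] for i in range(len(s))):
                        return True
            return False

        for _ in range(500):
            if rng.random() < 0.5:
                motif = "".join(rng.choices("ACGT", k=rng.randint(1, 3)))
                s = (motif * 12)[: rng.randint(4, 24)]
            else:
                s = "".join(rng.choices("ACGT", k=rng.randint(1, 24)))
            assert is_low_complexity(s) is oracle(s)


class TestPreprocessRead:
    def test_perfect_mirna_read(self, truseq_cfg):
        read = _read(LET7 + ADAPTER + "ATCACG" + "GTCAGTACGTACGTAC")
        out = preprocess_read(read, truseq_cfg)
        assert out.status == STATUS_ADAPTER_FOUND
        assert out.insert == LET7

    def test_adapter_dimer_discarded_at_zero_length(self, truseq_cfg):
        read = _read(ADAPTER + "ATCACGGTCAGTACGTACGTACGTA")
        out = preprocess_read(read, truseq_cfg)
        assert out.status == STATUS_DISCARDED
        assert out.discard_reason == REASON_TOO_SHORT
        assert out.insert == "" and out.adapter_found

    def test_no_adapter_long_read_unrecognized(self, truseq_cfg):
        # no adapter 8-mer, no T at the tail so no adapter-prefix suffix,
        # and not a motif-1..3 repeat
        seq = "GGCC" * 15
        out = preprocess_read(_read(seq), truseq_cfg)
        assert out.status == STATUS_ADAPTER_UNRECOGNIZED
        assert len(out.insert) == 50  # truncation cap, adapter never seen

    def test_low_quality_discard(self, truseq_cfg):
        read = _read("ACGT" * 10, [5] * 40)
        out = preprocess_read(read, truseq_cfg)
        assert out.discard_reason == REASON_LOW_QUALITY

    def test_ambiguous_nt_discard(self, truseq_cfg):
        read = _read("TGAGGTAGTANGTTGTATAGTT" + ADAPTER[:28])
        out = preprocess_read(read, truseq_cfg)
        assert out.discard_reason == REASON_AMBIGUOUS

    def test_low_complexity_discard(self, truseq_cfg):
        read = _read("ACACACACACACACACACAC" + ADAPTER[:28])
        out = preprocess_read(read, truseq_cfg)
        assert out.discard_reason == REASON_LOW_COMPLEXITY

    def test_umi_prefix_trimmed_first(self):
        cfg = SampleConfig(sample_id="u", adapter=ADAPTER, umi_prefix_len=10)
        read = _read("GTCAGTCAGT" + LET7 + ADAPTER[:18])
        out = preprocess_read(read, cfg)
        assert out.insert == LET7

    def test_conservation_identity(self, bundle, truseq_cfg):
        """input reads = QC-passed (both kinds) + sum of discards."""
        spec = SynthSpec(seed=21, n_reads=1500, per_base_error_rate=0.02, clade="primate")
        reads, _ = generate_sample(spec, bundle)
        counts = {}
        for read in reads:
            out = preprocess_read(read, truseq_cfg)
            key = out.status if out.qc_passed else out.discard_reason
            counts[key] = counts.get(key, 0) + 1
        assert sum(counts.values()) == len(reads)
        assert set(counts) <= {
            STATUS_ADAPTER_FOUND,
            STATUS_ADAPTER_UNRECOGNIZED,
            REASON_LOW_QUALITY,
            REASON_AMBIGUOUS,
            REASON_LOW_COMPLEXITY,
            REASON_TOO_SHORT,
        }


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=18, max_size=40))
def test_trim_idempotent_on_adapter_free_inserts(insert):
    """Trimming an insert with no adapter 8-mer and no adapter-prefix
    suffix changes nothing."""
    if DEFAULT_ADAPTER[:8] in insert:
        return
    if any(insert.endswith(DEFAULT_ADAPTER[:k]) for k in range(1, 8)):
        return
    got, found = trim_adapter_truseq(insert, DEFAULT_ADAPTER)
    assert (got, found) == (insert, False)


def test_trimming_oracle_equivalence(bundle, truseq_cfg):
    """On 10,000 error-free synthetic reads with known insert boundaries,
    TruSeq trimming recovers the exact insert whenever the insert itself
    lacks the adapter 8-mer (here: always, by fixture construction)."""
    spec = SynthSpec(seed=33, n_reads=10_000, per_base_error_rate=0.0, clade="bird")
    reads, truths = generate_sample(spec, bundle)
    exact = sum(
        preprocess_read(read, truseq_cfg).insert == truth.insert
        for read, truth in zip(reads, truths)
    )
    assert exact == len(reads)
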
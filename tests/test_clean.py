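"""Index demultiplexing and contamination cleaning."""

import random

import pytest

from cladetrace.clean import (
    VERDICT_CONSISTENT,
    VERDICT_INCONSISTENT,
    VERDICT_INDEX_MISMATCH,
    VERDICT_UNVERIFIABLE,
    clean_run,
    demultiplex,
    demultiplex_stream,
    extract_inline_index,
)
from cladetrace.io import SampleConfig, SequenceRead, read_fastq, write_fastq
from cladetrace.synth import (
    DEFAULT_ADAPTER,
    DEFAULT_INDICES,
    SynthSpec,
    generate_multiplexed_run,
)

ADAPTER = DEFAULT_ADAPTER
INSERT22 = "TGAGGTAGTAGGTTGTATAGTT"


def _read(seq, seq_index=None, read_id="r"):
    return SequenceRead(read_id, seq, [35] * len(seq), seq_index=seq_index)


def _samples(n=3):
    return [
        SampleConfig(
            sample_id=f"s{i}", adapter=ADAPTER, index=DEFAULT_INDICES[i]
        )
        for i in range(n)
    ]


class TestExtractInlineIndex:
    def test_protocol_arithmetic_75nt(self):
        """22 nt insert + 33 nt adapter + 6 nt index fits a 75-cycle read."""
        index = "ATCACG"
        seq = INSERT22 + ADAPTER + index + "GTCAGTCAGTCAGT"
        read = _read(seq[:75])
        assert len(ADAPTER) == 33
        assert extract_inline_index(read, ADAPTER, 6) == index

    def test_no_adapter_8mer(self):
        assert extract_inline_index(_read("GGCC" * 18), ADAPTER, 6) is None

    def test_truncated_index_unreadable(self):
        # 25 nt insert + 33 nt adapter + only 2 nt left in a 60-nt read
        seq = (INSERT22 + "ACG" + ADAPTER + "ATCACG")[:60]
        assert extract_inline_index(_read(seq), ADAPTER, 6) is None

    def test_partial_adapter_not_trusted(self):
        # the 8-mer occurs but the full adapter does not follow
        seq = INSERT22 + ADAPTER[:8] + "ATCACG" + "G" * 30
        assert extract_inline_index(_read(seq), ADAPTER, 6) is None

    def test_bad_index_len(self):
        with pytest.raises(ValueError):
            extract_inline_index(_read("A" * 75), ADAPTER, 0)


class TestDemultiplex:
    def _full_read(self, index, inline=None):
        inline = inline if inline is not None else index
        seq = (INSERT22 + ADAPTER + inline + "GTCAGTCAGTCAGT")[:75]
        return _read(seq, seq_index=index)

    def test_consistent_assignment(self):
        samples = _samples()
        decision = demultiplex(self._full_read(DEFAULT_INDICES[0]), samples)
        assert decision.verdict == VERDICT_CONSISTENT
        assert decision.assigned_sample == "s0"

    def test_one_mismatch_assigned_under_mismatch1_rejected_under_strict(self):
        samples = _samples()
        corrupted = "T" + DEFAULT_INDICES[0][1:]
        assert corrupted != DEFAULT_INDICES[0]
        read = self._full_read(corrupted, inline=DEFAULT_INDICES[0])
        assert demultiplex(read, samples, mode="mismatch1").assigned_sample == "s0"
        assert demultiplex(read, samples, mode="strict").verdict == VERDICT_INDEX_MISMATCH

    def test_mispairing_rejected_only_by_consistency_check(self):
        samples = _samples()
        # sequencer says s0, but the transcript (inline copy) came from s1
        read = self._full_read(DEFAULT_INDICES[0], inline=DEFAULT_INDICES[1])
        assert demultiplex(read, samples, mode="strict").assigned_sample == "s0"
        decision = demultiplex(read, samples, mode="strict_consistent")
        assert decision.verdict == VERDICT_INCONSISTENT
        assert decision.assigned_sample is None

    def test_unreadable_inline_index_is_unverifiable(self):
        samples = _samples()
        read = _read("GGCC" * 18, seq_index=DEFAULT_INDICES[0])
        decision = demultiplex(read, samples, mode="strict_consistent")
        assert decision.verdict == VERDICT_UNVERIFIABLE
        assert decision.assigned_sample == "s0"

    def test_missing_seq_index_rejected(self):
        decision = demultiplex(_read("A" * 20), _samples())
        assert decision.verdict == VERDICT_INDEX_MISMATCH

    def test_close_indices_warn_in_mismatch1(self):
        samples = [
            SampleConfig(sample_id="a", adapter=ADAPTER, index="AAAAAA"),
            SampleConfig(sample_id="b", adapter=ADAPTER, index="AAAAAT"),
        ]
        reads = [self._full_read("AAAAAA")]
        with pytest.warns(UserWarning, match="Hamming"):
            list(demultiplex_stream(reads, samples, mode="mismatch1"))


@pytest.fixture(scope="module")
def mispaired_run(bundle):
    """Three-sample multiplexed run with 5% mis-pairing, no misreads."""
    specs = [
        SynthSpec(
            seed=100 + i,
            n_reads=800,
            per_base_error_rate=0.0,
            index=DEFAULT_INDICES[i],
            clade=clade,
        )
        for i, clade in enumerate(("primate", "rodent", "bird"))
    ]
    return generate_multiplexed_run(specs, bundle, mispair_rate=0.05, seed=5)


class TestCleaningOnGroundTruth:
    def test_monotone_stringency(self, mispaired_run):
        """reads(strict_consistent) <= reads(strict) <= reads(mismatch1)."""
        reads, _ = mispaired_run
        samples = _samples()
        kept = {}
        for mode in ("mismatch1", "strict", "strict_consistent"):
            kept[mode] = {
                read.read_id
                for read, decision in demultiplex_stream(reads, samples, mode=mode)
                if decision.assigned_sample is not None
            }
        assert kept["strict_consistent"] <= kept["strict"] <= kept["mismatch1"]

    def test_mispairing_removal_complete_and_without_false_rejections(self, mispaired_run):
        """strict keeps mis-paired reads; strict_consistent removes every
        readable one and rejects no clean read."""
        reads, truths = mispaired_run
        samples = _samples()
        mispaired = {t.read_id for t in truths if "mispair" in t.events}
        assert mispaired  # the simulation did corrupt something
        strict_kept = set()
        consistent_kept = set()
        inconsistent = set()
        for read, decision in demultiplex_stream(reads, samples, mode="strict"):
            if decision.assigned_sample is not None:
                strict_kept.add(read.read_id)
        for read, decision in demultiplex_stream(reads, samples, mode="strict_consistent"):
            if decision.assigned_sample is not None:
                consistent_kept.add(read.read_id)
            if decision.verdict == VERDICT_INCONSISTENT:
                inconsistent.add(read.read_id)
        # both indices are valid, so plain strict demultiplexing keeps them
        assert mispaired <= strict_kept
        # every generated read has a readable inline index (error-free, 75 nt)
        assert inconsistent == mispaired
        assert consistent_kept == strict_kept - mispaired

    def test_misread_removal_under_strict(self, bundle):
        specs = [
            SynthSpec(
                seed=200 + i,
                n_reads=600,
                per_base_error_rate=0.0,
                index=DEFAULT_INDICES[i],
                clade=clade,
            )
            for i, clade in enumerate(("primate", "rodent"))
        ]
        reads, truths = generate_multiplexed_run(
            specs, bundle, index_misread_rate=0.01, seed=6
        )
        samples = _samples(2)
        misread = {
            t.read_id
            for t in truths
            if any(e.startswith("index_misread") for e in t.events)
        }
        assert misread
        for read, decision in demultiplex_stream(reads, samples, mode="strict"):
            if read.read_id in misread:
                assert decision.verdict == VERDICT_INDEX_MISMATCH
            else:
                assert decision.assigned_sample is not None


class TestCleanRun:
    def test_outputs_and_report(self, tmp_path, mispaired_run):
        reads, truths = mispaired_run
        fastq = tmp_path / "run.fastq"
        write_fastq(reads, fastq)
        samples = _samples()
        report = clean_run(fastq, samples, tmp_path / "out", mode="strict_consistent")
        assert set(report["sample"]) == {"s0", "s1", "s2", "unassigned"}
        n_mispaired = sum("mispair" in t.events for t in truths)
        assert report[VERDICT_INCONSISTENT].sum() == n_mispaired
        total = report[
            [VERDICT_CONSISTENT, VERDICT_UNVERIFIABLE, VERDICT_INDEX_MISMATCH, VERDICT_INCONSISTENT]
        ].to_numpy().sum()
        assert total == len(reads)

    def test_retained_reads_unmodified(self, tmp_path, mispaired_run):
        reads, _ = mispaired_run
        fastq = tmp_path / "run.fastq"
        write_fastq(reads, fastq)
        samples = _samples()
        clean_run(fastq, samples, tmp_path / "out", mode="strict_consistent")
        originals = {r.read_id: r for r in reads}
        for sample in samples:
            for rec in read_fastq(tmp_path / "out" / f"{sample.sample_id}.fastq.gz"):
                orig = originals[rec.read_id]
                assert rec.seq == orig.seq and rec.quals == orig.quals

    def test_no_corruption_means_identical_keeps(self, tmp_path, bundle):
        specs = [
            SynthSpec(seed=300 + i, n_reads=300, per_base_error_rate=0.0,
                      index=DEFAULT_INDICES[i], clade="primate")
            for i in range(2)
        ]
        reads, _ = generate_multiplexed_run(specs, bundle, seed=7)
        fastq = tmp_path / "run.fastq"
        write_fastq(reads, fastq)
        samples = _samples(2)
        keeps = {}
        for mode in ("mismatch1", "strict_consistent"):
            out = tmp_path / mode
            clean_run(fastq, samples, out, mode=mode, gzip_output=False)
            keeps[mode] = {
                rec.read_id
                for s in samples
                for rec in read_fastq(out / f"{s.sample_id}.fastq")
            }
        assert keeps["mismatch1"] == keeps["strict_consistent"]
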
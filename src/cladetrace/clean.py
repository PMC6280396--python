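"""Post-sequencing contamination removal via index demultiplexing.

Multiplexed runs assign each read to a sample through a short index read.
Two error modes contaminate samples: index *misreading* (sequencing errors
in the index read) and index *mis-pairing* (a correct index paired with the
wrong transcript's read). Because small-RNA inserts are short, the main
sequencing reaction usually runs through the 3' adapter into the index, so
the index is read twice; comparing the sequencer-assigned index with this
*inline* copy catches mis-pairing events that perfect-match demultiplexing
cannot.

Three regimes of increasing stringency:

* ``mismatch1``         - assign if exactly one sample index is within
                          Hamming distance 1 (the common default).
* ``strict``            - perfect index matches only (removes misreads).
* ``strict_consistent`` - perfect match AND, when the inline index is
                          readable, it must equal the sequencer index
                          (removes readable mis-pairings too).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .io import SampleConfig, SequenceRead, read_fastq, write_fastq
from .preprocess import ADAPTER_SEED_LEN

MODES = ("mismatch1", "strict", "strict_consistent")

VERDICT_CONSISTENT = "assigned_consistent"
VERDICT_UNVERIFIABLE = "assigned_unverifiable"
VERDICT_INDEX_MISMATCH = "rejected_index_mismatch"
VERDICT_INCONSISTENT = "rejected_inconsistent"
VERDICTS = (VERDICT_CONSISTENT, VERDICT_UNVERIFIABLE, VERDICT_INDEX_MISMATCH, VERDICT_INCONSISTENT)


@dataclass(frozen=True)
class DemuxDecision:
    assigned_sample: Optional[str]
    inline_index: Optional[str]
    verdict: str

    def __post_init__(self) -> None:
        assert (self.assigned_sample is not None) == self.verdict.startswith("assigned")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def extract_inline_index(
    raw_read: SequenceRead, adapter: str, index_len: int
) -> Optional[str]:
    """Read the inline copy of the sample index from an untruncated read.

    The FULL 3' adapter must be present (located at the last occurrence of
    its leading 8-mer) and ``index_len`` bases must follow it entirely
    within the read; otherwise the inline index is unreadable and None is
    returned. Requiring the whole adapter avoids mistaking insert bases
    for index bases.
    """
    if index_len < 1:
        raise ValueError("index_len must be >= 1")
    if len(adapter) < ADAPTER_SEED_LEN:
        raise ValueError(f"adapter must be at least {ADAPTER_SEED_LEN} nt")
    seq = raw_read.seq
    pos = seq.rfind(adapter[:ADAPTER_SEED_LEN])
    if pos == -1:
        return None
    if seq[pos : pos + len(adapter)] != adapter:
        return None
    start = pos + len(adapter)
    if start + index_len > len(seq):
        return None
    return seq[start : start + index_len]


def _check_index_distances(samples: list[SampleConfig]) -> None:
    indices = [(s.sample_id, s.index) for s in samples if s.index]
    for i, (id_a, a) in enumerate(indices):
        for id_b, b in indices[i + 1 :]:
            if len(a) == len(b) and hamming(a, b) < 3:
                warnings.warn(
                    f"sample indices {id_a}={a} and {id_b}={b} are within Hamming "
                    "distance 2; one-mismatch demultiplexing may be ambiguous"
                )


def demultiplex(
    read: SequenceRead,
    samples: list[SampleConfig],
    mode: str = "strict_consistent",
    index_len: Optional[int] = None,
    adapter: Optional[str] = None,
) -> DemuxDecision:
    """Assign one read to a sample (or reject it) under the given regime.

    ``adapter`` and ``index_len`` are only needed for ``strict_consistent``
    (they locate the inline index); ``index_len`` defaults to the length of
    the first sample index.
    """
    if mode not in MODES:
        raise ValueError(f"unknown demultiplexing mode {mode!r}")
    indexed = [s for s in samples if s.index]
    if not indexed:
        raise ValueError("no sample defines an expected index")
    if index_len is None:
        index_len = len(indexed[0].index)

    seq_index = read.seq_index
    if not seq_index:
        return DemuxDecision(None, None, VERDICT_INDEX_MISMATCH)

    if mode == "mismatch1":
        hits = [
            s for s in indexed
            if len(s.index) == len(seq_index) and hamming(s.index, seq_index) <= 1
        ]
        if len(hits) != 1:
            return DemuxDecision(None, None, VERDICT_INDEX_MISMATCH)
        return DemuxDecision(hits[0].sample_id, None, VERDICT_UNVERIFIABLE)

    hits = [s for s in indexed if s.index == seq_index]
    if len(hits) != 1:
        return DemuxDecision(None, None, VERDICT_INDEX_MISMATCH)
    sample = hits[0]
    if mode == "strict":
        return DemuxDecision(sample.sample_id, None, VERDICT_UNVERIFIABLE)

    # strict_consistent: compare with the inline copy when readable.
    use_adapter = adapter if adapter is not None else sample.adapter
    inline = extract_inline_index(read, use_adapter, index_len) if use_adapter else None
    if inline is None:
        return DemuxDecision(sample.sample_id, None, VERDICT_UNVERIFIABLE)
    if inline != seq_index:  # exact comparison; N counts as a mismatch
        return DemuxDecision(None, inline, VERDICT_INCONSISTENT)
    return DemuxDecision(sample.sample_id, inline, VERDICT_CONSISTENT)


def demultiplex_stream(
    reads: Iterable[SequenceRead],
    samples: list[SampleConfig],
    mode: str = "strict_consistent",
    index_len: Optional[int] = None,
) -> Iterator[tuple[SequenceRead, DemuxDecision]]:
    if mode == "mismatch1":
        _check_index_distances(samples)
    for read in reads:
        yield read, demultiplex(read, samples, mode=mode, index_len=index_len)


def clean_run(
    fastq_path: str | Path,
    samples: list[SampleConfig],
    out_dir: str | Path,
    mode: str = "strict_consistent",
    index_len: Optional[int] = None,
    drop_unverifiable: bool = False,
    phred_offset: int = 33,
    gzip_output: bool = True,
) -> pd.DataFrame:
    """Demultiplex a multiplexed FASTQ into per-sample cleaned FASTQ files.

    Accepted reads are written untouched (sequence and qualities
    unmodified). Unverifiable reads (inline index unreadable) are RETAINED
    unless ``drop_unverifiable`` is set. Returns the cleaning report: one
    row per sample plus an ``unassigned`` row, one column per verdict.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    suffix = ".fastq.gz" if gzip_output else ".fastq"
    counts: dict[str, Counter[str]] = {s.sample_id: Counter() for s in samples}
    counts["unassigned"] = Counter()
    handles = {}
    import gzip as _gzip

    opener = (lambda p: _gzip.open(p, "wt")) if gzip_output else (lambda p: open(p, "wt"))
    try:
        for s in samples:
            handles[s.sample_id] = opener(out_dir / f"{s.sample_id}{suffix}")
        reads = read_fastq(fastq_path, phred_offset=phred_offset, parse_header_index=True)
        for read, decision in demultiplex_stream(reads, samples, mode=mode, index_len=index_len):
            target = decision.assigned_sample or "unassigned"
            counts[target][decision.verdict] += 1
            keep = decision.assigned_sample is not None and not (
                drop_unverifiable and decision.verdict == VERDICT_UNVERIFIABLE
            )
            if keep:
                qual = "".join(chr(q + phred_offset) for q in read.quals)
                handles[decision.assigned_sample].write(
                    f"@{read.read_id}\n{read.seq}\n+\n{qual}\n"
                )
    finally:
        for handle in handles.values():
            handle.close()

    report = pd.DataFrame(
        [
            {"sample": sample, **{v: counts[sample].get(v, 0) for v in VERDICTS}}
            for sample in [s.sample_id for s in samples] + ["unassigned"]
        ]
    )
    report.to_csv(out_dir / "cleaning_report.tsv", sep="\t", index=False)
    return report
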
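"""Read pre-processing: truncation, quality filter, adapter trimming,
ambiguity/complexity/length filters.

The pipeline order is fixed: UMI prefix trim -> truncation to 50 nt ->
PHRED quality filter -> protocol-specific adapter trimming -> ambiguous-
nucleotide filter -> low-complexity filter -> minimum-length filter.
Inserts of at least 18 nt survive as "QC-passed" reads, whether or not the
adapter was recognized; everything else is discarded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .io import SampleConfig, SequenceRead

#: Reads longer than this are truncated before any other processing.
READ_LENGTH_CAP = 50
#: A read fails QC when more than this fraction of bases is below MIN_PHRED.
MAX_LOW_QUALITY_FRACTION = 0.5
MIN_PHRED = 20
#: Minimum insert length for a QC-passed read.
MIN_INSERT_LEN = 18
#: Length of the adapter prefix searched for during trimming.
ADAPTER_SEED_LEN = 8

STATUS_ADAPTER_FOUND = "qc_passed_adapter_found"
STATUS_ADAPTER_UNRECOGNIZED = "qc_passed_adapter_unrecognized"
STATUS_DISCARDED = "discarded"

REASON_NONE = "none"
REASON_LOW_QUALITY = "low_quality"
REASON_AMBIGUOUS = "ambiguous_nt"
REASON_LOW_COMPLEXITY = "low_complexity"
REASON_TOO_SHORT = "too_short"

DISCARD_REASONS = (REASON_LOW_QUALITY, REASON_AMBIGUOUS, REASON_LOW_COMPLEXITY, REASON_TOO_SHORT)


@dataclass
class ProcessedRead:
    insert: str
    status: str
    discard_reason: str = REASON_NONE
    pre_trim_len: int = 0
    adapter_found: bool = False

    @property
    def qc_passed(self) -> bool:
        return self.status != STATUS_DISCARDED


def truncate_read(read: SequenceRead) -> SequenceRead:
    """Trim sequence and qualities beyond the first 50 nt."""
    if len(read.seq) <= READ_LENGTH_CAP:
        return read
    return SequenceRead(
        read_id=read.read_id,
        seq=read.seq[:READ_LENGTH_CAP],
        quals=read.quals[:READ_LENGTH_CAP],
        seq_index=read.seq_index,
    )


def passes_quality(read: SequenceRead) -> bool:
    """True unless MORE than 50% of bases have PHRED < 20 (strict: a read
    with exactly half its bases below threshold passes). Empty reads fail."""
    n = len(read.quals)
    if n == 0:
        return False
    low = sum(1 for q in read.quals if q < MIN_PHRED)
    return low * 2 <= n


def trim_adapter_truseq(seq: str, adapter: str) -> tuple[str, bool]:
    """TruSeq/QiaSeq adapter removal.

    The read is searched for the first 8-mer of the 3' adapter; if found,
    the LAST occurrence and everything after it are removed. Otherwise the
    longest read suffix equal to an adapter prefix (7 nt down to 1 nt) is
    removed, but the adapter counts as unrecognized.
    """
    if len(adapter) < ADAPTER_SEED_LEN:
        raise ValueError(
            f"adapter must be at least {ADAPTER_SEED_LEN} nt, got {len(adapter)}"
        )
    seed = adapter[:ADAPTER_SEED_LEN]
    pos = seq.rfind(seed)
    if pos != -1:
        return seq[:pos], True
    for k in range(ADAPTER_SEED_LEN - 1, 0, -1):
        if seq.endswith(adapter[:k]):
            return seq[:-k], False
    return seq, False


def trim_adapter_nextflex(seq: str, adapter: str) -> tuple[str, bool]:
    """NEXTflex adapter removal: the protocol puts 4 randomized bases on
    each side of the insert, so 4 leading nt are dropped, the adapter is
    trimmed as for TruSeq, and (when the adapter was found) the last 4 nt
    of the remaining insert are dropped as well."""
    insert, found = trim_adapter_truseq(seq[4:], adapter)
    if found:
        insert = insert[:-4] if len(insert) > 4 else ""
    return insert, found


def trim_adapter_cats(seq: str) -> tuple[str, bool]:
    """CATS adapter removal: 3 leading nt are dropped, then the LEFT-most
    poly-A 8-mer and everything after it. With no A-8-mer, progressively
    shorter trailing poly-A runs (7 nt down to a single A) are trimmed."""
    seq = seq[3:]
    pos = seq.find("A" * ADAPTER_SEED_LEN)
    if pos != -1:
        return seq[:pos], True
    for k in range(ADAPTER_SEED_LEN - 1, 0, -1):
        if seq.endswith("A" * k):
            return seq[:-k], False
    return seq, False


def is_low_complexity(insert: str) -> bool:
    """True iff the insert is a tandem repeat (truncated final unit
    allowed) of a single motif of length 1, 2 or 3."""
    n = len(insert)
    if n == 0:
        return False
    for m in (1, 2, 3):
        if n <= m:
            continue
        motif = insert[:m]
        repeated = (motif * (n // m + 1))[:n]
        if insert == repeated:
            return True
    return False


def _trim_adapter(seq: str, cfg: SampleConfig) -> tuple[str, bool]:
    if cfg.protocol == "truseq_qiaseq":
        return trim_adapter_truseq(seq, cfg.adapter)
    if cfg.protocol == "nextflex":
        return trim_adapter_nextflex(seq, cfg.adapter)
    return trim_adapter_cats(seq)


def preprocess_read(
    read: SequenceRead,
    cfg: SampleConfig,
    complexity_filter: Callable[[str], bool] = is_low_complexity,
) -> ProcessedRead:
    """Run the full pre-processing cascade on one read.

    Returns a :class:`ProcessedRead` whose status is one of
    ``qc_passed_adapter_found``, ``qc_passed_adapter_unrecognized`` or
    ``discarded`` (with a reason). ``pre_trim_len`` is the read length
    after truncation, before adapter removal; the insert length histogram
    of the QC report is taken from ``len(insert)``.
    """
    if cfg.umi_prefix_len:
        read = SequenceRead(
            read_id=read.read_id,
            seq=read.seq[cfg.umi_prefix_len :],
            quals=read.quals[cfg.umi_prefix_len :],
            seq_index=read.seq_index,
        )
    read = truncate_read(read)
    pre_trim_len = len(read.seq)
    if not passes_quality(read):
        return ProcessedRead("", STATUS_DISCARDED, REASON_LOW_QUALITY, pre_trim_len, False)
    insert, adapter_found = _trim_adapter(read.seq, cfg)
    if any(c not in "ACGT" for c in insert):
        return ProcessedRead(insert, STATUS_DISCARDED, REASON_AMBIGUOUS, pre_trim_len, adapter_found)
    if complexity_filter(insert):
        return ProcessedRead(insert, STATUS_DISCARDED, REASON_LOW_COMPLEXITY, pre_trim_len, adapter_found)
    if len(insert) < MIN_INSERT_LEN:
        return ProcessedRead(insert, STATUS_DISCARDED, REASON_TOO_SHORT, pre_trim_len, adapter_found)
    status = STATUS_ADAPTER_FOUND if adapter_found else STATUS_ADAPTER_UNRECOGNIZED
    return ProcessedRead(insert, status, REASON_NONE, pre_trim_len, adapter_found)
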
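"""Specificity model, QC flags, and expression bookkeeping.

The spurious-match model treats a uniform-random read's leading 20-mer as
a uniform draw from the 4^20 possible 20-mers; with W distinct indexed
20-mers, the probability of a random hit is 1 - (1 - 4^-20)^W and the
expected number of spurious clade calls among N reads is N times that.
For the catalog's actual scale (W on the order of tens of thousands) this
is ~ N*W/4^20: a ten-million-read dataset yields well under one spurious
match, which is what makes 20-mer marker matching usable for tracing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .refdb import KMER_LEN

_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}


def expected_spurious_matches(window_count: int, n_reads: int, kmer_len: int = KMER_LEN) -> float:
    """Expected number of uniform-random reads hitting a W-key 20-mer index."""
    if window_count < 0 or n_reads < 0:
        raise ValueError("window_count and n_reads must be non-negative")
    p_miss = (1.0 - 4.0 ** (-kmer_len)) ** window_count
    return n_reads * (1.0 - p_miss)


def encode_kmers(kmers: list[str]) -> np.ndarray:
    """Pack A/C/G/T k-mers into integers (2 bits per base)."""
    out = np.empty(len(kmers), dtype=np.uint64)
    for i, kmer in enumerate(kmers):
        value = 0
        for base in kmer:
            value = (value << 2) | _BASE_TO_BITS[base]
        out[i] = value
    return out


def simulate_spurious_matches(
    kmers: list[str],
    n_reads: int,
    seed: int,
    kmer_len: int = KMER_LEN,
) -> int:
    """Monte-Carlo count of uniform-random reads whose leading 20-mer hits
    the index. Random 20-mers are drawn as uniform integers in [0, 4^20)
    and compared against the bit-packed index, so 10^7 draws take seconds.
    """
    keys = np.unique(encode_kmers(kmers))
    rng = np.random.default_rng(seed)
    space = 4**kmer_len
    total = 0
    chunk = 2_000_000
    remaining = n_reads
    while remaining > 0:
        n = min(chunk, remaining)
        draws = rng.integers(0, space, size=n, dtype=np.uint64)
        total += int(np.isin(draws, keys).sum())
        remaining -= n
    return total


# --- QC flags (thresholds are strict inequalities, as reported) ---------

#: Flag when < 25% of QC-passed reads have insert length in [20, 25] nt.
LENGTH_FLAG_FRACTION = 0.25
LENGTH_FLAG_RANGE = (20, 25)
#: Flag when < 10% of QC-passed reads are annotated as miRNA.
MIRNA_CONTENT_FRACTION = 0.10
#: Flag when < 10% of the species' known precursors are observed.
COMPLEXITY_FRACTION = 0.10

LENGTH_FLAG = "length_flag"
MIRNA_CONTENT_FLAG = "mirna_content_flag"
COMPLEXITY_FLAG = "complexity_flag"


def qc_flags(
    length_histogram: dict[int, int],
    qc_passed_reads: int,
    mirna_reads: int,
    distinct_precursors: int,
    total_known_precursors: int,
) -> list[str]:
    """Evaluate the three QC flags from per-sample accumulators.

    * ``length_flag``: fewer than 25% of the adapter-trimmed sequences in
      the length panel are 20-25 nt long (miRNA-sized); degraded or
      adapter-artifact-heavy libraries trip it.
    * ``mirna_content_flag``: miRNA-annotated reads are under 10% of
      QC-passed reads.
    * ``complexity_flag``: the sample covers under 10% of the known miRNA
      precursors of the studied species.
    """
    flags: list[str] = []
    lo, hi = LENGTH_FLAG_RANGE
    histogram_total = sum(length_histogram.values())
    if histogram_total > 0:
        in_range = sum(n for length, n in length_histogram.items() if lo <= length <= hi)
        if in_range / histogram_total < LENGTH_FLAG_FRACTION:
            flags.append(LENGTH_FLAG)
    if qc_passed_reads > 0:
        if mirna_reads / qc_passed_reads < MIRNA_CONTENT_FRACTION:
            flags.append(MIRNA_CONTENT_FLAG)
    if total_known_precursors > 0:
        if distinct_precursors / total_known_precursors < COMPLEXITY_FRACTION:
            flags.append(COMPLEXITY_FLAG)
    return flags


# --- RPM normalization and differential-expression bookkeeping ----------

RPM_SCALE = 1_000_000
#: A miRNA must reach this expression in at least one sample to be callable.
DE_MIN_RPM = 10.0
#: Fold change must STRICTLY exceed this (in either direction).
DE_MIN_FOLD = 2.0


def rpm_normalize(counts: dict[str, int]) -> dict[str, float]:
    """Reads-per-million: count / total * 10^6. Totals must be positive."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("cannot RPM-normalize an all-zero count table")
    return {key: count / total * RPM_SCALE for key, count in counts.items()}


def call_de(rpm_a: dict[str, float], rpm_b: dict[str, float]) -> set[str]:
    """Differentially expressed IDs between two RPM profiles.

    An ID present in both profiles is DE iff its larger value is >= 10 RPM
    and the fold change strictly exceeds 2 in either direction. An ID
    present in only one profile is DE iff that value is >= 10 RPM.
    """
    de: set[str] = set()
    for key in set(rpm_a) | set(rpm_b):
        a, b = rpm_a.get(key), rpm_b.get(key)
        if a is None or b is None:
            value = a if a is not None else b
            if value >= DE_MIN_RPM:
                de.add(key)
            continue
        if max(a, b) < DE_MIN_RPM:
            continue
        if a == 0 or b == 0:
            if max(a, b) >= DE_MIN_RPM:
                de.add(key)
            continue
        fold = a / b if a > b else b / a
        if fold > DE_MIN_FOLD:
            de.add(key)
    return de


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(
    counts: ConfusionCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(TPR, SPC, ACC) = (TP/(TP+FN), TN/(TN+FP), (TP+TN)/total).

    A ratio with a zero denominator is undefined and reported as None.
    """
    tpr = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    spc = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    total = counts.tp + counts.fp + counts.tn + counts.fn
    acc = (counts.tp + counts.tn) / total if total > 0 else None
    return tpr, spc, acc
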
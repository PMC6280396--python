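"""Taxonomic tracing: clade/species assignment of reads by exact 20-mer
matching against the marker catalog, and clade composition profiles.

A read is called clade-specific when its first 20 nt occur verbatim in
the marker index (any window of a marker in clade mode; marker prefixes
only in species mode). Matching is strand-specific: small RNAs are
sequenced sense, so no reverse complement is considered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .refdb import CladeCatalog


@dataclass
class CladeProfile:
    """Per-sample clade composition.

    ``read_counts`` counts clade-specific reads per clade;
    ``unique_sequence_counts`` counts distinct insert sequences per clade.
    Composition percentages use clade-specific reads as the denominator,
    not all reads.
    """

    read_counts: dict[str, int] = field(default_factory=dict)
    unique_sequence_counts: dict[str, int] = field(default_factory=dict)
    unassigned_reads: int = 0

    @property
    def total_clade_specific_reads(self) -> int:
        return sum(self.read_counts.values())

    def fractions(self) -> dict[str, float]:
        """Clade fractions among clade-specific reads (empty when none)."""
        total = self.total_clade_specific_reads
        if total == 0:
            return {}
        return {clade: n / total for clade, n in self.read_counts.items()}


def assign_clade(insert: str, catalog: CladeCatalog) -> Optional[str]:
    """Assign an insert to a clade via its leading 20-mer, or None.

    Inserts shorter than 20 nt cannot form a query and stay unassigned.
    """
    if len(insert) < catalog.kmer_len:
        return None
    return catalog.window_index.get(insert[: catalog.kmer_len])


def assign_species(insert: str, catalog: CladeCatalog) -> Optional[str]:
    """Species-mode assignment: first 20 nt against reference prefixes only."""
    if catalog.mode != "species":
        raise ValueError("assign_species requires a catalog built in species mode")
    return assign_clade(insert, catalog)


def build_clade_profile(inserts: Iterable[str], catalog: CladeCatalog) -> CladeProfile:
    """Count clade-specific reads and distinct sequences over a QC-passed
    insert stream. The profile is independent of read order."""
    read_counts: Counter[str] = Counter()
    unique: dict[str, set[str]] = {}
    unassigned = 0
    for insert in inserts:
        clade = assign_clade(insert, catalog)
        if clade is None:
            unassigned += 1
            continue
        read_counts[clade] += 1
        unique.setdefault(clade, set()).add(insert)
    return CladeProfile(
        read_counts=dict(read_counts),
        unique_sequence_counts={c: len(s) for c, s in unique.items()},
        unassigned_reads=unassigned,
    )


def detect_contamination(
    profile: CladeProfile,
    expected_clade: str,
    min_reads: int = 1,
) -> tuple[list[tuple[str, int, float]], bool]:
    """Report foreign clades present in a profile.

    Returns ``(entries, no_evidence)`` where each entry is
    (foreign clade, read count, fraction of clade-specific reads), sorted
    by descending count then clade name, and ``no_evidence`` is True when
    the profile contains no clade-specific reads at all (so absence of
    contamination cannot be concluded).
    """
    total = profile.total_clade_specific_reads
    if total == 0:
        return [], True
    entries = [
        (clade, count, count / total)
        for clade, count in profile.read_counts.items()
        if clade != expected_clade and count >= min_reads
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries, False
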
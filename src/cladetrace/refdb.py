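"""Marker and annotation reference databases.

Two structures are built here:

* :class:`CladeCatalog` - an index of 20-mers drawn from mature miRNA
  sequences whose families are clade-specific, used for taxonomic tracing.
  In *clade* mode every 20-nt window of each admitted mature sequence is
  indexed; in *species* mode only the first 20 nt of each reference.
* :class:`RnaTypeDB` - ordered collections of miRNA precursor, tRNA and
  rRNA sequences supporting ungapped substring lookup at 0 or 1
  substitutions, plus an 18-mer index over sequencing-artifact sequences.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .io import canonical_family, parse_clade_catalog, read_fasta

KMER_LEN = 20
ARTIFACT_KMER_LEN = 18

# miRBase-style mature ID: species prefix, miR/let stem, family number,
# optional suffix letters and arm, e.g. hsa-miR-580-5p, dme-let-7, mmu-miR-124a-3p
_MIRBASE_ID = re.compile(
    r"^[a-z0-9]{3,4}-(mir|let)-?(\d+)", re.IGNORECASE
)


def parse_family_number(mature_id: str) -> Optional[str]:
    """Extract the canonical family key from a miRBase-style mature ID.

    ``hsa-miR-580-5p`` -> ``"580"``; ``dme-let-7`` -> ``"let-7"`` (the
    ``let`` names occupy their own namespace, distinct from miR-7).
    Returns None when the ID cannot be parsed.
    """
    match = _MIRBASE_ID.match(mature_id)
    if not match:
        return None
    stem, number = match.group(1).lower(), int(match.group(2))
    if stem == "let":
        return canonical_family(f"let-{number}")
    return str(number)


@dataclass
class CladeCatalog:
    """20-mer marker index used by the trace step.

    ``window_index`` maps each unambiguous 20-mer to its clade;
    ``window_refs`` records the reference sequences each 20-mer came from.
    ``ambiguous`` lists 20-mers found in references of two or more clades;
    they are excluded from the index (markers must be clade-exclusive) and
    surfaced so catalog curators can fix the source.
    """

    mode: str = "clade"  # or "species"
    kmer_len: int = KMER_LEN
    window_index: dict[str, str] = field(default_factory=dict)
    window_refs: dict[str, set[str]] = field(default_factory=dict)
    ambiguous: dict[str, set[str]] = field(default_factory=dict)
    clades: list[str] = field(default_factory=list)
    n_references: int = 0
    total_reference_nt: int = 0

    @property
    def window_count(self) -> int:
        """Number of distinct indexed 20-mers (the W of the specificity model)."""
        return len(self.window_index)


def build_clade_catalog(
    catalog: dict[str, str],
    matures: Iterable[tuple[str, str]],
    mode: str = "clade",
) -> CladeCatalog:
    """Expand a family->clade catalog into a 20-mer index over mature miRNAs.

    A mature sequence is admitted iff its parsed family number is listed in
    the catalog. In ``clade`` mode all 20-nt windows of each admitted
    sequence are indexed under its clade; in ``species`` mode only the
    first 20 nt (prefix-to-prefix matching). 20-mers occurring in two
    clades are excluded and reported in ``ambiguous``. The result is
    independent of input order.
    """
    if mode not in ("clade", "species"):
        raise ValueError(f"unknown catalog mode {mode!r}")
    result = CladeCatalog(mode=mode)
    # Sort for order-independence: identical indexes from shuffled FASTAs.
    entries: list[tuple[str, str, str]] = []  # (ref_id, seq, clade)
    for ref_id, seq in sorted(matures):
        family = parse_family_number(ref_id)
        if family is None:
            warnings.warn(f"cannot parse a family number from ID {ref_id!r}; skipped")
            continue
        clade = catalog.get(family)
        if clade is None:
            continue
        if len(seq) < KMER_LEN:
            warnings.warn(f"reference {ref_id!r} shorter than {KMER_LEN} nt; excluded")
            continue
        entries.append((ref_id, seq, clade))

    result.n_references = len(entries)
    result.total_reference_nt = sum(len(seq) for _, seq, _ in entries)
    clades_seen: set[str] = set()
    for ref_id, seq, clade in entries:
        clades_seen.add(clade)
        if mode == "species":
            windows = [seq[:KMER_LEN]]
        else:
            windows = [seq[i : i + KMER_LEN] for i in range(len(seq) - KMER_LEN + 1)]
        for kmer in windows:
            if kmer in result.ambiguous:
                result.ambiguous[kmer].add(clade)
                continue
            existing = result.window_index.get(kmer)
            if existing is not None and existing != clade:
                # Cross-clade collision: demote to the ambiguity report.
                result.ambiguous[kmer] = {existing, clade}
                del result.window_index[kmer]
                del result.window_refs[kmer]
                continue
            result.window_index[kmer] = clade
            result.window_refs.setdefault(kmer, set()).add(ref_id)
    result.clades = sorted(clades_seen)
    return result


class _SubstringIndex:
    """Ungapped substring lookup over a sequence collection.

    Queries ask: is the read a contiguous substring of any member, with at
    most k substitutions (k in {0, 1}), no indels. The 1-substitution case
    uses the pigeonhole principle: one half of the read must match exactly,
    so exact occurrences of each half seed candidate alignments that are
    then verified by Hamming distance.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.records = sorted(records)  # sorted: deterministic tie-breaking

    def find(self, query: str, max_mismatches: int = 0) -> Optional[str]:
        """Return the ID of the first matching member (lexicographically
        smallest, as records are sorted), or None."""
        if not query:
            return None
        if max_mismatches == 0:
            for ref_id, seq in self.records:
                if query in seq:
                    return ref_id
            return None
        if max_mismatches != 1:
            raise ValueError("only 0 or 1 substitutions supported")
        half = len(query) // 2
        left, right = query[:half], query[half:]
        for ref_id, seq in self.records:
            if self._hits_with_one_mismatch(query, seq, left, right, half):
                return ref_id
        return None

    @staticmethod
    def _hits_with_one_mismatch(query: str, seq: str, left: str, right: str, half: int) -> bool:
        qlen = len(query)
        checked: set[int] = set()
        # Seed with exact occurrences of the left half...
        start = seq.find(left)
        while start != -1:
            if start + qlen <= len(seq) and start not in checked:
                checked.add(start)
                window = seq[start : start + qlen]
                if sum(a != b for a, b in zip(query, window)) <= 1:
                    return True
            start = seq.find(left, start + 1)
        # ...and of the right half (alignment start is offset by `half`).
        start = seq.find(right)
        while start != -1:
            align = start - half
            if align >= 0 and align + qlen <= len(seq) and align not in checked:
                checked.add(align)
                window = seq[align : align + qlen]
                if sum(a != b for a, b in zip(query, window)) <= 1:
                    return True
            start = seq.find(right, start + 1)
        return False


@dataclass
class RnaTypeDB:
    """Ordered annotation references: precursor miRNA, tRNA, rRNA, artifacts.

    Collection priority is fixed: precursor -> tRNA -> rRNA (a read is
    annotated by the first collection it aligns to). Artifact sequences are
    matched separately by shared 18-mers ("18 nt stretch of identity").
    """

    precursor_mirna: _SubstringIndex
    trna: _SubstringIndex
    rrna: _SubstringIndex
    artifact_kmers: dict[str, str]  # 18-mer -> artifact id
    species: str = ""
    n_precursors: int = 0

    COLLECTIONS = ("precursor_mirna", "trna", "rrna")

    def collection(self, name: str) -> _SubstringIndex:
        return getattr(self, name)

    def find_artifact(self, query: str) -> Optional[str]:
        """Return an artifact ID sharing an 18-mer with the query, or None.

        Ties across artifact sequences resolve to the lexicographically
        smallest ID for determinism.
        """
        n = len(query)
        if n < ARTIFACT_KMER_LEN:
            return None
        best: Optional[str] = None
        for i in range(n - ARTIFACT_KMER_LEN + 1):
            hit = self.artifact_kmers.get(query[i : i + ARTIFACT_KMER_LEN])
            if hit is not None and (best is None or hit < best):
                best = hit
        return best


def build_rnatype_db(
    precursors: Iterable[tuple[str, str]] = (),
    trnas: Iterable[tuple[str, str]] = (),
    rrnas: Iterable[tuple[str, str]] = (),
    artifacts: Iterable[tuple[str, str]] = (),
    species: str = "",
) -> RnaTypeDB:
    """Index the annotation references. Empty collections simply never match."""
    precursors = list(precursors)
    artifact_kmers: dict[str, str] = {}
    for art_id, seq in sorted(artifacts):
        for i in range(len(seq) - ARTIFACT_KMER_LEN + 1):
            kmer = seq[i : i + ARTIFACT_KMER_LEN]
            if kmer not in artifact_kmers or art_id < artifact_kmers[kmer]:
                artifact_kmers[kmer] = art_id
    return RnaTypeDB(
        precursor_mirna=_SubstringIndex(precursors),
        trna=_SubstringIndex(trnas),
        rrna=_SubstringIndex(rrnas),
        artifact_kmers=artifact_kmers,
        species=species,
        n_precursors=len(precursors),
    )


BUNDLE_FILES = {
    "catalog": "clade_catalog.tsv",
    "mature": "mature.fa",
    "precursor": "precursor.fa",
    "trna": "trna.fa",
    "rrna": "rrna.fa",
    "artifacts": "artifacts.fa",
}


def load_reference_bundle(
    directory: str | Path, mode: str = "clade", species: str = ""
) -> tuple[CladeCatalog, RnaTypeDB]:
    """Load a reference bundle directory into both databases.

    The directory layout mirrors a ``reference_databases`` folder:
    clade_catalog.tsv, mature.fa, precursor.fa, trna.fa, rrna.fa,
    artifacts.fa. Missing annotation FASTAs are treated as empty.
    """
    directory = Path(directory)
    catalog = parse_clade_catalog(directory / BUNDLE_FILES["catalog"])
    matures = read_fasta(directory / BUNDLE_FILES["mature"])
    clade_catalog = build_clade_catalog(catalog, matures, mode=mode)

    def optional(name: str) -> list[tuple[str, str]]:
        path = directory / BUNDLE_FILES[name]
        return read_fasta(path) if path.exists() else []

    rnatype_db = build_rnatype_db(
        precursors=optional("precursor"),
        trnas=optional("trna"),
        rrnas=optional("rrna"),
        artifacts=optional("artifacts"),
        species=species,
    )
    return clade_catalog, rnatype_db
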
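"""Streaming FASTQ/FASTA readers and writers, and catalog/config parsing.

All readers are constant-space: they yield one record at a time and sniff
gzip compression from the file's magic bytes, so plain and ``.gz`` inputs
are interchangeable.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

GZIP_MAGIC = b"\x1f\x8b"

#: Valid PHRED encodings (Sanger/Illumina 1.8+ and legacy Illumina 1.3-1.7).
PHRED_OFFSETS = (33, 64)


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records; names the offending record."""


@dataclass
class SequenceRead:
    """One FASTQ record.

    ``seq_index`` is the sample index (barcode) assigned by the sequencer,
    taken from the read header or from a parallel index read.
    """

    read_id: str
    seq: str
    quals: list[int]
    seq_index: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise FastqFormatError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )


@dataclass
class SampleConfig:
    """Per-sample run configuration.

    ``protocol`` selects the adapter-trimming logic: ``truseq_qiaseq``
    (plain 3' adapter), ``nextflex`` (4 randomized bases flanking the
    insert) or ``cats`` (poly-A tailing instead of a ligated adapter).
    ``umi_prefix_len`` random bases are removed from the 5' end before any
    other processing (some single-cell protocols put a UMI there).
    """

    sample_id: str
    adapter: str = ""
    protocol: str = "truseq_qiaseq"
    species: str = ""
    umi_prefix_len: int = 0
    index: Optional[str] = None
    phred_offset: int = 33
    path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protocol not in ("truseq_qiaseq", "nextflex", "cats"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol in ("truseq_qiaseq", "nextflex") and not self.adapter:
            raise ValueError(f"protocol {self.protocol!r} requires an adapter sequence")
        if self.umi_prefix_len < 0:
            raise ValueError("umi_prefix_len must be >= 0")
        if self.phred_offset not in PHRED_OFFSETS:
            raise ValueError(f"phred_offset must be one of {PHRED_OFFSETS}")
        self.adapter = self.adapter.upper().replace("U", "T")


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed text file, sniffing magic bytes."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _index_from_header(header: str) -> Optional[str]:
    """Extract the sample index from a CASAVA-style header.

    Illumina bcl2fastq writes ``@inst:...:pos 1:N:0:ACGTAC``; the index is
    the field after the last ``:`` of the second whitespace token. Returns
    None when the header carries no index-like field.
    """
    parts = header.split()
    if len(parts) < 2 or ":" not in parts[1]:
        return None
    candidate = parts[1].rsplit(":", 1)[1].upper()
    if candidate and all(c in "ACGTN+" for c in candidate):
        return candidate
    return None


def read_fastq(
    path: str | Path,
    phred_offset: int = 33,
    parse_header_index: bool = False,
) -> Iterator[SequenceRead]:
    """Stream SequenceReads from a (possibly gzipped) FASTQ file.

    Sequences are uppercased; qualities decoded with ``phred_offset``.
    Malformed records raise :class:`FastqFormatError` naming the record
    number (1-based).
    """
    if phred_offset not in PHRED_OFFSETS:
        raise ValueError(f"phred_offset must be one of {PHRED_OFFSETS}")
    record_no = 0
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            record_no += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"record {record_no} in {path}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {record_no} in {path}: sequence/quality length mismatch"
                )
            quals = [ord(c) - phred_offset for c in qual]
            if quals and min(quals) < 0:
                raise FastqFormatError(
                    f"record {record_no} in {path}: negative PHRED value "
                    f"(wrong offset {phred_offset}?)"
                )
            seq_index = _index_from_header(title) if parse_header_index else None
            yield SequenceRead(
                read_id=title.split()[0] if title else "",
                seq=seq.upper(),
                quals=quals,
                seq_index=seq_index,
            )


def read_fastq_with_index(
    path: str | Path,
    index_path: str | Path,
    phred_offset: int = 33,
) -> Iterator[SequenceRead]:
    """Stream reads pairing READ 1 with a parallel index-read FASTQ.

    The n-th index read's sequence becomes ``seq_index`` of the n-th main
    read. A length mismatch between the two files is a hard error.
    """
    main = read_fastq(path, phred_offset)
    index = read_fastq(index_path, phred_offset)
    for read in main:
        try:
            idx_read = next(index)
        except StopIteration:
            raise FastqFormatError(
                f"index file {index_path} has fewer records than {path}"
            ) from None
        read.seq_index = idx_read.seq
        yield read
    if next(index, None) is not None:
        raise FastqFormatError(f"index file {index_path} has more records than {path}")


def write_fastq(
    records: Iterable[SequenceRead],
    path: str | Path,
    phred_offset: int = 33,
) -> int:
    """Write records as 4-line FASTQ (gzipped when path ends in .gz).

    A record carrying a ``seq_index`` gets a CASAVA-style header
    (``@id 1:N:0:INDEX``) so the index survives a round trip through
    :func:`read_fastq` with ``parse_header_index=True``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for rec in records:
            qual = "".join(chr(q + phred_offset) for q in rec.quals)
            title = rec.read_id
            if rec.seq_index:
                title = f"{rec.read_id} 1:N:0:{rec.seq_index}"
            out.write(f"@{title}\n{rec.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into ordered (id, sequence) pairs.

    RNA alphabets are converted to DNA (U->T) and sequences uppercased.
    Duplicate IDs are kept with a warning; an empty sequence is an error.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0] if title else ""
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"empty sequence for FASTA record {name!r} in {path}")
            if name in seen:
                warnings.warn(f"duplicate FASTA ID {name!r} in {path}; keeping both")
            seen.add(name)
            records.append((name, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> int:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
            n += 1
    return n


def parse_clade_catalog(path: str | Path) -> dict[str, str]:
    """Parse the TSV catalog mapping miRNA family numbers to clade labels.

    Two tab-separated columns: family number (e.g. ``580`` or ``let-7``)
    and clade label. A header line starting with ``family`` is skipped.
    A family listed under two different clades is a hard error - markers
    must be exclusive to one clade.
    """
    catalog: dict[str, str] = {}
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {line_no} in {path}: expected 2 tab-separated columns")
            family, clade = fields[0].strip(), fields[1].strip()
            if line_no == 1 and family.lower() in ("family", "family_number"):
                continue
            family = canonical_family(family)
            if family in catalog and catalog[family] != clade:
                raise ValueError(
                    f"family {family} listed under two clades "
                    f"({catalog[family]!r} and {clade!r}) in {path}"
                )
            catalog[family] = clade
    return catalog


def canonical_family(token: str) -> str:
    """Canonical family key: plain integers for miR families, ``let-N`` for lets."""
    token = token.strip()
    low = token.lower()
    if low.startswith("let-") or low.startswith("let"):
        digits = "".join(c for c in token if c.isdigit())
        if digits:
            return f"let-{int(digits)}"
    if token.isdigit():
        return str(int(token))
    return token


def load_sample_sheet(path: str | Path) -> list[SampleConfig]:
    """Load sample configurations from a TSV or JSON sample sheet.

    TSV columns: sample_id, path, adapter, protocol, species, index
    (header required; missing optional columns default).
    """
    path = Path(path)
    samples: list[SampleConfig] = []
    if path.suffix == ".json":
        for entry in json.loads(path.read_text()):
            samples.append(SampleConfig(**entry))
        return samples
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        if "sample_id" not in cols:
            raise ValueError(f"sample sheet {path} lacks a 'sample_id' column")
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")

            def get(name: str, default: str = "") -> str:
                i = cols.get(name)
                return fields[i].strip() if i is not None and i < len(fields) else default

            samples.append(
                SampleConfig(
                    sample_id=get("sample_id"),
                    path=get("path") or None,
                    adapter=get("adapter"),
                    protocol=get("protocol") or "truseq_qiaseq",
                    species=get("species"),
                    umi_prefix_len=int(get("umi_prefix_len") or 0),
                    index=get("index") or None,
                    phred_offset=int(get("phred_offset") or 33),
                )
            )
    return samples
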
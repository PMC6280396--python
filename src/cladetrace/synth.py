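"""Synthetic fixtures with known provenance.

Everything the pipeline consumes can be generated here: a reference bundle
(clade catalog, mature/precursor miRNAs, tRNA/rRNA/artifact collections),
per-sample FASTQ reads with protocol-correct adapter decorations, spike-in
mixtures, and multiplexed runs with controlled index-misread and
mis-pairing rates. Each generated read carries a ground-truth record
(source reference, clade, true insert, true index, corruption events) so
every pipeline stage can be scored without re-deriving labels.

Generation is a pure function of its parameters and seed: the same call
produces byte-identical output on any platform. Sequencing errors are
substitution-only, matching the ungapped matching model of the pipeline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import SequenceRead, write_fasta
from .refdb import (
    CladeCatalog,
    RnaTypeDB,
    build_clade_catalog,
    build_rnatype_db,
)

#: Illumina TruSeq small RNA 3' adapter (33 nt), the protocol arithmetic of
#: a 75-cycle run: ~22 nt insert + 33 nt adapter + 6 nt index fits in 61 nt.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

#: TruSeq-style 6-nt sample indices, pairwise Hamming distance >= 3.
DEFAULT_INDICES = (
    "ATCACG", "CGATGT", "TTAGGC", "TGACCA", "ACAGTG", "GCCAAT",
    "CAGATC", "ACTTGA", "GATCAG", "TAGCTT", "GGCTAC", "CTTGTA",
)

#: The 14 animal and plant clades of the default marker world.
DEFAULT_CLADES = (
    "primate", "rodent", "carnivore", "bird", "fish", "amphibian",
    "nematode", "insect", "lophotrochozoan", "echinoderm",
    "eudicot", "monocot", "conifer", "moss",
)

BASES = "ACGT"
_FORBIDDEN_IN_MATURE = (DEFAULT_ADAPTER[:8], "A" * 8)


@dataclass
class ReferenceBundle:
    """In-memory reference bundle; ``write`` lays it out as a directory."""

    catalog: dict[str, str]  # family -> clade
    matures: list[tuple[str, str]]
    precursors: list[tuple[str, str]]
    trnas: list[tuple[str, str]]
    rrnas: list[tuple[str, str]]
    artifacts: list[tuple[str, str]]
    clades: list[str]
    mature_by_clade: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def clade_catalog(self, mode: str = "clade") -> CladeCatalog:
        return build_clade_catalog(self.catalog, self.matures, mode=mode)

    def rnatype_db(self, species: str = "") -> RnaTypeDB:
        return build_rnatype_db(
            precursors=self.precursors,
            trnas=self.trnas,
            rrnas=self.rrnas,
            artifacts=self.artifacts,
            species=species,
        )

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "clade_catalog.tsv", "wt") as out:
            out.write("family_number\tclade\n")
            for family, clade in self.catalog.items():
                out.write(f"{family}\t{clade}\n")
        write_fasta(self.matures, directory / "mature.fa")
        write_fasta(self.precursors, directory / "precursor.fa")
        write_fasta(self.trnas, directory / "trna.fa")
        write_fasta(self.rrnas, directory / "rrna.fa")
        write_fasta(self.artifacts, directory / "artifacts.fa")
        return directory


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(BASES, k=length))


def _mature_ok(seq: str, used_windows: set[str], kmer_len: int = 20) -> bool:
    for bad in _FORBIDDEN_IN_MATURE:
        if bad in seq:
            return False
    windows = {seq[i : i + kmer_len] for i in range(len(seq) - kmer_len + 1)}
    return not (windows & used_windows)


def generate_reference_bundle(
    n_clades: int = 14,
    families_per_clade: int = 24,
    species_per_family: int = 4,
    mature_len: int = 22,
    n_trna: int = 20,
    n_rrna: int = 10,
    n_artifacts: int = 6,
    seed: int = 0,
    clade_names: Optional[Sequence[str]] = None,
) -> ReferenceBundle:
    """Generate a clade-exclusive marker world plus annotation references.

    Each clade gets ``families_per_clade`` miRNA families; a family's
    mature sequence is shared by ``species_per_family`` species of the
    clade (miRNA families are conserved in sequence), under miRBase-style
    IDs whose family numbers realize the catalog. No 20-mer is shared
    between clades, so catalog construction yields zero ambiguity
    exclusions and clade assignment of error-free reads is exact. The
    default sizing (14 x 24 families x 4 species x 22 nt ~ 30k reference
    nt) mirrors the scale of a curated clade-marker catalog.

    Raises RuntimeError when collision-free generation is infeasible for
    the requested volume.
    """
    if min(n_clades, families_per_clade, species_per_family) < 1:
        raise ValueError("n_clades, families_per_clade and species_per_family must be >= 1")
    if mature_len < 20:
        raise ValueError("mature_len must be >= 20 for 20-mer indexing")
    rng = random.Random(seed)
    if clade_names is None:
        if n_clades <= len(DEFAULT_CLADES):
            clade_names = DEFAULT_CLADES[:n_clades]
        else:
            clade_names = [f"clade{i:02d}" for i in range(n_clades)]
    elif len(clade_names) != n_clades:
        raise ValueError("clade_names length must equal n_clades")

    catalog: dict[str, str] = {}
    matures: list[tuple[str, str]] = []
    precursors: list[tuple[str, str]] = []
    mature_by_clade: dict[str, list[tuple[str, str]]] = {c: [] for c in clade_names}
    used_windows: set[str] = set()
    family_number = 100
    # Synthetic miRBase-style species prefixes: three letters per species.
    alphabet = "abcdefghijklmnopqrstuvwxyz"

    for ci, clade in enumerate(clade_names):
        prefixes = [
            alphabet[ci % 26] + alphabet[(ci // 26) % 26] + alphabet[s % 26]
            for s in range(species_per_family)
        ]
        for _ in range(families_per_clade):
            for attempt in range(1000):
                seq = _random_seq(rng, mature_len)
                if _mature_ok(seq, used_windows):
                    break
            else:
                raise RuntimeError(
                    "could not generate collision-free marker sequences; "
                    "requested volume is too large for the 20-mer space"
                )
            used_windows.update(
                seq[i : i + 20] for i in range(len(seq) - 20 + 1)
            )
            catalog[str(family_number)] = clade
            for si, prefix in enumerate(prefixes):
                arm = "-5p" if si % 2 == 0 else "-3p"
                ref_id = f"{prefix}-miR-{family_number}{arm}"
                matures.append((ref_id, seq))
                mature_by_clade[clade].append((ref_id, seq))
            # One hairpin per family: flanks + mature embedded verbatim.
            hairpin = _random_seq(rng, 15) + seq + _random_seq(rng, 25)
            precursors.append((f"{prefixes[0]}-mir-{family_number}", hairpin))
            family_number += 1

    trnas = [(f"trna-{i:03d}", _random_seq(rng, 75)) for i in range(n_trna)]
    rrnas = [(f"rrna-{i:03d}", _random_seq(rng, 120)) for i in range(n_rrna)]
    artifacts = [(f"artifact-{i:02d}", _random_seq(rng, 50)) for i in range(n_artifacts)]
    return ReferenceBundle(
        catalog=catalog,
        matures=matures,
        precursors=precursors,
        trnas=trnas,
        rrnas=rrnas,
        artifacts=artifacts,
        clades=list(clade_names),
        mature_by_clade=mature_by_clade,
    )


@dataclass
class SynthSpec:
    """Parameters of one synthetic sample.

    Defaults state a typical modern small-RNA run: 75-cycle single-end
    reads, TruSeq-style ligation adapter, insert lengths peaked at 22 nt
    (the canonical mature miRNA length), PHRED ~36, and a 0.1% per-base
    substitution error rate.
    """

    seed: int = 0
    n_reads: int = 10_000
    insert_length_distribution: dict[int, float] = field(
        default_factory=lambda: {20: 0.1, 21: 0.2, 22: 0.7}
    )
    per_base_error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    protocol: str = "truseq_qiaseq"
    read_length: int = 75
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    umi_prefix_len: int = 0
    index: Optional[str] = None
    index_misread_rate: float = 0.0
    mispair_rate: float = 0.0
    clade: Optional[str] = None

    def __post_init__(self) -> None:
        total = sum(self.insert_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("insert_length_distribution must sum to 1")
        for p in (self.per_base_error_rate, self.index_misread_rate, self.mispair_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")


@dataclass
class GroundTruth:
    """Provenance of one generated read."""

    read_id: str
    source_ref: Optional[str]
    clade: Optional[str]
    insert: str
    true_index: Optional[str] = None
    events: list[str] = field(default_factory=list)


def _qualities(rng_np: np.random.Generator, n: int, length: int, mean: float, sd: float) -> np.ndarray:
    quals = np.rint(rng_np.normal(mean, sd, size=(n, length))).astype(np.int64)
    return np.clip(quals, 2, 41)


def generate_sample(
    spec: SynthSpec,
    bundle: ReferenceBundle,
    clade: Optional[str] = None,
    id_prefix: str = "r",
) -> tuple[list[SequenceRead], list[GroundTruth]]:
    """Generate reads whose inserts are drawn from one clade's markers.

    Read layout per protocol (before truncation to ``read_length``):

    * truseq_qiaseq: [UMI] + insert + adapter + index + random filler
    * nextflex:      4 random + insert + 4 random + adapter + index + filler
    * cats:          3 random + insert + poly-A tail

    Substitution errors are applied uniformly over the final read at
    ``per_base_error_rate`` and recorded in the ground truth.
    """
    clade = clade or spec.clade
    if clade is None or clade not in bundle.mature_by_clade:
        raise ValueError(f"unknown clade {clade!r}")
    pool = bundle.mature_by_clade[clade]
    if not pool:
        raise ValueError(f"no marker sequences for clade {clade!r}")
    rng = random.Random(spec.seed)
    rng_np = np.random.default_rng(spec.seed)

    lengths = sorted(spec.insert_length_distribution)
    weights = [spec.insert_length_distribution[l] for l in lengths]
    qual_matrix = _qualities(rng_np, spec.n_reads, spec.read_length, spec.quality_mean, spec.quality_sd)

    reads: list[SequenceRead] = []
    truths: list[GroundTruth] = []
    index = spec.index or ""
    for i in range(spec.n_reads):
        ref_id, mature = rng.choice(pool)
        ins_len = rng.choices(lengths, weights)[0]
        insert = mature[: min(ins_len, len(mature))]
        if spec.protocol == "truseq_qiaseq":
            body = insert + spec.adapter + index
        elif spec.protocol == "nextflex":
            body = _random_seq(rng, 4) + insert + _random_seq(rng, 4) + spec.adapter + index
        elif spec.protocol == "cats":
            body = _random_seq(rng, 3) + insert + "A" * spec.read_length
        else:
            raise ValueError(f"unknown protocol {spec.protocol!r}")
        umi = _random_seq(rng, spec.umi_prefix_len) if spec.umi_prefix_len else ""
        full = umi + body
        if len(full) < spec.read_length:
            full += _random_seq(rng, spec.read_length - len(full))
        full = full[: spec.read_length]

        events: list[str] = []
        if spec.per_base_error_rate > 0:
            chars = list(full)
            for pos in range(len(chars)):
                if rng.random() < spec.per_base_error_rate:
                    chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
                    events.append(f"subst@{pos}")
            full = "".join(chars)

        read_id = f"{id_prefix}{i:07d}"
        reads.append(
            SequenceRead(
                read_id=read_id,
                seq=full,
                quals=qual_matrix[i].tolist(),
                seq_index=spec.index,
            )
        )
        truths.append(
            GroundTruth(
                read_id=read_id,
                source_ref=ref_id,
                clade=clade,
                insert=insert,
                true_index=spec.index,
                events=events,
            )
        )
    return reads, truths


def spike_mix(
    host: Sequence[SequenceRead],
    contaminant: Sequence[SequenceRead],
    fraction: float,
    total_n: int,
    seed: int = 0,
) -> tuple[list[SequenceRead], list[bool]]:
    """Mix contaminant reads into host reads at a controlled fraction.

    Takes round(fraction * total_n) contaminant reads and the remainder
    from the host, both subsampled without replacement, and shuffles the
    union deterministically. Returns the mixture and a parallel
    is-contaminant mask. Insufficient source reads raise ValueError.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_cont = round(fraction * total_n)
    n_host = total_n - n_cont
    if n_cont > len(contaminant):
        raise ValueError(f"need {n_cont} contaminant reads, have {len(contaminant)}")
    if n_host > len(host):
        raise ValueError(f"need {n_host} host reads, have {len(host)}")
    rng = random.Random(seed)
    picked_host = rng.sample(range(len(host)), n_host)
    picked_cont = rng.sample(range(len(contaminant)), n_cont)
    mixture = [(host[i], False) for i in picked_host] + [
        (contaminant[i], True) for i in picked_cont
    ]
    rng.shuffle(mixture)
    return [r for r, _ in mixture], [c for _, c in mixture]


def generate_multiplexed_run(
    specs: Sequence[SynthSpec],
    bundle: ReferenceBundle,
    index_misread_rate: float = 0.0,
    mispair_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRead], list[GroundTruth]]:
    """Simulate a multiplexed flow cell with index corruption.

    Every spec must define a distinct ``index`` and a ``clade``. Each
    read's sequencer-assigned index (``seq_index``) starts as its true
    index; with probability ``mispair_rate`` it is replaced by another
    sample's index (a mis-pairing: the inline copy inside the read stays
    true), otherwise each of its bases is misread with probability
    ``index_misread_rate``. All corruptions are recorded as ground-truth
    events (``mispair`` / ``index_misread@pos``). Reads are interleaved
    deterministically by seed.
    """
    indices = [s.index for s in specs]
    if None in indices or len(set(indices)) != len(indices):
        raise ValueError("every sample spec must define a distinct index")
    if any(s.clade is None for s in specs):
        raise ValueError("every sample spec must define a clade")
    rng = random.Random(seed)
    merged: list[tuple[SequenceRead, GroundTruth]] = []
    for si, spec in enumerate(specs):
        reads, truths = generate_sample(spec, bundle, id_prefix=f"s{si}_r")
        other_indices = [idx for idx in indices if idx != spec.index]
        for read, truth in zip(reads, truths):
            if mispair_rate > 0 and rng.random() < mispair_rate:
                read.seq_index = rng.choice(other_indices)
                truth.events.append("mispair")
            elif index_misread_rate > 0:
                chars = list(read.seq_index)
                for pos in range(len(chars)):
                    if rng.random() < index_misread_rate:
                        chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
                        truth.events.append(f"index_misread@{pos}")
                read.seq_index = "".join(chars)
            merged.append((read, truth))
    rng.shuffle(merged)
    return [r for r, _ in merged], [t for _, t in merged]


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    """Serialize ground truth as TSV (events joined by commas)."""
    with open(path, "wt") as out:
        out.write("read_id\tsource_ref\tclade\tinsert\ttrue_index\tevents\n")
        for t in truths:
            out.write(
                f"{t.read_id}\t{t.source_ref or ''}\t{t.clade or ''}\t{t.insert}\t"
                f"{t.true_index or ''}\t{','.join(t.events)}\n"
            )
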
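"""RNA-type annotation of QC-passed reads, and the miRNA complexity curve.

Annotation is a prioritized cascade: a read is first aligned, as an
ungapped substring with no mismatches, to miRNA precursors, then tRNAs,
then rRNAs; only if all three fail is the cascade repeated allowing one
substitution. Reads still unmatched are compared against sequencing
artifact sequences (an 18-nt stretch of identity suffices); the rest are
"unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .refdb import RnaTypeDB

RNA_TYPES = ("mirna", "trna", "rrna", "artifact", "unknown")

_COLLECTION_TYPE = {"precursor_mirna": "mirna", "trna": "trna", "rrna": "rrna"}


@dataclass(frozen=True)
class RnaAnnotation:
    rna_type: str
    matched_reference_id: Optional[str] = None
    mismatches_used: Optional[int] = None  # None for artifact/unknown

    def __post_init__(self) -> None:
        assert (self.matched_reference_id is not None) == (self.rna_type != "unknown")


def classify_rna_type(insert: str, db: RnaTypeDB) -> RnaAnnotation:
    """Classify one insert through the 0-then-1-mismatch cascade.

    The zero-mismatch pass over all three collections completes before the
    one-mismatch pass starts, so an exact rRNA hit beats a one-mismatch
    precursor hit. Classification depends only on (insert, db).
    """
    for mismatches in (0, 1):
        for name in RnaTypeDB.COLLECTIONS:
            hit = db.collection(name).find(insert, max_mismatches=mismatches)
            if hit is not None:
                return RnaAnnotation(_COLLECTION_TYPE[name], hit, mismatches)
    artifact = db.find_artifact(insert)
    if artifact is not None:
        return RnaAnnotation("artifact", artifact)
    return RnaAnnotation("unknown")


@dataclass
class ComplexityCurve:
    """Cumulative distinct miRNA precursors vs raw sequencing depth.

    Depths count processed raw reads (QC-passed or not); the distinct
    count covers precursors hit by miRNA-annotated reads so far. More
    distinct precursors at a given depth means a more complex library.
    """

    checkpoints: list[tuple[int, int]] = field(default_factory=list)

    @property
    def final_distinct(self) -> int:
        return self.checkpoints[-1][1] if self.checkpoints else 0


DEFAULT_CHECKPOINT_STEP = 10_000


def complexity_curve(
    precursor_hits: Iterable[Optional[str]],
    checkpoint_step: int = DEFAULT_CHECKPOINT_STEP,
) -> ComplexityCurve:
    """Accumulate the complexity curve from a per-raw-read hit stream.

    ``precursor_hits`` yields, for every processed raw read in input
    order, the matched precursor ID when the read was annotated as miRNA,
    else None. A checkpoint is recorded every ``checkpoint_step`` raw
    reads and at end of stream.
    """
    if checkpoint_step < 1:
        raise ValueError("checkpoint_step must be >= 1")
    curve = ComplexityCurve()
    seen: set[str] = set()
    depth = 0
    for hit in precursor_hits:
        depth += 1
        if hit is not None:
            seen.add(hit)
        if depth % checkpoint_step == 0:
            curve.checkpoints.append((depth, len(seen)))
    if depth == 0 or depth % checkpoint_step != 0:
        curve.checkpoints.append((depth, len(seen)))
    return curve
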
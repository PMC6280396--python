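"""Run orchestration and reporting.

Two run modes are provided. *QC mode* runs the full per-sample flow -
pre-processing, RNA-type annotation, complexity accumulation, clade
tracing, flag evaluation - and renders six report panels (PHRED score
distribution, read length distribution, QC statistics, RNA type, miRNA
complexity, contamination) into a single self-contained HTML file plus
per-panel TSVs and a machine-readable JSON summary. *Trace mode* runs
only pre-processing and clade tracing.

Every number rendered in a figure is also written to a TSV or the JSON
summary: figures are views, never the only record.
"""

from __future__ import annotations

import base64
import io as _io
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .annotate import ComplexityCurve, classify_rna_type, complexity_curve, RNA_TYPES
from .io import SampleConfig, SequenceRead, read_fastq
from .preprocess import (
    DISCARD_REASONS,
    STATUS_ADAPTER_FOUND,
    STATUS_ADAPTER_UNRECOGNIZED,
    preprocess_read,
)
from .refdb import CladeCatalog, RnaTypeDB
from .stats import qc_flags
from .trace import CladeProfile, assign_clade, build_clade_profile

#: Fixed 14-clade palette: one stable color per clade label, so the same
#: clade is always drawn in the same color across reports.
CLADE_COLORS = plt.get_cmap("tab20").colors


@dataclass
class SampleSummary:
    """All per-sample accumulators produced by a QC or trace run."""

    sample_id: str
    n_input_reads: int = 0
    phred_histogram: dict[int, int] = field(default_factory=dict)
    length_histogram: dict[int, int] = field(default_factory=dict)
    qc_category_counts: dict[str, int] = field(default_factory=dict)
    rna_type_counts: dict[str, int] = field(default_factory=dict)
    complexity_curve: Optional[ComplexityCurve] = None
    clade_profile: Optional[CladeProfile] = None
    flags: list[str] = field(default_factory=list)
    failed: bool = False
    error: Optional[str] = None

    @property
    def qc_passed_reads(self) -> int:
        return self.qc_category_counts.get(STATUS_ADAPTER_FOUND, 0) + self.qc_category_counts.get(
            STATUS_ADAPTER_UNRECOGNIZED, 0
        )


def summarize_sample(
    reads: Iterable[SequenceRead],
    cfg: SampleConfig,
    catalog: CladeCatalog,
    rnatype_db: Optional[RnaTypeDB] = None,
    checkpoint_step: int = 10_000,
    total_known_precursors: Optional[int] = None,
    annotate: bool = True,
) -> SampleSummary:
    """Stream one sample through the pipeline, accumulating the summary.

    With ``annotate=False`` (trace mode) RNA typing, the complexity curve
    and the QC flags are skipped. The PHRED histogram bins reads by their
    mean PHRED score (rounded); the length histogram records the
    post-trimming insert length of every read that survived the quality
    filter - zero-length entries are adapter dimers, lengths above 50
    indicate an unrecognized adapter.
    """
    summary = SampleSummary(sample_id=cfg.sample_id)
    phred: Counter[int] = Counter()
    lengths: Counter[int] = Counter()
    categories: Counter[str] = Counter()
    rna_types: Counter[str] = Counter()
    precursor_hits: list[Optional[str]] = []
    inserts: list[str] = []

    do_annotate = annotate and rnatype_db is not None
    for read in reads:
        summary.n_input_reads += 1
        if read.quals:
            phred[round(sum(read.quals) / len(read.quals))] += 1
        processed = preprocess_read(read, cfg)
        if processed.status == "discarded":
            categories[processed.discard_reason] += 1
            if processed.discard_reason != "low_quality":
                lengths[len(processed.insert)] += 1
            if do_annotate:
                precursor_hits.append(None)
            continue
        categories[processed.status] += 1
        lengths[len(processed.insert)] += 1
        inserts.append(processed.insert)
        if do_annotate:
            annotation = classify_rna_type(processed.insert, rnatype_db)
            rna_types[annotation.rna_type] += 1
            precursor_hits.append(
                annotation.matched_reference_id if annotation.rna_type == "mirna" else None
            )

    summary.phred_histogram = dict(sorted(phred.items()))
    summary.length_histogram = dict(sorted(lengths.items()))
    summary.qc_category_counts = dict(categories)
    summary.clade_profile = build_clade_profile(inserts, catalog)
    if do_annotate:
        summary.rna_type_counts = {t: rna_types.get(t, 0) for t in RNA_TYPES}
        summary.complexity_curve = complexity_curve(precursor_hits, checkpoint_step)
        known = total_known_precursors
        if known is None:
            known = rnatype_db.n_precursors
        summary.flags = qc_flags(
            length_histogram=summary.length_histogram,
            qc_passed_reads=summary.qc_passed_reads,
            mirna_reads=summary.rna_type_counts.get("mirna", 0),
            distinct_precursors=summary.complexity_curve.final_distinct,
            total_known_precursors=known,
        )
    return summary


def _sample_reads(cfg: SampleConfig) -> Iterable[SequenceRead]:
    if cfg.path is None:
        raise ValueError(f"sample {cfg.sample_id!r} has no FASTQ path")
    return read_fastq(cfg.path, phred_offset=cfg.phred_offset)


def run_qc(
    samples: list[SampleConfig],
    catalog: CladeCatalog,
    rnatype_db: RnaTypeDB,
    out_dir: str | Path,
    checkpoint_step: int = 10_000,
    reads_by_sample: Optional[dict[str, Iterable[SequenceRead]]] = None,
) -> list[SampleSummary]:
    """QC mode: full pipeline for every sample plus report files.

    ``reads_by_sample`` allows in-memory read streams to stand in for the
    per-sample FASTQ paths. A sample whose FASTQ cannot be read is marked
    failed and the run continues.
    """
    summaries: list[SampleSummary] = []
    for cfg in samples:
        try:
            reads = (
                reads_by_sample[cfg.sample_id]
                if reads_by_sample is not None
                else _sample_reads(cfg)
            )
            summaries.append(
                summarize_sample(reads, cfg, catalog, rnatype_db, checkpoint_step)
            )
        except (OSError, ValueError) as exc:
            failed = SampleSummary(sample_id=cfg.sample_id, failed=True, error=str(exc))
            summaries.append(failed)
    write_report(summaries, catalog, Path(out_dir), mode="qc")
    return summaries


def run_trace(
    samples: list[SampleConfig],
    catalog: CladeCatalog,
    out_dir: str | Path,
    reads_by_sample: Optional[dict[str, Iterable[SequenceRead]]] = None,
) -> list[SampleSummary]:
    """Trace mode: pre-processing and clade composition only."""
    summaries: list[SampleSummary] = []
    for cfg in samples:
        try:
            reads = (
                reads_by_sample[cfg.sample_id]
                if reads_by_sample is not None
                else _sample_reads(cfg)
            )
            summaries.append(summarize_sample(reads, cfg, catalog, annotate=False))
        except (OSError, ValueError) as exc:
            summaries.append(SampleSummary(sample_id=cfg.sample_id, failed=True, error=str(exc)))
    write_report(summaries, catalog, Path(out_dir), mode="trace")
    return summaries


# --- serialization ------------------------------------------------------


def summary_to_dict(summary: SampleSummary) -> dict:
    data = {
        "sample_id": summary.sample_id,
        "failed": summary.failed,
        "error": summary.error,
        "n_input_reads": summary.n_input_reads,
        "qc_passed_reads": summary.qc_passed_reads,
        "phred_histogram": summary.phred_histogram,
        "length_histogram": summary.length_histogram,
        "qc_category_counts": summary.qc_category_counts,
        "rna_type_counts": summary.rna_type_counts,
        "flags": summary.flags,
    }
    if summary.complexity_curve is not None:
        data["complexity_curve"] = summary.complexity_curve.checkpoints
    if summary.clade_profile is not None:
        data["clade_read_counts"] = summary.clade_profile.read_counts
        data["clade_unique_sequence_counts"] = summary.clade_profile.unique_sequence_counts
        data["unassigned_reads"] = summary.clade_profile.unassigned_reads
    return data


def _clade_table(summaries: list[SampleSummary], catalog: CladeCatalog, which: str) -> pd.DataFrame:
    rows = {}
    for s in summaries:
        profile = s.clade_profile or CladeProfile()
        source = profile.read_counts if which == "reads" else profile.unique_sequence_counts
        rows[s.sample_id] = {clade: source.get(clade, 0) for clade in catalog.clades}
    return pd.DataFrame(rows).T.rename_axis("sample")


def write_tables(summaries: list[SampleSummary], catalog: CladeCatalog, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _clade_table(summaries, catalog, "reads").to_csv(out_dir / "clade_read_counts.tsv", sep="\t")
    _clade_table(summaries, catalog, "unique").to_csv(
        out_dir / "clade_unique_sequence_counts.tsv", sep="\t"
    )
    qc_rows = []
    for s in summaries:
        row = {"sample": s.sample_id, "input_reads": s.n_input_reads}
        for key in (STATUS_ADAPTER_FOUND, STATUS_ADAPTER_UNRECOGNIZED) + DISCARD_REASONS:
            row[key] = s.qc_category_counts.get(key, 0)
        qc_rows.append(row)
    pd.DataFrame(qc_rows).to_csv(out_dir / "qc_statistics.tsv", sep="\t", index=False)
    if any(s.rna_type_counts for s in summaries):
        pd.DataFrame(
            [{"sample": s.sample_id, **{t: s.rna_type_counts.get(t, 0) for t in RNA_TYPES}} for s in summaries]
        ).to_csv(out_dir / "rna_type_counts.tsv", sep="\t", index=False)
    length_rows = []
    for s in summaries:
        for length, count in s.length_histogram.items():
            length_rows.append({"sample": s.sample_id, "insert_length": length, "reads": count})
    pd.DataFrame(length_rows).to_csv(out_dir / "length_distribution.tsv", sep="\t", index=False)


def _fig_to_base64(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _panel_phred(summaries):
    fig, ax = plt.subplots(figsize=(6, 3))
    for s in summaries:
        if s.phred_histogram:
            xs = sorted(s.phred_histogram)
            ax.plot(xs, [s.phred_histogram[x] for x in xs], label=s.sample_id)
    ax.set_xlabel("mean PHRED score")
    ax.set_ylabel("reads")
    ax.set_title("PHRED score distribution")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=6)
    return fig


def _panel_lengths(summaries):
    fig, ax = plt.subplots(figsize=(6, 3))
    for s in summaries:
        if s.length_histogram:
            xs = sorted(s.length_histogram)
            ax.plot(xs, [s.length_histogram[x] for x in xs], label=s.sample_id)
    ax.set_xlabel("insert length (nt)")
    ax.set_ylabel("reads")
    ax.set_title("Read length distribution")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=6)
    return fig


def _panel_stacked(summaries, keys, values_fn, title, colors=None):
    fig, ax = plt.subplots(figsize=(6, 3))
    bottoms = [0.0] * len(summaries)
    xs = range(len(summaries))
    for ki, key in enumerate(keys):
        heights = [values_fn(s).get(key, 0) for s in summaries]
        color = colors[ki % len(colors)] if colors else None
        ax.bar(xs, heights, bottom=bottoms, label=key, color=color)
        bottoms = [b + h for b, h in zip(bottoms, heights)]
    ax.set_xticks(list(xs))
    ax.set_xticklabels([s.sample_id for s in summaries], rotation=45, ha="right", fontsize=6)
    ax.set_ylabel("reads")
    ax.set_title(title)
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=6)
    return fig


def _panel_complexity(summaries):
    fig, ax = plt.subplots(figsize=(6, 3))
    for s in summaries:
        if s.complexity_curve and s.complexity_curve.checkpoints:
            xs, ys = zip(*s.complexity_curve.checkpoints)
            ax.plot(xs, ys, label=s.sample_id, marker=".")
    ax.set_xlabel("raw read depth")
    ax.set_ylabel("distinct precursors")
    ax.set_title("miRNA complexity")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=6)
    return fig


def write_report(
    summaries: list[SampleSummary],
    catalog: CladeCatalog,
    out_dir: Path,
    mode: str = "qc",
) -> Path:
    """Write summary.json, the per-panel TSVs and the self-contained HTML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tables(summaries, catalog, out_dir)
    with open(out_dir / "summary.json", "wt") as out:
        json.dump([summary_to_dict(s) for s in summaries], out, indent=1)

    ok = [s for s in summaries if not s.failed]
    panels: list[tuple[str, str]] = []
    if ok:
        panels.append(("PHRED score distribution", _fig_to_base64(_panel_phred(ok))))
        panels.append(("Read length distribution", _fig_to_base64(_panel_lengths(ok))))
        panels.append(
            (
                "Quality control statistics",
                _fig_to_base64(
                    _panel_stacked(
                        ok,
                        (STATUS_ADAPTER_FOUND, STATUS_ADAPTER_UNRECOGNIZED) + DISCARD_REASONS,
                        lambda s: s.qc_category_counts,
                        "Quality control statistics",
                    )
                ),
            )
        )
        if mode == "qc":
            panels.append(
                (
                    "RNA type",
                    _fig_to_base64(
                        _panel_stacked(ok, RNA_TYPES, lambda s: s.rna_type_counts, "RNA type")
                    ),
                )
            )
            panels.append(("miRNA complexity", _fig_to_base64(_panel_complexity(ok))))
        contamination = _fig_to_base64(
            _panel_stacked(
                ok,
                tuple(catalog.clades),
                lambda s: (s.clade_profile.read_counts if s.clade_profile else {}),
                "Clade-specific miRNAs" if mode == "trace" else "Contamination",
                colors=CLADE_COLORS,
            )
        )
        panels.append(("Contamination" if mode == "qc" else "Clade composition", contamination))

    rows = []
    for s in summaries:
        note = "FAILED: " + (s.error or "") if s.failed else (", ".join(s.flags) or "-")
        profile = s.clade_profile
        if profile is not None and profile.total_clade_specific_reads == 0 and not s.failed:
            note += " [no clade-specific reads]"
        rows.append(
            f"<tr><td>{s.sample_id}</td><td>{s.n_input_reads}</td>"
            f"<td>{s.qc_passed_reads}</td><td>{note}</td></tr>"
        )
    imgs = "\n".join(
        f"<h2>{title}</h2><img src='data:image/png;base64,{b64}'/>" for title, b64 in panels
    )
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>small RNA-seq report</title>"
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px}</style></head><body>"
        f"<h1>Small RNA-seq {'quality control' if mode == 'qc' else 'trace'} report</h1>"
        "<table><tr><th>sample</th><th>input reads</th><th>QC-passed</th><th>flags</th></tr>"
        + "".join(rows)
        + "</table>"
        + imgs
        + "</body></html>"
    )
    report_path = out_dir / "report.html"
    report_path.write_text(html)
    return report_path
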
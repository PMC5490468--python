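"""Batch comparison of one sequence pair under many matrix configurations.

One alignment is computed per config; scores, the four percent identities,
per-column annotation and search results are collected into a
:class:`ComparisonReport`, together with per-metric rankings and min-max
normalized values (the machine-readable counterpart of a sorted blue-to-red
overview bar).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Union

from . import __version__
from .align import Alignment, AlignmentMode, align_pair
from .errors import AlignmentError, InputError, ReportError
from .matrices import MatrixConfig
from .metrics import AlignmentColumn, PIDSet, annotate_columns, pid_set
from .search import IndelRecord, MatchRegion, find_indels, find_match_regions
from .seqio import ProteinSequence

RANK_KEYS = ("score", "pid1", "pid2", "pid3", "pid4")


@dataclass(frozen=True)
class ConfigResult:
    """Everything computed for one matrix configuration."""

    label: str
    matrix_label: str
    gap_open: float
    gap_extend: float
    score: float
    pids: PIDSet
    alignment: Alignment
    columns: List[AlignmentColumn]
    indels: List[IndelRecord]
    match_regions: List[MatchRegion]

    def value(self, key: str) -> float:
        if key == "score":
            return self.score
        if key in RANK_KEYS:
            return self.pids.get(int(key[-1]))
        raise InputError(f"unknown ranking key {key!r}; expected one of {RANK_KEYS}")


@dataclass
class ComparisonReport:
    meta: Dict[str, str]
    results: List[ConfigResult]
    rankings: Dict[str, List[str]] = field(default_factory=dict)
    normalized: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def result(self, label: str) -> ConfigResult:
        for r in self.results:
            if r.label == label:
                return r
        raise InputError(f"no config labelled {label!r} in report")


def normalize_values(values: Sequence[float]) -> List[float]:
    """Min-max normalize to [0, 1]; all-equal inputs map to 0.5 each."""
    values = list(values)
    if not values:
        raise InputError("normalize_values: empty value list")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.5] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rank_configs(report: ComparisonReport, key: str) -> List[str]:
    """Config labels sorted descending by ``key``, ties lexicographic."""
    if key not in RANK_KEYS:
        raise InputError(f"unknown ranking key {key!r}; expected one of {RANK_KEYS}")
    return [
        r.label
        for r in sorted(report.results, key=lambda r: (-r.value(key), r.label))
    ]


def run_comparison(
    pattern: ProteinSequence,
    subject: ProteinSequence,
    configs: Sequence[MatrixConfig],
    mode: Union[AlignmentMode, str],
    *,
    lenient: bool = False,
) -> ComparisonReport:
    """Align one pattern/subject pair once per config and assemble the report."""
    mode = AlignmentMode.parse(mode)
    if not configs:
        raise InputError("run_comparison requires at least one matrix config")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise InputError(f"config labels must be unique; got {labels}")

    results: List[ConfigResult] = []
    for config in configs:
        try:
            alignment = align_pair(pattern, subject, config, mode, lenient=lenient)
            pids = pid_set(alignment)
            columns = annotate_columns(alignment, config.matrix, lenient=lenient)
            indels = find_indels(alignment)
            regions = find_match_regions(alignment)
        except AlignmentError:
            raise
        except Exception as exc:
            raise AlignmentError(f"config {config.label}: {exc}") from exc
        results.append(
            ConfigResult(
                label=config.label,
                matrix_label=config.matrix.label,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
                score=alignment.score,
                pids=pids,
                alignment=alignment,
                columns=columns,
                indels=indels,
                match_regions=regions,
            )
        )

    meta = {
        "pattern_id": pattern.id,
        "subject_id": subject.id,
        "pattern_length": len(pattern),
        "subject_length": len(subject),
        "mode": mode.value,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "tool_version": __version__,
    }
    report = ComparisonReport(meta=meta, results=results)
    for key in RANK_KEYS:
        report.rankings[key] = rank_configs(report, key)
        norm = normalize_values([r.value(key) for r in results])
        report.normalized[key] = {r.label: v for r, v in zip(results, norm)}
    return report


def column_histogram(report: ComparisonReport, position: int) -> Dict[str, int]:
    """Character counts (pattern and subject rows) at one alignment column
    across all configs; alignments shorter than ``position`` contribute
    nothing."""
    if position < 1:
        raise InputError(f"position must be >= 1, got {position}")
    counts: Counter = Counter()
    for r in report.results:
        if len(r.alignment) >= position:
            counts[r.alignment.aligned_pattern[position - 1]] += 1
            counts[r.alignment.aligned_subject[position - 1]] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# Serialization


def _result_to_dict(r: ConfigResult) -> dict:
    return {
        "label": r.label,
        "matrix": r.matrix_label,
        "gap_open": r.gap_open,
        "gap_extend": r.gap_extend,
        "score": r.score,
        "pid": r.pids.as_dict(),
        "alignment": {
            "pattern": r.alignment.aligned_pattern,
            "subject": r.alignment.aligned_subject,
            "pattern_range": list(r.alignment.pattern_range)
            if r.alignment.pattern_range
            else None,
            "subject_range": list(r.alignment.subject_range)
            if r.alignment.subject_range
            else None,
        },
        "columns": [
            {
                "position": c.position,
                "pattern": c.pattern_char,
                "subject": c.subject_char,
                "log_odds": c.log_odds,
                "conservation": c.conservation.value,
                "is_identity": c.is_identity,
                "is_indel": c.is_indel,
            }
            for c in r.columns
        ],
        "indels": [dataclasses.asdict(i) for i in r.indels],
        "match_regions": [[m.start, m.end] for m in r.match_regions],
    }


def report_to_dict(report: ComparisonReport) -> dict:
    return {
        "meta": report.meta,
        "configs": [_result_to_dict(r) for r in report.results],
        "rankings": report.rankings,
        "normalized": report.normalized,
    }


def _blue_red(t: float) -> str:
    """Linear blue (0) to red (1) hex color."""
    t = min(1.0, max(0.0, t))
    r = round(255 * t)
    b = round(255 * (1.0 - t))
    return f"#{r:02x}00{b:02x}"


def _render_tsv(report: ComparisonReport) -> str:
    header = "label\tmatrix\tgap_open\tgap_extend\tscore\tpid1\tpid2\tpid3\tpid4"
    rows = [header]
    for r in report.results:
        pids = "\t".join(f"{r.pids.get(t):.2f}" for t in (1, 2, 3, 4))
        rows.append(
            f"{r.label}\t{r.matrix_label}\t{r.gap_open:g}\t{r.gap_extend:g}"
            f"\t{r.score:g}\t{pids}"
        )
    return "\n".join(rows) + "\n"


def _render_html(report: ComparisonReport) -> str:
    meta = report.meta
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>pairsub comparison</title>"
        "<style>body{font-family:sans-serif}td,th{padding:3px 8px;"
        "border:1px solid #ccc}table{border-collapse:collapse;margin:1em 0}"
        ".cell{color:#fff;text-align:center}</style></head><body>",
        f"<h1>Alignment comparison: {meta['pattern_id']} vs {meta['subject_id']}"
        f" ({meta['mode']})</h1>",
    ]
    # Overview: one row per metric, cells ordered by ranking, colored by
    # normalized value (blue = lowest, red = highest).
    parts.append("<h2>Overview</h2><table>")
    for key in RANK_KEYS:
        cells = []
        for label in report.rankings[key]:
            t = report.normalized[key][label]
            cells.append(
                f"<td class='cell overview-{key}' style='background:{_blue_red(t)}'>"
                f"{label}</td>"
            )
        parts.append(f"<tr><th>{key}</th>{''.join(cells)}</tr>")
    parts.append("</table>")

    parts.append(
        "<h2>Per-config details</h2><table><tr><th>label</th><th>matrix</th>"
        "<th>gap open</th><th>gap extend</th><th>score</th>"
        "<th>PID1</th><th>PID2</th><th>PID3</th><th>PID4</th></tr>"
    )
    for r in report.results:
        pid_cells = "".join(f"<td>{r.pids.get(t):.2f}</td>" for t in (1, 2, 3, 4))
        parts.append(
            f"<tr><td>{r.label}</td><td>{r.matrix_label}</td><td>{r.gap_open:g}</td>"
            f"<td>{r.gap_extend:g}</td><td>{r.score:g}</td>{pid_cells}</tr>"
        )
    parts.append("</table>")

    parts.append("<h2>Alignments</h2>")
    for r in report.results:
        parts.append(
            f"<h3>{r.label}</h3><pre>pattern  {r.alignment.aligned_pattern}\n"
            f"subject  {r.alignment.aligned_subject}</pre>"
        )
    parts.append("</body></html>")
    return "".join(parts)


def write_report(
    report: ComparisonReport,
    format: str,
    dest: Union[str, "os.PathLike[str]"],
) -> None:
    """Serialize the report as ``json`` (full), ``tsv`` (summary) or ``html``."""
    if format == "json":
        text = json.dumps(report_to_dict(report), indent=2) + "\n"
    elif format == "tsv":
        text = _render_tsv(report)
    elif format == "html":
        text = _render_html(report)
    else:
        raise ReportError(f"unknown report format {format!r}; use json, tsv or html")
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write(text)
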
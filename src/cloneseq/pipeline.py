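"""Glue between the stages: run a sample end to end and serialise results."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .alignment_io import (DEFAULT_MIN_MAPQ, DEFAULT_MIN_OVERHANG,
                           AlignmentRecord, CoverageProfile,
                           JunctionEvidence, coverage_profile,
                           extract_junctions, read_alignments)
from .event_caller import CallResult, SpliceEvent, call_events
from .gene_models import GeneModel
from .quantify import FilterPolicy, SampleSummary, summarize_sample


@dataclass
class SampleRun:
    summary: SampleSummary
    call: CallResult
    junctions: list[JunctionEvidence]
    coverage: CoverageProfile


def call_sample(records: Sequence[AlignmentRecord], model: GeneModel,
                sample_id: str = "sample",
                policy: FilterPolicy = FilterPolicy(),
                min_overhang: int = DEFAULT_MIN_OVERHANG,
                region: Optional[tuple[int, int]] = None) -> SampleRun:
    """Junctions + coverage + event calling + filtering for one sample."""
    records = list(records)
    if region is None:
        lo, hi = model.genomic_span
        region = (max(1, lo - 500), hi + 500)
    junctions = extract_junctions(records, min_overhang=min_overhang)
    coverage = coverage_profile(records, region)
    result = call_events(junctions, coverage, model, records)
    summary = summarize_sample(sample_id, result.events, policy,
                               total_mapped_reads=len(records),
                               model_ref=model.transcript_accession)
    return SampleRun(summary, result, junctions, coverage)


def call_sample_from_sam(path: Union[str, Path], model: GeneModel,
                         sample_id: str = "sample",
                         policy: FilterPolicy = FilterPolicy(),
                         min_mapq: int = DEFAULT_MIN_MAPQ,
                         min_overhang: int = DEFAULT_MIN_OVERHANG) -> SampleRun:
    lo, hi = model.genomic_span
    region = (model.chrom, max(1, lo - 500), hi + 500)
    records = list(read_alignments(path, region=region, min_mapq=min_mapq))
    return call_sample(records, model, sample_id, policy, min_overhang)


def _event_row(ev: SpliceEvent, status: str, reason: str = "") -> dict:
    nm = ev.name
    return {
        "event_class": ev.event_class,
        "exons": ",".join(ev.affected_exons),
        "genomic_start": ev.genomic_span[0],
        "genomic_end": ev.genomic_span[1],
        "hgvs_r": nm.hgvs_r if nm else "",
        "approximate": bool(nm.approximate) if nm else False,
        "frame_effect": nm.frame_effect if nm else "not_applicable",
        "nmd_predicted": bool(nm.nmd_predicted) if nm else False,
        "supporting_reads": ev.supporting_reads,
        "region_reads": ev.region_reads,
        # report to one decimal; internal precision is kept on the event
        "percent": round(ev.percent, 1) if ev.percent is not None else None,
        "low_confidence": ev.low_confidence,
        "status": status,
        "filter_reason": reason,
    }


def events_table(summary: SampleSummary) -> pd.DataFrame:
    rows = [_event_row(ev, "retained") for ev in summary.events]
    rows += [_event_row(ev, "filtered", reason)
             for ev, reason in summary.filtered_events]
    cols = list(_event_row(summary.events[0], "")) if summary.events else \
        list(_event_row(summary.filtered_events[0][0], "")) if \
        summary.filtered_events else [
            "event_class", "exons", "genomic_start", "genomic_end", "hgvs_r",
            "approximate", "frame_effect", "nmd_predicted",
            "supporting_reads", "region_reads", "percent", "low_confidence",
            "status", "filter_reason"]
    return pd.DataFrame(rows, columns=cols)


def write_events(run: SampleRun, out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = events_table(run.summary)
    df.to_csv(out / "events.tsv", sep="\t", index=False)
    payload = {
        "sample_id": run.summary.sample_id,
        "model_ref": run.summary.model_ref,
        "total_mapped_reads": run.summary.total_mapped_reads,
        "events": df.to_dict(orient="records"),
        "unresolved_junctions": [
            {"donor": j.donor_g, "acceptor": j.acceptor_g,
             "support": j.read_support} for j in run.call.unresolved
        ],
    }
    (out / "events.json").write_text(json.dumps(payload, indent=2))
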
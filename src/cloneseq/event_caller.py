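"""Classify splice junctions and coverage patterns into splicing events.

Five event classes are recognised against a single-transcript gene model:

1. **exon_skipping** — a junction joining an annotated exon end to a later
   annotated exon start, bypassing one or more whole exons.  Also reported,
   with a low-confidence flag, when one or more consecutive exons have zero
   coverage but no junction directly evidences the skip.
2. **partial_exon_skipping** — a junction with exactly one side strictly
   inside an annotated exon (alternative exonic donor/acceptor).
3. **partial_intron_inclusion** — a junction with exactly one side strictly
   inside an annotated intron (alternative intronic donor/acceptor), the
   intronic end of the intron being covered contiguously with its exon.
4. **intron_retention** — contiguous nonzero coverage across an entire
   annotated intron; support counts reads whose aligned blocks cross an
   exon-intron boundary without a gap.
5. **cryptic_exon** — a covered island strictly inside an intron, bounded
   by junctions on both sides, with zero coverage over the rest of the
   intron.

Junctions exactly matching an annotated intron are canonical and produce no
event.  Junctions that cannot be reconciled with the model are reported as
unresolved, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment_io import AlignmentRecord, CoverageProfile, JunctionEvidence
from .gene_models import EventName, GeneModel, name_deletion, name_insertion
from .quantify import compute_percent

EVENT_CLASSES = (
    "exon_skipping",
    "partial_exon_skipping",
    "partial_intron_inclusion",
    "intron_retention",
    "cryptic_exon",
    "canonical",
)


@dataclass
class SpliceEvent:
    """One classified splicing event with its read accounting.

    ``supporting_reads`` counts reads that directly evidence the event;
    ``region_reads`` counts all reads whose aligned span overlaps the
    event's genomic span (supporting and non-supporting alike), which is
    the denominator of the percent-spliced statistic.
    """

    event_class: str
    affected_exons: list[str]
    genomic_span: tuple[int, int]
    supporting_reads: int
    region_reads: int
    percent: Optional[float]
    name: Optional[EventName] = None
    low_confidence: bool = False

    def key(self) -> tuple[str, tuple[int, int]]:
        return (self.event_class, self.genomic_span)


@dataclass
class CallResult:
    """Events plus junctions that could not be reconciled with the model."""

    events: list[SpliceEvent]
    unresolved: list[JunctionEvidence] = field(default_factory=list)
    canonical_junctions: list[JunctionEvidence] = field(default_factory=list)


def _side_status(model: GeneModel, gpos: int) -> tuple[str, Optional[int]]:
    """Where a junction side falls: ('exon_end'|'exon_start'|'exon_interior',
    exon index in genomic order) or ('intron', intron index) or
    ('outside', None)."""
    gsorted = sorted(range(len(model.exons)),
                     key=lambda i: model.exons[i].genomic_start)
    for rank, i in enumerate(gsorted):
        e = model.exons[i]
        if e.genomic_start <= gpos <= e.genomic_end:
            if gpos == e.genomic_end:
                return "exon_end", rank
            if gpos == e.genomic_start:
                return "exon_start", rank
            return "exon_interior", rank
    for k, (s, e) in enumerate(model.introns_genomic()):
        if s <= gpos <= e:
            return "intron", k
    return "outside", None


def _exons_genomic_order(model: GeneModel):
    return sorted(model.exons, key=lambda e: e.genomic_start)


def _region_reads(records: Optional[Sequence[AlignmentRecord]],
                  span: tuple[int, int],
                  coverage: CoverageProfile,
                  floor: int) -> int:
    """Reads overlapping ``span``; falls back to peak coverage when the
    record stream is unavailable (an underestimate for long spans)."""
    if records is not None:
        s, e = span
        return sum(
            1 for r in records
            if r.reference_span[0] <= e and r.reference_span[1] >= s
        )
    approx = int(coverage.slice(*span).max(initial=0))
    return max(approx, floor)


def _tx_interval_of_exons(model: GeneModel, labels: list[str]) -> tuple[int, int]:
    exs = [model.exon_by_label(lb) for lb in labels]
    return min(e.tx_start for e in exs), max(e.tx_end for e in exs)


def _upstream_exon_tx_end(model: GeneModel, intron_idx: int) -> int:
    """Transcript position of the last exonic base 5' of the given intron
    (introns indexed in genomic order)."""
    gsorted = _exons_genomic_order(model)
    left, right = gsorted[intron_idx], gsorted[intron_idx + 1]
    up = left if left.tx_start < right.tx_start else right
    return up.tx_end


def call_events(
    junctions: Sequence[JunctionEvidence],
    coverage: CoverageProfile,
    model: GeneModel,
    records: Optional[Sequence[AlignmentRecord]] = None,
    *,
    nmd_boundary: int = 55,
) -> CallResult:
    """Apply the five classification rules to junctions and coverage.

    ``records`` (the alignment stream the junctions and coverage were
    derived from) enables exact region-read denominators and exact
    intron-retention support; without it both are approximated from the
    coverage profile.
    """
    records = list(records) if records is not None else None
    gsorted = _exons_genomic_order(model)
    introns = model.introns_genomic()
    events: list[SpliceEvent] = []
    unresolved: list[JunctionEvidence] = []
    canonical: list[JunctionEvidence] = []
    consumed: set[tuple[int, int]] = set()

    # ---- rule 5 first: cryptic exons consume their two flanking junctions
    jset = {(j.donor_g, j.acceptor_g): j for j in junctions}
    for k, (istart, iend) in enumerate(introns):
        depth = coverage.slice(istart, iend)
        if not depth.any() or depth.all():
            continue
        runs = _covered_runs(depth, istart)
        if len(runs) != 1:
            continue
        rs, re_ = runs[0]
        if rs == istart or re_ == iend:
            continue  # touches an intron end: alternative-site territory
        left_j = jset.get((istart - 1, rs))
        right_j = jset.get((re_, iend + 1))
        if left_j is None or right_j is None:
            continue
        support = min(left_j.read_support, right_j.read_support)
        span = (rs, re_)
        region = _region_reads(records, span, coverage, support)
        after_tx = _upstream_exon_tx_end(model, k)
        events.append(SpliceEvent(
            "cryptic_exon", [], span, support, region,
            compute_percent(support, region),
            name_insertion(model, after_tx, re_ - rs + 1,
                           nmd_boundary=nmd_boundary),
        ))
        consumed.add((left_j.donor_g, left_j.acceptor_g))
        consumed.add((right_j.donor_g, right_j.acceptor_g))

    # ---- junction-driven rules 1-3
    skip_spans: list[tuple[int, int]] = []
    for j in junctions:
        key = (j.donor_g, j.acceptor_g)
        if key in consumed:
            continue
        d_stat, d_idx = _side_status(model, j.donor_g)
        a_stat, a_idx = _side_status(model, j.acceptor_g)

        if d_stat == "exon_end" and a_stat == "exon_start":
            if a_idx == d_idx + 1:
                canonical.append(j)
                continue
            if a_idx is not None and d_idx is not None and a_idx > d_idx + 1:
                skipped = gsorted[d_idx + 1: a_idx]
                labels = sorted((e.label for e in skipped),
                                key=lambda lb: model.exon_by_label(lb).tx_start)
                span = (skipped[0].genomic_start, skipped[-1].genomic_end)
                region = _region_reads(records, span, coverage, j.read_support)
                t1, t2 = _tx_interval_of_exons(model, labels)
                events.append(SpliceEvent(
                    "exon_skipping", labels, span, j.read_support, region,
                    compute_percent(j.read_support, region),
                    name_deletion(model, t1, t2, nmd_boundary=nmd_boundary),
                ))
                skip_spans.append(span)
                continue
            unresolved.append(j)
            continue

        exon_interior = [s for s in (d_stat, a_stat) if s == "exon_interior"]
        intron_side = [s for s in (d_stat, a_stat) if s == "intron"]
        if "outside" in (d_stat, a_stat):
            unresolved.append(j)
            continue

        if len(exon_interior) == 1 and not intron_side:
            # alternative exonic donor or acceptor truncating one exon
            removed = (j.donor_g + 1, j.acceptor_g - 1)
            which = d_idx if d_stat == "exon_interior" else a_idx
            label = gsorted[which].label
            span = removed
            region = _region_reads(records, span, coverage, j.read_support)
            tx_iv = _removed_exonic_tx(model, removed)
            name = (name_deletion(model, *tx_iv, approximate=True,
                                  nmd_boundary=nmd_boundary)
                    if tx_iv else None)
            events.append(SpliceEvent(
                "partial_exon_skipping", [label], span, j.read_support,
                region, compute_percent(j.read_support, region), name,
            ))
            continue

        if len(intron_side) == 1 and not exon_interior:
            # alternative intronic site: part of the intron is included.
            # The boundary side must flank this same intron, otherwise the
            # junction combines events and is reported unresolved.
            k = d_idx if d_stat == "intron" else a_idx
            istart, iend = introns[k]
            if d_stat == "intron":
                if not (a_stat == "exon_start" and a_idx == k + 1):
                    unresolved.append(j)
                    continue
                included = (istart, j.donor_g)
            else:
                if not (d_stat == "exon_end" and d_idx == k):
                    unresolved.append(j)
                    continue
                included = (j.acceptor_g, iend)
            length = included[1] - included[0] + 1
            region = _region_reads(records, included, coverage, j.read_support)
            after_tx = _upstream_exon_tx_end(model, k)
            events.append(SpliceEvent(
                "partial_intron_inclusion", [], included, j.read_support,
                region, compute_percent(j.read_support, region),
                name_insertion(model, after_tx, length,
                               nmd_boundary=nmd_boundary),
            ))
            continue

        unresolved.append(j)

    # ---- rule 4: intron retention from full-intron coverage
    for k, (istart, iend) in enumerate(introns):
        depth = coverage.slice(istart, iend)
        if len(depth) == 0 or not depth.all():
            continue
        if records is not None:
            support = _boundary_crossing_reads(records, istart, iend)
        else:
            support = int(max(coverage.at(istart), coverage.at(iend)))
        span = (istart, iend)
        region = _region_reads(records, span, coverage, support)
        after_tx = _upstream_exon_tx_end(model, k)
        events.append(SpliceEvent(
            "intron_retention", [], span, support, region,
            compute_percent(support, region),
            name_insertion(model, after_tx, iend - istart + 1,
                           nmd_boundary=nmd_boundary),
        ))

    # ---- rule 1, coverage trigger: zero-coverage exons without a junction
    zero_runs = _zero_coverage_exon_runs(model, coverage, gsorted)
    for labels, span in zero_runs:
        if any(s <= span[0] and span[1] <= e for s, e in skip_spans):
            continue  # already reported from a skip junction
        t1, t2 = _tx_interval_of_exons(model, labels)
        events.append(SpliceEvent(
            "exon_skipping", labels, span, 0,
            _region_reads(records, span, coverage, 0),
            None,
            name_deletion(model, t1, t2, nmd_boundary=nmd_boundary),
            low_confidence=True,
        ))

    events.sort(key=lambda ev: (ev.genomic_span, ev.event_class))
    return CallResult(events, unresolved, canonical)


def name_event(model: GeneModel, event: SpliceEvent, *,
               nmd_boundary: int = 55) -> EventName:
    """RNA-level name for an already-classified event.

    Whole-exon skipping is named exactly (``r.A_BdelN``); intron retention
    and alternative-site classes carry approximate names, since short-read
    alignment cannot fix their breakpoints base-exactly.
    """
    cls = event.event_class
    if cls == "canonical":
        return EventName("r.=", False, "in_frame", False)
    if cls == "exon_skipping":
        t1, t2 = _tx_interval_of_exons(model, event.affected_exons)
        return name_deletion(model, t1, t2, nmd_boundary=nmd_boundary)
    if cls == "partial_exon_skipping":
        tx_iv = _removed_exonic_tx(model, event.genomic_span)
        if tx_iv is None:
            raise ValueError("partial skip span contains no exonic bases")
        return name_deletion(model, *tx_iv, approximate=True,
                             nmd_boundary=nmd_boundary)
    if cls in ("partial_intron_inclusion", "intron_retention",
               "cryptic_exon"):
        s, e = event.genomic_span
        for k, (istart, iend) in enumerate(model.introns_genomic()):
            if istart <= s and e <= iend:
                after_tx = _upstream_exon_tx_end(model, k)
                return name_insertion(model, after_tx, e - s + 1,
                                      nmd_boundary=nmd_boundary)
        raise ValueError("event span not within an annotated intron")
    raise ValueError(f"unknown event class {cls!r}")


def _covered_runs(depth: np.ndarray, offset: int) -> list[tuple[int, int]]:
    """Maximal runs of nonzero depth, as 1-based genomic intervals."""
    runs = []
    nz = depth > 0
    i = 0
    n = len(nz)
    while i < n:
        if nz[i]:
            j = i
            while j + 1 < n and nz[j + 1]:
                j += 1
            runs.append((offset + i, offset + j))
            i = j + 1
        else:
            i += 1
    return runs


def _removed_exonic_tx(model: GeneModel, removed: tuple[int, int]
                       ) -> Optional[tuple[int, int]]:
    """Transcript interval of the exonic bases inside a removed genomic
    interval, or None if none are exonic."""
    txs = []
    for e in model.exons:
        lo = max(removed[0], e.genomic_start)
        hi = min(removed[1], e.genomic_end)
        if lo <= hi:
            txs.extend([model.genomic_to_transcript(lo),
                        model.genomic_to_transcript(hi)])
    if not txs:
        return None
    return min(txs), max(txs)


def _boundary_crossing_reads(records: Sequence[AlignmentRecord],
                             istart: int, iend: int) -> int:
    """Reads with a gapless block spanning either exon-intron boundary."""
    n = 0
    for r in records:
        for s, e in r.blocks:
            if (s <= istart - 1 and e >= istart) or (s <= iend and e >= iend + 1):
                n += 1
                break
    return n


def _zero_coverage_exon_runs(model: GeneModel, coverage: CoverageProfile,
                             gsorted) -> list[tuple[list[str], tuple[int, int]]]:
    """Consecutive (transcript order) exons with zero coverage throughout,
    excluding the terminal exons (amplicon primers anchor in those)."""
    zero = []
    for e in model.exons:
        d = coverage.slice(e.genomic_start, e.genomic_end)
        zero.append(not d.any())
    runs = []
    i = 1  # skip first exon
    last = len(model.exons) - 1
    while i < last:
        if zero[i]:
            j = i
            while j + 1 < last and zero[j + 1]:
                j += 1
            # absence is only evidence when the flanking exons are covered
            if zero[i - 1] or zero[j + 1]:
                i = j + 1
                continue
            exs = model.exons[i: j + 1]
            span = (min(e.genomic_start for e in exs),
                    max(e.genomic_end for e in exs))
            runs.append(([e.label for e in exs], span))
            i = j + 1
        else:
            i += 1
    return runs
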
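"""Percent-spliced quantification, noise filtering and sample comparison.

The quantitative statistic is the percent of an alternative splicing event:

    percent = 100 * supporting_reads / region_reads

where ``region_reads`` counts all reads in the region covering the event.
Noise from sequencing/alignment errors and ultra-rare isoforms is removed
by three thresholds applied with strict inequalities: events with fewer
than 20 supporting reads, fewer than 50 region reads, or a percent below
2.5 are filtered out (values exactly at a threshold are retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

DEFAULT_MIN_SUPPORT = 20
DEFAULT_MIN_REGION_READS = 50
DEFAULT_MIN_PERCENT = 2.5


class ContractError(ValueError):
    pass


def compute_percent(supporting: int, region: int) -> Optional[float]:
    """Percent of reads supporting an event among all reads in its region.

    Returns ``None`` (undefined) when ``region`` is zero.
    """
    if supporting < 0 or region < 0:
        raise ContractError("read counts must be non-negative")
    if supporting > region:
        raise ContractError(
            f"supporting reads ({supporting}) exceed region reads ({region})"
        )
    if region == 0:
        return None
    return 100.0 * supporting / region


@dataclass(frozen=True)
class FilterPolicy:
    """The three noise thresholds; events strictly below any are removed."""

    min_support: int = DEFAULT_MIN_SUPPORT
    min_region_reads: int = DEFAULT_MIN_REGION_READS
    min_percent: float = DEFAULT_MIN_PERCENT

    def __post_init__(self) -> None:
        if min(self.min_support, self.min_region_reads, self.min_percent) < 0:
            raise ValueError("filter thresholds must be >= 0")


def apply_filters(events: Sequence, policy: FilterPolicy = FilterPolicy()
                  ) -> tuple[list, list]:
    """Split events into (retained, filtered-with-reason).

    An event is filtered iff supporting < min_support OR region <
    min_region_reads OR percent < min_percent, checked in that order; the
    first failing reason is attached.  Returns ``(retained,
    [(event, reason), ...])``.
    """
    retained, filtered = [], []
    for ev in events:
        pct = ev.percent
        if ev.supporting_reads < policy.min_support:
            filtered.append((ev, "min_support"))
        elif ev.region_reads < policy.min_region_reads:
            filtered.append((ev, "min_region_reads"))
        elif pct is None or pct < policy.min_percent:
            filtered.append((ev, "min_percent"))
        else:
            retained.append(ev)
    return retained, filtered


@dataclass
class SampleSummary:
    """Post-filter events for one sample, with the filtered remainder."""

    sample_id: str
    events: list
    filtered_events: list  # (event, reason) pairs
    total_mapped_reads: int = 0
    model_ref: str = ""  # transcript accession the events were called against


def summarize_sample(sample_id: str, events: Sequence,
                     policy: FilterPolicy = FilterPolicy(),
                     total_mapped_reads: int = 0,
                     model_ref: str = "") -> SampleSummary:
    retained, filtered = apply_filters(events, policy)
    return SampleSummary(sample_id, retained, filtered, total_mapped_reads,
                         model_ref)


@dataclass
class EventComparison:
    """A case event's percent against each control's percent."""

    event_class: str
    genomic_span: tuple[int, int]
    case_percent: Optional[float]
    control_percents: list[float] = field(default_factory=list)
    case_specific: Optional[bool] = None  # None: not evaluable (no controls)


def compare_to_controls(case: SampleSummary,
                        controls: Sequence[SampleSummary]
                        ) -> list[EventComparison]:
    """For each retained case event, report every control's percent for the
    same (class, span) event (0 when absent post-filter) and flag the event
    case-specific when no control retains it.  With no controls the flag is
    None (not evaluable)."""
    for c in controls:
        if case.model_ref and c.model_ref and c.model_ref != case.model_ref:
            raise ValueError(
                f"control {c.sample_id!r} was called against a different "
                f"gene model ({c.model_ref!r} vs {case.model_ref!r})"
            )
    out = []
    for ev in case.events:
        ctrl = []
        present = []
        for c in controls:
            match = next((e for e in c.events if e.key() == ev.key()), None)
            ctrl.append(0.0 if match is None or match.percent is None
                        else match.percent)
            present.append(match is not None)
        flag = (not any(present)) if controls else None
        out.append(EventComparison(ev.event_class, ev.genomic_span,
                                   ev.percent, ctrl, flag))
    return out
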
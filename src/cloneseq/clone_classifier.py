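"""Classify full-length clone (Sanger-style) sequences by exon composition.

Each clone is one subcloned RT-PCR product — a single transcript molecule.
Rather than wrapping a general long-read spliced aligner, the classifier
enumerates the plausible isoform space for the targeted gene (full length,
every single and consecutive multi-exon skip of internal exons, every
single intron retention, plus any caller-discovered structures supplied by
the user), reconstructs each candidate's sequence, and assigns the clone to
the candidate maximizing sequence identity.  This is deterministic and
entirely adequate for clone-grade (low-error) sequences; structures outside
the enumerated space surface as low-identity unclassified calls rather than
being force-fitted.

Identity is ``1 - edit_distance / max(len_clone, len_candidate)`` with the
edit distance from global (Needleman-Wunsch) alignment.  Two candidates
within the tie tolerance (default 0.5% identity) make the call ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import edlib

from .gene_models import GeneModel
from .simulate import build_isoform_sequence, isoform_label

DEFAULT_MIN_IDENTITY = 0.90  # below this, no candidate explains the clone
DEFAULT_TIE_TOLERANCE = 0.005


@dataclass(frozen=True)
class IsoformCall:
    """The classification of one clone sequence.

    ``status`` is ``ok``, ``ambiguous`` (two candidates within the tie
    tolerance), ``unclassified`` (no candidate above the identity floor) or
    ``not_evaluable`` (sequence too short to be informative).
    """

    clone_id: str
    isoform_label: str
    structure: str
    match_fraction: float
    status: str = "ok"
    exon_sequence: tuple[str, ...] = ()


def candidate_structures(model: GeneModel,
                         extra: Iterable[str] = ()) -> list[str]:
    """FL, all single and consecutive multi-exon skips of internal exons,
    all single intron retentions, plus ``extra`` descriptors.  Terminal
    exons anchor the amplicon primers and cannot be skipped."""
    labels = [e.label for e in model.exons]
    out = ["FL"]
    n = len(labels)
    for i in range(1, n - 1):
        for j in range(i, n - 1):
            out.append("skip:" + ",".join(labels[i:j + 1]))
    for k in range(1, n):
        out.append(f"retain_intron:{k}")
    for s in extra:
        if s not in out:
            out.append(s)
    return out


def classify_clone(seq: str, model: GeneModel, genome: str,
                   extra_structures: Iterable[str] = (),
                   clone_id: str = "clone",
                   min_identity: float = DEFAULT_MIN_IDENTITY,
                   tie_tolerance: float = DEFAULT_TIE_TOLERANCE
                   ) -> IsoformCall:
    """Assign a clone sequence to the identity-maximizing isoform."""
    structures = candidate_structures(model, extra_structures)
    cands = {s: build_isoform_sequence(model, s, genome) for s in structures}
    min_informative = min(len(c) for c in cands.values()) // 2
    seq = seq.strip().upper()
    if len(seq) < min_informative:
        return IsoformCall(clone_id, "NA", "NA", 0.0, "not_evaluable")
    scored = []
    for s, cand in cands.items():
        dist = edlib.align(seq, cand, mode="NW", task="distance")[
            "editDistance"]
        ident = 1.0 - dist / max(len(seq), len(cand))
        scored.append((ident, s))
    scored.sort(reverse=True)
    best_ident, best_s = scored[0]
    if best_ident < min_identity:
        return IsoformCall(clone_id, "NA", "NA", best_ident, "unclassified")
    status = "ok"
    if len(scored) > 1 and scored[0][0] - scored[1][0] < tie_tolerance:
        status = "ambiguous"
    from .simulate import isoform_segments
    segs = tuple(f"{gs}-{ge}" for gs, ge in
                 isoform_segments(model, best_s))
    return IsoformCall(clone_id, isoform_label(best_s), best_s,
                       best_ident, status, segs)


@dataclass
class ReplicateFrequencies:
    """Per-isoform relative frequencies across biological replicates.

    ``per_replicate[label]`` lists one frequency per retained replicate
    (frequencies within a replicate sum to 1); ``median_frequency[label]``
    is the reported statistic, the median across replicates.
    """

    per_replicate: dict[str, list[float]] = field(default_factory=dict)
    median_frequency: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 0


def replicate_summary(calls_by_replicate: Sequence[Sequence[IsoformCall]]
                      ) -> ReplicateFrequencies:
    """Relative isoform frequencies per replicate and their medians.

    Only clean (``status == "ok"``) calls enter the denominators; a
    replicate with no classifiable clone is excluded with a warning.
    Absent isoforms count as frequency 0 in replicates where they do not
    appear, so medians are comparable across isoforms.
    """
    kept: list[dict[str, int]] = []
    for r, calls in enumerate(calls_by_replicate, 1):
        counts: dict[str, int] = {}
        for c in calls:
            if c.status == "ok":
                counts[c.isoform_label] = counts.get(c.isoform_label, 0) + 1
        if not counts:
            warnings.warn(f"replicate {r} has no classifiable clones; "
                          "excluded from frequency summary")
            continue
        kept.append(counts)
    labels = sorted({lb for c in kept for lb in c})
    out = ReplicateFrequencies(n_replicates=len(kept))
    for lb in labels:
        freqs = [c.get(lb, 0) / sum(c.values()) for c in kept]
        out.per_replicate[lb] = freqs
        out.median_frequency[lb] = median(freqs)
    return out
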
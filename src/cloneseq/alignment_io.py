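"""Reduce splice-aware SAM/BAM alignments to junction evidence and coverage.

The event caller needs only two views of the alignments over the targeted
locus: the set of splice junctions (reference gaps) with read support, and
per-base coverage.  CIGAR ``N`` operations are always treated as junction
signal; ``D`` operations shorter than a configurable threshold are treated
as small indels (sequencing artifacts) and bridged, while longer deletions
are promoted to junction gaps.

Clone-pool amplicon libraries are intentionally duplicated, so no duplicate
marking or PCR-duplicate filtering is applied anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pysam

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_OVERHANG = 6
DEFAULT_GAP_THRESHOLD = 20  # D ops >= this many nt count as junctions

_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N = 0, 1, 2, 3
_CIGAR_EQ, _CIGAR_X = 7, 8


@dataclass(frozen=True)
class AlignmentRecord:
    """A single aligned read reduced to its gapless reference blocks.

    ``blocks`` are 1-based inclusive genomic intervals, sorted and
    non-overlapping; the gaps between consecutive blocks are the skipped
    reference (intron) segments of the alignment.
    """

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost
    blocks: tuple[tuple[int, int], ...]
    is_read1: bool = True
    mapq: int = 60

    @property
    def reference_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def gaps(self) -> list[tuple[int, int, int, int]]:
        """(donor, acceptor, left_overhang, right_overhang) per block gap.

        ``donor`` is the last aligned base before the gap and ``acceptor``
        the first aligned base after it, on the genomic plus axis.
        """
        out = []
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            out.append((e1, s2, e1 - s1 + 1, e2 - s2 + 1))
        return out


@dataclass(frozen=True)
class JunctionEvidence:
    """One distinct splice junction with its read support."""

    donor_g: int  # last exonic base before the gap (plus axis)
    acceptor_g: int  # first exonic base after the gap
    read_support: int


@dataclass
class CoverageProfile:
    """Per-base read depth over a genomic interval (1-based inclusive)."""

    region_start: int
    region_end: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        n = self.region_end - self.region_start + 1
        if len(self.depth) != n:
            raise ValueError("depth length does not match region")

    def at(self, gpos: int) -> int:
        if not (self.region_start <= gpos <= self.region_end):
            return 0
        return int(self.depth[gpos - self.region_start])

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depth over ``start..end`` inclusive; positions outside the
        profiled region read as zero."""
        out = np.zeros(end - start + 1, dtype=self.depth.dtype)
        lo, hi = max(start, self.region_start), min(end, self.region_end)
        if lo <= hi:
            out[lo - start: hi - start + 1] = self.depth[
                lo - self.region_start: hi - self.region_start + 1
            ]
        return out


def _blocks_from_cigar(pos0: int, cigartuples, gap_threshold: int
                       ) -> tuple[tuple[int, int], ...]:
    """Gapless reference blocks (1-based inclusive) from a CIGAR, bridging
    deletions shorter than ``gap_threshold``."""
    blocks: list[list[int]] = []
    ref = pos0  # 0-based walking cursor
    open_block: Optional[list[int]] = None
    for op, length in cigartuples:
        if op in (_CIGAR_M, _CIGAR_EQ, _CIGAR_X):
            if open_block is None:
                open_block = [ref, ref + length]
            else:
                open_block[1] += length
            ref += length
        elif op == _CIGAR_D:
            if length >= gap_threshold:
                if open_block is not None:
                    blocks.append(open_block)
                    open_block = None
            elif open_block is not None:
                open_block[1] += length
            ref += length
        elif op == _CIGAR_N:
            if open_block is not None:
                blocks.append(open_block)
                open_block = None
            ref += length
        # I, S, H, P consume no reference
    if open_block is not None:
        blocks.append(open_block)
    return tuple((s + 1, e) for s, e in blocks)  # to 1-based inclusive


def read_alignments(
    path: Union[str, Path],
    region: Optional[tuple[str, int, int]] = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from SAM/BAM over an optional region.

    ``region`` is (chrom, start, end) 1-based inclusive.  Secondary,
    supplementary and unmapped records are skipped, as are records with
    mapping quality below ``min_mapq``.  Region queries on BAM use the
    index; for plain SAM the file is scanned and filtered.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        if region is not None and mode == "rb":
            chrom, start, end = region
            it = af.fetch(chrom, start - 1, end)
        else:
            it = af.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            blocks = _blocks_from_cigar(
                aln.reference_start, aln.cigartuples or (), gap_threshold
            )
            if not blocks:
                continue
            rec = AlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                pos=aln.reference_start + 1,
                blocks=blocks,
                is_read1=not aln.is_read2,
                mapq=aln.mapping_quality,
            )
            if region is not None:
                chrom, start, end = region
                s, e = rec.reference_span
                if rec.chrom != chrom or e < start or s > end:
                    continue
            yield rec


def extract_junctions(
    records: Iterable[AlignmentRecord],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[JunctionEvidence]:
    """Collapse alignment gaps into distinct junctions with read support.

    A read contributes support to a junction only if it has at least
    ``min_overhang`` aligned bases on both sides of the gap; each read
    counts once per distinct gap it contains.
    """
    support: dict[tuple[int, int], int] = {}
    for rec in records:
        seen: set[tuple[int, int]] = set()
        for donor, acceptor, left, right in rec.gaps():
            if left < min_overhang or right < min_overhang:
                continue
            key = (donor, acceptor)
            if key not in seen:
                seen.add(key)
                support[key] = support.get(key, 0) + 1
    return [
        JunctionEvidence(d, a, n)
        for (d, a), n in sorted(support.items())
    ]


def coverage_profile(
    records: Iterable[AlignmentRecord],
    region: tuple[int, int],
) -> CoverageProfile:
    """Per-base depth over ``region`` (1-based inclusive): depth at a base
    is the number of aligned blocks covering it; gapped segments contribute
    nothing."""
    start, end = region
    depth = np.zeros(end - start + 1, dtype=np.int64)
    for rec in records:
        for s, e in rec.blocks:
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                depth[lo - start: hi - start + 1] += 1
    return CoverageProfile(start, end, depth)
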
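"""Gene structure, coordinate systems and RNA-level event nomenclature.

A :class:`GeneModel` holds the exon/intron structure of a single targeted
transcript, with every exon carrying both genomic coordinates (1-based,
inclusive, on the reference assembly) and transcript coordinates (1-based
nucleotide positions along the mature mRNA, 5'->3').  Exon labels are taken
from the locus configuration, never computed from ordinal position: genes
such as BRCA1 use historical exon numbering with gaps, and positional
numbering would misname events.

User-facing coordinates in this module are 1-based inclusive, matching HGVS
convention; interval arithmetic internally uses 0-based half-open ranges
where convenient.  RNA-level (``r.``) coordinates are reported numerically
equal to the CDS-relative (``c.``) coordinates of the reference transcript,
which is how targeted splicing assays conventionally print them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union


class AnnotationError(ValueError):
    """Structural or configuration problem in the locus annotation."""


class CoordinateError(ValueError):
    """A position that cannot be resolved against the gene model."""


@dataclass(frozen=True)
class Exon:
    """One exon with paired genomic and transcript coordinates.

    ``label`` is annotation-supplied text (e.g. ``"23"``).  Genomic and
    transcript intervals are 1-based inclusive and have equal lengths.
    """

    label: str
    genomic_start: int
    genomic_end: int
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.genomic_end < self.genomic_start:
            raise AnnotationError(
                f"exon {self.label}: genomic_end < genomic_start"
            )
        if self.tx_end - self.tx_start != self.genomic_end - self.genomic_start:
            raise AnnotationError(
                f"exon {self.label}: transcript and genomic lengths differ"
            )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one transcript on one strand.

    ``exons`` are ordered 5'->3' in *transcript* orientation; on the minus
    strand their genomic coordinates therefore decrease along the list.
    ``cds_start_offset``/``cds_end`` are transcript coordinates of the first
    and last coding base.
    """

    gene_symbol: str
    chrom: str
    strand: str
    transcript_accession: str
    exons: tuple[Exon, ...]
    cds_start_offset: int = 1
    cds_end: int = 0  # 0 means "last transcript base"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"unknown strand symbol {self.strand!r}")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise AnnotationError("gene model needs at least one exon")
        # transcript intervals contiguous
        if exons[0].tx_start != 1:
            raise AnnotationError("first exon must start at transcript nt 1")
        for a, b in zip(exons, exons[1:]):
            if b.tx_start != a.tx_end + 1:
                raise AnnotationError(
                    f"transcript gap between exons {a.label} and {b.label}"
                )
        # non-overlapping in genomic space, ordered along the strand
        gsorted = sorted(exons, key=lambda e: e.genomic_start)
        for a, b in zip(gsorted, gsorted[1:]):
            if b.genomic_start <= a.genomic_end:
                raise AnnotationError(
                    f"exons {a.label} and {b.label} overlap genomically"
                )
        expected = gsorted if self.strand == "+" else gsorted[::-1]
        if tuple(expected) != exons:
            raise AnnotationError(
                "exon transcript order inconsistent with strand"
            )
        cds_end = self.cds_end or self.tx_length
        object.__setattr__(self, "cds_end", cds_end)
        if not (1 <= self.cds_start_offset <= cds_end <= self.tx_length):
            raise AnnotationError("CDS interval outside transcript")

    # -- basic geometry ---------------------------------------------------

    @property
    def tx_length(self) -> int:
        return self.exons[-1].tx_end

    @property
    def genomic_span(self) -> tuple[int, int]:
        """(min, max) genomic position covered by any exon, 1-based incl."""
        return (
            min(e.genomic_start for e in self.exons),
            max(e.genomic_end for e in self.exons),
        )

    def introns_genomic(self) -> list[tuple[int, int]]:
        """Intronic intervals (1-based inclusive) on the genomic plus axis,
        ordered by genomic position."""
        gsorted = sorted(self.exons, key=lambda e: e.genomic_start)
        return [
            (a.genomic_end + 1, b.genomic_start - 1)
            for a, b in zip(gsorted, gsorted[1:])
        ]

    def exon_by_label(self, label: str) -> Exon:
        for e in self.exons:
            if e.label == label:
                return e
        raise AnnotationError(f"no exon labelled {label!r}")

    # -- coordinate conversion --------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> Union[int, str]:
        """Map a genomic position to a transcript nt or intronic descriptor.

        Exonic positions return the 1-based transcript position (int).
        Intronic positions return a string in CDS-relative offset form,
        e.g. ``"100+5"`` (5 nt 3' of the donor at c.100) or ``"101-12"``
        (12 nt 5' of the acceptor at c.101), using whichever exon boundary
        is nearer (ties go to the donor side).
        """
        lo, hi = self.genomic_span
        if not (lo <= gpos <= hi):
            raise CoordinateError(f"position {gpos} outside gene span {lo}-{hi}")
        for e in self.exons:
            if e.genomic_start <= gpos <= e.genomic_end:
                if self.strand == "+":
                    return e.tx_start + (gpos - e.genomic_start)
                return e.tx_start + (e.genomic_end - gpos)
        # intronic: find flanking exons in transcript order
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                inside = up.genomic_end < gpos < down.genomic_start
                off_donor = gpos - up.genomic_end
                off_acceptor = down.genomic_start - gpos
            else:
                inside = down.genomic_end < gpos < up.genomic_start
                off_donor = up.genomic_start - gpos
                off_acceptor = gpos - down.genomic_end
            if inside:
                if off_donor <= off_acceptor:
                    return f"{self.tx_to_cds(up.tx_end)}+{off_donor}"
                return f"{self.tx_to_cds(down.tx_start)}-{off_acceptor}"
        raise CoordinateError(f"position {gpos} not resolvable")  # pragma: no cover

    def transcript_to_genomic(self, tpos: int) -> int:
        if not (1 <= tpos <= self.tx_length):
            raise CoordinateError(f"transcript position {tpos} out of range")
        for e in self.exons:
            if e.tx_start <= tpos <= e.tx_end:
                if self.strand == "+":
                    return e.genomic_start + (tpos - e.tx_start)
                return e.genomic_end - (tpos - e.tx_start)
        raise CoordinateError(f"transcript position {tpos} unmapped")  # pragma: no cover

    def tx_to_cds(self, tpos: int) -> int:
        """Transcript nt -> CDS-relative (c./r.) numbering.

        Positions 5' of the CDS come out zero or negative; callers targeting
        strict HGVS 5'-UTR syntax should format those themselves.
        """
        return tpos - self.cds_start_offset + 1

    def last_junction_tx(self) -> Optional[int]:
        """Transcript position of the last exonic base before the final
        exon-exon junction, or None for single-exon transcripts."""
        if len(self.exons) < 2:
            return None
        return self.exons[-2].tx_end


# ---------------------------------------------------------------------------
# Event naming


@dataclass(frozen=True)
class EventName:
    """RNA-level description of a splicing change.

    ``hgvs_r`` uses CDS-relative numbering (``r.`` values numerically equal
    to ``c.``).  ``approximate`` is set for event classes whose breakpoints
    short-read alignment cannot pin down base-exactly (intron retention and
    alternative-site events).
    """

    hgvs_r: str
    approximate: bool = False
    frame_effect: str = "not_applicable"  # in_frame | frameshift | not_applicable
    nmd_predicted: bool = False


def frame_and_nmd(
    model: GeneModel,
    change_len: int,
    event_span_tx: tuple[int, int],
    *,
    inserted: bool = False,
    nmd_boundary: int = 55,
) -> tuple[str, bool]:
    """Reading-frame effect and NMD prediction for a deletion/insertion.

    ``change_len`` is the number of deleted or inserted nucleotides and
    ``event_span_tx`` the affected transcript interval (1-based inclusive;
    a zero-length change uses an empty span ``(p, p-1)``).

    Frame: ``in_frame`` iff ``change_len % 3 == 0`` and the span lies within
    the CDS; outside the CDS the effect is ``not_applicable``.

    NMD: predicted for frameshift events whose premature termination codon
    lies more than ``nmd_boundary`` nt upstream of the last exon-exon
    junction of the altered transcript.  Without the transcript sequence the
    PTC cannot be located exactly, so it is approximated at the event's 5'
    breakpoint — adequate for flagging, not for clinical assertion.
    """
    start, end = event_span_tx
    if change_len == 0:
        return "in_frame", False
    if end > model.tx_length or start < 1:
        raise CoordinateError("event span outside transcript")
    within_cds = model.cds_start_offset <= start and end <= model.cds_end
    if not within_cds:
        return "not_applicable", False
    frame = "in_frame" if change_len % 3 == 0 else "frameshift"
    nmd = False
    if frame == "frameshift":
        last_j = model.last_junction_tx()
        if last_j is not None:
            ptc_proxy = start
            # position of the last junction in the altered transcript
            if end <= last_j:
                delta = change_len if inserted else -(end - start + 1)
                last_j_alt = last_j + delta
            else:
                last_j_alt = last_j
            nmd = (last_j_alt - ptc_proxy) > nmd_boundary
    return frame, nmd


def name_deletion(model: GeneModel, tx_start: int, tx_end: int,
                  *, approximate: bool = False,
                  nmd_boundary: int = 55) -> EventName:
    """HGVS r. name for a transcript-level deletion spanning
    ``tx_start..tx_end`` (1-based inclusive transcript coordinates)."""
    if tx_end < tx_start:  # empty span: identity
        return EventName("r.=", False, "in_frame", False)
    n = tx_end - tx_start + 1
    c1, c2 = model.tx_to_cds(tx_start), model.tx_to_cds(tx_end)
    frame, nmd = frame_and_nmd(model, n, (tx_start, tx_end),
                               nmd_boundary=nmd_boundary)
    return EventName(f"r.{c1}_{c2}del{n}", approximate, frame, nmd)


def name_insertion(model: GeneModel, after_tx: int, length: int,
                   *, approximate: bool = True,
                   nmd_boundary: int = 55) -> EventName:
    """HGVS r.-style name for ``length`` nt inserted between transcript
    positions ``after_tx`` and ``after_tx + 1`` (intron retention, cryptic
    exons).  Breakpoints from short reads are approximate by nature."""
    if length == 0:
        return EventName("r.=", False, "in_frame", False)
    c1 = model.tx_to_cds(after_tx)
    frame, nmd = frame_and_nmd(model, length, (after_tx, after_tx),
                               inserted=True, nmd_boundary=nmd_boundary)
    return EventName(f"r.{c1}_{c1 + 1}ins{length}", approximate, frame, nmd)


# ---------------------------------------------------------------------------
# Annotation loading

_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_locus_config(path: Union[str, Path]) -> dict:
    """Key-value locus config: accession, strand, cds_start, cds_end and an
    ``exon_labels`` line giving comma-separated labels in transcript order."""
    cfg: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        if not _:
            key, _, val = line.partition(":")
        cfg[key.strip()] = val.strip()
    if "exon_labels" in cfg:
        cfg["exon_labels"] = [s.strip() for s in cfg["exon_labels"].split(",")]
    return cfg


def load_gene_model(annotation_path: Union[str, Path],
                    config: Union[str, Path, dict]) -> GeneModel:
    """Build a :class:`GeneModel` from GFF3 or BED12 plus a locus config.

    The annotation must describe exactly one transcript for the configured
    accession; the config supplies ``gene``, ``accession``, ``strand`` (GFF3
    may carry it too), CDS offsets in transcript coordinates, and the
    ``exon_labels`` list covering every exon in transcript order.
    """
    cfg = config if isinstance(config, dict) else _parse_locus_config(config)
    path = Path(annotation_path)
    text = path.read_text()
    if path.suffix.lower() in (".bed", ".bed12") or _looks_like_bed12(text):
        chrom, strand, exon_ivs = _read_bed12(text, cfg.get("accession"))
    else:
        chrom, strand, exon_ivs = _read_gff3_exons(text, cfg.get("accession"))
    if "strand" in cfg and cfg["strand"] != strand:
        raise AnnotationError(
            f"config strand {cfg['strand']!r} contradicts annotation {strand!r}"
        )
    return build_gene_model(
        gene_symbol=cfg.get("gene", cfg.get("accession", "gene")),
        chrom=chrom,
        strand=strand,
        transcript_accession=cfg.get("accession", "tx"),
        exon_genomic=exon_ivs,
        exon_labels=cfg.get("exon_labels"),
        cds_start_offset=int(cfg.get("cds_start", 1)),
        cds_end=int(cfg.get("cds_end", 0)),
    )


def build_gene_model(gene_symbol: str, chrom: str, strand: str,
                     transcript_accession: str,
                     exon_genomic: Iterable[tuple[int, int]],
                     exon_labels: Optional[Iterable[str]] = None,
                     cds_start_offset: int = 1,
                     cds_end: int = 0) -> GeneModel:
    """Assemble a model from genomic exon intervals (1-based inclusive),
    deriving transcript coordinates from cumulative exon lengths in strand
    orientation."""
    if strand not in ("+", "-"):
        raise AnnotationError(f"unknown strand symbol {strand!r}")
    ivs = sorted(exon_genomic)
    if strand == "-":
        ivs = ivs[::-1]
    labels = list(exon_labels) if exon_labels is not None else [
        str(i + 1) for i in range(len(ivs))
    ]
    if len(labels) != len(ivs):
        raise AnnotationError(
            f"{len(ivs)} exons but {len(labels)} labels in config"
        )
    exons = []
    tx = 1
    for label, (gs, ge) in zip(labels, ivs):
        length = ge - gs + 1
        exons.append(Exon(label, gs, ge, tx, tx + length - 1))
        tx += length
    return GeneModel(gene_symbol, chrom, strand, transcript_accession,
                     tuple(exons), cds_start_offset, cds_end)


def _looks_like_bed12(text: str) -> bool:
    for line in text.splitlines():
        if line and not line.startswith(("#", "track", "browser")):
            return len(line.split("\t")) >= 12
    return False


def _read_bed12(text: str, accession: Optional[str]) -> tuple[str, str, list]:
    rows = []
    for line in text.splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise AnnotationError("BED12 requires 12 columns")
        if accession and f[3] != accession:
            continue
        rows.append(f)
    if len(rows) != 1:
        raise AnnotationError(
            f"expected exactly one BED12 record for {accession!r}, got {len(rows)}"
        )
    f = rows[0]
    chrom, chrom_start, strand = f[0], int(f[1]), f[5]
    sizes = [int(s) for s in f[10].rstrip(",").split(",")]
    starts = [int(s) for s in f[11].rstrip(",").split(",")]
    ivs = [
        (chrom_start + st + 1, chrom_start + st + sz)  # BED 0-based -> 1-based
        for st, sz in zip(starts, sizes)
    ]
    return chrom, strand, ivs


def _read_gff3_exons(text: str, accession: Optional[str]) -> tuple[str, str, list]:
    chrom = strand = None
    ivs: list[tuple[int, int]] = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2].lower() != "exon":
            continue
        attrs = dict(_GFF_ATTR.findall(f[8]))
        parent = attrs.get("Parent", attrs.get("transcript_id", ""))
        if accession and accession not in parent.split(","):
            continue
        if f[6] not in ("+", "-"):
            raise AnnotationError(f"unknown strand symbol {f[6]!r}")
        if chrom is None:
            chrom, strand = f[0], f[6]
        elif f[0] != chrom or f[6] != strand:
            raise AnnotationError("exons span multiple chromosomes/strands")
        ivs.append((int(f[3]), int(f[4])))
    if not ivs:
        raise AnnotationError(f"no exons found for transcript {accession!r}")
    return chrom, strand, ivs
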
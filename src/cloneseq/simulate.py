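"""Synthetic clone-pool amplicon experiments with machine-readable truth.

The simulator emulates the data a cloned RT-PCR product pool produces:
a mixture of transcript isoforms over one targeted gene, sheared into
fragments and sequenced as 2x250 paired-end reads.  Because every fragment
derives from a known isoform, the simulator can emit a *truth* SAM in which
each read carries its correct spliced placement on the genome (match blocks
separated by N gaps across excluded segments); the event caller is thereby
testable without running an external spliced aligner.  FASTQ is emitted
alongside for users who want to push the reads through a real aligner.

Clone-length (Sanger-style) sequences of whole isoforms are simulated the
same way for the clone-classification path.

The error model is substitutions only (default 0.1%): plasmid-derived
amplicon sequencing is high fidelity and indel errors would only exercise
the aligner, which is out of scope here.  Fragment lengths are normal
(mean 300, sd 30), emulating sonication to a 250-350 bp target; fragments
shorter than two read lengths yield overlapping mates, as in real 2x250
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .alignment_io import AlignmentRecord
from .gene_models import AnnotationError, GeneModel, build_gene_model

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed internal seed so the packaged toy reference is identical for every
# user and every run, independent of simulation seeds
_TOY_GENOME_SEED = 941

DEFAULT_READ_LEN = 250
DEFAULT_FRAG_MEAN = 300.0
DEFAULT_FRAG_SD = 30.0
DEFAULT_SUB_RATE = 0.001


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Toy reference locus


def toy_locus(n_exons: int = 3, exon_len: int = 100, intron_len: int = 100,
              strand: str = "+", chrom: str = "chrT",
              flank: int = 1000) -> tuple[GeneModel, str]:
    """A deterministic synthetic reference: ``n_exons`` exons of
    ``exon_len`` nt separated by ``intron_len`` nt introns, embedded in
    ``flank`` nt of flanking sequence, on a random but fixed genome.

    The default (3 x 100 nt exons starting at genomic 1001) gives exon
    boundaries at easily checkable round numbers.
    """
    rng = np.random.default_rng(_TOY_GENOME_SEED)
    glen = 2 * flank + n_exons * exon_len + (n_exons - 1) * intron_len
    genome = b"".join(
        _BASES[rng.integers(0, 4, glen)].tolist()
    ).decode()
    ivs = []
    pos = flank + 1
    for _ in range(n_exons):
        ivs.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    labels = [f"E{i + 1}" for i in range(n_exons)]
    model = build_gene_model(
        gene_symbol="TOY1", chrom=chrom, strand=strand,
        transcript_accession="TOY1.1", exon_genomic=ivs, exon_labels=labels,
    )
    return model, genome


# ---------------------------------------------------------------------------
# Isoform structures


def isoform_segments(model: GeneModel, structure: str
                     ) -> list[tuple[int, int]]:
    """Retained genomic segments (1-based inclusive) of an isoform, in
    transcript orientation.

    Structure descriptors:

    - ``"FL"`` — full length, every exon;
    - ``"skip:<label>[,<label>...]"`` — whole-exon skipping of the listed
      (consecutive) exons;
    - ``"retain_intron:<i>"`` — retention of the i-th intron (1-based,
      transcript order);
    - ``"alt_donor:<label>:<d>"`` — exon truncated by ``d`` nt at its
      transcript 3' end (alternative exonic donor);
    - ``"alt_acceptor:<label>:<d>"`` — exon truncated by ``d`` nt at its
      transcript 5' end (alternative exonic acceptor);
    - ``"extend_donor:<label>:<d>"`` — exon extended ``d`` nt into the
      downstream intron (alternative intronic donor);
    - ``"cryptic:<i>:<offset>:<len>"`` — a ``len`` nt cryptic exon inside
      intron ``i`` starting ``offset`` nt after the intron's transcript 5'
      end.
    """
    exons = list(model.exons)
    minus = model.strand == "-"

    def seg(e) -> tuple[int, int]:
        return (e.genomic_start, e.genomic_end)

    if structure == "FL":
        return [seg(e) for e in exons]

    kind, _, rest = structure.partition(":")
    if kind == "skip":
        labels = [s.strip() for s in rest.split(",")]
        idx = [i for i, e in enumerate(exons) if e.label in labels]
        if len(idx) != len(labels):
            raise AnnotationError(f"unknown exon label in {structure!r}")
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise AnnotationError("skipped exons must be consecutive")
        return [seg(e) for i, e in enumerate(exons) if i not in idx]
    if kind == "retain_intron":
        k = int(rest) - 1
        if not (0 <= k < len(exons) - 1):
            raise AnnotationError(f"no intron {rest} in model")
        segs = []
        for i, e in enumerate(exons):
            segs.append(seg(e))
            if i == k:
                nxt = exons[i + 1]
                if minus:
                    segs.append((nxt.genomic_end + 1, e.genomic_start - 1))
                else:
                    segs.append((e.genomic_end + 1, nxt.genomic_start - 1))
        return segs
    if kind in ("alt_donor", "alt_acceptor", "extend_donor"):
        label, _, d_s = rest.partition(":")
        d = int(d_s)
        segs = []
        for i, e in enumerate(exons):
            gs, ge = seg(e)
            if e.label == label:
                if kind == "alt_donor":  # truncate transcript 3' end
                    gs, ge = (gs + d, ge) if minus else (gs, ge - d)
                elif kind == "alt_acceptor":  # truncate transcript 5' end
                    gs, ge = (gs, ge - d) if minus else (gs + d, ge)
                else:  # extend into downstream intron
                    if i == len(exons) - 1:
                        raise AnnotationError("cannot extend the last exon")
                    gs, ge = (gs - d, ge) if not minus else (gs, ge + d)
                if ge < gs:
                    raise AnnotationError(f"{structure!r} removes whole exon")
            segs.append((gs, ge))
        return segs
    if kind == "cryptic":
        i_s, off_s, len_s = rest.split(":")
        k, off, clen = int(i_s) - 1, int(off_s), int(len_s)
        if not (0 <= k < len(exons) - 1):
            raise AnnotationError(f"no intron {i_s} in model")
        up, down = exons[k], exons[k + 1]
        if minus:
            cstart = up.genomic_start - off - clen
            island = (cstart, cstart + clen - 1)
            if island[0] <= down.genomic_end:
                raise AnnotationError("cryptic exon leaves the intron")
        else:
            cstart = up.genomic_end + off + 1
            island = (cstart, cstart + clen - 1)
            if island[1] >= down.genomic_start:
                raise AnnotationError("cryptic exon leaves the intron")
        segs = [seg(e) for e in exons]
        segs.insert(k + 1, island)
        return segs
    raise AnnotationError(f"unknown structure descriptor {structure!r}")


def build_isoform_sequence(model: GeneModel, structure: str,
                           genome: str) -> str:
    """Nucleotide sequence of an isoform: the retained segments
    concatenated in transcript orientation (reverse-complemented on the
    minus strand)."""
    segs = isoform_segments(model, structure)
    parts = []
    for gs, ge in segs:
        s = genome[gs - 1: ge]
        parts.append(revcomp(s) if model.strand == "-" else s)
    return "".join(parts)


def isoform_label(structure: str) -> str:
    """Canonical short label: FL, Δ23, Δ23+24, IR1, ..."""
    if structure == "FL":
        return "FL"
    kind, _, rest = structure.partition(":")
    if kind == "skip":
        return "Δ" + "+".join(s.strip() for s in rest.split(","))
    if kind == "retain_intron":
        return f"IR{rest}"
    return structure


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class MixtureSpec:
    """An isoform mixture plus sequencing parameters.

    ``isoforms`` pairs structure descriptors with proportions summing to 1.
    """

    isoforms: tuple[tuple[str, float], ...]
    n_read_pairs: int
    read_len: int = DEFAULT_READ_LEN
    frag_mean: float = DEFAULT_FRAG_MEAN
    frag_sd: float = DEFAULT_FRAG_SD
    substitution_rate: float = DEFAULT_SUB_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.isoforms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isoform proportions sum to {total}, not 1")
        if self.read_len > self.frag_mean:
            raise ValueError("read length exceeds mean fragment length")


@dataclass
class SimTruth:
    """What the simulator actually emitted, for downstream verification."""

    seed: int
    n_read_pairs: int
    per_isoform_pairs: dict[str, int] = field(default_factory=dict)
    per_event: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def per_isoform_reads(self) -> dict[str, int]:
        return {k: 2 * v for k, v in self.per_isoform_pairs.items()}


@dataclass
class SimResult:
    fastq1: Optional[Path]
    fastq2: Optional[Path]
    sam: Optional[Path]
    truth: SimTruth
    records: list[AlignmentRecord]


def _segments_to_blocks(segs: Sequence[tuple[int, int]], minus: bool,
                        start: int, length: int) -> list[tuple[int, int]]:
    """Genomic blocks (ascending, 1-based inclusive) covered by isoform
    interval [start, start+length) given the isoform's retained segments in
    transcript orientation."""
    blocks = []
    off = 0
    remaining_start, remaining = start, length
    for gs, ge in segs:
        seg_len = ge - gs + 1
        lo = max(remaining_start - off, 0)
        hi = min(remaining_start + remaining - off, seg_len)
        if lo < hi:
            if minus:
                # transcript offset o maps to genomic ge - o
                blocks.append((ge - (hi - 1), ge - lo))
            else:
                blocks.append((gs + lo, gs + hi - 1))
        off += seg_len
    blocks.sort()
    # merge genomically adjacent blocks (retained introns)
    merged: list[list[int]] = []
    for b in blocks:
        if merged and b[0] == merged[-1][1] + 1:
            merged[-1][1] = b[1]
        else:
            merged.append(list(b))
    return [tuple(b) for b in merged]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _truth_events_for_structure(model: GeneModel, structure: str
                                ) -> Optional[tuple[str, tuple[int, int],
                                                    tuple[int, int]]]:
    """(label, event genomic span, junction (donor, acceptor)) for the
    event a structure creates; None for FL or structures whose truth events
    are not junction-shaped (retention)."""
    kind, _, rest = structure.partition(":")
    if kind != "skip":
        return None
    labels = [s.strip() for s in rest.split(",")]
    exs = [model.exon_by_label(lb) for lb in labels]
    span = (min(e.genomic_start for e in exs), max(e.genomic_end for e in exs))
    gsorted = sorted(model.exons, key=lambda e: e.genomic_start)
    left = [e for e in gsorted if e.genomic_end < span[0]]
    right = [e for e in gsorted if e.genomic_start > span[1]]
    if not left or not right:
        return None  # terminal-exon skip: no flanking junction exists
    return (isoform_label(structure), span,
            (left[-1].genomic_end, right[0].genomic_start))


def simulate_reads(model: GeneModel, genome: str, spec: MixtureSpec,
                   out_dir: Optional[Union[str, Path]] = None,
                   sample_id: str = "sim",
                   min_overhang: int = 6) -> SimResult:
    """Draw paired-end fragments from the isoform mixture and emit truth
    alignments.

    Fragments start uniformly along each isoform with normally jittered
    lengths (clipped to [read_len, isoform length]).  When ``out_dir`` is
    given, FASTQ (R1/R2) and a coordinate-order truth SAM are written
    there; the in-memory :class:`AlignmentRecord` list is returned either
    way, so the caller pipeline can run without touching disk.
    """
    rng = np.random.default_rng(spec.seed)
    minus = model.strand == "-"
    structures = [s for s, _ in spec.isoforms]
    props = np.array([p for _, p in spec.isoforms])
    seqs = {s: build_isoform_sequence(model, s, genome) for s in structures}
    segs = {s: isoform_segments(model, s) for s in structures}

    truth = SimTruth(seed=spec.seed, n_read_pairs=spec.n_read_pairs)
    for s in structures:
        truth.per_isoform_pairs[isoform_label(s)] = 0

    choices = rng.choice(len(structures), size=spec.n_read_pairs, p=props)
    rl = spec.read_len
    reads = []  # (qname, is_read1, blocks, seq, strand_of_gene)
    records: list[AlignmentRecord] = []
    for i, ci in enumerate(choices):
        s = structures[ci]
        iso_seq, iso_segs = seqs[s], segs[s]
        L = len(iso_seq)
        flen = int(round(rng.normal(spec.frag_mean, spec.frag_sd)))
        flen = max(min(flen, L), min(rl, L))
        fstart = int(rng.integers(0, L - flen + 1))
        # a fragment shorter than the read length is read end-to-end
        rl_eff = min(rl, flen)
        truth.per_isoform_pairs[isoform_label(s)] += 1
        qname = f"{sample_id}:{isoform_label(s)}:{i}"
        r1 = _mutate(iso_seq[fstart: fstart + rl_eff], rng,
                     spec.substitution_rate)
        r2_src = iso_seq[fstart + flen - rl_eff: fstart + flen]
        r2 = _mutate(revcomp(r2_src), rng, spec.substitution_rate)
        b1 = _segments_to_blocks(iso_segs, minus, fstart, rl_eff)
        b2 = _segments_to_blocks(iso_segs, minus, fstart + flen - rl_eff,
                                 rl_eff)
        reads.append((qname, True, b1, r1))
        reads.append((qname, False, b2, r2))
        for is_r1, blocks in ((True, b1), (False, b2)):
            records.append(AlignmentRecord(
                read_id=qname, chrom=model.chrom, pos=blocks[0][0],
                blocks=tuple(blocks), is_read1=is_r1, mapq=60,
            ))

    _fill_truth_events(truth, model, structures, records, min_overhang)

    f1 = f2 = samp = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        f1, f2 = out / f"{sample_id}_R1.fastq", out / f"{sample_id}_R2.fastq"
        samp = out / f"{sample_id}.truth.sam"
        _write_fastq(reads, f1, f2, rl)
        _write_truth_sam(reads, model, genome, samp, minus)
    return SimResult(f1, f2, samp, truth, records)


def _fill_truth_events(truth: SimTruth, model: GeneModel,
                       structures: Sequence[str],
                       records: Sequence[AlignmentRecord],
                       min_overhang: int) -> None:
    for s in structures:
        ev = _truth_events_for_structure(model, s)
        if ev is None:
            continue
        label, span, (donor, acceptor) = ev
        supporting = 0
        region = 0
        for r in records:
            rs, re_ = r.reference_span
            if rs <= span[1] and re_ >= span[0]:
                region += 1
            for d, a, left, right in r.gaps():
                if (d, a) == (donor, acceptor) and \
                        left >= min_overhang and right >= min_overhang:
                    supporting += 1
                    break
        truth.per_event[label] = {"supporting": supporting, "region": region}


def _write_fastq(reads, f1: Path, f2: Path, read_len: int) -> None:
    qual = "I" * read_len
    with open(f1, "w") as h1, open(f2, "w") as h2:
        for qname, is_r1, _, seq in reads:
            h = h1 if is_r1 else h2
            h.write(f"@{qname}\n{seq}\n+\n{qual[:len(seq)]}\n")


def _write_truth_sam(reads, model: GeneModel, genome: str, path: Path,
                     minus: bool) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.chrom, "LN": len(genome)}],
    }
    by_name: dict[str, list] = {}
    for qname, is_r1, blocks, seq in reads:
        by_name.setdefault(qname, []).append((is_r1, blocks, seq))
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        recs = []
        for qname, pair in by_name.items():
            pair.sort(key=lambda t: not t[0])
            for (is_r1, blocks, seq), (_, mblocks, _) in zip(
                    pair, pair[::-1]):
                a = pysam.AlignedSegment(af.header)
                a.query_name = qname
                a.reference_id = 0
                a.reference_start = blocks[0][0] - 1
                a.mapping_quality = 60
                cig = []
                prev_end = None
                for bs, be in blocks:
                    if prev_end is not None:
                        cig.append((3, bs - prev_end - 1))  # N
                    cig.append((0, be - bs + 1))  # M
                    prev_end = be
                a.cigartuples = cig
                # reads were generated in transcript orientation; store the
                # reference-plus-strand sequence
                reverse = (minus == is_r1)
                a.query_sequence = revcomp(seq) if reverse else seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(seq))
                a.flag = (0x1 | 0x2
                          | (0x40 if is_r1 else 0x80)
                          | (0x10 if reverse else 0x20))
                a.next_reference_id = 0
                a.next_reference_start = mblocks[0][0] - 1
                recs.append(a)
        recs.sort(key=lambda a: a.reference_start)
        for a in recs:
            af.write(a)


# ---------------------------------------------------------------------------
# Clone (Sanger-style full-length) simulation


def simulate_clones(model: GeneModel, genome: str, spec: MixtureSpec,
                    n_clones: int, n_replicates: int = 1,
                    out_fasta: Optional[Union[str, Path]] = None,
                    sample_id: str = "sim"
                    ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Full-length clone sequences drawn multinomially from the mixture.

    Returns ``(records, truth)`` where records are ``(clone_id, sequence)``
    with IDs ``sample|rep<r>|clone<i>`` and truth pairs each ID with its
    source isoform label.  Substitution noise follows the spec's rate.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(spec.seed)
    structures = [s for s, _ in spec.isoforms]
    props = np.array([p for _, p in spec.isoforms])
    seqs = {s: build_isoform_sequence(model, s, genome) for s in structures}
    records, truth = [], []
    for rep in range(1, n_replicates + 1):
        picks = rng.choice(len(structures), size=n_clones, p=props)
        for i, ci in enumerate(picks, 1):
            s = structures[ci]
            cid = f"{sample_id}|rep{rep}|clone{i}"
            seq = _mutate(seqs[s], rng, spec.substitution_rate)
            records.append((cid, seq))
            truth.append((cid, isoform_label(s)))
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for cid, seq in records:
                fh.write(f">{cid}\n{seq}\n")
    return records, truth
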
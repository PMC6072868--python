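# Methods

## The assay being modelled

A targeted RT-PCR product spanning several exons of one transcript is
cloned into plasmids; the pooled colonies are purified, sheared and
sequenced as 2×250 paired-end reads. Every sequenced fragment derives from
one cloned transcript molecule, so the read pool is a (PCR- and
cloning-biased) sample of the transcript isoform mixture. Aligned
splice-aware to the reference genome, aberrant isoforms appear as
non-canonical junctions and coverage patterns over the locus. A companion
low-throughput path sequences individual colonies end-to-end
(Sanger-style), giving one whole transcript per clone.

## Event model

All calling is done against a single annotated transcript (exon intervals
with both genomic and transcript coordinates; exon labels supplied by the
annotation, since historical numbering schemes have gaps). Junctions are
reference gaps in the alignments (CIGAR `N`, plus `D` runs of at least
`gap_threshold` = 20 nt — shorter deletions are treated as indel artifacts
and bridged). A read supports a junction only with ≥ `min_overhang` = 6
aligned nt on both sides; records below `min_mapq` = 20 and
secondary/supplementary records are ignored. No duplicate filtering is
ever applied: clone pools are intentionally duplicated and a PCR-duplicate
filter would erase the signal.

The five classes, applied per junction / per intron:

1. **exon skipping** — junction from an annotated exon end to a later
   annotated exon start bypassing ≥ 1 whole exon. Consecutive skipped
   exons are reported as one event listing all labels. A run of
   consecutive internal exons with zero coverage, flanked by covered
   exons, is also reported as skipping but flagged low-confidence
   (support 0), since no junction directly evidences it.
2. **partial exon skipping** — exactly one junction side strictly inside
   an exon (alternative exonic donor/acceptor).
3. **partial intron inclusion** — exactly one junction side strictly
   inside an intron, the other at the flanking boundary of that same
   intron (alternative intronic donor/acceptor).
4. **intron retention** — nonzero coverage across an entire intron;
   support counts reads whose gapless blocks cross either exon–intron
   boundary, the unambiguous retention evidence.
5. **cryptic exon** — a single covered island strictly inside an intron,
   zero coverage over the rest of the intron, bounded by junctions into
   the flanking exons on both sides; the two flanking junctions are
   consumed by the event and its support is their minimum.

Junctions exactly matching an annotated intron are canonical and produce
no event. Junctions reconcilable with none of the rules (e.g. outside the
gene span, or combining two alterations in one gap) are returned in a
separate `unresolved` list, never dropped. Matching of junction ends to
annotation is exact (0 nt tolerance): the caller consumes reference-based
alignments, where boundary wobble would indicate an aligner problem rather
than biology.

## Quantification and filtering

`percent = 100 × supporting / region` where `region` counts all reads
whose aligned span overlaps the event's genomic span (supporting and
contradicting alike); with `region = 0` the value is undefined (`None`).
The phrase "reads in the region covering the event" admits a
junction-locus reading as well; span-overlap was chosen as the denominator
because it is well-defined for coverage-shaped events (retention, cryptic
exons) too. Each read of a pair counts independently — the statistic is a
read ratio, and mates overlapping the event both genuinely observed it.

Noise filters (defaults 20 supporting / 50 region / 2.5 percent) use
strict `<` comparisons: values exactly at a threshold are retained. An
event is annotated with the first failing criterion in that order.
Filtered events are kept alongside retained ones, with their reason, so
nothing silently disappears. Case/control comparison is descriptive: per
retained case event, every control's percent (0 when absent post-filter)
and a case-specific flag set when no control retains the event; no
significance test is implied.

## Naming, frame and NMD

RNA-level names use CDS-relative numbering (r. values numerically equal to
c. of the reference transcript, the convention of targeted splicing
reports). Whole-exon skips are exact deletions `r.A_BdelN`; partial exon
skips name the exonic part of the removed span; intron retention, partial
inclusion and cryptic exons are written as insertions between the flanking
exonic bases (`r.A_{A+1}insL`) and always flagged *approximate* — short
reads bound, but do not prove, those breakpoints.

Frame effect is `in_frame` iff the changed length is a multiple of 3 and
the span lies within the CDS; outside the CDS it is `not_applicable`. NMD
is predicted for frameshift events whose premature termination codon lies
more than 55 nt (configurable) upstream of the last exon–exon junction.
Without translating an actual sequence the PTC cannot be located, so it is
approximated at the event's 5′ breakpoint — adequate for flagging
candidates, not for clinical assertion, and documented as such on the
flag.

## Simulator

The simulator is the package's source of study conditions, not a tuning
knob. Defaults: 2×250 nt reads; fragment lengths normal with mean 300 and
sd 30 (sonication to a 250–350 bp target), truncated to the isoform
length, with fragments shorter than the read length read end-to-end (as
read-through does in practice); substitution errors only at 0.1%
(plasmid-derived material is high fidelity; indel errors would exercise an
aligner, which is out of scope because the simulator emits *truth*
alignments — correct spliced CIGARs — directly). Fragment starts are
uniform along the isoform. Clone sequences are whole isoforms drawn
multinomially per replicate, 56 clones per replicate by default in the
packaged experiments (a realistic per-sample colony count). The toy
reference (3–8 exons of 100 nt, 100 nt introns, random sequence from a
fixed internal seed) is generated at run time; identical for every user.

What the simulator does **not** model: RT-PCR amplification and cloning
efficiency bias, NMD kinetics and inhibitor effects, inter-individual
variability of isoform proportions, alignment errors and soft-clipping,
base-quality structure. Passing end-to-end tests therefore demonstrates
correctness of the *computational* pipeline under clean alignments, not
robustness to aligner pathologies — users aligning real FASTQ should
expect boundary wobble that the configurable matching tolerance and
overhang threshold exist to absorb.

## Clone classification

Each clone is compared against the enumerated candidate space: full
length, every single and consecutive multi-exon skip of internal exons
(terminal exons anchor the primers), every single intron retention, plus
caller-discovered structures the user passes in. Identity is
`1 − editDistance/max(len)` under global alignment (edlib); the best
candidate wins. Calls within 0.5% identity of the runner-up are
*ambiguous*; best identity below 0.90 is *unclassified*; sequences shorter
than half the shortest candidate are *not evaluable*. Only clean calls
enter replicate frequencies; the reported statistic is the per-isoform
median across replicates, with absent isoforms counted as frequency 0 in
replicates lacking them so medians are comparable.

## Numerical and design choices

- User-facing coordinates are 1-based inclusive (HGVS convention);
  internal arithmetic is 0-based half-open where convenient.
- Events are keyed and deduplicated by (class, genomic span).
- `call_events` takes the junction list and coverage profile as its
  primary inputs and additionally accepts the originating record stream;
  with records, region denominators and retention support are exact,
  without them both fall back to documented coverage-based approximations
  (peak depth over the span; boundary depth).
- Intronic positions are reported in offset form from the nearer exon
  boundary, ties going to the donor side.
- Determinism: one `numpy` generator seeded from the mixture spec drives
  all randomness; identical seeds give byte-identical FASTQ/SAM/FASTA and
  pipeline outputs.
- Problem sizes in the packaged experiments — 5,000 read pairs for
  mixture recovery, 3×56 clones, 800-read oracle mixtures, exhaustive
  read placement over a 30 nt-exon toy gene — were chosen as the smallest
  sizes at which binomial intervals are informative for the effects under
  study.

## Known limitations

- Single-transcript reference only: no multi-isoform annotation, no
  genome-wide mode, no fusion or assembly logic.
- Combined events in one read gap (e.g. a skip plus an alternative site)
  are reported unresolved rather than decomposed.
- The NMD flag is a heuristic (see above); protein-level consequences are
  not computed.
- HGVS output is the pragmatic subset used in splicing reports, not a
  full nomenclature engine (no 5′-UTR `c.-` syntax, no `p.` names).
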
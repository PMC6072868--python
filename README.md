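# cloneseq

Detection, classification, naming and quantification of mRNA splicing
events in **clone-pool amplicon sequencing** — the assay in which a
targeted RT-PCR product (e.g. a *BRCA1* or *BRCA2* amplicon from a
patient-derived cell line) is cloned into plasmids, the pooled colonies are
fragmented and sequenced as 2×250 paired-end reads, and the spliced
alignments are mined for aberrant transcripts. The package is aimed at
laboratories characterising putative spliceogenic variants who need
absolute read counts and relative isoform abundances, not just a gel band.

## What it computes

From splice-aware alignments over a single targeted transcript the caller
recognises five event classes: whole-exon skipping, partial exon skipping
(alternative exonic donor/acceptor), partial intron inclusion (alternative
intronic donor/acceptor), intron retention, and cryptic-exon insertion.
Each event is quantified as

```
percent = 100 × (reads supporting the event)
              / (all reads in the region covering the event)
```

the percent-spliced-in (PSI) style statistic for the event, and passed
through three strict (`<`) noise filters: events with fewer than 20
supporting reads, fewer than 50 region reads, or a percent below 2.5 are
removed. Whole-exon skips are named exactly in HGVS RNA-level notation —
skipping an exon occupying c.A–c.B yields `r.A_BdelN` with N = B−A+1 —
with the reading-frame effect (N mod 3) and a nonsense-mediated-decay flag
(55-nt last-junction rule); names for intron retention and
alternative-site events are marked approximate, since short reads cannot
pin their breakpoints base-exactly.

Two further paths complete the workflow: a **clone classifier** that
assigns full-length (Sanger-style) clone sequences to isoforms by
identity-maximising comparison against the enumerated isoform space and
reports median relative frequencies across biological replicates, and a
**simulator** that generates isoform mixtures, paired-end reads with truth
alignments (spliced CIGARs), clone sequences, and machine-readable truth,
so the whole pipeline is testable without patient data or an external
aligner.

## Worked example

Simulate a carrier-like sample expressing 70% full-length and 30%
exon-2-skipped transcript over the built-in three-exon toy locus, then call
events on the truth alignments:

```bash
cat > case.yaml <<'YAML'
sample_id: carrier
locus:
  n_exons: 3
mixture:
  isoforms:
    - {structure: FL, proportion: 0.7}
    - {structure: "skip:E2", proportion: 0.3}
  n_read_pairs: 5000
YAML
cloneseq report --config case.yaml --seed 42 --out run
```

prints

```
exon_skipping (1201, 1300) r.101_200del100 support=2944 region=10000 percent=29.4
```

i.e. one retained exon-skipping event over genomic span 1201–1300 (toy
exon E2, transcript c.101–c.200, hence `r.101_200del100`), supported by
2,944 of the 10,000 reads covering the region — 29.4%, within binomial
noise of the simulated 30%. `run/` contains `events.tsv` / `events.json`
(full event table with names, frame and NMD flags, filter status),
`sashimi_junctions.tsv` and `coverage.bedGraph` (the numeric tables a
sashimi plot is drawn from — here the canonical junction carries 7,056
reads and the skip junction 2,944), the simulated FASTQ pair and truth
SAM, and `manifest.json` for byte-identical reruns.

The other subcommands follow the same pattern: `cloneseq simulate` (reads
only), `call` (events from any SAM/BAM over the locus), `clones`
(classify a clone FASTA and summarise replicate frequencies), and
`compare` (case-vs-control percents with a case-specific flag per event).
Real loci are supplied as GFF3 or BED12 plus a small locus config
(accession, strand, exon labels, CDS offsets) in place of the toy locus.

## Layout

| module | responsibility |
|---|---|
| `cloneseq.gene_models` | annotation loading, genomic↔transcript coordinates, HGVS r. naming, frame/NMD |
| `cloneseq.alignment_io` | SAM/BAM ingestion, junction evidence, per-base coverage |
| `cloneseq.event_caller` | the five classification rules |
| `cloneseq.quantify` | percent statistic, noise filters, case/control comparison |
| `cloneseq.clone_classifier` | full-length clone → isoform calls, replicate frequencies |
| `cloneseq.simulate` | synthetic mixtures, reads, truth SAM, clone FASTA |
| `cloneseq.cli` / `cloneseq.sashimi` | subcommands, sashimi tables, manifests |

See `docs/methods.md` for the model, parameter defaults and limitations.
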
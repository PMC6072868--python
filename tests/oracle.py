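"""Literal, independent re-statement of the five classification rules.

Deliberately brute force: every junction is tested against every exon and
intron with the rule definitions written out verbatim, and intron patterns
are read directly off the per-base coverage.  Used only as the oracle the
production caller is compared against.
"""


def brute_force_classify(junctions, coverage, model):
    """Return the set of (event_class, genomic_span) the five rules imply."""
    exons = sorted(model.exons, key=lambda e: e.genomic_start)
    introns = []
    for a, b in zip(exons, exons[1:]):
        introns.append((a.genomic_end + 1, b.genomic_start - 1))
    found = set()

    for j in junctions:
        d, a = j.donor_g, j.acceptor_g
        # canonical: exactly an annotated intron
        if any(d == s - 1 and a == e + 1 for s, e in introns):
            continue
        # (1) exon skipping: flanking exon boundaries, >=1 whole exon between
        donor_is_exon_end = any(d == ex.genomic_end for ex in exons)
        acceptor_is_exon_start = any(a == ex.genomic_start for ex in exons)
        between = [ex for ex in exons
                   if d < ex.genomic_start and ex.genomic_end < a]
        if donor_is_exon_end and acceptor_is_exon_start and between:
            span = (between[0].genomic_start, between[-1].genomic_end)
            found.add(("exon_skipping", span))
            continue
        # (2) partial exon skipping: one junction side inside an exon
        d_in_exon = any(ex.genomic_start <= d < ex.genomic_end
                        for ex in exons)
        a_in_exon = any(ex.genomic_start < a <= ex.genomic_end
                        for ex in exons)
        if (d_in_exon != a_in_exon) and \
                (d_in_exon and acceptor_is_exon_start
                 or a_in_exon and donor_is_exon_end):
            found.add(("partial_exon_skipping", (d + 1, a - 1)))
            continue
        # (3) partial intron inclusion: one side inside an intron, the
        # included intronic stub attached to the neighbouring exon
        for k, (s, e) in enumerate(introns):
            if s <= d <= e and a == exons[k + 1].genomic_start:
                found.add(("partial_intron_inclusion", (s, d)))
                break
            if s <= a <= e and d == exons[k].genomic_end:
                found.add(("partial_intron_inclusion", (a, e)))
                break

    jset = {(j.donor_g, j.acceptor_g) for j in junctions}
    for k, (s, e) in enumerate(introns):
        depth = [coverage.at(p) for p in range(s, e + 1)]
        # (4) intron retention: alignment across the whole intron
        if all(v > 0 for v in depth):
            found.add(("intron_retention", (s, e)))
            continue
        # (5) cryptic exon: alignment in the middle, none in the rest
        covered = [p for p, v in zip(range(s, e + 1), depth) if v > 0]
        if covered:
            lo, hi = covered[0], covered[-1]
            contiguous = (hi - lo + 1) == len(covered)
            if contiguous and lo > s and hi < e and \
                    (s - 1, lo) in jset and (hi, e + 1) in jset:
                found.add(("cryptic_exon", (lo, hi)))
    # drop inclusion stubs inside an intron that rule 5 already explains
    for cls, (lo, hi) in list(found):
        if cls != "cryptic_exon":
            continue
        for other in list(found):
            if other[0] == "partial_intron_inclusion":
                s, e = other[1]
                if s <= lo and hi <= e or lo <= s <= hi or lo <= e <= hi:
                    found.discard(other)
    return found
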
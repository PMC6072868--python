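import pytest

from cloneseq import (AlignmentRecord, MixtureSpec, call_events,
                      coverage_profile, extract_junctions, name_event,
                      simulate_reads)
from oracle import brute_force_classify


def _call(records, model, **kw):
    records = list(records)
    junctions = extract_junctions(records)
    lo, hi = model.genomic_span
    cov = coverage_profile(records, (lo - 200, hi + 200))
    return call_events(junctions, cov, model, records, **kw), junctions, cov


def _reads(blocks_list, prefix="r"):
    return [AlignmentRecord(f"{prefix}{i}", "chrT", b[0][0], tuple(b))
            for i, b in enumerate(blocks_list)]


def test_canonical_junction_produces_no_event(toy_model):
    recs = _reads([[(1051, 1100), (1201, 1250)]] * 30)
    res, junctions, _ = _call(recs, toy_model)
    assert res.events == []
    assert res.unresolved == []
    assert [(j.donor_g, j.acceptor_g) for j in res.canonical_junctions] == \
        [(1100, 1201)]


def test_whole_exon_skip_junction(toy_model):
    skip = _reads([[(1051, 1100), (1401, 1450)]] * 40, "s")
    fl = _reads([[(1051, 1100), (1201, 1250)]] * 60, "f")
    res, _, _ = _call(skip + fl, toy_model)
    [ev] = [e for e in res.events if not e.low_confidence]
    assert ev.event_class == "exon_skipping"
    assert ev.affected_exons == ["E2"]
    assert ev.genomic_span == (1201, 1300)
    assert ev.supporting_reads == 40
    assert ev.name.hgvs_r == "r.101_200del100"
    assert not ev.name.approximate


def test_multi_exon_skip_reported_as_single_event():
    from cloneseq import toy_locus
    model, _ = toy_locus(n_exons=4)
    e1, e4 = model.exons[0], model.exons[3]
    recs = _reads([[(e1.genomic_end - 49, e1.genomic_end),
                    (e4.genomic_start, e4.genomic_start + 49)]] * 30)
    res, _, _ = _call(recs, model)
    skips = [e for e in res.events if e.event_class == "exon_skipping"
             and not e.low_confidence]
    assert len(skips) == 1
    assert skips[0].affected_exons == ["E2", "E3"]


def test_partial_exon_skip_from_internal_donor(toy_model):
    # donor 30 nt before the annotated end of exon 2
    recs = _reads([[(1221, 1270), (1401, 1450)]] * 25)
    cover = _reads([[(1201, 1300)]] * 50, "c")
    res, _, _ = _call(recs + cover, toy_model)
    [ev] = [e for e in res.events if e.event_class == "partial_exon_skipping"]
    assert ev.affected_exons == ["E2"]
    assert ev.genomic_span == (1271, 1400)
    assert ev.name.approximate
    assert ev.name.hgvs_r == "r.171_200del30"  # 30 nt exonic truncation


def test_partial_intron_inclusion_from_intronic_acceptor(toy_model):
    # exon 3 extended 51 nt 5'-ward into intron 2 (alternative acceptor)
    recs = _reads([[(1251, 1300), (1350, 1440)]] * 25)
    res, _, _ = _call(recs, toy_model)
    [ev] = [e for e in res.events
            if e.event_class == "partial_intron_inclusion"]
    assert ev.genomic_span == (1350, 1400)
    assert ev.name.approximate
    assert ev.name.hgvs_r == "r.200_201ins51"


def test_intron_retention_support_counts_boundary_crossers(toy_model):
    retained = _reads([[(1051, 1250)]] * 20, "ir")  # cross E1/I1 boundary
    body = _reads([[(1120, 1190)]] * 5, "b")
    tail = _reads([[(1190, 1290)]] * 7, "t")  # cross I1/E2 boundary
    res, _, _ = _call(retained + body + tail, toy_model)
    [ev] = [e for e in res.events if e.event_class == "intron_retention"]
    assert ev.genomic_span == (1101, 1200)
    assert ev.supporting_reads == 27  # both boundary-crossing groups
    assert ev.name.hgvs_r == "r.100_101ins100"


def test_cryptic_exon_island_with_flanking_junctions(toy_model):
    # 60 nt island centred in intron 2 (1301-1400), zero elsewhere
    recs = _reads([[(1251, 1300), (1330, 1389), (1401, 1450)]] * 30)
    res, _, _ = _call(recs, toy_model)
    [ev] = [e for e in res.events if e.event_class == "cryptic_exon"]
    assert ev.genomic_span == (1330, 1389)
    assert ev.supporting_reads == 30
    assert ev.name.hgvs_r == "r.200_201ins60"


def test_zero_coverage_exon_reported_low_confidence(toy_model):
    # no junction evidence at all: single-block reads on exons 1 and 3
    recs = _reads([[(1001, 1100)]] * 10 + [[(1401, 1500)]] * 10)
    res, _, _ = _call(recs, toy_model)
    [ev] = res.events
    assert ev.event_class == "exon_skipping"
    assert ev.low_confidence
    assert ev.supporting_reads == 0
    assert ev.affected_exons == ["E2"]


def test_junction_outside_model_is_unresolved_not_dropped(toy_model):
    recs = _reads([[(401, 500), (701, 800)]] * 10)
    cover = _reads([[(1051, 1100), (1201, 1250)]] * 10, "c")
    res, junctions, _ = _call(recs + cover, toy_model)
    assert [(j.donor_g, j.acceptor_g) for j in res.unresolved] == [(500, 701)]


def test_every_junction_is_attributed_exactly_once(toy_model):
    recs = _reads(
        [[(1051, 1100), (1401, 1450)]] * 30      # skip
        + [[(1051, 1100), (1201, 1250)]] * 30    # canonical
        + [[(401, 500), (701, 800)]] * 10        # unresolvable
        + [[(1251, 1300), (1330, 1389), (1401, 1450)]] * 30  # cryptic
    )
    res, junctions, _ = _call(recs, toy_model)
    n_cryptic_j = 2
    attributed = (len(res.canonical_junctions) + len(res.unresolved)
                  + sum(1 for e in res.events
                        if e.event_class not in ("intron_retention",)
                        and not e.low_confidence
                        and e.event_class != "cryptic_exon")
                  + n_cryptic_j)
    assert attributed == len(junctions)


def test_adding_supporting_reads_never_removes_an_event(toy_model):
    base = _reads([[(1051, 1100), (1401, 1450)]] * 25, "a")
    res1, _, _ = _call(base, toy_model)
    keys1 = {e.key() for e in res1.events if not e.low_confidence}
    more = base + _reads([[(1051, 1100), (1401, 1450)]] * 50, "b")
    res2, _, _ = _call(more, toy_model)
    keys2 = {e.key() for e in res2.events if not e.low_confidence}
    assert keys1 <= keys2


@pytest.mark.parametrize("structures", [
    (("FL", 0.5), ("skip:E2", 0.5)),
    (("FL", 0.4), ("skip:E2,E3", 0.3), ("retain_intron:1", 0.3)),
    (("FL", 0.5), ("alt_donor:E2:30", 0.25), ("extend_donor:E2:40", 0.25)),
    (("FL", 0.6), ("cryptic:2:30:60", 0.4)),
])
def test_caller_matches_brute_force_oracle(structures):
    """The production caller and a literal restatement of the five rules
    agree on every simulated mixture."""
    from cloneseq import toy_locus
    model, genome = toy_locus(n_exons=4)
    spec = MixtureSpec(isoforms=structures, n_read_pairs=800, seed=13,
                       substitution_rate=0.0)
    res = simulate_reads(model, genome, spec)
    junctions = extract_junctions(res.records)
    lo, hi = model.genomic_span
    cov = coverage_profile(res.records, (lo - 200, hi + 200))
    called = call_events(junctions, cov, model, res.records)
    got = {(e.event_class, e.genomic_span)
           for e in called.events if not e.low_confidence}
    expected = brute_force_classify(junctions, cov, model)
    assert got == expected
    assert called.unresolved == []


def test_name_event_dispatch_matches_inline_names(toy_model):
    recs = _reads(
        [[(1051, 1100), (1401, 1450)]] * 30
        + [[(1051, 1250)]] * 25  # retention of intron 1
    )
    res, _, _ = _call(recs, toy_model)
    for ev in res.events:
        assert name_event(toy_model, ev) == ev.name


def test_unknown_event_class_is_a_contract_error(toy_model):
    from cloneseq.event_caller import SpliceEvent
    bogus = SpliceEvent("inversion", [], (1201, 1300), 1, 1, 100.0)
    with pytest.raises(ValueError):
        name_event(toy_model, bogus)
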
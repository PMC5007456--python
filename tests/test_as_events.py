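import itertools
from collections import defaultdict

import pytest

from conftest import make_tx
from kiwitx import as_events as ae
from kiwitx.transcript_model import GeneModel, derive_introns


def locus(*txs, gid="g"):
    return GeneModel(gid, list(txs))


def exons_from_introns(introns, span=(1, 2000)):
    """Complement of an intron chain inside a fixed span."""
    exons, pos = [], span[0]
    for s, e in sorted(introns):
        exons.append((pos, s - 1))
        pos = e + 1
    exons.append((pos, span[1]))
    return exons


# ------------------------------------------------------------ spec examples

def test_intron_retention_example():
    t1 = make_tx("t1", [(1, 100), (201, 300)])
    t2 = make_tx("t2", [(1, 300)])
    (ev,) = ae.enumerate_events(locus(t1, t2))
    assert ev.category == ae.INTRON_RETENTION
    assert ev.signature.side_a == ()
    assert ev.signature.side_b == ((101, 200),)
    assert ev.supporting_a == {"t2"} and ev.supporting_b == {"t1"}


def test_exon_skipping_example():
    t1 = make_tx("t1", [(1, 100), (201, 300), (401, 500)])
    t2 = make_tx("t2", [(1, 100), (401, 500)])
    (ev,) = ae.enumerate_events(locus(t1, t2))
    assert ev.category == ae.EXON_SKIPPING
    assert set(ev.signature.side_a) | set(ev.signature.side_b) == {
        (101, 200), (301, 400), (101, 400),
    }


def test_alt_sites_strand_corrected():
    # shared genomic-left boundary
    t1 = make_tx("t1", [(1, 100), (201, 300)])
    t2 = make_tx("t2", [(1, 100), (241, 300)])
    (ev,) = ae.enumerate_events(locus(t1, t2))
    assert ev.category == ae.ALT_ACCEPTOR
    m1 = make_tx("m1", [(1, 100), (201, 300)], strand="-")
    m2 = make_tx("m2", [(1, 100), (241, 300)], strand="-")
    (mev,) = ae.enumerate_events(locus(m1, m2))
    assert mev.category == ae.ALT_DONOR
    # shared genomic-right boundary
    t3 = make_tx("t3", [(1, 100), (201, 300)])
    t4 = make_tx("t4", [(1, 60), (201, 300)])
    (ev2,) = ae.enumerate_events(locus(t3, t4))
    assert ev2.category == ae.ALT_DONOR


def test_window_restriction():
    t1 = make_tx("t1", [(1, 100), (201, 300)])
    t2 = make_tx("t2", [(250, 500)])
    assert ae.enumerate_events(locus(t1, t2)) == []


def test_dedup_three_isoforms():
    a = make_tx("a", [(1, 100), (201, 300)])
    b = make_tx("b", [(1, 100), (201, 300)])
    c = make_tx("c", [(1, 300)])
    (ev,) = ae.enumerate_events(locus(a, b, c))
    assert ev.supporting == {"a", "b", "c"}
    assert ev.supporting_a == {"c"}  # empty side sorts first
    assert ev.supporting_b == {"a", "b"}


def test_classify_event_errors():
    with pytest.raises(ValueError, match="identical sides"):
        ae.classify_event(ae.EventSignature("chr1", "+", ((1, 9),), ((1, 9),)))
    with pytest.raises(ValueError, match="stranded"):
        ae.classify_event(ae.EventSignature("chr1", ".", (), ((1, 9),)))


def test_classify_event_multi_skip_is_other():
    sig = ae.EventSignature.make(
        "chr1", "+", ((101, 200), (301, 400), (501, 600)), ((101, 600),)
    )
    assert ae.classify_event(sig) == ae.OTHER_EVENT
    # two introns vs one that does not bridge them
    sig2 = ae.EventSignature.make(
        "chr1", "+", ((101, 200), (301, 400)), ((101, 390),)
    )
    assert ae.classify_event(sig2) == ae.OTHER_EVENT


# --------------------------------------------------- brute-force pair oracle

def naive_pair_events(t1, t2):
    """Independent re-derivation of the pairwise variation regions."""
    w0 = max(t1.span.start, t2.span.start)
    w1 = min(t1.span.end, t2.span.end)
    if w1 <= w0:
        return set()
    chains = []
    for t in (t1, t2):
        chains.append([
            (i.start, i.end) for i in derive_introns(t)
            if i.start >= w0 and i.end <= w1
        ])
    sites = []
    for ci, chain in enumerate(chains):
        for s, e in chain:
            sites.append((s, "L", ci))
            sites.append((e, "R", ci))
    tagged = sorted({(p, r) for p, r, _ in sites},
                    key=lambda x: (x[0], x[1] == "L"))
    owners = defaultdict(set)
    for p, r, ci in sites:
        owners[(p, r)].add(ci)
    # bucket non-common sites by how many common sites precede them
    buckets = defaultdict(list)
    commons = []
    for site in tagged:
        if owners[site] == {0, 1}:
            commons.append(site)
        else:
            buckets[len(commons)].append(site)
    out = set()
    for idx, run in buckets.items():
        left = commons[idx - 1] if idx > 0 else None
        right = commons[idx] if idx < len(commons) else None
        sides = []
        for ci, chain in enumerate(chains):
            mine = tuple(sorted(
                iv for iv in chain
                if (iv[0], "L") in run or (iv[1], "R") in run
            ))
            if (not mine and left and right and left[1] == "L"
                    and right[1] == "R" and (left[0], right[0]) in chain):
                mine = ((left[0], right[0]),)
            sides.append(mine)
        if sides[0] != sides[1]:
            out.add(tuple(sorted(sides)))
    return out


CANDIDATE_INTRONS = [
    (101, 200), (101, 240), (61, 200),
    (301, 400), (301, 440), (61, 400),
    (501, 600), (301, 600), (101, 600),
    (701, 800), (501, 800),
]


def random_chain(rng):
    chain = []
    for iv in rng.permutation(len(CANDIDATE_INTRONS)):
        cand = CANDIDATE_INTRONS[iv]
        if rng.random() < 0.5:
            continue
        if all(cand[1] < s - 1 or cand[0] > e + 1 for s, e in chain):
            chain.append(cand)
    return sorted(chain)


def test_enumerate_against_pair_oracle(rng):
    for trial in range(40):
        n_iso = int(rng.integers(2, 5))
        txs = []
        for i in range(n_iso):
            exons = exons_from_introns(random_chain(rng))
            txs.append(make_tx(f"t{trial}_{i}", exons))
        events = ae.enumerate_events(locus(*txs))
        expected = set()
        for t1, t2 in itertools.combinations(txs, 2):
            expected |= naive_pair_events(t1, t2)
        got = {(e.signature.side_a, e.signature.side_b) for e in events}
        assert got == expected
        # every supporter must actually carry its side's introns
        by_id = {t.transcript_id: t for t in txs}
        for ev in events:
            for side, tids in ((ev.signature.side_a, ev.supporting_a),
                               (ev.signature.side_b, ev.supporting_b)):
                for tid in tids:
                    chain = {(i.start, i.end) for i in derive_introns(by_id[tid])}
                    assert set(side) <= chain


# ----------------------------------------------------- strand symmetry props

def test_strand_relabel_swaps_alt_categories(rng):
    for trial in range(20):
        txs_p, txs_m = [], []
        for i in range(3):
            exons = exons_from_introns(random_chain(rng))
            txs_p.append(make_tx(f"p{i}", exons, strand="+"))
            txs_m.append(make_tx(f"m{i}", exons, strand="-"))
        ev_p = ae.enumerate_events(locus(*txs_p))
        ev_m = ae.enumerate_events(locus(*txs_m))
        swap = {ae.ALT_ACCEPTOR: ae.ALT_DONOR, ae.ALT_DONOR: ae.ALT_ACCEPTOR}
        assert [swap.get(e.category, e.category) for e in ev_p] == [
            e.category for e in ev_m
        ]


def test_coordinate_mirror_preserves_categories(rng):
    M = 3000
    for trial in range(20):
        txs, mirrored = [], []
        for i in range(3):
            exons = exons_from_introns(random_chain(rng))
            txs.append(make_tx(f"f{i}", exons, strand="+"))
            mirrored.append(make_tx(
                f"r{i}", [(M + 1 - e, M + 1 - s) for s, e in reversed(exons)],
                strand="-",
            ))
        fwd = ae.enumerate_events(locus(*txs))
        rev = ae.enumerate_events(locus(*mirrored))
        assert sorted(e.category for e in fwd) == sorted(e.category for e in rev)


# --------------------------------------------------------------- splice sites

def test_splice_site_classes_plus_and_minus():
    genome = {"chr1": "AAGTCCAGAA"}
    plus = make_tx("p", [(1, 2), (9, 10)])
    (rec,) = ae.classify_splice_sites(ae.extract_splice_chains([plus]), genome)
    assert (rec.donor_dinucleotide, rec.acceptor_dinucleotide, rec.site_class) == (
        "GT", "AG", "GT-AG",
    )
    genome_m = {"chr1": "AACTCCACAA"}
    minus = make_tx("m", [(1, 2), (9, 10)], strand="-")
    (rm,) = ae.classify_splice_sites(ae.extract_splice_chains([minus]), genome_m)
    assert rm.site_class == "GT-AG"
    # GC-AG and AT-AC and other
    for seq, cls in (("AAGCCCAGAA", "GC-AG"), ("AAATCCACAA", "AT-AC"),
                     ("AACCCCCCAA", "other")):
        (r,) = ae.classify_splice_sites(
            ae.extract_splice_chains([make_tx("t", [(1, 2), (9, 10)])]),
            {"chr1": seq},
        )
        assert r.site_class == cls


def test_splice_site_unique_and_short(caplog):
    genome = {"chr1": "AAGTCCAGAA" * 3}
    a = make_tx("a", [(1, 2), (9, 12)])
    b = make_tx("b", [(1, 2), (9, 14)])  # same intron 3-8
    recs = ae.classify_splice_sites(ae.extract_splice_chains([a, b]), genome)
    assert len(recs) == 1
    recs2 = ae.classify_splice_sites(
        ae.extract_splice_chains([a, b]), genome, unique=False
    )
    assert len(recs2) == 2
    with caplog.at_level("WARNING"):
        (short,) = ae.classify_splice_sites(
            ae.extract_splice_chains([make_tx("s", [(1, 2), (6, 8)])]), genome
        )
    assert short.site_class == "other" and "shorter than 4" in caplog.text
    tally = ae.tally_site_classes(recs + [short])
    assert tally == {"GT-AG": 1, "GC-AG": 0, "AT-AC": 0, "other": 1}


# -------------------------------------------------------- per-stage counting

def test_count_events_by_stage():
    t1 = make_tx("t1", [(1, 100), (201, 300)])
    t2 = make_tx("t2", [(1, 300)])
    (ev,) = ae.enumerate_events(locus(t1, t2))
    stage_fpkm = {
        "s1": {"t1": 5.0, "t2": 5.0},   # both sides on
        "s2": {"t1": 5.0, "t2": 0.05},  # one side below threshold
        "s3": {"t1": 0.1, "t2": 0.1},   # boundary: >= threshold counts
    }
    table = ae.count_events_by_stage([ev], stage_fpkm, ["s1", "s2", "s3"])
    assert table["s1"][ae.INTRON_RETENTION] == 1
    assert table["s2"][ae.INTRON_RETENTION] == 0
    assert table["s3"][ae.INTRON_RETENTION] == 1
    assert sum(table["s2"].values()) == 0
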
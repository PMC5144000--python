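"""Junction caller: candidate geometry, microhomology arbitration, aggregation,
fusion pairing."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from backsplice.caller import (
    CircCall,
    FusionJunction,
    Locus,
    aggregate_calls,
    call_junctions,
    microhomology_range,
    pair_fusion_circs,
    resolve_breakpoint,
    resolve_junction,
    select_bsj_candidates,
    select_fusion_candidates,
    BsjCandidate,
)
from backsplice.formats import AlignmentSegment, ChimericRead
from backsplice.maxent import SpliceStrength


def seg(chrom, strand, rs, re_, gs, ge):
    return AlignmentSegment(chrom, strand, rs, re_, gs, ge)


def read(read_id, segments, length=100, count=1, weight=1.0):
    return ChimericRead(read_id, "A" * length, segments, count, weight)


# ---------------------------------------------------------------------------
# candidate geometry


def test_canonical_backsplice_is_candidate():
    r = read("r", [seg("chr1", "+", 0, 50, 2000, 2050), seg("chr1", "+", 50, 100, 1000, 1050)])
    cands = select_bsj_candidates({"r": r})
    assert len(cands) == 1
    c = cands[0]
    assert (c.start, c.end, c.strand) == (1050 - 50, 2050, "+")
    assert c.donor == Locus("chr1", "+", 2050)
    assert c.acceptor == Locus("chr1", "+", 1000)


def test_collinear_pair_is_not_candidate():
    r = read("r", [seg("chr1", "+", 0, 50, 2000, 2050), seg("chr1", "+", 50, 100, 3000, 3050)])
    assert select_bsj_candidates({"r": r}) == []


def test_minus_strand_backsplice_geometry():
    # transcript runs right-to-left: later read part maps genomically downstream
    r = read("r", [seg("chr1", "-", 0, 50, 1000, 1050), seg("chr1", "-", 50, 100, 2000, 2050)])
    cands = select_bsj_candidates({"r": r})
    assert len(cands) == 1
    c = cands[0]
    assert (c.start, c.end) == (1000, 2050)
    assert c.donor == Locus("chr1", "-", 1000)
    assert c.acceptor == Locus("chr1", "-", 2050)


def test_strand_discordant_pair_routed_to_fusion():
    r = read("r", [seg("chr1", "+", 0, 50, 2000, 2050), seg("chr1", "-", 50, 100, 1000, 1050)])
    assert select_bsj_candidates({"r": r}) == []
    fus = select_fusion_candidates({"r": r})
    assert len(fus) == 1
    assert fus[0].donor == Locus("chr1", "+", 2050)
    assert fus[0].acceptor == Locus("chr1", "-", 1050)


def test_distant_same_strand_pair_routed_to_fusion():
    r = read("r", [seg("chr1", "+", 0, 50, 5_000_000, 5_000_050), seg("chr1", "+", 50, 100, 1000, 1050)])
    assert select_bsj_candidates({"r": r}) == []
    assert len(select_fusion_candidates({"r": r})) == 1


def test_short_segment_and_low_coverage_filters():
    r = read("r", [seg("chr1", "+", 0, 10, 2000, 2010), seg("chr1", "+", 10, 100, 1000, 1090)])
    assert select_bsj_candidates({"r": r}) == []  # 10 < min_segment
    r2 = read("r2", [seg("chr1", "+", 0, 40, 2000, 2040), seg("chr1", "+", 40, 80, 1000, 1040)])
    assert select_bsj_candidates({"r2": r2}) == []  # covers 80 of 100 < 0.9
    assert len(select_bsj_candidates({"r2": r2}, min_read_coverage=0.8)) == 1


def test_three_segment_read_pairs_match_brute_force():
    """All qualifying segment pairs enumerated, as by an exhaustive oracle."""
    segs = [
        seg("chr1", "+", 0, 30, 5000, 5030),
        seg("chr1", "+", 30, 70, 1000, 1040),
        seg("chr1", "+", 70, 100, 500, 530),
    ]
    r = read("r", segs)
    got = {(c.upstream_seg.read_start, c.downstream_seg.read_start)
           for c in select_bsj_candidates({"r": r})}
    expect = set()
    for a, b in itertools.combinations(sorted(segs, key=lambda s: s.read_start), 2):
        adjacent = b.read_start - a.read_end <= 5
        inverted = b.ref_start < a.ref_start
        long_enough = a.read_span >= 15 and b.read_span >= 15
        if adjacent and inverted and long_enough:
            expect.add((a.read_start, b.read_start))
    assert got == expect and len(got) == 2


# ---------------------------------------------------------------------------
# microhomology arbitration


def planted_plus_circle(genome30):
    """A '+'-strand circle over internal exons with planted splice sites."""
    for t in genome30.transcripts:
        if t.strand == "+" and len(t.exons) >= 4:
            start = t.exons[1][0]
            end = t.exons[2][1]
            if end - start >= 100:
                return t, start, end
    raise AssertionError("fixture genome lacks a suitable transcript")


def force_microhomology(genome30, start, end, chrom, m=2):
    seq = genome30.chromosomes[chrom]
    seq = seq[:end] + seq[start : start + m] + seq[end + m :]
    g = dict(genome30.chromosomes)
    g[chrom] = seq
    return g


def brute_force_resolve(genome, model, donor, acceptor, window=10, threshold=10.0):
    """Independent enumeration of every partition offset in +-window."""
    from backsplice.formats import revcomp

    def flank(locus, n, downstream):
        s = genome[locus.chrom]
        fwd = (locus.strand == "+") == downstream
        a, b = (locus.pos, locus.pos + n) if fwd else (locus.pos - n, locus.pos)
        frag = s[a:b] if 0 <= a <= b <= len(s) else None
        if frag is None:
            return None
        return frag if locus.strand == "+" else revcomp(frag)

    best = None
    for delta in range(-window, window + 1):
        n = abs(delta)
        if delta > 0:
            ok = flank(donor, n, True) == flank(acceptor, n, True) != None  # noqa: E711
        elif delta < 0:
            ok = flank(donor, n, False) == flank(acceptor, n, False) != None  # noqa: E711
        else:
            ok = True
        if not ok:
            continue
        d = Locus(donor.chrom, donor.strand, donor.pos + (delta if donor.strand == "+" else -delta))
        a = Locus(
            acceptor.chrom,
            acceptor.strand,
            acceptor.pos + (delta if acceptor.strand == "+" else -delta),
        )
        ss = model.splice_strength(genome, (d.chrom, d.strand, d.pos), (a.chrom, a.strand, a.pos))
        if ss.total == float("-inf"):
            continue
        rank = (-ss.total, abs(delta), a.pos)
        if best is None or rank < best[0]:
            best = (rank, (d, a, ss, delta))
    if best is None or best[1][2].total < threshold:
        return None
    return best[1]


def test_resolve_breakpoint_recovers_planted_partition(genome30, model):
    """With an engineered 2-nt microhomology, only the planted partition wins."""
    t, start, end = planted_plus_circle(genome30)
    genome = force_microhomology(genome30, start, end, t.chrom, m=2)
    # candidate reported 2 nt downstream of the true junction (aligner overshoot)
    cand = BsjCandidate(
        "r",
        seg(t.chrom, "+", 0, 50, end - 48, end + 2),
        seg(t.chrom, "+", 50, 100, start + 2, start + 52),
        t.chrom,
        "+",
        start + 2,
        end + 2,
    )
    bwd, fwd = microhomology_range(genome, cand.donor, cand.acceptor, 10)
    assert bwd >= 2
    call = resolve_breakpoint(cand, genome, model)
    assert call is not None
    assert (call.start, call.end) == (start, end)
    oracle = brute_force_resolve(genome, model, cand.donor, cand.acceptor)
    assert oracle is not None
    assert (oracle[0].pos, oracle[1].pos) == (call.end, call.start)


def test_resolve_rejects_below_threshold(genome30, model):
    """Random intergenic breakpoints carry no splice signal."""
    chrom = "chr1"
    cand = BsjCandidate(
        "r",
        seg(chrom, "+", 0, 50, 150, 200),
        seg(chrom, "+", 50, 100, 30, 80),
        chrom,
        "+",
        30,
        200,
    )
    assert resolve_breakpoint(cand, genome30.chromosomes, model) is None


def test_zero_ambiguity_candidate_returned_unchanged(genome30, model):
    t, start, end = planted_plus_circle(genome30)
    genome = genome30.chromosomes
    bwd, fwd = microhomology_range(genome, Locus(t.chrom, "+", end), Locus(t.chrom, "+", start), 10)
    cand = BsjCandidate(
        "r",
        seg(t.chrom, "+", 0, 50, end - 50, end),
        seg(t.chrom, "+", 50, 100, start, start + 50),
        t.chrom,
        "+",
        start,
        end,
    )
    call = resolve_breakpoint(cand, genome, model)
    assert call is not None and (call.start, call.end) == (start, end)
    if bwd == fwd == 0:
        rj = resolve_junction(genome, model, cand.donor, cand.acceptor)
        assert rj.offset == 0


# ---------------------------------------------------------------------------
# aggregation


def make_call(start=100, end=300):
    return CircCall("chr1", "+", start, end, SpliceStrength(6.0, 6.0))


def test_aggregate_sums_collapse_counts():
    per_read = [(make_call(), 2.0), (make_call(), 1.0), (make_call(), 1.0)]
    (merged,) = aggregate_calls(per_read)
    assert merged.support == 4.0


def test_aggregate_pair_weight_arithmetic():
    per_read = [(make_call(), 1.0), (make_call(), 0.5)]
    (merged,) = aggregate_calls(per_read)
    assert merged.support == 1.5


def test_aggregate_matches_groupby_oracle(rng):
    per_read, oracle = [], {}
    for _ in range(200):
        s = int(rng.integers(0, 5)) * 100
        w = float(rng.choice([0.5, 1.0, 2.0]))
        per_read.append((make_call(s, s + 500), w))
        oracle[s] = oracle.get(s, 0.0) + w
    merged = aggregate_calls(per_read)
    assert {c.start: c.support for c in merged} == pytest.approx(oracle)
    assert [c.start for c in merged] == sorted(oracle)


# ---------------------------------------------------------------------------
# fusion pairing


def fj(dchrom, dstrand, dpos, achrom, astrand, apos, support=5.0):
    return FusionJunction(
        Locus(dchrom, dstrand, dpos), Locus(achrom, astrand, apos), SpliceStrength(8, 8), support
    )


def test_reciprocal_pair_yields_one_fusion_circ():
    j1 = fj("chr1", "+", 1000, "chr2", "+", 5000)  # A_j -> B_m
    j2 = fj("chr2", "+", 5400, "chr1", "+", 800)  # B_n -> A_i
    calls = pair_fusion_circs([j1, j2])
    assert len(calls) == 1
    assert {calls[0].junction_ab.key, calls[0].junction_ba.key} == {j1.key, j2.key}
    assert not calls[0].multi_pairing


def test_lone_fusion_junction_is_linear_fusion_transcript_only():
    assert pair_fusion_circs([fj("chr1", "+", 1000, "chr2", "+", 5000)]) == []


def test_ordering_violation_rejected():
    j1 = fj("chr1", "+", 1000, "chr2", "+", 5000)
    j2 = fj("chr2", "+", 5400, "chr1", "+", 1200)  # acceptor downstream of donor: i > j
    assert pair_fusion_circs([j1, j2]) == []


def test_minus_strand_ordering_uses_transcript_orientation():
    # gene A on '-': upstream means larger genomic coordinate
    j1 = fj("chr1", "-", 1000, "chr2", "+", 5000)
    j2 = fj("chr2", "+", 5400, "chr1", "-", 1300)  # A_i acceptor genomically right = upstream
    assert len(pair_fusion_circs([j1, j2])) == 1
    j2_bad = fj("chr2", "+", 5400, "chr1", "-", 900)
    assert pair_fusion_circs([j1, j2_bad]) == []


def test_max_span_limits_pairing():
    j1 = fj("chr1", "+", 1000, "chr2", "+", 5000)
    j2 = fj("chr2", "+", 5400, "chr1", "+", 800)
    assert pair_fusion_circs([j1, j2], max_span=100) == []


def test_multi_pairing_flagged():
    j1 = fj("chr1", "+", 1000, "chr2", "+", 5000)
    j2 = fj("chr2", "+", 5400, "chr1", "+", 800)
    j3 = fj("chr2", "+", 5600, "chr1", "+", 700)
    calls = pair_fusion_circs([j1, j2, j3])
    assert len(calls) == 2
    assert all(c.multi_pairing for c in calls)


# ---------------------------------------------------------------------------
# whole-caller properties


def test_every_reported_call_reaches_threshold(genome30, model, aligner30, tmp_path):
    from backsplice import simulate as sim
    from tests.conftest import align_via_sam

    rng = np.random.default_rng(4)
    circs = sim.simulate_circs(genome30, rng=rng)
    reads1, _, _ = sim.simulate_reads(circs, genome30, None, read_len=100, rng=rng)
    _, parsed = align_via_sam(aligner30, genome30, [s for _, s in reads1], tmp_path)
    res = call_junctions(parsed.chimeric, genome30.chromosomes, model, threshold=10.0)
    assert res.circ_calls
    for c in res.circ_calls:
        assert c.splice_strength.total >= 10.0
        assert c.end - c.start >= 100
    for j in res.fusion_junctions:
        assert j.splice_strength.total >= 10.0
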
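"""Back-splice and fusion junction calling with microhomology arbitration.

A chimeric read whose segments map to the same chromosome and strand in
inverted genomic order is a back-splice junction (BSJ) candidate; segments on
different chromosomes/strands (or very distant same-strand loci) are fusion
junction candidates.  Sequence identity flanking the two breakpoints
(microhomology) makes the exact junction ambiguous from the read alone: every
partition of the read within the microhomology window is enumerated and the
one whose implied donor + acceptor splice strength is maximal is reported,
provided it reaches the score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats import AlignmentSegment, ChimericRead, revcomp
from .maxent import DEFAULT_THRESHOLD, SpliceSiteModel, SpliceStrength

MIN_SEGMENT = 15
MIN_READ_COVERAGE = 0.9
MICROHOMOLOGY_WINDOW = 10
MIN_CIRC_LEN = 100
CIRC_MAX_SPAN = 1_000_000
MAX_READ_GAP = 5  # junction segments must be (nearly) adjacent in the read


@dataclass(frozen=True, order=True)
class Locus:
    """A strand-aware breakpoint: 0-based inter-base genomic coordinate."""

    chrom: str
    strand: str
    pos: int


@dataclass(frozen=True)
class BsjCandidate:
    read_id: str
    upstream_seg: AlignmentSegment  # covers the LEFT (earlier) part of the read
    downstream_seg: AlignmentSegment
    chrom: str
    strand: str
    start: int  # implied circle start (acceptor side)
    end: int  # implied circle end (donor side), half-open

    @property
    def donor(self) -> Locus:
        pos = self.end if self.strand == "+" else self.start
        return Locus(self.chrom, self.strand, pos)

    @property
    def acceptor(self) -> Locus:
        pos = self.start if self.strand == "+" else self.end
        return Locus(self.chrom, self.strand, pos)


@dataclass(frozen=True)
class FusionCandidate:
    read_id: str
    upstream_seg: AlignmentSegment
    downstream_seg: AlignmentSegment
    donor: Locus
    acceptor: Locus


@dataclass
class CircCall:
    chrom: str
    strand: str
    start: int
    end: int
    splice_strength: SpliceStrength
    support: float = 0.0
    abundance: float | None = None

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def key(self):
        return (self.chrom, self.strand, self.start, self.end)


@dataclass
class FusionJunction:
    donor: Locus
    acceptor: Locus
    splice_strength: SpliceStrength
    support: float = 0.0

    @property
    def key(self):
        return (self.donor, self.acceptor)

    @property
    def junction_id(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{d.chrom}:{d.pos}:{d.strand}>{a.chrom}:{a.pos}:{a.strand}"


@dataclass
class FusionCircCall:
    junction_ab: FusionJunction
    junction_ba: FusionJunction
    multi_pairing: bool = False


@dataclass
class CallerStats:
    reads_examined: int = 0
    collinear_pairs: int = 0
    filtered_pairs: int = 0
    below_threshold: int = 0
    ambiguous_reads: int = 0
    low_mapq_pairs: int = 0


# ---------------------------------------------------------------------------
# Candidate selection


def _segment_pairs(segments: list[AlignmentSegment]):
    segs = sorted(segments, key=lambda s: (s.read_start, s.read_end))
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segs[i].read_end <= segs[j].read_start + min(
                segs[i].read_span, segs[j].read_span
            ) - 1:
                yield segs[i], segs[j]


def _read_length(read: ChimericRead) -> int:
    if read.sequence is not None:
        return len(read.sequence)
    return max(s.read_end for s in read.segments)


def _junction_loci(s1: AlignmentSegment, s2: AlignmentSegment) -> tuple[Locus, Locus]:
    """Donor (3' end of the read-upstream segment) and acceptor breakpoints.

    If the segments' read intervals overlap (an aligner placed microhomology
    bases on both sides), the partition is normalized to the start of the
    later segment by retracting the donor boundary.
    """
    overlap = max(0, s1.read_end - s2.read_start)
    if s1.strand == "+":
        donor = Locus(s1.chrom, "+", s1.ref_end - overlap)
    else:
        donor = Locus(s1.chrom, "-", s1.ref_start + overlap)
    if s2.strand == "+":
        acceptor = Locus(s2.chrom, "+", s2.ref_start)
    else:
        acceptor = Locus(s2.chrom, "-", s2.ref_end)
    return donor, acceptor


def select_bsj_candidates(
    chimeric: Mapping[str, ChimericRead],
    min_segment: int = MIN_SEGMENT,
    min_read_coverage: float = MIN_READ_COVERAGE,
    circ_max_span: int = CIRC_MAX_SPAN,
    stats: CallerStats | None = None,
) -> list[BsjCandidate]:
    """Same-chromosome, same-strand segment pairs in inverted genomic order."""
    out = []
    for read in chimeric.values():
        out.extend(
            _bsj_candidates_for_read(
                read, min_segment, min_read_coverage, circ_max_span, stats
            )
        )
    return out


def _aligned_coverage(read: ChimericRead) -> float:
    """Fraction of the read covered by the union of all its segments."""
    read_len = _read_length(read)
    covered, cur = 0, None
    for s in sorted(read.segments, key=lambda s: s.read_start):
        if cur is None or s.read_start > cur[1]:
            if cur:
                covered += cur[1] - cur[0]
            cur = [s.read_start, s.read_end]
        else:
            cur[1] = max(cur[1], s.read_end)
    if cur:
        covered += cur[1] - cur[0]
    return covered / read_len


def _pair_passes_filters(read, s1, s2, min_segment, min_read_coverage, stats) -> bool:
    """Both segments long enough, read-adjacent, and the read mostly aligned.

    Coverage is assessed over all of the read's segments, not just the pair:
    a read wrapping around a short circle legitimately splits into three
    blocks of which the junction pair covers only part.  The pair itself must
    be contiguous in the read (the junction is a single point in the read);
    pairs separated by another aligned block are linear-splice artifacts.
    """
    if s1.read_span < min_segment or s2.read_span < min_segment:
        if stats:
            stats.filtered_pairs += 1
        return False
    if s2.read_start - s1.read_end > MAX_READ_GAP:
        if stats:
            stats.filtered_pairs += 1
        return False
    if _aligned_coverage(read) < min_read_coverage:
        if stats:
            stats.filtered_pairs += 1
        return False
    return True


def _bsj_candidates_for_read(
    read, min_segment, min_read_coverage, circ_max_span, stats
) -> list[BsjCandidate]:
    out = []
    for s1, s2 in _segment_pairs(read.segments):
        if s1.chrom != s2.chrom or s1.strand != s2.strand:
            continue
        donor, acceptor = _junction_loci(s1, s2)
        if s1.strand == "+":
            inverted = s2.ref_start < s1.ref_start
            start, end = acceptor.pos, donor.pos
        else:
            inverted = s2.ref_start > s1.ref_start
            start, end = donor.pos, acceptor.pos
        if not inverted:
            if stats:
                stats.collinear_pairs += 1
            continue
        if end - start > circ_max_span:
            continue  # routed to fusion handling
        if not _pair_passes_filters(read, s1, s2, min_segment, min_read_coverage, stats):
            continue
        out.append(
            BsjCandidate(read.read_id, s1, s2, s1.chrom, s1.strand, start, end)
        )
    return out


def select_fusion_candidates(
    chimeric: Mapping[str, ChimericRead],
    min_segment: int = MIN_SEGMENT,
    min_read_coverage: float = MIN_READ_COVERAGE,
    circ_max_span: int = CIRC_MAX_SPAN,
    stats: CallerStats | None = None,
) -> list[FusionCandidate]:
    """Segment pairs on different chromosomes/strands, or >circ_max_span apart."""
    out = []
    for read in chimeric.values():
        for s1, s2 in _segment_pairs(read.segments):
            cross = s1.chrom != s2.chrom or s1.strand != s2.strand
            if not cross:
                span = max(s1.ref_end, s2.ref_end) - min(s1.ref_start, s2.ref_start)
                if span <= circ_max_span:
                    continue  # BSJ or short-range linear geometry
            if not _pair_passes_filters(read, s1, s2, min_segment, min_read_coverage, stats):
                continue
            donor, acceptor = _junction_loci(s1, s2)
            out.append(FusionCandidate(read.read_id, s1, s2, donor, acceptor))
    return out


# ---------------------------------------------------------------------------
# Microhomology arbitration


def _flank(genome, locus: Locus, n: int, downstream: bool) -> str | None:
    """n transcript-oriented bases immediately up/downstream of a breakpoint."""
    seq = genome.get(locus.chrom)
    if seq is None:
        return None
    fwd = (locus.strand == "+") == downstream
    if fwd:
        s, e = locus.pos, locus.pos + n
    else:
        s, e = locus.pos - n, locus.pos
    if s < 0 or e > len(seq):
        return None
    frag = seq[s:e]
    return frag if locus.strand == "+" else revcomp(frag)


def microhomology_range(genome, donor: Locus, acceptor: Locus, window: int) -> tuple[int, int]:
    """Maximal (backward, forward) shift of the partition point that keeps both
    segments exact-matching the genome; shifts are in transcript direction."""
    down_d = _flank(genome, donor, window, downstream=True) or ""
    down_a = _flank(genome, acceptor, window, downstream=True) or ""
    fwd = 0
    for x, y in zip(down_d, down_a):
        if x != y:
            break
        fwd += 1
    up_d = _flank(genome, donor, window, downstream=False) or ""
    up_a = _flank(genome, acceptor, window, downstream=False) or ""
    bwd = 0
    for x, y in zip(reversed(up_d), reversed(up_a)):
        if x != y:
            break
        bwd += 1
    return bwd, fwd


def _shift_locus(locus: Locus, delta: int) -> Locus:
    pos = locus.pos + delta if locus.strand == "+" else locus.pos - delta
    return Locus(locus.chrom, locus.strand, pos)


@dataclass(frozen=True)
class ResolvedJunction:
    donor: Locus
    acceptor: Locus
    splice_strength: SpliceStrength
    offset: int


def resolve_junction(
    genome,
    model: SpliceSiteModel,
    donor: Locus,
    acceptor: Locus,
    threshold: float = DEFAULT_THRESHOLD,
    window: int = MICROHOMOLOGY_WINDOW,
) -> ResolvedJunction | None:
    """Pick the partition in the microhomology window with maximal splice strength.

    Ties are broken by the smallest absolute offset, then the leftmost genomic
    acceptor position.  Returns None if no offset reaches the threshold (or
    every window is unscorable).
    """
    bwd, fwd = microhomology_range(genome, donor, acceptor, window)
    best = None
    for delta in range(-bwd, fwd + 1):
        d = _shift_locus(donor, delta)
        a = _shift_locus(acceptor, delta)
        ss = model.splice_strength(
            genome, (d.chrom, d.strand, d.pos), (a.chrom, a.strand, a.pos)
        )
        if ss.total == float("-inf"):
            continue
        rank = (-ss.total, abs(delta), a.pos)
        if best is None or rank < best[0]:
            best = (rank, ResolvedJunction(d, a, ss, delta))
    if best is None or best[1].splice_strength.total < threshold:
        return None
    return best[1]


def resolve_breakpoint(
    cand: BsjCandidate,
    genome,
    model: SpliceSiteModel,
    threshold: float = DEFAULT_THRESHOLD,
    window: int = MICROHOMOLOGY_WINDOW,
    min_circ_len: int = MIN_CIRC_LEN,
) -> CircCall | None:
    """Resolve a BSJ candidate to an exact circle, or None below threshold."""
    if cand.end - cand.start < min_circ_len:
        return None
    rj = resolve_junction(genome, model, cand.donor, cand.acceptor, threshold, window)
    if rj is None:
        return None
    if cand.strand == "+":
        start, end = rj.acceptor.pos, rj.donor.pos
    else:
        start, end = rj.donor.pos, rj.acceptor.pos
    return CircCall(cand.chrom, cand.strand, start, end, rj.splice_strength)


# ---------------------------------------------------------------------------
# Per-read arbitration and aggregation


def aggregate_calls(per_read: Iterable[tuple[CircCall, float]]) -> list[CircCall]:
    """Merge identical junctions; support = sum of read weights."""
    merged: dict[tuple, CircCall] = {}
    for call, weight in per_read:
        cur = merged.get(call.key)
        if cur is None:
            cur = CircCall(
                call.chrom, call.strand, call.start, call.end, call.splice_strength
            )
            merged[call.key] = cur
        cur.support += weight
    return sorted(merged.values(), key=lambda c: (c.chrom, c.start, c.end, c.strand))


def aggregate_fusion_junctions(
    per_read: Iterable[tuple[ResolvedJunction, float]]
) -> list[FusionJunction]:
    merged: dict[tuple, FusionJunction] = {}
    for rj, weight in per_read:
        cur = merged.get((rj.donor, rj.acceptor))
        if cur is None:
            cur = FusionJunction(rj.donor, rj.acceptor, rj.splice_strength)
            merged[(rj.donor, rj.acceptor)] = cur
        cur.support += weight
    return sorted(merged.values(), key=lambda j: (j.donor, j.acceptor))


@dataclass
class CallResult:
    circ_calls: list[CircCall] = field(default_factory=list)
    fusion_junctions: list[FusionJunction] = field(default_factory=list)
    stats: CallerStats = field(default_factory=CallerStats)


def call_junctions(
    chimeric: Mapping[str, ChimericRead],
    genome: dict[str, str],
    model: SpliceSiteModel,
    threshold: float = DEFAULT_THRESHOLD,
    window: int = MICROHOMOLOGY_WINDOW,
    min_segment: int = MIN_SEGMENT,
    min_read_coverage: float = MIN_READ_COVERAGE,
    min_circ_len: int = MIN_CIRC_LEN,
    circ_max_span: int = CIRC_MAX_SPAN,
) -> CallResult:
    """Resolve every chimeric read to at most one junction and aggregate.

    A read admitting several interpretations (multiple qualifying pairs,
    and/or both BSJ and fusion geometries) is assigned to the interpretation
    whose segment pair explains the most read bases, with ties resolved by
    the highest splice strength; reads whose best interpretation is attained
    by more than one distinct junction are dropped as ambiguous.
    """
    res = CallResult()
    stats = res.stats
    per_read_circ: list[tuple[CircCall, float]] = []
    per_read_fusion: list[tuple[ResolvedJunction, float]] = []

    def pair_bases(cand) -> int:
        s1, s2 = cand.upstream_seg, cand.downstream_seg
        return s1.read_span + s2.read_span - max(0, s1.read_end - s2.read_start)

    for read in chimeric.values():
        stats.reads_examined += 1
        one = {read.read_id: read}
        resolved: list[tuple[tuple[int, float], str, object]] = []
        for cand in select_bsj_candidates(one, min_segment, min_read_coverage, circ_max_span, stats):
            call = resolve_breakpoint(cand, genome, model, threshold, window, min_circ_len)
            if call is None:
                stats.below_threshold += 1
            else:
                resolved.append(((pair_bases(cand), call.splice_strength.total), "circ", call))
        for cand in select_fusion_candidates(one, min_segment, min_read_coverage, circ_max_span, stats):
            rj = resolve_junction(genome, model, cand.donor, cand.acceptor, threshold, window)
            if rj is None:
                stats.below_threshold += 1
            else:
                resolved.append(((pair_bases(cand), rj.splice_strength.total), "fusion", rj))
        if not resolved:
            continue
        best_rank = max(r for r, _, _ in resolved)
        best = [(kind, obj) for r, kind, obj in resolved if r == best_rank]
        keys = {
            (obj.key if kind == "circ" else (obj.donor, obj.acceptor))
            for kind, obj in best
        }
        if len(keys) > 1:
            stats.ambiguous_reads += 1
            continue
        kind, obj = best[0]
        if kind == "circ":
            per_read_circ.append((obj, read.weight))
        else:
            per_read_fusion.append((obj, read.weight))
    res.circ_calls = aggregate_calls(per_read_circ)
    res.fusion_junctions = aggregate_fusion_junctions(per_read_fusion)
    return res


def call_fusion_junctions(
    chimeric: Mapping[str, ChimericRead],
    genome: dict[str, str],
    model: SpliceSiteModel,
    threshold: float = DEFAULT_THRESHOLD,
    **kwargs,
) -> list[FusionJunction]:
    return call_junctions(chimeric, genome, model, threshold, **kwargs).fusion_junctions


# ---------------------------------------------------------------------------
# Reciprocal fusion pairing


def _upstream_or_equal(a: Locus, b: Locus) -> bool:
    """True if breakpoint a is at/transcript-upstream of b (same chrom+strand)."""
    return a.pos <= b.pos if a.strand == "+" else a.pos >= b.pos


def pair_fusion_circs(
    junctions: list[FusionJunction], max_span: int = CIRC_MAX_SPAN
) -> list[FusionCircCall]:
    """Pair reciprocal fusion junctions (A_j->B_m with B_n->A_i, i<=j, m<=n).

    Lone junctions indicate linear fusion transcripts, not fusion circRNAs,
    and yield no call.  A junction may participate in several pairings; such
    calls carry a multi-pairing flag.
    """
    calls: list[FusionCircCall] = []
    usage: dict[tuple, int] = {}
    for x, j1 in enumerate(junctions):
        for j2 in junctions[x + 1 :]:
            for ab, ba in ((j1, j2), (j2, j1)):
                # gene A carries ab's donor and ba's acceptor
                if (ab.donor.chrom, ab.donor.strand) != (ba.acceptor.chrom, ba.acceptor.strand):
                    continue
                if (ab.acceptor.chrom, ab.acceptor.strand) != (ba.donor.chrom, ba.donor.strand):
                    continue
                if not _upstream_or_equal(ba.acceptor, ab.donor):  # i <= j on gene A
                    continue
                if not _upstream_or_equal(ab.acceptor, ba.donor):  # m <= n on gene B
                    continue
                if abs(ab.donor.pos - ba.acceptor.pos) > max_span:
                    continue
                if abs(ba.donor.pos - ab.acceptor.pos) > max_span:
                    continue
                calls.append(FusionCircCall(ab, ba))
                usage[ab.key] = usage.get(ab.key, 0) + 1
                usage[ba.key] = usage.get(ba.key, 0) + 1
                break  # one orientation per unordered pair
    for c in calls:
        c.multi_pairing = usage[c.junction_ab.key] > 1 or usage[c.junction_ba.key] > 1
    return calls
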
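"""Benchmark simulator: synthetic genomes with planted splice sites, circRNA
and fusion-circRNA definitions, and error-free SE/PE junction reads with truth
tables.

The generator emulates the benchmark design of exon-derived circRNAs: genes
with realistic exon/intron structure are laid on random chromosome sequence,
every internal exon boundary carries a donor or acceptor window sampled from
the splice-site model (rejection-sampled to score comfortably above the
caller threshold), circles are built from one or two internal exons and
discarded under 100 nt, each definition receives a fixed number of error-free
reads placed uniformly among junction-spanning positions, and linear decoy
reads are drawn from transcripts longer than 300 nt.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .caller import Locus
from .formats import Transcript, revcomp
from .maxent import (
    ACCEPTOR_WINDOW,
    BASES,
    DEFAULT_THRESHOLD,
    DONOR_WINDOW,
    SpliceSiteModel,
    train_splice_model,
)

MIN_FLANK = 4  # junction reads carry at least this many bases on each side
READS_PER_DEFINITION = 20
READS_PER_FUSION_JUNCTION = 10
N_FUSION_EVENTS = 10
MIN_LINEAR_LENGTH = 300
MIN_CIRC_LENGTH = 100
FRAC_TWO_CIRC = 0.05


# ---------------------------------------------------------------------------
# Splice-site training material (synthetic consensus PWMs)

def canonical_donor_pwm() -> np.ndarray:
    """Donor 9-mer consensus (A,C,G,T columns): MAG|GTRAGT-like."""
    return np.array(
        [
            [0.30, 0.35, 0.20, 0.15],
            [0.65, 0.10, 0.15, 0.10],
            [0.08, 0.05, 0.80, 0.07],
            [0.01, 0.01, 0.97, 0.01],  # +1 G
            [0.01, 0.01, 0.01, 0.97],  # +2 T
            [0.60, 0.03, 0.30, 0.07],
            [0.70, 0.08, 0.12, 0.10],
            [0.06, 0.06, 0.80, 0.08],
            [0.15, 0.15, 0.20, 0.50],
        ]
    )


def canonical_acceptor_pwm() -> np.ndarray:
    """Acceptor 23-mer consensus: polypyrimidine tract + AG | G-rich exon start."""
    rows = [[0.07, 0.40, 0.08, 0.45]] * 18
    rows += [
        [0.95, 0.02, 0.02, 0.01],  # branch-distal A
        [0.01, 0.01, 0.97, 0.01],  # intron-terminal G
        [0.25, 0.12, 0.50, 0.13],
        [0.30, 0.25, 0.25, 0.20],
        [0.25, 0.25, 0.25, 0.25],
    ]
    return np.array(rows)


def sample_pwm_sites(pwm: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    cols = [rng.choice(4, size=n, p=row) for row in pwm]
    mat = np.stack(cols, axis=1)
    return ["".join(BASES[k] for k in row) for row in mat]


def default_splice_model(seed: int = 0, n_train: int = 2000) -> SpliceSiteModel:
    """Splice-site model trained on sites sampled from the synthetic consensus."""
    rng = np.random.default_rng(seed)
    donors = sample_pwm_sites(canonical_donor_pwm(), n_train, rng)
    acceptors = sample_pwm_sites(canonical_acceptor_pwm(), n_train, rng)
    return train_splice_model(donors, acceptors)


# ---------------------------------------------------------------------------
# Genome construction

@dataclass(frozen=True)
class PlantedSite:
    kind: str  # "donor" | "acceptor"
    chrom: str
    strand: str
    breakpoint: int
    score: float


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    transcripts: list[Transcript]
    planted_sites: list[PlantedSite]
    model: SpliceSiteModel


def _rejection_sample_sites(
    dist, background, n: int, min_score: float, rng, max_tries: int = 200
) -> list[str]:
    """Sites sampled from the model's high-probability region (score >= min_score)."""
    out: list[str] = []
    bg_log2 = np.log2(background)
    for _ in range(max_tries):
        need = n - len(out)
        if need <= 0:
            break
        batch = dist.sample_array(rng, max(need * 4, 64))
        scores = dist.log2_prob_array(batch) - bg_log2[batch].sum(axis=1)
        for row, sc in zip(batch, scores):
            if sc >= min_score:
                out.append("".join(BASES[k] for k in row))
                if len(out) == n:
                    break
    if len(out) < n:
        raise RuntimeError("rejection sampling failed; lower the planting score floor")
    return out


def make_genome(
    n_genes: int = 50,
    seed: int = 0,
    model: SpliceSiteModel | None = None,
    n_chroms: int = 2,
    exons_per_gene: tuple[int, int] = (3, 6),
    exon_len: tuple[int, int] = (60, 200),
    intron_len: tuple[int, int] = (80, 400),
    intergenic: tuple[int, int] = (200, 600),
    threshold: float = DEFAULT_THRESHOLD,
    planting_margin: float = 2.0,
) -> SyntheticGenome:
    """Random genome with one multi-exon gene model per gene.

    Every internal exon boundary carries a donor (exon 3' end) or acceptor
    (exon 5' start) window sampled from the model with per-site score at
    least ``threshold + planting_margin``, so each planted site individually
    clears the caller's (total-score) threshold and any planted donor +
    acceptor pair does so with a wide margin.
    """
    if exon_len[0] < 20:
        raise ValueError("exon length distribution must not yield exons < 20 nt")
    if intron_len[0] < sum(DONOR_WINDOW) + sum(ACCEPTOR_WINDOW):
        raise ValueError("introns must be long enough to hold both splice windows")
    rng = np.random.default_rng(seed)
    if model is None:
        model = default_splice_model(int(rng.integers(2**31)))
    per_site_floor = threshold + planting_margin

    # pre-draw planted windows in bulk
    n_boundaries = 0
    gene_layout = []
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exlens = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        inlens = rng.integers(intron_len[0], intron_len[1] + 1, size=max(n_ex - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_layout.append((n_ex, exlens, inlens, strand))
        n_boundaries += n_ex - 1
    donor_pool = _rejection_sample_sites(
        model.donor, model.background, n_boundaries, per_site_floor, rng
    )
    acceptor_pool = _rejection_sample_sites(
        model.acceptor, model.background, n_boundaries, per_site_floor, rng
    )

    chroms = {f"chr{i + 1}": [] for i in range(n_chroms)}
    transcripts: list[Transcript] = []
    planted: list[PlantedSite] = []
    cursors = {c: 0 for c in chroms}
    d_i = a_i = 0

    def random_seq(n: int) -> str:
        return "".join(BASES[k] for k in rng.integers(0, 4, size=n))

    for g, (n_ex, exlens, inlens, strand) in enumerate(gene_layout):
        chrom = f"chr{g % n_chroms + 1}"
        parts = chroms[chrom]
        gap = int(rng.integers(intergenic[0], intergenic[1] + 1))
        parts.append(random_seq(gap))
        pos = cursors[chrom] + gap
        exons = []
        body = []
        p = pos
        for k in range(n_ex):
            exons.append((p, p + int(exlens[k])))
            body.append(random_seq(int(exlens[k])))
            p += int(exlens[k])
            if k < n_ex - 1:
                body.append(random_seq(int(inlens[k])))
                p += int(inlens[k])
        gene_seq = list("".join(body))
        du, dd = DONOR_WINDOW
        au, ad = ACCEPTOR_WINDOW
        # one donor + one acceptor per intron; on '-' strand the transcript
        # runs right-to-left so the donor flanks the genomic-RIGHT exon's start
        for k in range(n_ex - 1):
            left_end, right_start = exons[k][1], exons[k + 1][0]
            dsite, asite = donor_pool[d_i], acceptor_pool[a_i]
            d_i += 1
            a_i += 1
            if strand == "+":
                db, ab = left_end, right_start
                gene_seq[db - du - pos : db + dd - pos] = dsite
                gene_seq[ab - au - pos : ab + ad - pos] = asite
            else:
                db, ab = right_start, left_end
                gene_seq[db - dd - pos : db + du - pos] = revcomp(dsite)
                gene_seq[ab - ad - pos : ab + au - pos] = revcomp(asite)
            planted.append(PlantedSite("donor", chrom, strand, db, model.score_donor(dsite)))
            planted.append(
                PlantedSite("acceptor", chrom, strand, ab, model.score_acceptor(asite))
            )
        parts.append("".join(gene_seq))
        cursors[chrom] = p
        transcripts.append(Transcript(f"tx{g}", f"gene{g}", chrom, strand, exons))

    genome = {c: "".join(parts) for c, parts in chroms.items()}
    return SyntheticGenome(genome, transcripts, planted, model)

# ---------------------------------------------------------------------------
# CircRNA definitions


@dataclass(frozen=True)
class CircDef:
    circ_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    monomer: str


def _tx_order_exons(t: Transcript) -> list[tuple[int, int]]:
    return t.exons if t.strand == "+" else list(reversed(t.exons))


def _exon_seq(genome, t: Transcript, exon: tuple[int, int]) -> str:
    s = genome[t.chrom][exon[0] : exon[1]]
    return revcomp(s) if t.strand == "-" else s


def _circ_from_exons(genome, t: Transcript, lo: int, hi: int) -> CircDef:
    """Circle over genomic exon indices [lo, hi] of transcript t."""
    start = t.exons[lo][0]
    end = t.exons[hi][1]
    block = t.exons[lo : hi + 1]
    monomer = "".join(genome[t.chrom][s:e] for s, e in block)
    if t.strand == "-":
        monomer = revcomp(monomer)
    circ_id = f"{t.chrom}:{start}-{end}:{t.strand}"
    return CircDef(circ_id, t.transcript_id, t.chrom, t.strand, start, end, monomer)


def simulate_circs(
    genome: SyntheticGenome,
    frac_two_circ: float = FRAC_TWO_CIRC,
    min_len: int = MIN_CIRC_LENGTH,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CircDef]:
    """One circle of 1-2 internal exons per >=3-exon transcript; a fraction of
    transcripts receives a second, distinct circle; short circles discarded."""
    rng = np.random.default_rng(seed) if rng is None else rng
    chroms = genome.chromosomes
    defs: list[CircDef] = []
    for t in genome.transcripts:
        n = len(t.exons)
        if n < 3:
            continue
        picks = 2 if rng.random() < frac_two_circ else 1
        chosen: set[tuple[int, int]] = set()
        for _ in range(picks):
            for _attempt in range(10):
                width = 1 if n == 3 else int(rng.integers(1, 3))
                lo = int(rng.integers(1, n - width))  # internal: 1 .. n-2
                key = (lo, lo + width - 1)
                if key not in chosen:
                    chosen.add(key)
                    break
        for lo, hi in sorted(chosen):
            cd = _circ_from_exons(chroms, t, lo, hi)
            if len(cd.monomer) >= min_len:
                defs.append(cd)
    return defs


# ---------------------------------------------------------------------------
# Fusion circRNA definitions


@dataclass(frozen=True)
class FusionDef:
    event_id: str
    circle_seq: str
    junction_pos: int  # position of the A_j -> B_m junction within circle_seq
    junction_ab: tuple[Locus, Locus]  # (donor, acceptor)
    junction_ba: tuple[Locus, Locus]
    gene_a: str
    gene_b: str


def _internal_range(t: Transcript, rng, min_part_len: int, genome) -> tuple[int, int, str] | None:
    """Contiguous transcript-internal exon range with concat length >= min_part_len.

    Returns genomic exon index range (lo, hi) and the concatenated sequence,
    or None if the transcript cannot supply one.
    """
    n = len(t.exons)
    if n < 3:
        return None
    internal = list(range(1, n - 1))
    start_choices = internal.copy()
    rng.shuffle(start_choices)
    for lo in start_choices:
        hi = lo
        total = t.exons[lo][1] - t.exons[lo][0]
        while total < min_part_len and hi + 1 <= n - 2:
            hi += 1
            total += t.exons[hi][1] - t.exons[hi][0]
        if total >= min_part_len:
            seq = "".join(genome[t.chrom][s:e] for s, e in t.exons[lo : hi + 1])
            if t.strand == "-":
                seq = revcomp(seq)
            return lo, hi, seq
    return None


def _donor_locus(t: Transcript, genomic_exon_idx: int) -> Locus:
    """Donor breakpoint at the transcript 3' end of a genomic exon."""
    s, e = t.exons[genomic_exon_idx]
    return Locus(t.chrom, t.strand, e if t.strand == "+" else s)


def _acceptor_locus(t: Transcript, genomic_exon_idx: int) -> Locus:
    s, e = t.exons[genomic_exon_idx]
    return Locus(t.chrom, t.strand, s if t.strand == "+" else e)


def simulate_fusions(
    genome: SyntheticGenome,
    n_events: int = N_FUSION_EVENTS,
    min_part_len: int = 150,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[FusionDef]:
    """Reciprocal fusion circles: internal exon ranges A[i..j], B[m..n] joined
    A_j->B_m and B_n->A_i, with the two genes on different chromosomes."""
    rng = np.random.default_rng(seed) if rng is None else rng
    chroms = genome.chromosomes
    eligible = [t for t in genome.transcripts if len(t.exons) >= 3]
    defs: list[FusionDef] = []
    seen_junctions: set = set()
    if len({t.chrom for t in eligible}) < 2:
        raise ValueError("need multi-exon genes on at least two chromosomes")
    attempts = 0
    while len(defs) < n_events and attempts < n_events * 50:
        attempts += 1
        ta, tb = (eligible[i] for i in rng.choice(len(eligible), size=2, replace=False))
        if ta.chrom == tb.chrom:
            continue
        ra = _internal_range(ta, rng, min_part_len, chroms)
        rb = _internal_range(tb, rng, min_part_len, chroms)
        if ra is None or rb is None:
            continue
        lo_a, hi_a, seq_a = ra
        lo_b, hi_b, seq_b = rb
        # transcript-order endpoints: on '-' strand the transcript-first exon
        # of the range is the genomic-rightmost one
        a_first, a_last = (lo_a, hi_a) if ta.strand == "+" else (hi_a, lo_a)
        b_first, b_last = (lo_b, hi_b) if tb.strand == "+" else (hi_b, lo_b)
        jab = (_donor_locus(ta, a_last), _acceptor_locus(tb, b_first))
        jba = (_donor_locus(tb, b_last), _acceptor_locus(ta, a_first))
        if any(j in seen_junctions for j in (jab, jba)):
            continue  # keep the n_events * 2 true junctions distinct
        seen_junctions.update((jab, jba))
        defs.append(
            FusionDef(
                f"fusion{len(defs)}",
                seq_a + seq_b,
                len(seq_a),
                jab,
                jba,
                ta.gene_id,
                tb.gene_id,
            )
        )
    if len(defs) < n_events:
        raise RuntimeError("could not construct the requested number of fusion events")
    return defs


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimTruth:
    seed: int | None
    circ_counts: dict[str, int] = field(default_factory=dict)
    linear_counts: dict[str, int] = field(default_factory=dict)
    fusion_counts: dict[tuple[Locus, Locus], int] = field(default_factory=dict)
    fusion_events: list[FusionDef] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return (
            sum(self.circ_counts.values())
            + sum(self.linear_counts.values())
            + sum(self.fusion_counts.values())
        )


def _junction_read_starts(
    circle_len: int, junction: int, read_len: int, n: int, min_flank: int, rng
) -> list[int]:
    """Uniform read starts (on the tiled circle) crossing `junction` with at
    least min_flank bases on each side."""
    lo = max(0, junction - read_len + min_flank)
    hi = junction - min_flank
    if hi < lo:
        return []
    return [int(x) for x in rng.integers(lo, hi + 1, size=n)]


def _tile(seq: str, need: int) -> str:
    reps = max(2, -(-need // len(seq)) + 1)
    return seq * reps


def simulate_reads(
    circ_defs: list[CircDef],
    genome: SyntheticGenome,
    fusion_defs: list[FusionDef] | None = None,
    mode: str = "SE",
    read_len: int = 100,
    n_reads_each: int = READS_PER_DEFINITION,
    reads_per_junction: int = READS_PER_FUSION_JUNCTION,
    insert_mean: float = 200.0,
    insert_sd: float = 50.0,
    min_flank: int = MIN_FLANK,
    min_linear_len: int = MIN_LINEAR_LENGTH,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]] | None, SimTruth]:
    """Error-free reads for circle, linear-decoy and fusion definitions.

    Returns (reads, mates2, truth); mates2 is None in SE mode.  Circle reads
    are placed uniformly among BSJ-spanning positions with >= min_flank bases
    on each side of the junction; PE inserts are drawn from N(insert_mean,
    insert_sd) truncated to [read_len, monomer length] (<=100 redraws, then
    the definition is skipped); linear reads are drawn uniformly from spliced
    transcripts longer than min_linear_len.  Read ids encode their truth
    record.  Deterministic given the seed.
    """
    if mode not in ("SE", "PE"):
        raise ValueError("mode must be SE or PE")
    rng = np.random.default_rng(seed) if rng is None else rng
    truth = SimTruth(seed)
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []

    def emit(rid: str, tiled: str, p: int, insert: int):
        if mode == "SE":
            reads1.append((rid, tiled[p : p + read_len]))
        else:
            reads1.append((rid, tiled[p : p + read_len]))
            reads2.append((rid, revcomp(tiled[p + insert - read_len : p + insert])))

    for cd in circ_defs:
        L = len(cd.monomer)
        if read_len > L and mode == "PE":
            warnings.warn(f"{cd.circ_id}: monomer shorter than read; skipped in PE mode")
            continue
        tiled = _tile(cd.monomer, read_len + L)
        n_emitted = 0
        for k in range(n_reads_each):
            if mode == "SE":
                starts = _junction_read_starts(L, L, read_len, 1, min_flank, rng)
                if not starts:
                    break
                emit(f"circ|{cd.circ_id}|{k}", tiled, starts[0], read_len)
                n_emitted += 1
            else:
                insert = None
                for _ in range(100):
                    x = int(round(rng.normal(insert_mean, insert_sd)))
                    if read_len <= x <= L:
                        insert = x
                        break
                if insert is None:
                    break
                lo = max(0, L - insert + min_flank)
                hi = L - min_flank
                if hi < lo:
                    break
                p = int(rng.integers(lo, hi + 1))
                emit(f"circ|{cd.circ_id}|{k}", tiled, p, insert)
                n_emitted += 1
        if n_emitted:
            truth.circ_counts[cd.circ_id] = n_emitted
        else:
            warnings.warn(f"{cd.circ_id}: no valid junction-spanning placement")

    for t in genome.transcripts:
        seq = t.spliced_sequence(genome.chromosomes)
        if len(seq) <= min_linear_len or len(seq) < read_len:
            continue
        n_emitted = 0
        for k in range(n_reads_each):
            if mode == "SE":
                p = int(rng.integers(0, len(seq) - read_len + 1))
                reads1.append((f"linear|{t.transcript_id}|{k}", seq[p : p + read_len]))
                n_emitted += 1
            else:
                insert = None
                for _ in range(100):
                    x = int(round(rng.normal(insert_mean, insert_sd)))
                    if read_len <= x <= len(seq):
                        insert = x
                        break
                if insert is None:
                    break
                p = int(rng.integers(0, len(seq) - insert + 1))
                reads1.append((f"linear|{t.transcript_id}|{k}", seq[p : p + read_len]))
                reads2.append(
                    (f"linear|{t.transcript_id}|{k}", revcomp(seq[p + insert - read_len : p + insert]))
                )
                n_emitted += 1
        if n_emitted:
            truth.linear_counts[t.transcript_id] = n_emitted

    for fd in fusion_defs or []:
        C = len(fd.circle_seq)
        tiled = _tile(fd.circle_seq, read_len + C)
        truth.fusion_events.append(fd)
        for tag, junction_pos, key in (
            ("AB", fd.junction_pos, fd.junction_ab),
            ("BA", C, fd.junction_ba),
        ):
            starts = _junction_read_starts(
                C, junction_pos, read_len, reads_per_junction, min_flank, rng
            )
            for k, p in enumerate(starts):
                if mode == "SE":
                    reads1.append((f"fusion|{fd.event_id}|{tag}|{k}", tiled[p : p + read_len]))
                else:
                    insert = max(read_len, min(C, int(round(rng.normal(insert_mean, insert_sd)))))
                    reads1.append((f"fusion|{fd.event_id}|{tag}|{k}", tiled[p : p + read_len]))
                    reads2.append(
                        (
                            f"fusion|{fd.event_id}|{tag}|{k}",
                            revcomp(tiled[p + insert - read_len : p + insert]),
                        )
                    )
            if starts:
                truth.fusion_counts[key] = len(starts)

    return reads1, (reads2 if mode == "PE" else None), truth
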
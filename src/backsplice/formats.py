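"""Standard-format I/O, read collapsing and paired-end to single-end conversion.

All internal coordinates are 0-based half-open.  SAM and GTF coordinates are
converted on read; BED is written natively 0-based.  FASTQ/FASTA readers are
gzip-transparent.  Base qualities are discarded after parsing: the pipeline is
alignment-driven and quantification counts reads, not base qualities.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp

VALID_BASES = frozenset("ACGTN")

# read origins
SE = "SE"
MERGED_PAIR = "MERGED_PAIR"
MATE1 = "MATE1"
MATE2 = "MATE2"


def revcomp(seq: str) -> str:
    return _bio_revcomp(seq)


class FastqParseError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class RawRead:
    """A read entering the collapser: sequence plus provenance and weight.

    ``pair_weight`` is 1.0 for single-end reads and merged pairs, and 0.5 for
    each mate of a pair that could not be merged, so that every input read or
    read pair contributes exactly 1 to downstream counts.
    """

    sequence: str
    origin: str = SE
    pair_weight: float = 1.0


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct read sequence with its multiplicity."""

    read_id: str
    sequence: str
    count: int
    origin: str = SE
    pair_weight: float = 1.0

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.sequence or set(self.sequence) - VALID_BASES:
            raise ValueError(f"invalid sequence for {self.read_id!r}")

    @property
    def weight(self) -> float:
        """Total library weight carried by this record."""
        return self.count * self.pair_weight


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned block of a read, with the read interval on the forward read."""

    chrom: str
    strand: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    edit_distance: int = 0
    mapq: int = 60

    def __post_init__(self):
        if not (self.read_start < self.read_end and self.ref_start < self.ref_end):
            raise ValueError("degenerate alignment segment")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class ChimericRead:
    """All aligned segments of one (collapsed) read."""

    read_id: str
    sequence: str | None
    segments: list[AlignmentSegment]
    count: int = 1
    pair_weight: float = 1.0

    @property
    def weight(self) -> float:
        return self.count * self.pair_weight


@dataclass
class Transcript:
    """Exon model; exons are 0-based half-open, sorted by genomic start."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


def open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, uppercase sequence); fatal on a malformed record."""
    with open_text(path) as fh:
        it = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {idx}: {exc}") from exc
            yield rec.id, str(rec.seq).upper()
            idx += 1


def read_fasta(path) -> Iterator[tuple[str, str]]:
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper()


def load_genome(path) -> dict[str, str]:
    """Load a (small) genome FASTA fully into memory."""
    return dict(read_fasta(path))


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Read collapsing and pair merging

_ID_RE = re.compile(r"_c(\d+)_w(1\.0|0\.5)$")


def encode_read_id(idx: int, count: int, pair_weight: float) -> str:
    """Collapsed-read ids carry multiplicity through external aligners."""
    return f"cr{idx}_c{count}_w{pair_weight:.1f}"


def decode_read_id(read_id: str) -> tuple[int, float]:
    """Recover (count, pair_weight) from an encoded id; (1, 1.0) if plain."""
    m = _ID_RE.search(read_id)
    if m:
        return int(m.group(1)), float(m.group(2))
    return 1, 1.0


def collapse_reads(reads: Iterable[RawRead | str]) -> list[CollapsedRead]:
    """Collapse identical sequences, keyed by (sequence, origin, pair_weight).

    Output is sorted by sequence so collapsing is order-independent.  The sum
    of ``count * pair_weight`` over the output equals the number of input
    reads (SE) or read pairs (PE).
    """
    tally: dict[tuple[str, str, float], int] = {}
    for r in reads:
        if isinstance(r, str):
            r = RawRead(r)
        seq = r.sequence.upper()
        if not seq or set(seq) - VALID_BASES:
            raise FastqParseError(f"invalid read sequence {seq[:20]!r}...")
        key = (seq, r.origin, r.pair_weight)
        tally[key] = tally.get(key, 0) + 1
    out = []
    for idx, (seq, origin, w) in enumerate(sorted(tally)):
        n = tally[(seq, origin, w)]
        out.append(CollapsedRead(encode_read_id(idx, n, w), seq, n, origin, w))
    return out


def _best_overlap(s1: str, s2r: str, min_overlap: int, max_mismatch_frac: float):
    """Longest suffix(s1)/prefix(s2r) overlap within the mismatch budget."""
    for olen in range(min(len(s1), len(s2r)), min_overlap - 1, -1):
        a, b = s1[-olen:], s2r[:olen]
        mm = sum(x != y for x, y in zip(a, b))
        if mm / olen <= max_mismatch_frac:
            return olen
    return None


def _pair_key(read_id: str) -> str:
    return re.sub(r"/[12]$", "", read_id.split()[0])


def merge_pairs(
    pairs: Iterable[tuple[str, str, str, str]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.05,
) -> Iterator[RawRead]:
    """Convert read pairs to single-end form.

    Mates are given in sequencing orientation; mate 2 is reverse-complemented
    before the overlap search.  Overlapping pairs are merged into one read
    (overlap bases taken from mate 1, weight 1.0); non-overlapping pairs are
    emitted as two independent reads of weight 0.5 each.
    """
    for id1, seq1, id2, seq2 in pairs:
        if _pair_key(id1) != _pair_key(id2):
            raise PairingError(f"mates with unequal ids: {id1!r} vs {id2!r}")
        seq1, seq2 = seq1.upper(), seq2.upper()
        s2r = revcomp(seq2)
        olen = _best_overlap(seq1, s2r, min_overlap, max_mismatch_frac)
        if olen is not None:
            yield RawRead(seq1 + s2r[olen:], MERGED_PAIR, 1.0)
        else:
            yield RawRead(seq1, MATE1, 0.5)
            yield RawRead(s2r, MATE2, 0.5)


# ---------------------------------------------------------------------------
# SAM parsing

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CLIP = {4, 5}  # S, H


@dataclass
class ParsedAlignments:
    chimeric: dict[str, ChimericRead] = field(default_factory=dict)
    linear: dict[str, ChimericRead] = field(default_factory=dict)
    skipped: int = 0


def _segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    cig = rec.cigartuples
    full_len = rec.infer_read_length()
    lclip = 0
    for op, n in cig:
        if op in _CLIP:
            lclip += n
        else:
            break
    qaln = sum(n for op, n in cig if op in _QUERY_CONSUMING and op not in _CLIP)
    if rec.is_reverse:
        read_start = full_len - lclip - qaln
    else:
        read_start = lclip
    nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
    return AlignmentSegment(
        chrom=rec.reference_name,
        strand="-" if rec.is_reverse else "+",
        read_start=read_start,
        read_end=read_start + qaln,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        edit_distance=int(nm),
        mapq=rec.mapping_quality,
    )


def parse_chimeric_alignments(sam_path) -> ParsedAlignments:
    """Group primary+supplementary alignments per read into segment lists.

    Read intervals are expressed on the original forward read; hard and soft
    clips are treated identically for coordinate reconstruction.  Reads with a
    single segment are routed to the linear pool; records whose CIGAR and
    sequence lengths disagree are skipped and counted.
    """
    out = ParsedAlignments()
    by_read: dict[str, ChimericRead] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        records = iter(sam)
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except OSError:
                # htslib rejects records whose CIGAR and SEQ disagree and
                # cannot resume past them; count and stop
                out.skipped += 1
                break
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.cigartuples is None:
                out.skipped += 1
                continue
            seq = rec.query_sequence
            if seq is not None:
                qlen = sum(n for op, n in rec.cigartuples if op in _QUERY_CONSUMING and op != 5)
                if qlen != len(seq):
                    out.skipped += 1
                    continue
            try:
                seg = _segment_from_record(rec)
            except (ValueError, KeyError):
                out.skipped += 1
                continue
            cr = by_read.get(rec.query_name)
            if cr is None:
                count, w = decode_read_id(rec.query_name)
                cr = ChimericRead(rec.query_name, None, [], count, w)
                by_read[rec.query_name] = cr
            cr.segments.append(seg)
            if not rec.is_supplementary and seq is not None and 5 not in {op for op, _ in rec.cigartuples}:
                cr.sequence = revcomp(seq) if rec.is_reverse else seq
    for rid, cr in by_read.items():
        cr.segments.sort(key=lambda s: (s.read_start, s.read_end))
        (out.chimeric if len(cr.segments) >= 2 else out.linear)[rid] = cr
    return out


def write_sam(
    chimeric_reads: Iterable[ChimericRead], genome: dict[str, str], path
) -> None:
    """Write split alignments as SAM (primary + supplementary records)."""
    names = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(genome[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for cr in chimeric_reads:
            L = len(cr.sequence)
            for i, seg in enumerate(cr.segments):
                rec = pysam.AlignedSegment()
                rec.query_name = cr.read_id
                rec.reference_id = tid[seg.chrom]
                rec.reference_start = seg.ref_start
                rec.mapping_quality = seg.mapq
                rec.flag = (16 if seg.strand == "-" else 0) | (2048 if i > 0 else 0)
                if seg.strand == "-":
                    lclip, rclip = L - seg.read_end, seg.read_start
                    rec.query_sequence = revcomp(cr.sequence)
                else:
                    lclip, rclip = seg.read_start, L - seg.read_end
                    rec.query_sequence = cr.sequence
                cigar = []
                if lclip:
                    cigar.append((4, lclip))
                cigar.append((0, seg.read_span))
                if rclip:
                    cigar.append((4, rclip))
                rec.cigartuples = cigar
                rec.set_tag("NM", seg.edit_distance)
                out.write(rec)


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path) -> list[Transcript]:
    """Parse exon models from a GTF file via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        verbose=False,
    )
    out = []
    for t in db.features_of_type("transcript"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(t, featuretype="exon", order_by="start")
        ]
        gene_id = t.attributes.get("gene_id", [t.id])[0]
        out.append(Transcript(t.id, gene_id, t.seqid, t.strand, exons))
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_gtf(transcripts: Sequence[Transcript], path, source: str = "backsplice") -> None:
    with open_text(path, "wt") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\tgene\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                f'gene_id "{t.gene_id}";\n'
            )
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for k, (s, e) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f'{attrs} exon_number "{k}";\n'
                )


# ---------------------------------------------------------------------------
# BED output

def write_bed(calls, path) -> None:
    """CircCalls as BED6+2: name, support, strand, splice_strength, abundance."""
    with open_text(path, "wt") as fh:
        for c in calls:
            abundance = "" if c.abundance is None else f"{c.abundance:g}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t{c.support:g}\t{c.strand}"
                f"\t{c.splice_strength.total:.3f}\t{abundance}\n"
            )
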
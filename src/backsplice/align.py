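"""Bundled exact split-read aligner for error-free (synthetic) reads.

Greedy seed-and-extend segmentation: starting from the left end of the read,
the longest exact genomic match (either strand) anchored at the current read
position is emitted as a segment, and segmentation resumes at the first
unmatched base.  This is sufficient to split error-free junction-spanning
reads into their constituent genomic blocks; real-data runs should use an
external split-read aligner (e.g. bwa mem) whose SAM output enters the
pipeline through the same parsing path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import AlignmentSegment, ChimericRead, CollapsedRead, revcomp


class SplitAligner:
    """Exact split aligner over an in-memory genome (k-mer hash seeds)."""

    def __init__(self, genome: dict[str, str], k: int = 14):
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(genome):
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self.index = index

    def _extend_forward(self, seq: str, pos: int, chrom: str, g: int) -> int:
        ref = self.genome[chrom]
        m = self.k
        while pos + m < len(seq) and g + m < len(ref) and seq[pos + m] == ref[g + m]:
            m += 1
        return m

    def _extend_reverse(self, seq: str, pos: int, chrom: str, g: int) -> int:
        # seed revcomp matched ref[g:g+k]; read extends rightward = genome leftward
        ref = self.genome[chrom]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        m = self.k
        while pos + m < len(seq) and g - (m - self.k) - 1 >= 0 and seq[pos + m] == comp.get(
            ref[g - (m - self.k) - 1], "N"
        ):
            m += 1
        return m

    def align(self, seq: str) -> list[AlignmentSegment]:
        """Segment a read into maximal exact genomic matches (may be empty)."""
        segments: list[AlignmentSegment] = []
        pos = 0
        L = len(seq)
        while L - pos >= self.k:
            seed = seq[pos : pos + self.k]
            best = None  # (length, strand, chrom, ref_start, n_ties)
            hits_f = self.index.get(seed, ())
            for chrom, g in hits_f:
                m = self._extend_forward(seq, pos, chrom, g)
                key = (m, "+", chrom, g)
                best = _better(best, key)
            hits_r = self.index.get(revcomp(seed), ())
            for chrom, g in hits_r:
                m = self._extend_reverse(seq, pos, chrom, g)
                key = (m, "-", chrom, g + self.k - m)
                best = _better(best, key)
            if best is None:
                pos += 1
                continue
            (m, strand, chrom, ref_start), ties = best
            segments.append(
                AlignmentSegment(
                    chrom=chrom,
                    strand=strand,
                    read_start=pos,
                    read_end=pos + m,
                    ref_start=ref_start,
                    ref_end=ref_start + m,
                    edit_distance=0,
                    mapq=0 if ties else 60,
                )
            )
            pos += m
        return segments

    def align_collapsed(self, reads: list[CollapsedRead]) -> list[ChimericRead]:
        out = []
        for r in reads:
            segs = self.align(r.sequence)
            if segs:
                out.append(ChimericRead(r.read_id, r.sequence, segs, r.count, r.pair_weight))
        return out


def _better(best, key):
    """Track the best (longest, then lexicographically first) hit and tie status."""
    if best is None:
        return key, False
    (bm, *brest), ties = best
    m = key[0]
    if m > bm:
        return key, False
    if m == bm:
        if key[1:] < tuple(brest):
            return key, True
        return best[0], True
    return best
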
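"""CircRNA abundance by realignment to a pseudo-circular reference.

The circle's sequence (its monomer: the genomic span between the BSJ
coordinates, or the concatenated annotated exons within that span) is repeated
twice; a linear alignment crossing the seam between the two copies is exactly
a read crossing the back-splice junction.  A read contributes to a circle iff
its best alignment overlaps the seam with at least ``min_overhang`` aligned
bases on BOTH sides, and each read/pair contributes its weight to at most one
circle: reads whose seam-crossing placements tie across circles are left
unassigned rather than fractionally split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .caller import CircCall
from .formats import CollapsedRead, Transcript, revcomp

MIN_OVERHANG = 4


@dataclass
class PseudoCircularReference:
    circ_id: str
    monomer_seq: str

    @property
    def doubled_seq(self) -> str:
        return self.monomer_seq * 2

    @property
    def seam(self) -> int:
        """Position of the BSJ image inside doubled_seq."""
        return len(self.monomer_seq)


def _host_transcript(call: CircCall, transcripts: Sequence[Transcript]) -> Transcript | None:
    """Pick the annotated transcript backing a call.

    Prefer transcripts with exon boundaries exactly at both BSJ coordinates,
    then the one with the largest exonic overlap with the circle span.
    """
    best = None
    for t in transcripts:
        if t.chrom != call.chrom or t.strand != call.strand:
            continue
        if t.end <= call.start or t.start >= call.end:
            continue
        starts = {s for s, _ in t.exons}
        ends = {e for _, e in t.exons}
        exact = call.start in starts and call.end in ends
        overlap = sum(
            max(0, min(e, call.end) - max(s, call.start)) for s, e in t.exons
        )
        rank = (exact, overlap, t.transcript_id)
        if best is None or rank > best[0]:
            best = (rank, t)
    return None if best is None else best[1]


def build_pseudo_reference(
    call: CircCall,
    genome: dict[str, str],
    transcripts: Sequence[Transcript] | None = None,
) -> PseudoCircularReference:
    """Monomer = genomic span [start, end), or annotated exons within it.

    The monomer is reported in transcript orientation (reverse-complemented
    for minus-strand circles).  If annotation is supplied but no transcript
    overlaps the call, falls back to the genomic span with a warning.
    """
    chrom_seq = genome[call.chrom]
    if call.end > len(chrom_seq) or call.start < 0:
        raise ValueError(f"call {call.circ_id} outside genome")
    monomer = None
    if transcripts is not None:
        host = _host_transcript(call, transcripts)
        if host is None:
            warnings.warn(f"no transcript overlaps {call.circ_id}; using genomic span")
        else:
            parts = [
                chrom_seq[max(s, call.start) : min(e, call.end)]
                for s, e in host.exons
                if min(e, call.end) > max(s, call.start)
            ]
            monomer = "".join(parts)
    if monomer is None:
        monomer = chrom_seq[call.start : call.end]
    if call.strand == "-":
        monomer = revcomp(monomer)
    return PseudoCircularReference(call.circ_id, monomer)


@dataclass
class QuantifyResult:
    abundance: dict[str, float] = field(default_factory=dict)
    ambiguous: float = 0.0  # weight of reads tied across circles
    assigned: float = 0.0


class _SeamIndex:
    """Seed index over doubled references; exact full-length read placement."""

    def __init__(self, references: Sequence[PseudoCircularReference], k: int = 32):
        self.k = k
        self.refs = list(references)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, ref in enumerate(self.refs):
            dbl = ref.doubled_seq
            kk = min(k, len(ref.monomer_seq))
            for i in range(len(dbl) - kk + 1):
                self.index.setdefault(dbl[i : i + kk], []).append((ri, i))

    def placements(self, seq: str) -> set[tuple[int, int]]:
        """Exact placements as (ref_idx, start mod monomer length), deduplicated."""
        out: set[tuple[int, int]] = set()
        for query in (seq, revcomp(seq)):
            kk = self.k
            if len(query) < kk:
                continue
            for ri, p in self.index.get(query[:kk], ()):
                ref = self.refs[ri]
                dbl = ref.doubled_seq
                if dbl[p : p + len(query)] == query and p + len(query) <= len(dbl):
                    out.add((ri, p % ref.seam))
        return out


def quantify(
    references: Sequence[PseudoCircularReference],
    reads: Sequence[CollapsedRead],
    min_overhang: int = MIN_OVERHANG,
    seed_k: int = 32,
) -> QuantifyResult:
    """Count seam-spanning reads per circle; each read/pair counted once.

    Placements at p and p + L in the doubled sequence are images of the same
    circular placement and are collapsed before counting, so doubling never
    double-counts.
    """
    res = QuantifyResult(abundance={r.circ_id: 0.0 for r in references})
    if not references:
        return res
    idx = _SeamIndex(references, seed_k)
    for read in reads:
        crossing_refs = set()
        for ri, p in idx.placements(read.sequence):
            ref = idx.refs[ri]
            L = ref.seam
            left = L - p
            right = p + len(read.sequence) - L
            if left >= min_overhang and right >= min_overhang:
                crossing_refs.add(ri)
        if not crossing_refs:
            continue
        if len(crossing_refs) > 1:
            res.ambiguous += read.weight
            continue
        ref = idx.refs[crossing_refs.pop()]
        res.abundance[ref.circ_id] += read.weight
        res.assigned += read.weight
    return res


def attach_abundance(calls: Sequence[CircCall], result: QuantifyResult) -> None:
    for c in calls:
        c.abundance = result.abundance.get(c.circ_id, 0.0)


def write_abundance_tsv(calls: Sequence[CircCall], path) -> None:
    """TSV: circ_id, support, abundance, rc placeholder (filled downstream)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in calls],
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "strand": [c.strand for c in calls],
            "splice_strength": [round(c.splice_strength.total, 3) for c in calls],
            "support": [c.support for c in calls],
            "abundance": [c.abundance for c in calls],
            "rc": [float("nan")] * len(calls),
        }
    )
    df.to_csv(path, sep="\t", index=False)
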
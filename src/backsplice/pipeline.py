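"""End-to-end orchestration: preprocess -> align/parse -> call -> quantify -> report.

Each stage is a thin composition of the library modules; every run writes a
JSON manifest (parameters, versions, input checksums) sufficient to reproduce
it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from bisect import bisect_right
from pathlib import Path

import pandas as pd

from . import __version__
from .align import SplitAligner
from .caller import CallResult, call_junctions, pair_fusion_circs
from .config import RunConfig
from .formats import (
    collapse_reads,
    merge_pairs,
    parse_chimeric_alignments,
    read_fastq,
    read_gtf,
    load_genome,
    write_bed,
    write_fasta,
    write_sam,
)
from .maxent import SpliceSiteModel
from .quantify import attach_abundance, build_pseudo_reference, quantify, write_abundance_tsv

log = logging.getLogger("backsplice")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(path, stage: str, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"{what} not found: {p}")
    return p


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_reads(reads1, reads2=None, config: RunConfig | None = None):
    """FASTQ (SE or PE) -> collapsed single-end read set."""
    config = config or RunConfig()
    _require(reads1, "preprocess", "reads FASTQ")
    if reads2 is None:
        return collapse_reads(seq for _, seq in read_fastq(reads1))
    _require(reads2, "preprocess", "mate-2 FASTQ")
    pair_stream = (
        (id1, s1, id2, s2)
        for (id1, s1), (id2, s2) in zip(read_fastq(reads1), read_fastq(reads2))
    )
    return collapse_reads(
        merge_pairs(pair_stream, config.min_overlap, config.max_mismatch_frac)
    )


def align_and_parse(collapsed, genome, out_dir: Path, config: RunConfig):
    """Bundled split alignment, materialized as SAM and re-parsed."""
    aligner = SplitAligner(genome, k=config.aligner_k)
    chimeric = aligner.align_collapsed(collapsed)
    sam_path = out_dir / "alignments.sam"
    write_sam(chimeric, genome, sam_path)
    return parse_chimeric_alignments(sam_path)


def _gene_abundance_from_linear(parsed, transcripts) -> dict[str, float]:
    """Weighted linear-pool read counts per gene (segment midpoint in gene span)."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end, t.gene_id))
    for v in by_chrom.values():
        v.sort()
    out: dict[str, float] = {}
    for read in parsed.linear.values():
        seg = max(read.segments, key=lambda s: s.read_span)
        spans = by_chrom.get(seg.chrom, [])
        mid = (seg.ref_start + seg.ref_end) // 2
        i = bisect_right(spans, (mid, float("inf"), ""))
        for s, e, gid in spans[max(0, i - 3) : i + 1]:
            if s <= mid < e:
                out[gid] = out.get(gid, 0.0) + read.weight
                break
    return out


def run_pipeline(
    genome_path,
    reads1,
    out_dir,
    reads2=None,
    gtf_path=None,
    model_path=None,
    config: RunConfig | None = None,
) -> dict:
    """Full run; returns a summary dict and writes the output bundle.

    Outputs: circs.bed, circs.tsv, pseudo_refs.fa, fusion_junctions.tsv,
    fusion_circs.tsv, gene_abundance.tsv (with annotation), manifest.json.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome_file = _require(genome_path, "input", "genome FASTA")
    genome = load_genome(genome_file)
    transcripts = None
    if gtf_path is not None:
        transcripts = read_gtf(_require(gtf_path, "input", "annotation GTF"))
    if model_path is not None:
        model = SpliceSiteModel.from_json(_require(model_path, "input", "splice model JSON"))
    else:
        from .simulate import default_splice_model

        log.info("no model supplied; training the default synthetic model")
        model = default_splice_model(config.seed)

    log.info("preprocessing reads")
    collapsed = preprocess_reads(reads1, reads2, config)
    log.info("collapsed to %d distinct reads", len(collapsed))

    log.info("aligning and parsing")
    parsed = align_and_parse(collapsed, genome, out_dir, config)
    log.info("%d chimeric, %d linear reads", len(parsed.chimeric), len(parsed.linear))

    log.info("calling junctions")
    result: CallResult = call_junctions(
        parsed.chimeric,
        genome,
        model,
        threshold=config.threshold,
        window=config.microhomology_window,
        min_segment=config.min_segment,
        min_read_coverage=config.min_read_coverage,
        min_circ_len=config.min_circ_len,
        circ_max_span=config.circ_max_span,
    )

    log.info("quantifying %d circles", len(result.circ_calls))
    refs = [build_pseudo_reference(c, genome, transcripts) for c in result.circ_calls]
    qres = quantify(refs, collapsed, config.min_overhang, config.seed_k)
    attach_abundance(result.circ_calls, qres)

    fusion_circs = pair_fusion_circs(result.fusion_junctions, config.fusion_max_span)

    write_bed(result.circ_calls, out_dir / "circs.bed")
    write_abundance_tsv(result.circ_calls, out_dir / "circs.tsv")
    write_fasta(
        ((r.circ_id, r.monomer_seq) for r in refs), out_dir / "pseudo_refs.fa"
    )
    pd.DataFrame(
        [
            {
                "junction_id": j.junction_id,
                "donor_chrom": j.donor.chrom,
                "donor_strand": j.donor.strand,
                "donor_pos": j.donor.pos,
                "acceptor_chrom": j.acceptor.chrom,
                "acceptor_strand": j.acceptor.strand,
                "acceptor_pos": j.acceptor.pos,
                "splice_strength": round(j.splice_strength.total, 3),
                "support": j.support,
            }
            for j in result.fusion_junctions
        ]
    ).to_csv(out_dir / "fusion_junctions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "junction_ab": fc.junction_ab.junction_id,
                "junction_ba": fc.junction_ba.junction_id,
                "support_ab": fc.junction_ab.support,
                "support_ba": fc.junction_ba.support,
                "multi_pairing": fc.multi_pairing,
            }
            for fc in fusion_circs
        ]
    ).to_csv(out_dir / "fusion_circs.tsv", sep="\t", index=False)

    gene_abundance = {}
    if transcripts is not None:
        gene_abundance = _gene_abundance_from_linear(parsed, transcripts)
        pd.DataFrame(
            sorted(gene_abundance.items()), columns=["gene_id", "abundance"]
        ).to_csv(out_dir / "gene_abundance.tsv", sep="\t", index=False)

    inputs = {"genome": str(genome_file), "reads1": str(reads1)}
    if reads2:
        inputs["reads2"] = str(reads2)
    if gtf_path:
        inputs["gtf"] = str(gtf_path)
    if model_path:
        inputs["model"] = str(model_path)
    manifest = {
        "package": "backsplice",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "summary": {
            "n_input_distinct_reads": len(collapsed),
            "n_chimeric_reads": len(parsed.chimeric),
            "n_linear_reads": len(parsed.linear),
            "n_circ_calls": len(result.circ_calls),
            "n_fusion_junctions": len(result.fusion_junctions),
            "n_fusion_circs": len(fusion_circs),
            "ambiguous_reads": result.stats.ambiguous_reads,
            "quantified_weight": qres.assigned,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest["summary"]
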
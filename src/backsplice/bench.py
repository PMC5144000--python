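"""Benchmark harness: seeded simulation runs with truth-based scoring.

These routines regenerate a synthetic benchmark from a single seed, run the
full pipeline (collapse -> split-align -> SAM -> parse -> call -> quantify)
and score the calls against the simulator's truth tables.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import simulate as sim
from .align import SplitAligner
from .caller import CallResult, call_junctions
from .formats import collapse_reads, parse_chimeric_alignments, write_sam
from .quantify import build_pseudo_reference, quantify


def _derive(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(2**31))


def run_caller(genome: sim.SyntheticGenome, sequences, threshold: float = 10.0):
    """Collapse sequences, align, round-trip through SAM, parse and call."""
    collapsed = collapse_reads(sequences)
    aligner = SplitAligner(genome.chromosomes)
    chimeric = aligner.align_collapsed(collapsed)
    with tempfile.TemporaryDirectory() as td:
        sam = Path(td) / "aln.sam"
        write_sam(chimeric, genome.chromosomes, sam)
        parsed = parse_chimeric_alignments(sam)
    result = call_junctions(parsed.chimeric, genome.chromosomes, genome.model, threshold)
    return collapsed, parsed, result


def fusion_recovery(
    seed: int,
    read_lengths: tuple[int, ...] = (50, 100, 150),
    n_events: int = 10,
    reads_per_junction: int = 10,
    n_genes: int = 30,
) -> dict[int, tuple[int, int]]:
    """Fraction of true fusion junctions recovered at each read length.

    Simulates ``n_events`` reciprocal fusion circles with error-free SE reads
    spanning each of the two junctions per event, runs the fusion caller, and
    counts exactly recovered (donor, acceptor) breakpoints.
    """
    model = sim.default_splice_model(_derive(seed, 1))
    genome = sim.make_genome(n_genes=n_genes, seed=_derive(seed, 2), model=model)
    out = {}
    for read_len in read_lengths:
        rng = np.random.default_rng([seed, 3, read_len])
        defs = sim.simulate_fusions(
            genome, n_events=n_events, min_part_len=max(150, read_len), rng=rng
        )
        reads1, _, truth = sim.simulate_reads(
            [], genome, defs, read_len=read_len,
            reads_per_junction=reads_per_junction, n_reads_each=0, rng=rng,
        )
        fusion_seqs = [s for rid, s in reads1 if rid.startswith("fusion|")]
        _, _, result = run_caller(genome, fusion_seqs)
        called = {(j.donor, j.acceptor) for j in result.fusion_junctions}
        truth_j = set(truth.fusion_counts)
        out[read_len] = (len(called & truth_j), len(truth_j))
    return out


@dataclass
class EndToEndMetrics:
    n_true: int
    n_called: int
    recall: float
    precision: float
    exact_abundance_fraction: float


def end_to_end(
    seed: int,
    n_circs: int = 200,
    n_genes: int = 500,
    read_len: int = 100,
    n_reads_each: int = 20,
) -> EndToEndMetrics:
    """Junction recovery and abundance fidelity on a circ + linear benchmark."""
    model = sim.default_splice_model(_derive(seed, 11))
    genome = sim.make_genome(
        n_genes=n_genes, seed=_derive(seed, 12), model=model, n_chroms=4
    )
    rng = np.random.default_rng([seed, 13])
    circs = sim.simulate_circs(genome, rng=rng)[:n_circs]
    reads1, _, truth = sim.simulate_reads(
        circs, genome, None, read_len=read_len, n_reads_each=n_reads_each, rng=rng
    )
    collapsed, _, result = run_caller(genome, [s for _, s in reads1])
    true_ids = set(truth.circ_counts)
    called = {c.circ_id for c in result.circ_calls}
    recall = len(called & true_ids) / len(true_ids)
    precision = len(called & true_ids) / len(called) if called else 1.0
    refs = [
        build_pseudo_reference(c, genome.chromosomes, genome.transcripts)
        for c in result.circ_calls
    ]
    qres = quantify(refs, collapsed)
    detected_true = [c for c in result.circ_calls if c.circ_id in true_ids]
    exact = sum(
        1 for c in detected_true
        if qres.abundance[c.circ_id] == truth.circ_counts[c.circ_id]
    )
    frac = exact / len(detected_true) if detected_true else 0.0
    return EndToEndMetrics(len(true_ids), len(called), recall, precision, frac)


def negative_control(seed: int, n_genes: int = 100, read_len: int = 100) -> CallResult:
    """Linear-transcript-only reads through the full caller."""
    model = sim.default_splice_model(_derive(seed, 21))
    genome = sim.make_genome(n_genes=n_genes, seed=_derive(seed, 22), model=model)
    rng = np.random.default_rng([seed, 23])
    reads1, _, _ = sim.simulate_reads([], genome, None, read_len=read_len, rng=rng)
    _, _, result = run_caller(genome, [s for _, s in reads1])
    return result
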
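"""Shared fixtures: a trained splice model and small synthetic genomes.

Everything is seeded; session scope keeps the expensive objects (model
training, genome construction, aligner index) shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from backsplice import simulate as sim
from backsplice.align import SplitAligner
from backsplice.formats import collapse_reads, parse_chimeric_alignments, write_sam


@pytest.fixture(scope="session")
def model():
    return sim.default_splice_model(seed=5, n_train=1500)


@pytest.fixture(scope="session")
def genome30(model):
    return sim.make_genome(n_genes=30, seed=21, model=model)


@pytest.fixture(scope="session")
def aligner30(genome30):
    return SplitAligner(genome30.chromosomes)


def align_via_sam(aligner, genome, sequences, tmp_path):
    """Collapse -> align -> SAM round-trip -> parsed alignments."""
    collapsed = collapse_reads(sequences)
    chimeric = aligner.align_collapsed(collapsed)
    sam = tmp_path / "aln.sam"
    write_sam(chimeric, genome.chromosomes, sam)
    return collapsed, parse_chimeric_alignments(sam)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
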
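"""Shared fixtures: tiny hand-built references and seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from deeqc.models import GeneModel, Reference, SequenceRead, TranscriptModel
from deeqc import simulate


def make_read(bases: str, quals=None, read_id: str = "r") -> SequenceRead:
    if quals is None:
        quals = (30,) * len(bases)
    elif isinstance(quals, int):
        quals = (quals,) * len(bases)
    return SequenceRead(read_id, bases, tuple(quals))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def two_gene_ref(rng) -> Reference:
    """Two single-transcript genes on one chromosome, opposite strands."""
    seq = "".join(rng.choice(list("ACGT"), size=600))
    g1 = GeneModel("GA", "ga", "chr1", "+", exons=[(50, 250)],
                   transcripts=[TranscriptModel("GA.T1", "GA", [(50, 250)])])
    g2 = GeneModel("GB", "gb", "chr1", "-", exons=[(350, 550)],
                   transcripts=[TranscriptModel("GB.T1", "GB", [(350, 550)])])
    return Reference(genome={"chr1": seq}, genes=[g1, g2])


@pytest.fixture(scope="session")
def sim_cfg() -> simulate.SimConfig:
    """Small default simulation: 10 genes, 2 isoforms each, 100 bp SE reads."""
    return simulate.SimConfig(seed=101, n_genes=10, n_tx_per_gene=2, read_length=100)


@pytest.fixture(scope="session")
def sim_run(sim_cfg):
    ref = simulate.make_reference(sim_cfg)
    batch, truth = simulate.simulate_reads(ref, sim_cfg)
    return ref, batch, truth
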
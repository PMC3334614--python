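import numpy as np
import pytest

from polyfate import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def loss_sim():
    """A hexaploid simulation with 20% homoeolog loss, shared across tests.

    Copies double as perfectly assembled clusters so homology-level
    statistics can be scored against the planted truth without the cost of
    read assembly.
    """
    config = sim.SimulationConfig(
        n_chromosomes=2,
        genes_per_chromosome=250,
        gene_length_mean=600,
        homoeolog_loss_prob=0.2,
        expr_divergence_prob=0.3,
        seed=101,
    )
    genome = sim.generate_genome(config)
    copies = sim.generate_hexaploid(genome, config)
    return config, genome, copies


@pytest.fixture(scope="session")
def loss_sim_cos(loss_sim):
    """Ortholog calls for the loss simulation via the exact toy aligner."""
    from polyfate import homology as H

    _config, genome, copies = loss_sim
    queries = {c.copy_id: c.sequence for c in copies if not c.deleted}
    hsps = H.diagonal_align(queries, genome.gene_sequences)
    scores = H.score_all(hsps, {q: len(s) for q, s in queries.items()})
    return H.call_orthologs(scores)
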
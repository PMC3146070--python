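import numpy as np
import pytest

from mesmark import (CoverageTrack, GeneTable, SimulationConfig,
                     annotate_genes, build_toy_genome, coverage_pipeline,
                     gene_body_score, simulate_replicates)
from mesmark.coverage import REPLICATE_AVERAGED
from mesmark.simulate import (default_control_model, default_mes4_model,
                              default_transcription_model)

# Shared study conditions for the simulation-backed tests: a toy genome
# of three 200-kb autosomes plus an X, 40 spaced genes per chromosome,
# two replicates of 2e5 reads per sample.
SIM_SEED = 11
N_READS = 200_000
CLASS_PROPS = {"germline": 0.3, "soma": 0.3, "ubiquitous": 0.4}
X_CLASS_PROPS = {"germline": 0.05, "soma": 0.45, "ubiquitous": 0.5}


@pytest.fixture(scope="session")
def sim_genome():
    return build_toy_genome(3, 200_000, include_x=True)


@pytest.fixture(scope="session")
def sim_genes(sim_genome):
    return annotate_genes(sim_genome, 40, (1_500, 4_000), CLASS_PROPS,
                          seed=SIM_SEED, x_class_proportions=X_CLASS_PROPS)


def _pipeline(genome, genes, model, seed):
    cfg = SimulationConfig(n_reads=N_READS, seed=seed, replicate_count=2)
    return coverage_pipeline(simulate_replicates(genome, genes, model, cfg),
                             genome)


@pytest.fixture(scope="session")
def mes4_track(sim_genome, sim_genes):
    return _pipeline(sim_genome, sim_genes, default_mes4_model(), 101)


@pytest.fixture(scope="session")
def n2_track(sim_genome, sim_genes):
    return _pipeline(sim_genome, sim_genes, default_transcription_model(), 102)


@pytest.fixture(scope="session")
def panh3_track(sim_genome, sim_genes):
    return _pipeline(sim_genome, sim_genes, default_control_model("pan_h3"),
                     103)


@pytest.fixture(scope="session")
def mes4_scores(mes4_track, sim_genes):
    return gene_body_score(mes4_track, sim_genes)


@pytest.fixture
def small_genome():
    return build_toy_genome(2, 20_000, include_x=True)


def make_track(genome, fill=0.0, state=REPLICATE_AVERAGED, rng=None,
               sample_id="t"):
    """Directly construct a track: constant fill or random Poisson."""
    data = {}
    for c in genome.chromosomes:
        if rng is not None:
            data[c.name] = rng.poisson(5.0, c.length).astype(float)
        else:
            data[c.name] = np.full(c.length, float(fill))
    return CoverageTrack(sample_id, genome, data, normalization_state=state)


def make_genes(genome, rows):
    """rows: (gene_id, chrom, start, end, strand, gene_class)."""
    import pandas as pd
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "gene_class"])
    return GeneTable(df, genome)
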
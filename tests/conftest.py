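import warnings

import pytest

from oxbs.chemistry import ChemistryParams
from oxbs.pipeline import ExperimentConfig, run_experiment
from oxbs.sim.genome import GenomeConfig, build_reference
from oxbs.sim.truth import HippocampusProfile, TruthModel


def mini_genome_config(**overrides) -> GenomeConfig:
    base = dict(
        autosome_lengths={"chr1": 60_000},
        chrx_length=30_000,
        chry_length=20_000,
        n_cgis=6,
        n_promoters=6,
        repeat_fraction=0.08,
    )
    base.update(overrides)
    return GenomeConfig(**base)


@pytest.fixture(scope="session")
def mini_reference():
    return build_reference(mini_genome_config(), seed=7)


@pytest.fixture(scope="session")
def mini_truth_model(mini_reference):
    genome, annotations = mini_reference
    return TruthModel(genome, annotations, HippocampusProfile())


@pytest.fixture(scope="session")
def mini_run():
    """Small but fully featured experiment with count tables retained."""
    config = ExperimentConfig(
        genome=mini_genome_config(),
        profile=HippocampusProfile(),
        chemistry=ChemistryParams(),
        coverage=10.0,
        n_per_cell=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_experiment(config, seed=11, keep_counts=True)


@pytest.fixture(scope="session")
def default_run():
    """The default study: ~1.2 Mb genome, 12 samples, 10x coverage."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_experiment(ExperimentConfig(), seed=1)
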
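import numpy as np
import pytest

from pankit.synthetic_data import (
    PangenomeSpec,
    ReadSimSpec,
    generate_pangenome,
    plant_missing_genes,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_panel():
    """A 4-genome panel small enough for exhaustive downstream checks."""
    spec = PangenomeSpec(n_genomes=4, core_families=10, kappa=8, alpha_true=0.5, seed=2)
    return generate_pangenome(spec)


@pytest.fixture(scope="session")
def planted_scenario(small_panel):
    """Genome 1 with 3 genes excised; reads simulated from the full genome."""
    genomes, truth = small_panel
    records, ann = genomes[0]
    rng = np.random.default_rng(7)
    excised, original, planted = plant_missing_genes(records, ann, 3, rng)
    reads1, reads2 = simulate_reads(original, ReadSimSpec(coverage=30.0, seed=5))
    return {
        "ann": ann,
        "excised": excised,
        "original": original,
        "planted": planted,
        "reads1": reads1,
        "reads2": reads2,
    }
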
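import numpy as np
import pytest

from imsfs import GenotypeMatrix, InferenceSettings, ModelParams
from imsfs.studies import REFERENCE_HISTORY


@pytest.fixture(scope="session")
def reference_history() -> ModelParams:
    """Published point estimates of a trans-Eurasian secondary-contact history.

    Western/eastern/ancestral diploid sizes, split and contact times (years),
    and asymmetric per-generation migration probabilities; serves as the
    generating truth in recovery studies.
    """
    return REFERENCE_HISTORY


@pytest.fixture
def quick_settings() -> InferenceSettings:
    """Desk-scale settings for fast unit-level fits."""
    return InferenceSettings(n_sims=1000, n_cycles=5, n_reps=2, seed=0)


def make_genotypes(dosages, popmap, lineages=None):
    """Assemble a GenotypeMatrix from a dict individual -> dosage list."""
    individuals = list(dosages)
    geno = np.array([dosages[i] for i in individuals], dtype=np.int8)
    loci = [f"L{j}:{j + 1}" for j in range(geno.shape[1])]
    return GenotypeMatrix(geno, individuals, loci, dict(popmap),
                          dict(lineages or {}))


@pytest.fixture
def toy_two_lineage_genotypes():
    """2 diploids per lineage, 6 loci with hand-checkable allele counts."""
    dosages = {
        "w1": [0, 1, 2, 0, 1, 0],
        "w2": [1, 1, 2, 0, 0, 0],
        "e1": [0, 0, 1, 0, 2, 0],
        "e2": [0, 0, 1, 1, 2, 0],
    }
    popmap = {"w1": "W", "w2": "W", "e1": "E", "e2": "E"}
    lineages = {"W": "west", "E": "east"}
    return make_genotypes(dosages, popmap, lineages)
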
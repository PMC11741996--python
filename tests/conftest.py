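import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mhcrep as m

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> m.GeneratorConfig:
    """Desk-scale study conditions shared by cross-module tests."""
    return m.GeneratorConfig(
        seed=11,
        n_reference_proteins=120,
        reference_length_range=(80, 200),
        n_viruses=8,
        proteins_per_virus=3,
        protein_length=120,
        n_supertypes=2,
        alleles_per_supertype=3,
        n_self_proteins=10,
    )


@pytest.fixture(scope="session")
def small_reference(small_config) -> m.ProteomeSet:
    return m.generate_reference_proteome(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, labels = m.generate_allele_panel(small_config)
    return panel, labels


@pytest.fixture(scope="session")
def small_repertoire(small_config, small_reference, small_panel) -> m.BinderRepertoire:
    panel, _ = small_panel
    viruses, _ = m.generate_virus_set(small_config)
    refs = {
        e.allele: m.build_rank_reference(
            e.model, small_reference, lengths=(8, 9, 10), per_length_count=2000, seed=7
        )
        for e in panel
    }
    return m.build_repertoire(panel, viruses, refs, lengths=(8, 9), threshold=2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
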
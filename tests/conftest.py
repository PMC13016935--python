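import pandas as pd
import pytest

from safetyome.fixtures import WorldConfig, generate_world
from safetyome.phenomap import Hierarchy

#: Compact world used by most integration tests: 9 organ systems (2 of
#: which are non-organ catch-alls), 4 phenotypes each, 250 genes.
SMALL_KW = dict(
    n_genes=250,
    n_socs=9,
    n_nonorgan_socs=2,
    pts_per_soc=4,
    diseases_per_soc=2,
    disease_size=12,
    n_core_truth=15,
    n_tissues=12,
    seed=11,
)


def small_config(**overrides) -> WorldConfig:
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return WorldConfig(**kw)


@pytest.fixture(scope="session")
def clean_world():
    """Zero-noise compact world: every record true, every trait verbatim."""
    return generate_world(
        small_config(trait_noise_rate=0.0, assoc_dropout=0.0, disease_noise_rate=0.0)
    )


@pytest.fixture(scope="session")
def noisy_world():
    return generate_world(
        small_config(trait_noise_rate=0.2, assoc_dropout=0.1, disease_noise_rate=0.2)
    )


@pytest.fixture(scope="session")
def tiny_hierarchy() -> Hierarchy:
    """Hand-built hierarchy: three concepts, one with two (PT, SOC) pairs."""
    frame = pd.DataFrame(
        [
            ("C001", "cardiac arrest", "PT_CARD_ARREST", "SOC_CARDIAC"),
            ("C001", "heart arrest", "PT_CARD_ARREST", "SOC_CARDIAC"),
            ("C002", "long qt syndrome", "PT_LONG_QT", "SOC_CARDIAC"),
            ("C002", "long qt syndrome", "PT_ECG_QT", "SOC_INVESTIGATIONS"),
            ("C003", "migraine", "PT_MIGRAINE", "SOC_NERVOUS"),
        ],
        columns=["concept_id", "synonym", "pt_term", "soc_term"],
    )
    return Hierarchy.from_frame(frame)
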
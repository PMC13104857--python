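import numpy as np
import pandas as pd
import pytest

from morphoscore import (
    ProfileTable,
    ScreenConfig,
    derive_signatures,
    generate_screen,
    reference_distance,
)


def make_table(features: dict, **metadata) -> ProfileTable:
    """Small helper to build a ProfileTable from plain dicts."""
    data = {f"Metadata_{k}": v for k, v in metadata.items()}
    data.update(features)
    return ProfileTable(pd.DataFrame(data))


@pytest.fixture(scope="session")
def two_state_screen():
    """Canonical planted two-state screen: 20 features, 5 shifted by 3 SD,
    500 cells per population, one treatment per efficacy grade."""
    table, truth = generate_screen(ScreenConfig(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def two_state_signature(two_state_screen):
    table, truth = two_state_screen
    reference = table.select({"treatment": "reference"})
    target = table.select({"treatment": "target"})
    sig = derive_signatures(reference, target, alpha=0.05)
    ref_dist = reference_distance(reference, target, sig)
    return reference, target, sig, ref_dist
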
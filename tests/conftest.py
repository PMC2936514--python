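import numpy as np
import pandas as pd
import pytest

from dipscreen.synthetic import SimulationConfig, generate_dataset


def make_instances(rows):
    """Instance sheet from (instance_id, drug, cell, batch, conc, is_control) tuples."""
    frame = pd.DataFrame(
        rows,
        columns=["instance_id", "drug_id", "cell_line", "batch_id",
                 "concentration_value", "is_control"],
    )
    frame["platform"] = "HT_HG-U133A"
    frame["concentration_unit"] = "uM"
    return frame


def make_matrix(probe_values, columns):
    """Probe x instance matrix from {probe: [values...]} in column order."""
    return pd.DataFrame(probe_values, index=columns).T


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic compendium shared across tests."""
    cfg = SimulationConfig(
        n_probes=400, n_drugs=24, n_cell_lines=2, batches_per_cell_line=2,
        treatments_per_batch=14, replicate_rate=0.2, signature_size=40,
        signature_amplitude=1.0, batch_sd=0.4, noise_sd=0.3,
        n_similar_groups=4, similar_group_size=2, n_relations=15,
        drugs_per_target=5, regulation_effect=1.0, fraction_regulated=0.4,
        controls_per_batch=2, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
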
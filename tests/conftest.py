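import warnings

import pandas as pd
import pytest

import silverback as sb


def pytest_configure(config):
    # mixed-model boundary fits legitimately warn; keep test output readable
    warnings.filterwarnings("ignore", message=".*convergence.*")
    warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def null_effects():
    return sb.OrphanEffectConfig.null()


@pytest.fixture(scope="session")
def small_study(null_effects):
    """Four incidents under the null generator (no orphan effects)."""
    cfg = sb.PopulationConfig(n_groups=4, seed=11, orphan_effects=null_effects)
    return sb.simulate_incident_dataset(cfg)


@pytest.fixture(scope="session")
def boosted_study():
    """Six incidents with the study-default orphan effects (dominant-male
    boost largest), for direction/sign checks."""
    cfg = sb.PopulationConfig(n_groups=6, seed=5)
    return sb.simulate_incident_dataset(cfg)


def make_scans(rows):
    """Build a focal-scan table from (date, focal, proximity, contact) tuples."""
    return pd.DataFrame(
        [
            {
                "date": pd.Timestamp(date),
                "group": "G00",
                "focal": focal,
                "proximity_partners": tuple(prox),
                "contact_partners": tuple(contact),
            }
            for date, focal, prox, contact in rows
        ]
    )
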
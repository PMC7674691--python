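import numpy as np
import pytest

import thyret as th


@pytest.fixture(scope="session")
def aerosol5_reference_curve() -> th.RetentionCurve:
    """Reference 5 um F-type inhalation retention curve for I-131."""
    return th.reference_retention(th.Route.AEROSOL_5UM)


@pytest.fixture(scope="session")
def ingestion_reference_curve() -> th.RetentionCurve:
    return th.reference_retention(th.Route.INGESTION)


@pytest.fixture(scope="session")
def ingestion_reference_system() -> th.CompartmentSystem:
    params = th.reference_parameters(th.Route.INGESTION)
    return th.build_system(th.Route.INGESTION, params)


@pytest.fixture(scope="session")
def small_ingestion_ensemble() -> th.RetentionEnsemble:
    """A modest ensemble for structural checks (summaries, percentiles)."""
    return th.propagate(th.Route.INGESTION, n=300, seed=7)


def degenerate_config() -> dict:
    """Config with every sampled distribution collapsed to its central value."""
    cfg = th.load_config()
    for block in cfg["deposition"].values():
        for region, entry in block.items():
            block[region] = {"kind": "fixed", "value": th.config.parse_distribution(entry).central()}
    for key, entry in cfg["total_deposition"].items():
        cfg["total_deposition"][key] = {
            "kind": "fixed", "value": th.config.parse_distribution(entry).central()
        }
    for key, entry in cfg["hatm"]["rates"].items():
        cfg["hatm"]["rates"][key] = {
            "kind": "fixed", "value": th.config.parse_distribution(entry).central()
        }
    cfg["hatm"]["f1"] = {"kind": "fixed", "value": 0.95}
    for key, entry in cfg["systemic"]["distributions"].items():
        cfg["systemic"]["distributions"][key] = {
            "kind": "fixed", "value": th.config.parse_distribution(entry).central()
        }
    return cfg
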
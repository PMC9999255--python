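import numpy as np
import pytest
from hypothesis import settings

import drscreen as d

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    """Validated base-case parameters and the two strategy arms."""
    return d.load_parameters()


@pytest.fixture(scope="session")
def base_result():
    """Base-case incremental comparison and per-arm traces."""
    return d.base_case()


@pytest.fixture()
def quiet_config():
    """A configuration with no disease events, no mortality and a single
    utility level: the closed-form annuity limit of the cohort model."""
    cfg = d.default_config()
    for entry in cfg["parameters"]:
        if entry["name"].startswith("p_") or entry["name"] in (
            "prev_dr", "frac_stdr_of_dr", "frac_dme_of_dr"
        ):
            entry["base"] = entry["low"] = entry["high"] = 0.0
        if entry["name"].startswith("u_"):
            entry["base"] = entry["low"] = entry["high"] = 0.8
    cfg["mortality"]["probs"] = [0.0] * len(cfg["mortality"]["ages"])
    return cfg


def make_config(value_overrides=None, settings_overrides=None):
    """Fresh default config with base values (and their ranges) replaced."""
    cfg = d.default_config()
    for entry in cfg["parameters"]:
        if value_overrides and entry["name"] in value_overrides:
            v = value_overrides[entry["name"]]
            entry["base"] = entry["low"] = entry["high"] = v
    if settings_overrides:
        cfg["settings"].update(settings_overrides)
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
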
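"""Shared fixtures: seeded synthetic studies reused across the suite."""
import warnings

import numpy as np
import pandas as pd
import pytest

from tmedecon import (
    BetaMatrix,
    SimulationConfig,
    build_bundle,
    deconvolve,
    simulate_mixtures,
    simulate_reference_panel,
    simulate_tumor_normal,
)
from tmedecon.simulate import _study_archetypes


@pytest.fixture(scope="session")
def study_cfg():
    return SimulationConfig(seed=17)


@pytest.fixture(scope="session")
def study(study_cfg):
    """Default synthetic study: panel, tumor/normal training, mixtures."""
    panel, class_archetypes = simulate_reference_panel(study_cfg)
    tumor, normal, differential = simulate_tumor_normal(study_cfg)
    mix, truth = simulate_mixtures(study_cfg)
    _, archetypes, _, _ = _study_archetypes(study_cfg)
    return {
        "cfg": study_cfg,
        "panel": panel,
        "class_archetypes": class_archetypes,
        "archetypes": archetypes,
        "tumor": tumor,
        "normal": normal,
        "differential": differential,
        "mix": mix,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def bundle(study):
    return build_bundle(
        study["tumor"], study["normal"], study["panel"], tumor_type="SYN"
    )


@pytest.fixture(scope="session")
def deconv_result(study, bundle):
    return deconvolve(study["mix"], bundle, h=6)


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free study: replicates identical to archetypes; exercises the
    degenerate zero-variance paths end to end."""
    cfg = SimulationConfig(seed=5, noise_sd=0.0)
    panel, _ = simulate_reference_panel(cfg)
    tumor, normal, _ = simulate_tumor_normal(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = build_bundle(tumor, normal, panel, tumor_type="SYN0")
    _, archetypes, _, _ = _study_archetypes(cfg)
    return {"cfg": cfg, "bundle": b, "archetypes": archetypes, "panel": panel}


@pytest.fixture
def toy_betas():
    rng = np.random.default_rng(7)
    vals = rng.uniform(0.0, 1.0, (100, 10))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:05d}" for i in range(100)],
            columns=[f"s{i}" for i in range(10)],
        )
    )
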
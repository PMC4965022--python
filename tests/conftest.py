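from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mammosim.config import load_config
from mammosim.coupling import run_coupled
from mammosim.mesh import mark_resection

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CONFIG_DIR = Path(__file__).resolve().parents[1] / "configs"


@pytest.fixture(scope="session")
def desk_cfg():
    return load_config(CONFIG_DIR / "desk.yaml")


@pytest.fixture(scope="session")
def smoke_cfg():
    return load_config(CONFIG_DIR / "smoke.yaml")


@pytest.fixture(scope="session")
def bio_defaults(desk_cfg):
    return desk_cfg.bio


@pytest.fixture(scope="session")
def desk_run(desk_cfg):
    """The full desk-preset healing/contraction simulation (run once)."""
    mesh = desk_cfg.make_phantom(seed=1)
    wounded = mark_resection(mesh, desk_cfg.resection)
    return run_coupled(
        wounded, desk_cfg.bio, desk_cfg.materials, desk_cfg.schedule,
        gravity=desk_cfg.heal_gravity(),
        formulation=desk_cfg.mechanics.get("formulation", "penalty"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20160728)
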
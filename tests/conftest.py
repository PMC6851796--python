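import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from fluospect import build_phantom, Geometry
from fluospect.experiment import desk_config, run_realization

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_phantom():
    """Desk-scale phantom: 64 x 64 x 48 voxels at 6 mm, 1:5 uptake."""
    return build_phantom(150.0, 5.0, (64, 64, 48), 6.0)


@pytest.fixture(scope="session")
def desk_geometry():
    return Geometry((64, 64, 48), 6.0, 60)


@pytest.fixture(scope="session")
def small_geometry():
    """Small grid for fast reconstruction unit tests."""
    return Geometry((32, 32, 24), 12.0, 30)


def _strip_heavy(art, keep_mvf):
    art.fluoro_set.frames = None
    art.nuclear_set.subframes = None
    if not keep_mvf:
        art.mvf = None
    return art


@pytest.fixture(scope="session")
def stable_experiment():
    """Five noise realizations of the stable-breathing desk experiment.

    1:5 uptake, 5-min analogue, 5 Hz, 1000 uGy, 5 bins; modes: none, gated,
    motion-vector-field.  Shared by the motion-extraction, MVF-recovery and
    mode-ordering acceptance tests.
    """
    cfg = desk_config(n_realizations=5, modes=("none", "gated", "mvf"),
                      master_seed=7)
    phantom = build_phantom(cfg.total_activity_mbq, cfg.uptake_ratio,
                            tuple(cfg.grid_dims), cfg.voxel_size_mm)
    arts = []
    for r in range(cfg.n_realizations):
        art = run_realization(cfg, r, phantom=phantom)
        arts.append(_strip_heavy(art, keep_mvf=(r == 0)))
    return cfg, phantom, arts


@pytest.fixture(scope="session")
def baseline_shift_experiment():
    """Three realizations of the baseline-shift pattern (none vs MVF)."""
    cfg = desk_config(n_realizations=3, modes=("none", "mvf"),
                      pattern_kind="baseline_shift", master_seed=11)
    phantom = build_phantom(cfg.total_activity_mbq, cfg.uptake_ratio,
                            tuple(cfg.grid_dims), cfg.voxel_size_mm)
    arts = [_strip_heavy(run_realization(cfg, r, phantom=phantom), False)
            for r in range(cfg.n_realizations)]
    return cfg, phantom, arts
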
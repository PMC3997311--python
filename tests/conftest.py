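import numpy as np
import pytest

from camtel.simulate import SimConfig, build_camera_grid, simulate_population


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=7,
        n_females=12,
        n_males=6,
        extent=(0.0, 0.0, 14_000.0, 14_000.0),
        camera_jitter=200.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from camtel.pipeline import simulate_study

    return simulate_study(small_config)


@pytest.fixture(scope="session")
def seasonal_surfaces(small_study):
    from camtel.pipeline import estimate_surfaces

    surf = {}
    for season in ("FallWinter", "Summer"):
        surf.update(estimate_surfaces(small_study.tracks, season))
    return surf


@pytest.fixture(scope="session")
def homerange_table(small_study, seasonal_surfaces):
    from camtel.encounters import build_encounter_table

    return build_encounter_table(
        small_study.tracks,
        seasonal_surfaces,
        small_study.cameras,
        small_study.detections,
        "homerange",
    )


@pytest.fixture(scope="session")
def proximity_table(small_study):
    from camtel.encounters import build_encounter_table

    return build_encounter_table(
        small_study.tracks, None, small_study.cameras, small_study.detections,
        "proximity",
    )


@pytest.fixture(scope="session")
def true_table():
    """Design table from ground truth (no kernel estimation error)."""
    from camtel.pipeline import true_pair_table

    cfg = SimConfig(
        seed=3,
        n_females=20,
        n_males=20,
        extent=(0.0, 0.0, 12_000.0, 12_000.0),
        camera_jitter=200.0,
    )
    pop = simulate_population(cfg)
    cams = build_camera_grid((1000, 3000, 11000, 9000), cfg)
    rng = np.random.default_rng(11)
    return true_pair_table(pop, cams, cfg, rng)
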
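import numpy as np
import pytest

import gripsig as gs


@pytest.fixture(scope="session")
def layout():
    return gs.default_layout()


@pytest.fixture(scope="session")
def template():
    """Single-bump template with an uneven but fixed region split."""
    weights = np.zeros(18)
    weights[[0, 2, 5, 14, 17]] = [0.15, 0.25, 0.10, 0.20, 0.30]
    return gs.TaskTemplate(
        gf_profile=gs.bump_profile([(0.5, 0.8, 30.0)]),
        region_weights=weights,
    )


@pytest.fixture(scope="session")
def noiseless_recording(template, layout):
    effects = gs.SubjectEffects(duration_s=6.0)
    return gs.generate_subject_recording(template, effects, layout, seed=0)


@pytest.fixture(scope="session")
def small_study(layout):
    """6 subjects x 3 tasks, light noise, random warps."""
    cfg = gs.SyntheticConfig(
        n_subjects=6, n_tasks=3, noise_sd_kPa=0.5, spike_rate=0.002,
        duration_mean_s=6.0, rng_seed=7,
    )
    return gs.generate_study(cfg, layout)
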
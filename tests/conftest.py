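import numpy as np
import pytest

from dimorphmap import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort with the four archetypal trajectories planted (14/sex)."""
    cfg = simulate.CohortConfig(seed=11)
    archs = simulate.default_archetypes(amplitude=0.05)
    return simulate.generate_cohort(cfg, archs), cfg, archs


@pytest.fixture(scope="session")
def planted_fields():
    """Determinant fields on a 20^3 grid with four planted ROIs."""
    cfg = simulate.CohortConfig(seed=7, dropout_rate=0.0)
    archs = simulate.default_archetypes(amplitude=3 * cfg.sigma_noise)
    g = (20, 20, 20)
    corners = [(6, 6, 6), (11, 6, 6), (6, 11, 6), (6, 6, 11)]
    for a, corner in zip(archs, corners):
        a.roi = simulate.box_roi(g, corner, (3, 3, 3))
    fields, atlas = simulate.generate_determinant_fields(cfg, g, archs)
    truth = np.zeros(g, dtype=bool)
    for a in archs:
        truth |= a.roi
    return fields, atlas, archs, truth


@pytest.fixture(scope="session")
def relative_fields(planted_fields):
    fields, atlas, archs, truth = planted_fields
    return [f for f in fields if f.kind == "relative"], atlas, archs, truth
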
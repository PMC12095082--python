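import numpy as np
import pytest

import bmiphase as bp


@pytest.fixture(scope="session")
def grid():
    return bp.standard_grid()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (small, single sex) shared across tests."""
    cfg = bp.SimConfig(n_per_cluster=8, sex_mode="female", seed=123)
    return bp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Warps only: amplitude, measurement and schedule noise all off."""
    cfg = bp.SimConfig(n_per_cluster=8, sex_mode="female", seed=11,
                       amplitude_sd=0.0, height_noise_sd=0.0,
                       weight_noise_sd=0.0, visit_jitter_sd=0.0)
    return bp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def template_grid(grid):
    """BMIGrid built directly from warped templates (no measurement stage).

    24 trajectories, 8 per timing type, each the type template composed with
    an individual random warp at the default strength.  Bypasses the spline
    stage so amplitude-level checks see only the elastic machinery.
    """
    from bmiphase.cohort_synth import _warp_age

    rng = np.random.default_rng(11)
    templates = bp.default_cluster_params()
    rows, ids, labels = [], [], []
    for ci, p in enumerate(templates, start=1):
        for j in range(8):
            w = bp.sample_warping(0.3, rng)
            rows.append(bp.make_template_bmi(p, _warp_age(grid, w)))
            ids.append(f"T{ci}_{j}")
            labels.append(ci)
    bmi = bp.BMIGrid(child_ids=ids, grid_ages=grid, values=np.vstack(rows),
                     sex=["F"] * len(ids))
    return bmi, np.array(labels)
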
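"""Shared fixtures: the scaled study profile, run once per session.

The trend suite re-analyses the same five experiments from several
angles, so each experiment is simulated a single time at the scaled-down
profile (200 realizations, 6 stimulus levels) and shared session-wide.
"""

import pytest

import fflcap.experiments as ex

#: master seed of the shared study runs
STUDY_SEED = 1
N_REAL = 200


@pytest.fixture(scope="session")
def mapk_result():
    return ex.run_mapk_cc(ex.ExperimentConfig.desk("mapk_cc", seed=STUDY_SEED, n_real=N_REAL))


@pytest.fixture(scope="session")
def minimal_result():
    return ex.run_minimal_cc(
        ex.ExperimentConfig.desk("minimal_cc", seed=STUDY_SEED, n_real=N_REAL)
    )


@pytest.fixture(scope="session")
def lvf_result():
    return ex.run_linear_vs_ffl(
        ex.ExperimentConfig.desk("linear_vs_ffl", seed=STUDY_SEED, n_real=N_REAL)
    )


@pytest.fixture(scope="session")
def affinity_result():
    return ex.run_affinity_mmi(
        ex.ExperimentConfig.desk("affinity_mmi", seed=STUDY_SEED, n_real=N_REAL)
    )


@pytest.fixture(scope="session")
def extrinsic_result():
    return ex.run_extrinsic_noise(
        ex.ExperimentConfig.desk(
            "extrinsic_noise",
            seed=STUDY_SEED,
            n_real=N_REAL,
            eps_grid=(0.0, 0.5, 1.0),
            pext_grid=(1.0, 200.0),
        )
    )
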
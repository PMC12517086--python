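import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_leadfield():
    from painconn.synthetic import make_toy_leadfield

    return make_toy_leadfield(n_sensors=32, n_parcels=21, n_networks=7, seed=0)


@pytest.fixture(scope="session")
def alpha_band():
    from painconn.datatypes import BANDS, BandSpec

    return BandSpec("alpha", *BANDS["alpha"])


@pytest.fixture(scope="session")
def small_recording(toy_leadfield):
    """One 60 s alpha-band source simulation projected to sensors."""
    from painconn.synthetic import simulate_network_sources, simulate_sensor_recording

    C = np.full((7, 7), 0.3)
    np.fill_diagonal(C, 1.0)
    truth = simulate_network_sources(
        C, "alpha", duration_s=60, fs=250, seed=11,
        parcel_labels=toy_leadfield.network_labels, parcel_noise=0.5,
    )
    rec = simulate_sensor_recording(truth, toy_leadfield, snr_db=3, seed=12)
    return truth, rec


@pytest.fixture(scope="session")
def small_cohort():
    """Feature-level cohort with one planted univariate effect (n=250)."""
    from painconn.datatypes import CohortConfig
    from painconn.synthetic import simulate_feature_cohort

    cfg = CohortConfig(
        n_per_site=(40, 30, 30, 30, 30, 30, 25, 35),
        planted_effects=(("theta_SN-LN", 0.25),),
        seed=5,
    )
    return simulate_feature_cohort(cfg)


def brute_force_frame_objective(Gs, d, p, n_starts=40, seed=0):
    """Independent oracle: maximise sum_i z_i^T G_i z_i over orthonormal
    frames by Nelder-Mead polish of many random starts, parameterising the
    frame as the QR orthonormalisation of an unconstrained d x p matrix."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)

    def negobj(flat):
        Q, R = np.linalg.qr(flat.reshape(d, p))
        Z = Q * np.sign(np.diag(R))[None, :]
        return -sum(Z[:, i] @ G @ Z[:, i] for i, G in enumerate(Gs))

    best = np.inf
    for _ in range(n_starts):
        res = minimize(
            negobj, rng.standard_normal(d * p), method="Nelder-Mead",
            options=dict(maxiter=4000, fatol=1e-12, xatol=1e-10),
        )
        best = min(best, res.fun)
    return -best
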
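import numpy as np
import pytest

from facedcm.design import build_stimulus_design
from facedcm.network import DCMParams, DCMSpec
from facedcm.priors import default_priors


@pytest.fixture(scope="session")
def spec():
    return DCMSpec.face_network()


@pytest.fixture(scope="session")
def priors(spec):
    return default_priors(spec)


@pytest.fixture(scope="session")
def short_design():
    """One block per condition: 60 scans, fast to integrate."""
    return build_stimulus_design(n_blocks_per_condition=1, rng=0)


@pytest.fixture(scope="session")
def medium_design():
    """Three blocks per condition: 180 scans."""
    return build_stimulus_design(n_blocks_per_condition=3, rng=0)


@pytest.fixture(scope="session")
def active_params(spec):
    """A stable, driven parameter set with visible face modulations."""
    p = DCMParams.zeros(spec)
    for src, tgt in [("lEVC", "lOFA"), ("lEVC", "lFFA"),
                     ("rEVC", "rOFA"), ("rEVC", "rFFA")]:
        p[f"A:{src}->{tgt}"] = 0.4
    p["A:lOFA->lFFA"] = 0.1
    p["A:lFFA->lOFA"] = 0.1
    p["C(visual):lEVC"] = 0.6
    p["C(visual):rEVC"] = 0.6
    p["B(faces):lOFA->lOFA"] = 0.5
    p["B(faces):lFFA->rFFA"] = -0.3
    return p


@pytest.fixture(scope="session")
def factorial_space(spec):
    from facedcm.modelspace import build_factorial_space

    return build_factorial_space(spec)


@pytest.fixture(scope="session")
def recovery_runs(spec, factorial_space):
    """Ten seeded group-level recovery studies on planted n=50 cohorts.

    Subject-level inversion is emulated by the generator's posterior
    simulator; the PEB fit, the 37^3 factorial comparison (with BMA) and
    the automatic search run in full.
    """
    from facedcm.cohort import (make_ground_truth, sample_covariates,
                                simulate_subject_posteriors)
    from facedcm.peb import PEB, GroupDesign

    runs = []
    for seed in range(10):
        cov = sample_covariates(50, seed)
        gt = make_ground_truth(spec, cov, seed)
        posts = simulate_subject_posteriors(gt, spec, obs_sd=0.15, rng=seed)
        peb = PEB(posts, GroupDesign.from_covariates(cov)).fit()
        comparison = peb.compare(factorial_space)
        search = peb.search()
        runs.append({"seed": seed, "gt": gt, "peb": peb,
                     "comparison": comparison, "search": search})
    return runs


@pytest.fixture(scope="session")
def small_report():
    """One full end-to-end pipeline run (simulation + inversion + PEB +
    comparison + search) at desk scale: 8 subjects, 120 scans."""
    from facedcm.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(n_subjects=8, seed=5,
                                       blocks_per_condition=2))


@pytest.fixture(scope="session")
def linear_problem():
    """A 5-parameter linear-Gaussian inverse problem with its closed form.

    Returns (design matrix L, data y, prior mean, prior variances, noise
    variance, posterior mean, posterior covariance, log evidence).
    """
    from scipy.stats import multivariate_normal

    rng = np.random.default_rng(42)
    p, n = 5, 40
    L = rng.normal(size=(n, p))
    m0 = rng.normal(size=p) * 0.3
    v0 = np.array([0.5, 1.0, 0.2, 0.8, 0.3])
    theta = m0 + rng.normal(size=p) * np.sqrt(v0)
    noise_var = 0.25
    y = L @ theta + rng.normal(size=n) * np.sqrt(noise_var)
    P0 = np.diag(1.0 / v0)
    Pq = L.T @ L / noise_var + P0
    Sq = np.linalg.inv(Pq)
    mq = Sq @ (L.T @ y / noise_var + P0 @ m0)
    logz = multivariate_normal.logpdf(
        y, mean=L @ m0, cov=noise_var * np.eye(n) + L @ np.diag(v0) @ L.T)
    return L, y, m0, v0, noise_var, mq, Sq, float(logz)
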
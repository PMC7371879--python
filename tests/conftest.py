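import logging
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rllgmn as rl
from rllgmn.core import ClassHMMGMM, HMMGMMParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("rllgmn").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning, module="rllgmn")


def random_theta(rng, C=2, K_max=3, M_max=3, d_max=3, d=None, uniform_pi=False,
                 K_fixed=None):
    """A random valid two-class HMM-GMM for oracle tests."""
    d = d or int(rng.integers(1, d_max + 1))
    classes = []
    for _ in range(C):
        K = K_fixed or int(rng.integers(1, K_max + 1))
        pi = np.full(K, 1.0 / K) if uniform_pi else _simplex(rng, K)
        trans = np.stack([_simplex(rng, K) for _ in range(K)])
        mixing, means, covs = [], [], []
        for _ in range(K):
            M = int(rng.integers(1, M_max + 1))
            mixing.append(_simplex(rng, M))
            means.append(rng.normal(0.0, 1.0, (M, d)))
            cv = []
            for _ in range(M):
                A = rng.normal(0.0, 1.0, (d, d))
                cv.append(A @ A.T + 0.5 * np.eye(d))
            covs.append(np.array(cv))
        classes.append(ClassHMMGMM(pi, trans, mixing, means, covs))
    return HMMGMMParams(classes)


def _simplex(rng, n):
    p = rng.dirichlet(np.full(n, 5.0)) + 1e-3
    return p / p.sum()


def random_weights(rng, shape, scale=0.3):
    w = rng.uniform(-scale, scale, shape.weight_array_shape)
    return rl.RLLGMNWeights(shape, w * shape.unit_mask[..., None])


def small_dataset(rng, n=6, T=5, d=2, offset=1.0):
    """A tiny two-class dataset with a mean offset between classes."""
    out = []
    for i in range(n):
        label = 1 + i % 2
        x = rng.normal(0.0, 1.0, (T, d)) + (offset if label == 2 else 0.0)
        teacher = np.zeros(2)
        teacher[label - 1] = 1.0
        out.append(rl.FeatureSequence(x=x, label=label, teacher=teacher,
                                      record_id=f"case-{i}"))
    return out


@pytest.fixture(scope="session")
def default_cohort():
    spec = rl.default_generator_spec(seed=1)
    return spec, rl.generate_cohort(spec)


@pytest.fixture(scope="session")
def cv_training_config():
    # harness sizing: 2 restarts / 300 epochs keep the 40-fold CV fast while
    # converging well past the stopping tolerance on this cohort
    return rl.TrainingConfig(restarts=2, max_epochs=300, seed=0)
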
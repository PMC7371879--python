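"""Seeded synthetic cohorts with the statistical structure the classifier
assumes.

Every generator draws from an explicit class-conditional HMM-GMM, so the
Bayes-optimal posterior is available in closed form (via the oracle forward
recursion) and end-to-end recovery can be checked against it.  Additional
generators emit vital-sign-like 4-channel records (heart rate, systolic /
diastolic / mean blood pressure at 1-min sampling) and RR-interval streams,
matched to the preprocessing module's input contracts.

Defaults emulate the geometry of small ICU cohorts: two classes, 3 hidden
states per class, single-Gaussian emissions in d=4 with identity covariance,
T=12 steps (12 min of 1-min samples), 20 positive and 20 negative
sequences, and a class-centroid separation of 3 pooled standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ClassHMMGMM, HMMGMMParams, reference_forward
from .exceptions import InvalidParameterError
from .preprocess import FeatureSequence, RRISequence, VitalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec",
    "SyntheticCohort",
    "default_theta",
    "default_generator_spec",
    "sample_hmm_gmm_sequence",
    "generate_cohort",
    "generate_vitals_record",
    "generate_rri_stream",
    "bayes_posterior",
]

DEFAULT_VITALS_TEMPLATE = {
    "dt_s": 60.0,
    "duration_s": 2400.0,          # 40 min of 1-min samples
    "baselines": {"HR": 80.0, "SBP": 120.0, "DBP": 70.0},
    "noise_sd": {"HR": 2.0, "SBP": 3.0, "DBP": 2.0, "MAP": 1.0},
    "drift": {"HR": 15.0, "SBP": -30.0, "DBP": -15.0},  # total change over the lead-in
}


def _sticky_transitions(K: int, stay: float = 0.8) -> np.ndarray:
    off = (1.0 - stay) / (K - 1) if K > 1 else 0.0
    G = np.full((K, K), off)
    np.fill_diagonal(G, stay if K > 1 else 1.0)
    return G


def default_theta(
    separation: float = 3.0, d: int = 4, K: int = 3, seed: int | None = None
) -> HMMGMMParams:
    """Ground-truth two-class HMM-GMM (single Gaussian per state).

    Class 1 ("normal") states sit at staggered small offsets around the
    origin; class 2 ("deterioration") shifts every state centroid by a vector
    of norm ``separation`` (identity covariances, so pooled-sigma units).
    """
    base = np.array([[0.0] * d, [0.5] * d, [-0.5] * d])[:K]
    # stagger the per-state offsets so states are distinguishable
    for k in range(K):
        base[k, k % d] += 0.25 * (k + 1)
    shift = separation / np.sqrt(d) * np.ones(d)
    classes = []
    for c in range(2):
        means = base + (shift if c == 1 else 0.0)
        classes.append(
            ClassHMMGMM(
                pi=np.full(K, 1.0 / K),
                trans=_sticky_transitions(K),
                mixing=[np.array([1.0]) for _ in range(K)],
                means=[means[k : k + 1].copy() for k in range(K)],
                covs=[np.eye(d)[None] for _ in range(K)],
            )
        )
    return HMMGMMParams(classes)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic cohort; (spec, seed) -> bit-identical data."""

    theta: HMMGMMParams
    T: int = 12
    n_pos: int = 20
    n_neg: int = 20
    seed: int = 0
    separation: float = 3.0
    vitals_template: dict = field(default_factory=lambda: dict(DEFAULT_VITALS_TEMPLATE))
    event_lead_min: float = 5.0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1 or self.T < 1:
            raise InvalidParameterError("n_pos, n_neg, T must be >= 1")
        if self.separation < 0:
            raise InvalidParameterError("separation must be >= 0")
        self.theta.validate()

    def digest(self) -> dict:
        return {
            "T": self.T, "n_pos": self.n_pos, "n_neg": self.n_neg,
            "seed": self.seed, "separation": self.separation,
            "d": self.theta.d, "K": list(self.theta.shape.K),
            "event_lead_min": self.event_lead_min,
        }


def default_generator_spec(
    separation: float = 3.0, seed: int = 0, n_pos: int = 20, n_neg: int = 20,
    T: int = 12, d: int = 4, K: int = 3,
) -> GeneratorSpec:
    return GeneratorSpec(
        theta=default_theta(separation=separation, d=d, K=K),
        T=T, n_pos=n_pos, n_neg=n_neg, seed=seed, separation=separation,
    )


@dataclass
class SyntheticCohort:
    sequences: list[FeatureSequence]
    state_paths: list[np.ndarray]
    spec: GeneratorSpec
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.array([fs.label for fs in self.sequences])


def sample_hmm_gmm_sequence(
    theta: HMMGMMParams, c: int, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observations (T,d), hidden state path (T,)) from class ``c`` (1-based)."""
    theta.validate()
    if not 1 <= c <= theta.C:
        raise InvalidParameterError(f"class {c} outside 1..{theta.C}")
    cl = theta.classes[c - 1]
    K, d = cl.K, cl.d
    path = np.empty(T, dtype=int)
    x = np.empty((T, d))
    state = int(rng.choice(K, p=cl.pi))
    for t in range(T):
        if t > 0:
            state = int(rng.choice(K, p=cl.trans[state]))
        path[t] = state
        m = int(rng.choice(len(cl.mixing[state]), p=cl.mixing[state]))
        L = np.linalg.cholesky(cl.covs[state][m])
        x[t] = cl.means[state][m] + L @ rng.standard_normal(d)
    return x, path


def generate_cohort(spec: GeneratorSpec) -> SyntheticCohort:
    """n_neg class-1 and n_pos class-2 sequences from the ground-truth model."""
    rng = np.random.default_rng(spec.seed)
    sequences: list[FeatureSequence] = []
    paths: list[np.ndarray] = []
    for c, n, tag in ((1, spec.n_neg, "neg"), (2, spec.n_pos, "pos")):
        for i in range(n):
            x, path = sample_hmm_gmm_sequence(spec.theta, c, spec.T, rng)
            teacher = np.zeros(2)
            teacher[c - 1] = 1.0
            rid = f"{tag}-{i:03d}"
            sequences.append(
                FeatureSequence(x=x, label=c, teacher=teacher,
                                record_id=rid, window_end=None, group=rid)
            )
            paths.append(path)
    return SyntheticCohort(sequences=sequences, state_paths=paths, spec=spec, seed=spec.seed)


def generate_vitals_record(
    spec: GeneratorSpec, positive: bool, rng: np.random.Generator,
    record_id: str = "rec",
) -> VitalRecord:
    """A 4-channel vital-sign record (HR, SBP, DBP, MAP) at 1-min sampling.

    Negative records are stationary baselines plus noise.  Positive records
    carry a deterministic drift (blood-pressure decline, heart-rate rise)
    starting ``event_lead_min`` minutes before the event at the record end.
    MAP is (SBP + 2 DBP)/3 plus measurement noise.
    """
    tpl = spec.vitals_template
    dt = float(tpl["dt_s"])
    n = int(round(float(tpl["duration_s"]) / dt))
    t = np.arange(n) * dt
    base, noise, drift = tpl["baselines"], tpl["noise_sd"], tpl["drift"]
    event_time = float(n * dt) if positive else None
    series = {}
    for ch in ("HR", "SBP", "DBP"):
        s = np.full(n, base[ch]) + noise[ch] * rng.standard_normal(n)
        if positive:
            lead_s = spec.event_lead_min * 60.0
            ramp = np.clip((t - (event_time - lead_s)) / lead_s, 0.0, 1.0)
            s = s + drift[ch] * ramp
        series[ch] = s
    series["MAP"] = (series["SBP"] + 2.0 * series["DBP"]) / 3.0 + noise[
        "MAP"
    ] * rng.standard_normal(n)
    values = np.column_stack([series[ch] for ch in ("HR", "SBP", "DBP", "MAP")])
    return VitalRecord(
        record_id=record_id, dt=dt, channels=["HR", "SBP", "DBP", "MAP"],
        values=values, event_time=event_time,
    )


def generate_rri_stream(
    duration_s: float,
    base_ms: float = 800.0,
    sdnn_ms: float = 50.0,
    rmssd_target_ms: float = 30.0,
    rng: np.random.Generator | None = None,
) -> RRISequence:
    """AR(1)-correlated beat intervals with tunable short-term variability.

    The AR coefficient is set from the identity
    ``RMSSD^2 = 2 SDNN^2 (1 - phi)``, so the realized RMSSD of a long stream
    approaches ``rmssd_target_ms`` while the overall spread stays at
    ``sdnn_ms``.  ``sdnn_ms = 0`` yields a perfectly regular rhythm.
    """
    if base_ms <= 0:
        raise InvalidParameterError("base_ms must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if sdnn_ms <= 0:
        n = int(np.ceil(duration_s * 1000.0 / base_ms)) + 1
        rri = np.full(n, base_ms)
        return RRISequence(np.cumsum(rri) / 1000.0, rri)
    phi = float(np.clip(1.0 - (rmssd_target_ms**2) / (2.0 * sdnn_ms**2), 0.0, 0.999))
    innov_sd = sdnn_ms * np.sqrt(1.0 - phi**2)
    intervals = []
    x = sdnn_ms * rng.standard_normal()
    total = 0.0
    while total < duration_s * 1000.0:
        rri = max(base_ms + x, 200.0)  # physiological floor
        intervals.append(rri)
        total += rri
        x = phi * x + innov_sd * rng.standard_normal()
    rri = np.asarray(intervals)
    return RRISequence(np.cumsum(rri) / 1000.0, rri)


def bayes_posterior(spec: GeneratorSpec, seq: np.ndarray) -> np.ndarray:
    """Exact generative class posteriors under the ground-truth model.

    Delegates to the oracle forward recursion with class priors
    ``n_neg : n_pos`` (class 1 first).  Returns the (T, C) posterior matrix.
    """
    return reference_forward(
        spec.theta, seq, class_priors=[spec.n_neg, spec.n_pos]
    )
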
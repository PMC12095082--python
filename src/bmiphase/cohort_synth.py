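"""Synthetic birth-cohort generator with known timing-cluster structure.

Real childhood growth records of the kind this pipeline targets are
application-restricted, so every downstream stage is exercised on synthetic
cohorts that emulate their statistical structure: sparse longitudinal
height/weight visits (dense in infancy, sparser at school age), BMI
trajectories with an infancy peak near 0.75 y, an adiposity-rebound valley in
mid-childhood and a pubertal rise, three latent *timing types* that differ in
phase (including a type with a mid-childhood bump), individual random time
warping, multiplicative amplitude noise, and additive measurement error.

Ground truth (cluster label and the individual warping function of each
child) is returned alongside the records, so cluster-recovery can be scored
with the adjusted Rand index.

The BMI template is a sum of a constant, Gaussian bumps and a logistic rise:

    B(t) = c0 + a_inf exp(-((t-p_inf)/s_inf)^2)
              + a_mid exp(-((t-p_mid)/s_mid)^2)
              + a_pub / (1 + exp(-(t-p_pub)/s_pub))

on ages t in [0.25, 16] years.  The height template is shared across
clusters, so all cluster signal lives in the timing of BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elastic import WarpingFunction
from .preprocess import GrowthRecordSet

__all__ = [
    "TemplateParams",
    "SimConfig",
    "SyntheticCohort",
    "default_cluster_params",
    "make_template_bmi",
    "height_template",
    "sample_warping",
    "simulate_cohort",
]

AGE_MIN = 0.25
AGE_MAX = 16.0

#: visit ages (years) mimicking regular infant check-ups followed by annual
#: school health records
DEFAULT_SCHEDULE = (0.3, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0,
                    7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0)


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of one cluster's BMI template (ages in years, BMI kg/m^2)."""

    c0: float = 13.0        # baseline level
    a_inf: float = 4.0      # infancy-peak height
    p_inf: float = 0.75     # infancy-peak age
    s_inf: float = 0.6      # infancy-peak width
    a_mid: float = 0.0      # mid-childhood bump height (0 = no bump)
    p_mid: float = 6.5      # mid-childhood bump age
    s_mid: float = 1.5      # mid-childhood bump width
    a_pub: float = 5.0      # pubertal-rise amplitude
    p_pub: float = 11.5     # pubertal-rise midpoint age
    s_pub: float = 1.5      # pubertal-rise steepness scale


def default_cluster_params() -> tuple[TemplateParams, ...]:
    """Three timing types: classic, mid-childhood bump, late maturer.

    Type 1 is the canonical trajectory (infancy peak, rebound, pubertal
    rise); Type 2 adds an intermediate BMI rise between ages four and nine;
    Type 3 shifts the pubertal rise two years later, delaying the rebound —
    a pure phase difference relative to Type 1.
    """
    t1 = TemplateParams(p_pub=9.0, s_pub=0.8)
    t2 = TemplateParams(a_mid=3.0, p_mid=6.5, s_mid=0.9, p_pub=12.5)
    t3 = TemplateParams(p_pub=15.2, s_pub=0.9, s_inf=2.0)
    return (t1, t2, t3)


def make_template_bmi(params: TemplateParams, ages) -> np.ndarray:
    """Evaluate a cluster's smooth BMI template at the given ages (years)."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < AGE_MIN) or np.any(ages > AGE_MAX):
        raise ValueError(f"ages must lie within [{AGE_MIN}, {AGE_MAX}] years")
    p = params
    b = (p.c0
         + p.a_inf * np.exp(-((ages - p.p_inf) / p.s_inf) ** 2)
         + p.a_mid * np.exp(-((ages - p.p_mid) / p.s_mid) ** 2)
         + p.a_pub / (1.0 + np.exp(-(ages - p.p_pub) / p.s_pub)))
    return b


def height_template(ages) -> np.ndarray:
    """Shared monotone height template (cm): rapid infant growth, pubertal spurt."""
    t = np.asarray(ages, dtype=float)
    return 50.0 + 110.0 * (1.0 - np.exp(-t / 2.8)) + 20.0 / (1.0 + np.exp(-(t - 12.0) / 1.2))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    ``warp_strength`` is the sd of the Gaussian Fourier coefficients of the
    log-slope field that builds each child's random warp (0 = no phase
    noise); ``amplitude_sd`` the sd of the child-level multiplicative
    log-amplitude factor; measurement noise is additive Gaussian on height
    (cm) and weight (kg).
    """

    n_per_cluster: int = 20
    cluster_params: tuple[TemplateParams, ...] = field(default_factory=default_cluster_params)
    warp_strength: float = 0.3
    amplitude_sd: float = 0.05
    height_noise_sd: float = 0.3
    weight_noise_sd: float = 0.1
    visit_schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    visit_jitter_sd: float = 0.05
    sex_mode: str = "alternating"  # alternating | female | male | random
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cluster < 1:
            raise ValueError("n_per_cluster must be >= 1")
        if self.warp_strength < 0:
            raise ValueError("warp_strength must be >= 0")
        if self.amplitude_sd < 0 or self.height_noise_sd < 0 or self.weight_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        sched = np.asarray(self.visit_schedule, dtype=float)
        if np.any(np.diff(sched) <= 0):
            raise ValueError("visit_schedule must be strictly increasing")
        if sched[0] >= 0.5:
            raise ValueError("first scheduled visit must be before 6 months")
        if sched[-1] < 16.0:
            raise ValueError("last scheduled visit must be at or after 16 years")
        if self.sex_mode not in ("alternating", "female", "male", "random"):
            raise ValueError(f"unknown sex_mode {self.sex_mode!r}")
        if not self.cluster_params:
            raise ValueError("at least one cluster template is required")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the ground truth behind them."""

    records: GrowthRecordSet
    true_labels: pd.Series        # child_id -> cluster label in 1..n_clusters
    true_warps: dict              # child_id -> WarpingFunction


def sample_warping(warp_strength: float, seed, n_points: int = 101,
                   n_harmonics: int = 1) -> WarpingFunction:
    """Draw a random boundary-fixed diffeomorphism of [0, 1].

    The warp is built from a log-slope field ``w``, a finite Fourier sine
    series with iid mean-zero Gaussian coefficients of sd ``warp_strength``:

        gamma(t) = int_0^t exp(w(s)) ds / int_0^1 exp(w(s)) ds.

    This guarantees gamma(0)=0, gamma(1)=1 and strict monotonicity for any
    coefficient draw.  ``seed`` may be an int or a numpy Generator.
    """
    if warp_strength < 0:
        raise ValueError("warp_strength must be >= 0")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    coeffs = rng.normal(0.0, warp_strength, size=n_harmonics)
    w = np.zeros_like(t)
    for k, c in enumerate(coeffs, start=1):
        w += c * np.sin(k * np.pi * t)
    ew = np.exp(w)
    cum = np.concatenate([[0.0], np.cumsum((ew[1:] + ew[:-1]) / 2.0 * np.diff(t))])
    gamma = cum / cum[-1]
    gamma[0], gamma[-1] = 0.0, 1.0
    return WarpingFunction(t=t, gamma=gamma)


def _warp_age(age, warp: WarpingFunction):
    """Apply a [0,1]-warp to chronological age via the affine age map."""
    s = (np.asarray(age, dtype=float) - AGE_MIN) / (AGE_MAX - AGE_MIN)
    s_w = np.interp(s, warp.t, warp.gamma)
    return AGE_MIN + (AGE_MAX - AGE_MIN) * s_w


def _visit_ages(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    ages = np.asarray(config.visit_schedule, dtype=float).copy()
    if config.visit_jitter_sd > 0:
        ages = ages + rng.normal(0.0, config.visit_jitter_sd, size=ages.size)
    # boundary visits clamped so selection criteria hold by construction
    ages = np.clip(ages, AGE_MIN, AGE_MAX)
    ages[0] = min(max(ages[0], AGE_MIN), 0.35)
    ages[-1] = AGE_MAX
    ages = np.unique(ages)
    return ages


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort of growth records with known cluster structure.

    Per child: the cluster template is composed with an individual random
    warp (time rescaled [0.25, 16] <-> [0, 1]) and scaled by
    ``exp(N(0, amplitude_sd))``; height follows the shared template; weight
    is derived as ``BMI * (height/100)^2`` from the noise-free height; both
    measurements then receive additive Gaussian noise at jittered visit ages.
    Reproducible: identical config (including seed) gives identical records.
    """
    rng = np.random.default_rng(config.seed)
    n_clusters = len(config.cluster_params)
    rows = []
    labels = {}
    warps = {}
    child = 0
    for ci, params in enumerate(config.cluster_params, start=1):
        for _ in range(config.n_per_cluster):
            cid = f"C{child:04d}"
            if config.sex_mode == "alternating":
                sex = "F" if child % 2 == 0 else "M"
            elif config.sex_mode == "random":
                sex = "F" if rng.random() < 0.5 else "M"
            else:
                sex = "F" if config.sex_mode == "female" else "M"
            warp = sample_warping(config.warp_strength, rng)
            amp = np.exp(rng.normal(0.0, config.amplitude_sd)) if config.amplitude_sd > 0 else 1.0
            ages = _visit_ages(config, rng)
            bmi = make_template_bmi(params, _warp_age(ages, warp)) * amp
            h_true = height_template(ages)
            height = h_true + (rng.normal(0.0, config.height_noise_sd, ages.size)
                               if config.height_noise_sd > 0 else 0.0)
            weight = bmi * (h_true / 100.0) ** 2
            weight = weight + (rng.normal(0.0, config.weight_noise_sd, ages.size)
                               if config.weight_noise_sd > 0 else 0.0)
            for a, h, w in zip(ages, height, weight):
                rows.append((cid, sex, float(a), float(h), float(w)))
            labels[cid] = ci
            warps[cid] = warp
            child += 1
    df = pd.DataFrame(rows, columns=["child_id", "sex", "age_years",
                                     "height_cm", "weight_kg"])
    records = GrowthRecordSet(df)
    true_labels = pd.Series(labels, name="true_label")
    assert all(true_labels.value_counts().eq(config.n_per_cluster)), \
        "label counts must equal n_per_cluster"
    return SyntheticCohort(records=records, true_labels=true_labels, true_warps=warps)
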
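"""Synthetic two-group cohorts: 1-hour RR epochs plus clinical covariates.

The generator stands in for a clinical cohort that cannot be shared. Each
subject's interbeat series is a direct interval model

    NN(t) = mean_nn + lf_amp sin(2 pi f_lf t + phi1)
                    + hf_amp sin(2 pi f_hf t + phi2) + AR(1) noise,

clipped to the physiologic neonatal range 200-2000 ms; the two default
group profiles reproduce the qualitative contrasts seen between normal-mild
and moderate-severe encephalopathy groups (longer mean NN, lower LF/HF
balance, narrower interval histogram and reduced multiscale-entropy
complexity in the severe group). The complexity contrast is carried by the
broadband noise term: the mild profile carries a large serially correlated
noise component (rich, irregular beat-to-beat modulation, hence high sample
entropy that decays slowly under smoothing), while the severe profile is
dominated by its regular oscillatory components with only a small white
noise term (predictable at the beat scale, and the little irregularity it
has is removed quickly by coarse-graining, giving a low entropy maximum and
a steeper short-scale decline). Clinical covariates are
sampled independently within group from distributions matched to the
published cohort contrasts; missingness is missing-completely-at-random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecificationError
from .series import RRSeries

__all__ = [
    "GroupProfile",
    "ClinicalProfile",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "default_group_profiles",
    "default_clinical_profiles",
    "generate_rr_series",
    "generate_clinical",
    "generate_cohort",
]

CLIP_LO_MS = 200.0
CLIP_HI_MS = 2000.0


@dataclass
class GroupProfile:
    """Generating parameters for one group's RR epochs.

    ``noise_sd_ms`` is the stationary SD of the AR(1) noise and
    ``noise_ar1`` its lag-one autocorrelation. When ``sd_nn_ms`` is given,
    the oscillatory amplitudes and noise SD are rescaled proportionally so
    the theoretical beat-to-beat SD matches it.

    ``between_subject_mean_sd_ms`` and ``between_subject_scale_sigma``
    control cohort-level heterogeneity: each subject draws its own mean NN
    (normal around ``mean_nn_ms``) and a common lognormal multiplier on the
    variability components, so group distributions overlap the way clinical
    cohorts do. They only act through :func:`generate_cohort`;
    :func:`generate_rr_series` uses a profile verbatim.
    """

    label: int
    mean_nn_ms: float
    lf_amp_ms: float = 0.0
    hf_amp_ms: float = 0.0
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.7
    noise_sd_ms: float = 0.0
    noise_ar1: float = 0.0
    artifact_rate: float = 0.0
    sd_nn_ms: float | None = None
    between_subject_mean_sd_ms: float = 0.0
    between_subject_scale_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_nn_ms <= 0:
            raise InvalidSpecificationError("mean_nn_ms must be positive")
        if not 0 <= self.artifact_rate < 0.5:
            raise InvalidSpecificationError("artifact_rate must be in [0, 0.5)")
        if not self.lf_freq_hz < self.hf_freq_hz:
            raise InvalidSpecificationError("lf_freq_hz must be below hf_freq_hz")
        if min(self.lf_amp_ms, self.hf_amp_ms, self.noise_sd_ms) < 0:
            raise InvalidSpecificationError("amplitudes and noise SD must be >= 0")
        if not -1 < self.noise_ar1 < 1:
            raise InvalidSpecificationError("noise_ar1 must be in (-1, 1)")
        if self.between_subject_mean_sd_ms < 0 or self.between_subject_scale_sigma < 0:
            raise InvalidSpecificationError("between-subject spreads must be >= 0")
        if self.label not in (0, 1):
            raise InvalidSpecificationError("label must be 0 or 1")

    def theoretical_sd_ms(self) -> float:
        return math.sqrt(
            self.lf_amp_ms**2 / 2 + self.hf_amp_ms**2 / 2 + self.noise_sd_ms**2
        )

    def _rescaled(self) -> "GroupProfile":
        if self.sd_nn_ms is None:
            return self
        base = self.theoretical_sd_ms()
        if base == 0:
            raise InvalidSpecificationError(
                "sd_nn_ms given but all variability components are zero"
            )
        f = self.sd_nn_ms / base
        return replace(
            self,
            lf_amp_ms=self.lf_amp_ms * f,
            hf_amp_ms=self.hf_amp_ms * f,
            noise_sd_ms=self.noise_sd_ms * f,
            sd_nn_ms=None,
        )


@dataclass
class ClinicalProfile:
    """Per-group generating distributions for the clinical covariates.

    Apgar scores are sampled from a rounded normal clipped to 0-10;
    continuous covariates are normal; binary covariates are Bernoulli.
    ``missingness`` maps covariate name to its missing-completely-at-random
    probability.
    """

    apgar1_mean: float = 2.5
    apgar1_sd: float = 2.0
    apgar5_mean: float = 5.5
    apgar5_sd: float = 2.0
    ventilation_prob: float = 0.415
    emergency_delivery_prob: float = 0.741
    foetal_distress_prob: float = 0.816
    male_prob: float = 0.593
    intrapartum_prob: float = 0.852
    cooled_prob: float = 0.611
    asm_prob: float = 0.0
    ga_weeks_mean: float = 40.4
    ga_weeks_sd: float = 1.2
    bw_g_mean: float = 3525.0
    bw_g_sd: float = 492.0
    ph_mean: float = 7.05
    ph_sd: float = 0.15
    lactate_mean: float = 10.9
    lactate_sd: float = 3.2
    base_deficit_mean: float = 14.6
    base_deficit_sd: float = 4.5
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "foetal_distress": 0.117,
            "apgar1": 0.033,
            "apgar5": 0.033,
            "ph": 0.15,
            "lactate": 0.292,
            "base_deficit": 0.258,
        }
    )

    def __post_init__(self) -> None:
        probs = [
            self.ventilation_prob,
            self.emergency_delivery_prob,
            self.foetal_distress_prob,
            self.male_prob,
            self.intrapartum_prob,
            self.cooled_prob,
            self.asm_prob,
            *self.missingness.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidSpecificationError("all probabilities must lie in [0, 1]")
        if min(self.apgar1_sd, self.apgar5_sd, self.ga_weeks_sd, self.bw_g_sd,
               self.ph_sd, self.lactate_sd, self.base_deficit_sd) < 0:
            raise InvalidSpecificationError("standard deviations must be >= 0")


def default_group_profiles() -> tuple[GroupProfile, GroupProfile]:
    """Default (normal-mild, moderate-severe) RR generating profiles."""
    mild = GroupProfile(
        label=0,
        mean_nn_ms=525.0,
        lf_amp_ms=22.0,
        hf_amp_ms=2.0,
        lf_freq_hz=0.1,
        hf_freq_hz=0.7,
        noise_sd_ms=24.0,
        noise_ar1=0.94,
        artifact_rate=0.01,
        between_subject_mean_sd_ms=60.0,
        between_subject_scale_sigma=0.35,
    )
    severe = GroupProfile(
        label=1,
        mean_nn_ms=590.0,
        lf_amp_ms=15.0,
        hf_amp_ms=8.0,
        lf_freq_hz=0.1,
        hf_freq_hz=0.7,
        noise_sd_ms=1.7,
        noise_ar1=0.0,
        artifact_rate=0.01,
        between_subject_mean_sd_ms=70.0,
        between_subject_scale_sigma=0.35,
    )
    return mild, severe


def default_clinical_profiles() -> tuple[ClinicalProfile, ClinicalProfile]:
    """Default clinical generating distributions (normal-mild, moderate-severe)."""
    mild = ClinicalProfile()
    severe = ClinicalProfile(
        apgar1_mean=1.2,
        apgar1_sd=1.5,
        apgar5_mean=2.7,
        apgar5_sd=2.0,
        ventilation_prob=0.892,
        emergency_delivery_prob=0.530,
        foetal_distress_prob=0.684,
        male_prob=0.652,
        intrapartum_prob=0.864,
        cooled_prob=0.970,
        asm_prob=0.288,
        ga_weeks_mean=40.0,
        ga_weeks_sd=1.2,
        bw_g_mean=3434.0,
        bw_g_sd=689.0,
        ph_mean=6.95,
        ph_sd=0.20,
        lactate_mean=13.0,
        lactate_sd=5.2,
        base_deficit_mean=17.0,
        base_deficit_sd=6.4,
    )
    return mild, severe


@dataclass
class SyntheticCohortSpec:
    """Full recipe for a paired RR + clinical cohort."""

    n_per_group: int = 50
    group_profiles: tuple[GroupProfile, GroupProfile] = field(
        default_factory=default_group_profiles
    )
    clinical_profiles: tuple[ClinicalProfile, ClinicalProfile] = field(
        default_factory=default_clinical_profiles
    )
    epoch_duration_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidSpecificationError("n_per_group must be >= 1")
        if self.epoch_duration_s < 600:
            raise InvalidSpecificationError("epoch_duration_s must be >= 600")


def generate_rr_series(
    profile: GroupProfile,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> RRSeries:
    """Simulate one epoch of interbeat intervals from a group profile.

    Beats are generated sequentially (each interval is evaluated at the
    current beat time) until the cumulative time covers ``duration_s``;
    artifact injection then halves (ectopic) or doubles (missed beat)
    randomly chosen intervals and records them in the artifact mask.
    """
    if duration_s <= 0:
        raise InvalidSpecificationError("duration_s must be positive")
    p = profile._rescaled()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi1, phi2 = rng.uniform(0.0, 2.0 * math.pi, size=2)

    # leave head-room so artifact halving cannot shrink the span below target
    target = duration_s * (1.0 + p.artifact_rate) + 5.0
    n_max = int(target * 1000.0 / max(p.mean_nn_ms - 4 * max(p.theoretical_sd_ms(), 1.0), CLIP_LO_MS)) + 16
    innov_sd = p.noise_sd_ms * math.sqrt(max(1.0 - p.noise_ar1**2, 0.0))
    innov = rng.normal(0.0, innov_sd, size=n_max) if innov_sd > 0 else np.zeros(n_max)
    z = rng.normal(0.0, p.noise_sd_ms) if p.noise_sd_ms > 0 else 0.0

    intervals: list[float] = []
    t = 0.0
    w_lf = 2.0 * math.pi * p.lf_freq_hz
    w_hf = 2.0 * math.pi * p.hf_freq_hz
    for i in range(n_max):
        x = (
            p.mean_nn_ms
            + p.lf_amp_ms * math.sin(w_lf * t + phi1)
            + p.hf_amp_ms * math.sin(w_hf * t + phi2)
            + z
        )
        x = min(max(x, CLIP_LO_MS), CLIP_HI_MS)
        intervals.append(x)
        t += x / 1000.0
        if t >= target:
            break
        z = p.noise_ar1 * z + innov[i]

    iv = np.asarray(intervals)
    mask = np.zeros(iv.size, dtype=bool)
    if p.artifact_rate > 0:
        hit = rng.random(iv.size) < p.artifact_rate
        kind = rng.random(iv.size) < 0.5  # True: ectopic (halve), False: missed (double)
        iv = np.where(hit & kind, iv / 2.0, iv)
        iv = np.where(hit & ~kind, np.minimum(iv * 2.0, CLIP_HI_MS), iv)
        mask = hit

    times = np.cumsum(iv) / 1000.0
    # trim just past the requested span
    stop = int(np.searchsorted(times, duration_s)) + 1
    return RRSeries(times[:stop], iv[:stop], mask[:stop], 0.0)


def _apgar(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    return np.clip(np.round(rng.normal(mean, sd, n)), 0, 10)


def generate_clinical(
    profiles: tuple[ClinicalProfile, ClinicalProfile],
    n_per_group: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample one clinical covariate row per subject for both groups.

    The outcome column ``moderate_severe`` is the group label; missing
    entries are inserted per-covariate at the profile's MCAR rates.
    """
    if n_per_group < 1:
        raise InvalidSpecificationError("n_per_group must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for g, prof in enumerate(profiles):
        n = n_per_group
        df = pd.DataFrame(
            {
                "moderate_severe": g,
                "ga_weeks": rng.normal(prof.ga_weeks_mean, prof.ga_weeks_sd, n),
                "emergency_delivery": (rng.random(n) < prof.emergency_delivery_prob).astype(float),
                "male": (rng.random(n) < prof.male_prob).astype(float),
                "bw_g": rng.normal(prof.bw_g_mean, prof.bw_g_sd, n),
                "apgar1": _apgar(rng, prof.apgar1_mean, prof.apgar1_sd, n),
                "apgar5": _apgar(rng, prof.apgar5_mean, prof.apgar5_sd, n),
                "foetal_distress": (rng.random(n) < prof.foetal_distress_prob).astype(float),
                "intrapartum_complications": (rng.random(n) < prof.intrapartum_prob).astype(float),
                "ventilation_10min": (rng.random(n) < prof.ventilation_prob).astype(float),
                "cooled": (rng.random(n) < prof.cooled_prob).astype(float),
                "any_asm": (rng.random(n) < prof.asm_prob).astype(float),
                "ph": rng.normal(prof.ph_mean, prof.ph_sd, n),
                "lactate": rng.normal(prof.lactate_mean, prof.lactate_sd, n),
                "base_deficit": rng.normal(prof.base_deficit_mean, prof.base_deficit_sd, n),
            }
        )
        for col, p_miss in prof.missingness.items():
            if p_miss > 0 and col in df.columns:
                df.loc[rng.random(n) < p_miss, col] = np.nan
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.index = [f"s{i:04d}" for i in range(len(out))]
    out.index.name = "subject_id"
    return out


@dataclass
class SyntheticCohort:
    """Paired RR epochs and clinical table sharing subject identifiers."""

    rr: dict[str, RRSeries]
    clinical: pd.DataFrame
    spec: SyntheticCohortSpec


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Deterministically generate the full cohort from a spec and seed."""
    ss = np.random.SeedSequence(spec.seed)
    clin_seed, rr_seed = ss.spawn(2)
    clinical = generate_clinical(
        spec.clinical_profiles, spec.n_per_group, np.random.default_rng(clin_seed)
    )
    rr_streams = rr_seed.spawn(len(clinical))
    rr = {}
    for (sid, row), child in zip(clinical.iterrows(), rr_streams):
        profile = spec.group_profiles[int(row["moderate_severe"])]
        rng = np.random.default_rng(child)
        subject = _subject_profile(profile, rng)
        rr[sid] = generate_rr_series(subject, spec.epoch_duration_s, rng)
    return SyntheticCohort(rr=rr, clinical=clinical, spec=spec)


def _subject_profile(profile: GroupProfile, rng: np.random.Generator) -> GroupProfile:
    """Draw one subject's profile around the group profile."""
    mean = profile.mean_nn_ms
    if profile.between_subject_mean_sd_ms > 0:
        mean = float(
            np.clip(
                rng.normal(mean, profile.between_subject_mean_sd_ms),
                CLIP_LO_MS + 100.0,
                CLIP_HI_MS - 800.0,
            )
        )
    s_lf = s_hf = s_noise = 1.0
    if profile.between_subject_scale_sigma > 0:
        # independent multipliers so spectral balance also varies between
        # subjects; the noise term uses half the sigma because the entropy
        # features respond very steeply to the noise-to-tolerance ratio
        sig = profile.between_subject_scale_sigma
        s_lf, s_hf = rng.lognormal(0.0, sig, 2)
        s_noise = rng.lognormal(0.0, sig / 2.0)
    return replace(
        profile,
        mean_nn_ms=mean,
        lf_amp_ms=profile.lf_amp_ms * s_lf,
        hf_amp_ms=profile.hf_amp_ms * s_hf,
        noise_sd_ms=profile.noise_sd_ms * s_noise,
        between_subject_mean_sd_ms=0.0,
        between_subject_scale_sigma=0.0,
    )
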
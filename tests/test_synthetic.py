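"""Synthetic cohort generator: determinism, contrasts, null calibration."""

import numpy as np
import pandas as pd
import pytest

from neohrv.exceptions import InvalidSpecificationError
from neohrv.features import extract_cohort
from neohrv.spectral import band_powers
from neohrv.synthetic import (
    ClinicalProfile,
    GroupProfile,
    SyntheticCohortSpec,
    default_clinical_profiles,
    default_group_profiles,
    generate_clinical,
    generate_cohort,
    generate_rr_series,
)


class TestGenerateRR:
    def test_noiseless_constant_profile(self):
        p = GroupProfile(label=0, mean_nn_ms=500.0)
        rr = generate_rr_series(p, 600.0, seed=0)
        assert rr.n_beats == 1200
        assert np.all(rr.intervals_ms == 500.0)
        assert rr.duration_s >= 600.0
        assert not rr.artifact_mask.any()

    def test_invalid_profiles_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            GroupProfile(label=0, mean_nn_ms=-1.0)
        with pytest.raises(InvalidSpecificationError):
            GroupProfile(label=0, mean_nn_ms=500.0, artifact_rate=0.6)
        with pytest.raises(InvalidSpecificationError):
            GroupProfile(label=0, mean_nn_ms=500.0, lf_freq_hz=1.0, hf_freq_hz=0.5)
        with pytest.raises(InvalidSpecificationError):
            generate_rr_series(GroupProfile(label=0, mean_nn_ms=500.0), -5.0)

    def test_hf_only_profile_dominated_by_hf_power(self):
        p = GroupProfile(label=0, mean_nn_ms=500.0, hf_amp_ms=10.0, hf_freq_hz=0.5)
        rr = generate_rr_series(p, 600.0, seed=1)
        powers = band_powers(rr.beat_times_s, rr.intervals_ms)
        assert powers["hf_power_ms2"] > 10 * powers["lf_power_ms2"]

    def test_group_contrast_mean_nn_and_lf_hf(self, mild_profile, severe_profile):
        """Across epochs the severe profile shows higher mean NN and lower
        LF/HF balance than the mild profile."""
        stats = {}
        for name, p in [("mild", mild_profile), ("severe", severe_profile)]:
            mean_nn, lfhf = [], []
            for seed in range(30):
                rr = generate_rr_series(p, 600.0, seed=seed)
                keep = ~rr.artifact_mask
                mean_nn.append(rr.intervals_ms[keep].mean())
                bp = band_powers(rr.beat_times_s[keep], rr.intervals_ms[keep])
                lfhf.append(bp["lf_hf_ratio"])
            stats[name] = (np.mean(mean_nn), np.median(lfhf))
        assert stats["severe"][0] > stats["mild"][0]
        assert stats["severe"][1] < stats["mild"][1]

    def test_ground_truth_mean_recovery(self):
        p = GroupProfile(label=0, mean_nn_ms=512.0)
        rr = generate_rr_series(p, 1200.0, seed=2)
        feats = extract_cohort({"s": rr})
        assert feats.loc["s", "mean_nn_ms"] == pytest.approx(512.0, abs=0.5)

    def test_hf_power_monotone_in_amplitude(self):
        """Extracted HF power strictly increases along an hf_amp grid."""
        powers = []
        for amp in (2.0, 4.0, 6.0, 8.0, 10.0):
            p = GroupProfile(label=0, mean_nn_ms=500.0, hf_amp_ms=amp, hf_freq_hz=0.5)
            rr = generate_rr_series(p, 600.0, seed=3)
            bp = band_powers(rr.beat_times_s, rr.intervals_ms)
            powers.append(bp["hf_power_ms2"])
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_sd_target_rescales_variability(self):
        p = GroupProfile(
            label=0, mean_nn_ms=500.0, lf_amp_ms=10.0, hf_amp_ms=5.0,
            noise_sd_ms=8.0, noise_ar1=0.3, sd_nn_ms=30.0,
        )
        rr = generate_rr_series(p, 1200.0, seed=6)
        assert np.std(rr.intervals_ms, ddof=1) == pytest.approx(30.0, rel=0.15)

    def test_artifact_injection_flagged_in_ground_truth(self, severe_profile):
        from dataclasses import replace

        p = replace(severe_profile, artifact_rate=0.05)
        rr = generate_rr_series(p, 600.0, seed=4)
        frac = rr.artifact_mask.mean()
        assert 0.01 < frac < 0.12


class TestGenerateClinical:
    def test_complete_rows_without_missingness(self):
        mild, severe = default_clinical_profiles()
        mild.missingness = {}
        severe.missingness = {}
        df = generate_clinical((mild, severe), 1, seed=0)
        assert len(df) == 2
        assert df.notna().all().all()

    def test_full_missingness_empties_column(self):
        mild, severe = default_clinical_profiles()
        mild.missingness = {"lactate": 1.0}
        severe.missingness = {"lactate": 1.0}
        df = generate_clinical((mild, severe), 5, seed=0)
        assert df["lactate"].isna().all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            ClinicalProfile(ventilation_prob=1.5)

    def test_group_contrasts_in_ventilation_and_apgar(self):
        df = generate_clinical(default_clinical_profiles(), 500, seed=1)
        g = df.groupby("moderate_severe")
        vent = g["ventilation_10min"].mean()
        assert vent[1] > vent[0]
        apgar = g["apgar5"].median()
        assert apgar[1] < apgar[0]


class TestGenerateCohort:
    def test_same_seed_identical_cohort(self):
        spec = SyntheticCohortSpec(n_per_group=3, epoch_duration_s=600.0, seed=9)
        c1 = generate_cohort(spec)
        c2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(c1.clinical, c2.clinical)
        for sid in c1.rr:
            np.testing.assert_array_equal(c1.rr[sid].intervals_ms, c2.rr[sid].intervals_ms)
            np.testing.assert_array_equal(c1.rr[sid].artifact_mask, c2.rr[sid].artifact_mask)

    def test_subjects_paired_across_outputs(self, small_cohort):
        assert set(small_cohort.rr) == set(small_cohort.clinical.index)

    def test_epoch_duration_validated(self):
        with pytest.raises(InvalidSpecificationError):
            SyntheticCohortSpec(n_per_group=2, epoch_duration_s=100.0)
        with pytest.raises(InvalidSpecificationError):
            SyntheticCohortSpec(n_per_group=0)


def test_null_profiles_give_nominal_type_one_error():
    """With identical RR profiles in both groups, each HRV feature's
    univariable p < 0.05 rate over repeated cohorts stays within
    (Bonferroni-adjusted) binomial bounds of the nominal 5% level."""
    from neohrv.models import StudyConfig, standardize, univariable_screen
    from neohrv.models import HRV_CANDIDATES

    mild, _ = default_group_profiles()
    from dataclasses import replace

    same = replace(mild, label=1)
    n_reps = 120
    n_per_group = 20
    hits = {f: 0 for f in HRV_CANDIDATES}
    base = np.random.SeedSequence(777)
    for rep_seed in base.spawn(n_reps):
        seed = int(rep_seed.generate_state(1)[0] % (2**31))
        spec = SyntheticCohortSpec(
            n_per_group=n_per_group,
            group_profiles=(mild, same),
            epoch_duration_s=600.0,
            seed=seed,
        )
        cohort = generate_cohort(spec)
        feats = extract_cohort(cohort.rr)
        data = feats.join(cohort.clinical["moderate_severe"])
        data, _rec = standardize(data, HRV_CANDIDATES)
        screen = univariable_screen(data, "moderate_severe", HRV_CANDIDATES)
        for f in HRV_CANDIDATES:
            if screen.table.loc[f, "p"] < 0.05:
                hits[f] += 1
    # two-sided binomial bounds at joint level 5% across 11 features
    from scipy.stats import binom

    lo, hi = binom.ppf([0.0025 / 11, 1 - 0.0025 / 11], n_reps, 0.05)
    for f, h in hits.items():
        assert lo <= h <= hi, f"{f}: {h} rejections outside [{lo}, {hi}]"
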
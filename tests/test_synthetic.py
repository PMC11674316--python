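"""Synthetic generator: determinism, signal recovery, scoped randomness."""

import dataclasses

import numpy as np
import pytest

from brainfuse.synthetic import (AgeSignalParams, generate_cohort,
                                 generate_subject, _atrophy_mask)

CLEAN = dataclasses.replace(AgeSignalParams(), noise_sd=0.0,
                            between_subject_sd=0.0, atrophy_focus_count=0)


def test_subject_determinism():
    a = generate_subject(40.0, AgeSignalParams(), (8, 8, 8), (4, 16), rng_seed=5)
    b = generate_subject(40.0, AgeSignalParams(), (8, 8, 8), (4, 16), rng_seed=5)
    np.testing.assert_array_equal(a.smri_map.data, b.smri_map.data)
    np.testing.assert_array_equal(a.dti_map.data, b.dti_map.data)
    np.testing.assert_array_equal(a.psd.values, b.psd.values)
    c = generate_subject(40.0, AgeSignalParams(), (8, 8, 8), (4, 16), rng_seed=6)
    assert not np.array_equal(a.smri_map.data, c.smri_map.data)


def test_noise_free_linear_trend_exact():
    """With all stochastic terms off, the voxel mean is exactly the line."""
    p = CLEAN
    for age in (25.0, 53.0, 80.0):
        subj = generate_subject(age, p, (8, 8, 8), (4, 16))
        expect_smri = p.baseline_intensity + p.slope_per_year * (age - p.reference_age)
        expect_dti = (p.dti_baseline_intensity
                      + p.dti_slope_per_year * (age - p.reference_age))
        np.testing.assert_allclose(subj.smri_map.data.mean(), expect_smri,
                                   atol=1e-6)
        np.testing.assert_allclose(subj.dti_map.data.mean(), expect_dti,
                                   atol=1e-6)


def test_slope_recovered_from_noise_free_cohort():
    p = CLEAN
    ages = np.linspace(20, 80, 13)
    means = [generate_subject(a, p, (8, 8, 8), (4, 16)).smri_map.data.mean()
             for a in ages]
    slope = np.polyfit(ages, means, 1)[0]
    np.testing.assert_allclose(slope, p.slope_per_year, rtol=1e-4)


def test_atrophy_foci_double_slope():
    p = dataclasses.replace(CLEAN, atrophy_focus_count=3)
    mask = _atrophy_mask((16, 16, 16), 3)
    assert mask.any() and not mask.all()
    young = generate_subject(33.0, p, (16, 16, 16), (4, 16)).smri_map.data
    old = generate_subject(73.0, p, (16, 16, 16), (4, 16)).smri_map.data
    decade_out = (old - young)[~mask].mean() / 40.0
    decade_in = (old - young)[mask].mean() / 40.0
    np.testing.assert_allclose(decade_out, p.slope_per_year, atol=1e-7)
    np.testing.assert_allclose(decade_in, 2 * p.slope_per_year, atol=1e-7)
    # focal geometry is a cohort-level constant
    np.testing.assert_array_equal(mask, _atrophy_mask((16, 16, 16), 3))


def test_alpha_peak_tracks_age():
    p = dataclasses.replace(CLEAN, noise_sd=0.0)
    freqs = None
    peaks = {}
    for age in (23.0, 83.0):
        subj = generate_subject(age, p, (8, 8, 8), (4, 64))
        spectrum = subj.psd.values.mean(axis=0)
        freqs = subj.psd.freqs_hz
        # ignore the 1/f low end; the alpha peak dominates above 4 Hz
        hi = freqs >= 4.0
        peaks[age] = freqs[hi][np.argmax(spectrum[hi])]
        expected = p.alpha_center_hz + p.psd_peak_shift_per_year * (age - p.reference_age)
        assert abs(peaks[age] - expected) <= 1.0   # 1 Hz bin resolution
    assert peaks[23.0] > peaks[83.0]


def test_age_correlates_with_modalities_under_noise():
    subjects, manifest = generate_cohort(80, (20.0, 80.0), AgeSignalParams(),
                                         (8, 8, 8), (4, 16), seed=3)
    ages = manifest["age"].to_numpy()
    smri_means = np.array([s.smri_map.data.mean() for s in subjects])
    dti_means = np.array([s.dti_map.data.mean() for s in subjects])
    assert np.corrcoef(ages, smri_means)[0, 1] < -0.9
    assert np.corrcoef(ages, dti_means)[0, 1] < -0.9


def test_zero_signal_gives_no_correlation():
    p = dataclasses.replace(AgeSignalParams(), slope_per_year=0.0,
                            dti_slope_per_year=0.0, psd_peak_shift_per_year=0.0,
                            atrophy_focus_count=0)
    subjects, manifest = generate_cohort(100, (20.0, 80.0), p,
                                         (8, 8, 8), (4, 16), seed=4)
    ages = manifest["age"].to_numpy()
    means = np.array([s.smri_map.data.mean() for s in subjects])
    assert abs(np.corrcoef(ages, means)[0, 1]) < 3.0 / np.sqrt(len(ages))


def test_cohort_structure():
    subjects, manifest = generate_cohort(20, (20.0, 80.0), seed=0,
                                         grid_shape=(8, 8, 8), psd_shape=(4, 16))
    assert len(subjects) == 20 and len(manifest) == 20
    assert manifest["subject_id"].is_unique
    assert manifest["age"].between(20, 80).all()
    counts = manifest["split"].value_counts()
    assert (counts["train"], counts["val"], counts["test"]) == (16, 2, 2)
    assert subjects[0].psd.values.shape == (4, 16)
    assert subjects[0].smri_map.data.dtype == np.float32
    # cohort generation is deterministic
    subjects2, manifest2 = generate_cohort(20, (20.0, 80.0), seed=0,
                                           grid_shape=(8, 8, 8),
                                           psd_shape=(4, 16))
    np.testing.assert_array_equal(subjects[3].psd.values,
                                  subjects2[3].psd.values)
    assert manifest.equals(manifest2)


def test_psd_positive_and_freqs():
    subj = generate_subject(50.0, AgeSignalParams(), (8, 8, 8), (4, 16))
    assert np.all(subj.psd.values > 0)
    np.testing.assert_allclose(subj.psd.freqs_hz, np.arange(1, 17, dtype=float))


def test_parameter_validation():
    with pytest.raises(ValueError, match="age"):
        generate_subject(0.0, AgeSignalParams())
    with pytest.raises(ValueError, match="grid_shape"):
        generate_subject(50.0, AgeSignalParams(), grid_shape=(4, 8, 8))
    with pytest.raises(ValueError, match="psd_shape"):
        generate_subject(50.0, AgeSignalParams(), psd_shape=(1, 16))
    with pytest.raises(ValueError, match="noise_sd"):
        AgeSignalParams(noise_sd=-0.1)
    with pytest.raises(ValueError, match="at least 3"):
        generate_cohort(2)
    with pytest.raises(ValueError, match="age range"):
        generate_cohort(10, (80.0, 20.0))
    with pytest.raises(ValueError, match="reference_age"):
        generate_cohort(10, (60.0, 80.0))   # default reference 53 outside
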
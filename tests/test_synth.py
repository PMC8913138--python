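"""Synthetic cohort generator: published profiles, determinism, invariants,
and convergence of the class-conditional draws to their truncated-normal
targets."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from picurisk.fuzzy import validate_evaluation_frame
from picurisk.glm import ModelSpec, fit_logistic_xy
from picurisk.synth import (
    default_profiles,
    generate_cohort,
    generate_multicenter,
    generate_multicenter_with_truth,
)


@pytest.fixture(scope="module")
def profiles():
    return default_profiles()


def test_default_profile_death_rates(profiles):
    oviedo, riga = profiles
    assert oviedo.n_patients == 308 and oviedo.n_deaths == 15
    assert riga.n_patients == 291 and riga.n_deaths == 9
    assert oviedo.death_rate == pytest.approx(15 / 308)  # ~4.9%


def test_default_profile_eval_count_distributions(profiles):
    oviedo, riga = profiles
    assert np.isclose(sum(oviedo.eval_count_probs), 1.0)
    assert np.isclose(sum(riga.eval_count_probs), 1.0)
    # the Riga mode is 3 evaluations; the published row sums to 293 so the
    # frequency vector is normalised by the row total
    assert int(np.argmax(riga.eval_count_probs)) + 1 == 3
    assert riga.eval_count_probs[2] == pytest.approx(115 / 293)


def test_generate_exact_counts_and_determinism(profiles):
    oviedo, _ = profiles
    c1, t1 = generate_cohort(oviedo, seed=99)
    c2, t2 = generate_cohort(oviedo, seed=99)
    assert len(c1) == 308 and c1.n_deaths == 15
    pd.testing.assert_frame_equal(c1.data, c2.data)
    pd.testing.assert_frame_equal(t1.evaluations, t2.evaluations)
    c3, _ = generate_cohort(oviedo, seed=100)
    assert not c3.data["MID"].equals(c1.data["MID"])


def test_generated_evaluations_satisfy_trapezoid_invariants(profiles):
    oviedo, riga = profiles
    for profile in (oviedo, riga):
        _, truth = generate_cohort(profile, seed=7)
        ev = truth.evaluations
        # strict validation raises on any violated invariant
        validate_evaluation_frame(ev, repair_nesting=False)
        assert (ev["long_lo"] >= 0).all() and (ev["long_hi"] <= 100).all()
        assert (ev["long_lo"] <= ev["short_lo"]).all()
        assert (ev["short_hi"] <= ev["long_hi"]).all()


def test_multicenter_composition():
    cohort = generate_multicenter(seed=3)
    assert len(cohort) == 599 and cohort.n_deaths == 24
    counts = cohort.data["center"].value_counts()
    assert counts["oviedo"] == 308 and counts["riga"] == 291
    assert cohort.data["patient_id"].is_unique


def test_nonsurvivor_mid_matches_truncated_normal_target(profiles):
    """Grand mean of nonsurvivor MID across many seeds sits at the
    truncated-normal mean implied by the published location/scale, and
    within +/-3 of the published raw mean."""
    oviedo, _ = profiles
    loc, scale = oviedo.class_conditional["MID"]["nonsurvivor"]
    a, b = (0 - loc) / scale, (100 - loc) / scale
    target = stats.truncnorm.mean(a, b, loc=loc, scale=scale)
    means = []
    for seed in range(200):
        _, truth = generate_cohort(oviedo, seed=seed)
        lat = truth.latent
        means.append(lat.loc[lat["outcome"] == 1, "latent_MID"].mean())
    grand = np.mean(means)
    # Monte-Carlo SE of the grand mean: sd(per-seed means)/sqrt(200)
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(grand - target) < 4 * se
    assert abs(grand - loc) < 3.0


def test_averaged_mid_converges_to_latent_with_more_evaluations(profiles):
    oviedo, _ = profiles
    one = dataclasses.replace(
        oviedo, eval_count_probs=(1.0,) + (0.0,) * 8, n_patients=2000, n_deaths=100
    )
    nine = dataclasses.replace(
        oviedo, eval_count_probs=(0.0,) * 8 + (1.0,), n_patients=2000, n_deaths=100
    )
    errs = {}
    for name, prof in (("one", one), ("nine", nine)):
        cohort, truth = generate_cohort(prof, seed=21)
        merged = cohort.data.merge(truth.latent, on="patient_id")
        errs[name] = np.std(merged["MID"] - merged["latent_MID"], ddof=1)
    # jitter sd 5: residual sd ~5 with one evaluation, ~5/3 with nine
    assert errs["nine"] < errs["one"] / 2
    assert errs["nine"] < 2.5


def test_class_conditional_moments_converge_at_large_n(profiles):
    oviedo, _ = profiles
    big = dataclasses.replace(oviedo, n_patients=50_000, n_deaths=25_000)
    _, truth = generate_cohort(big, seed=17)
    lat = truth.latent
    for var, col in (("MID", "latent_MID"), ("PIM2", "PIM2"), ("TISS28", "TISS28")):
        lo, hi = (0, 100) if var != "TISS28" else (0, np.inf)
        for cls, code in (("survivor", 0), ("nonsurvivor", 1)):
            loc, scale = oviedo.class_conditional[var][cls]
            a, b = (lo - loc) / scale, (hi - loc) / scale if np.isfinite(hi) else np.inf
            ref_mean = stats.truncnorm.mean(a, b, loc=loc, scale=scale)
            ref_std = stats.truncnorm.std(a, b, loc=loc, scale=scale)
            sample = lat.loc[lat["outcome"] == code, col]
            assert sample.mean() == pytest.approx(ref_mean, abs=0.03 * scale)
            assert sample.std(ddof=1) == pytest.approx(ref_std, abs=0.03 * scale)


def test_within_class_mid_pim2_correlation_is_positive(profiles):
    oviedo, _ = profiles
    big = dataclasses.replace(oviedo, n_patients=20_000, n_deaths=1_000)
    _, truth = generate_cohort(big, seed=23)
    surv = truth.latent[truth.latent["outcome"] == 0]
    r = np.corrcoef(surv["latent_MID"], surv["PIM2"])[0, 1]
    assert 0.1 < r < 0.5  # copula rho=0.3 on the latent normals


def test_logistic_truth_mode_records_coefficients(profiles):
    oviedo, _ = profiles
    cohort, truth = generate_cohort(oviedo, mode="logistic_truth", seed=31)
    assert truth.coefficients is not None
    assert set(truth.coefficients) >= {"intercept", "MID", "PIM2"}
    assert 0 < cohort.n_deaths < len(cohort)


def test_logistic_truth_fit_recovers_coefficients_roughly(profiles):
    """Single large draw: estimates land within 3 SEs of the truth."""
    oviedo, _ = profiles
    big = dataclasses.replace(oviedo, n_patients=20_000, n_deaths=1_000)
    _, truth = generate_cohort(big, mode="logistic_truth", seed=37)
    lat = truth.latent
    X = np.column_stack([np.ones(len(lat)), lat["latent_MID"], lat["PIM2"]])
    fit = fit_logistic_xy(lat["outcome"].to_numpy(float), X)
    for j, name in enumerate(["intercept", "MID", "PIM2"]):
        assert abs(fit.params[j] - truth.coefficients[name]) < 3 * fit.bse[j]


def test_invalid_profile_and_mode_rejected(profiles):
    oviedo, _ = profiles
    with pytest.raises(ValueError, match="mode"):
        generate_cohort(oviedo, mode="bootstrap", seed=1)
    with pytest.raises(ValueError, match="sum to 1"):
        dataclasses.replace(oviedo, eval_count_probs=(0.5, 0.4))
    with pytest.raises(ValueError, match="n_deaths"):
        dataclasses.replace(oviedo, n_deaths=400)


def test_multicenter_with_truth_aligns_with_cohort():
    cohort, truths = generate_multicenter_with_truth(seed=5)
    ids = pd.concat([t.latent["patient_id"] for t in truths], ignore_index=True)
    assert ids.tolist() == cohort.data["patient_id"].tolist()
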
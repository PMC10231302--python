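"""Synthetic-cohort generator: marginal fidelity, raters, outcomes."""

import numpy as np
import pytest

from mpras import (
    CohortParams,
    DEFAULT_OUTCOME_COEFFS,
    RiskFactor,
    VariableSpec,
    cohens_kappa,
    flip_probability_for_kappa,
    kappa_of_flip,
    preset_model,
    roc,
    score,
    simulate_clinicians,
    simulate_cohort,
    simulate_followup,
    validate_against_outcome,
)

MODEL1 = preset_model("model1")


@pytest.fixture(scope="module")
def big_cohort():
    return simulate_cohort(CohortParams(n=10000, seed=101))


def _values(cohort, attr_record=None, eye_attr=None):
    if attr_record:
        return np.array([getattr(r, attr_record) for r in cohort.records])
    vals = []
    for r in cohort.records:
        vals.append(getattr(r.right_eye, eye_attr))
        vals.append(getattr(r.left_eye, eye_attr))
    return np.array(vals)


MARGINALS = [
    ("age_at_presentation", "age_at_presentation_yr", None),
    ("age_of_onset", "age_of_onset_yr", None),
    ("nearwork", "nearwork_h_per_day", None),
    ("outdoors", "outdoors_h_per_day", None),
    ("ser", None, "ser_d"),
    ("ser_change", None, "ser_change_d_per_yr"),
    ("accom_error", None, "accom_error_d"),
    ("near_phoria", None, "near_phoria_pd"),
    ("rpr", None, "rpr_nasal_d"),
]


@pytest.mark.parametrize("param_name, rec_attr, eye_attr", MARGINALS)
def test_marginal_fidelity_at_n10000(big_cohort, param_name, rec_attr, eye_attr):
    """Sample mean/SD track the analytic truncated-normal targets."""
    spec: VariableSpec = getattr(big_cohort.params, param_name)
    target_mean, target_sd = spec.target_moments()
    x = _values(big_cohort, rec_attr, eye_attr)
    se = target_sd / np.sqrt(big_cohort.n)
    tol_mean = max(5 * se, 0.05 * target_sd)
    assert abs(x.mean() - target_mean) < tol_mean, param_name
    assert abs(x.std(ddof=1) - target_sd) < 0.05 * target_sd, param_name


def test_parent_category_frequencies(big_cohort):
    counts = np.bincount(
        [r.myopic_parents for r in big_cohort.records], minlength=3
    )
    freqs = counts / big_cohort.n
    for got, want in zip(freqs, (61 / 149, 59 / 149, 29 / 149)):
        assert abs(got - want) < 0.02


def test_structural_invariants(big_cohort):
    for r in big_cohort.records[:500]:
        assert r.age_of_onset_yr <= r.age_at_presentation_yr
        assert r.right_eye.ser_d <= -0.50 and r.left_eye.ser_d <= -0.50


def test_inter_eye_correlation_close_to_target(big_cohort):
    ser_r = np.array([r.right_eye.ser_d for r in big_cohort.records])
    ser_l = np.array([r.left_eye.ser_d for r in big_cohort.records])
    rho = np.corrcoef(ser_r, ser_l)[0, 1]
    assert abs(rho - big_cohort.params.rho_eye) < 0.03


def test_same_seed_reproduces_bit_for_bit():
    a = simulate_cohort(CohortParams(n=80, seed=5))
    b = simulate_cohort(CohortParams(n=80, seed=5))
    assert a.records == b.records
    assert np.array_equal(a.gold_outcome, b.gold_outcome)
    assert np.array_equal(a.clinician_labels, b.clinician_labels)
    c = simulate_cohort(CohortParams(n=80, seed=6))
    assert c.records != a.records


def test_infeasible_truncation_rejected():
    with pytest.raises(ValueError, match="6 SD"):
        VariableSpec(mean=0.0, sd=1.0, lower=10.0, upper=20.0)


class TestClinicians:
    def test_perfect_kappa_gives_identical_raters(self):
        rng = np.random.default_rng(0)
        labels = simulate_clinicians(
            rng.random(500), n_raters=4, target_kappa=1.0, seed=1
        )
        assert np.array_equal(labels, np.tile(labels[0], (4, 1)))

    def test_flip_half_with_balanced_labels_kills_agreement(self):
        # closed form: eps = 0.5 makes the copy independent of rater 1
        assert kappa_of_flip(0.5, 0.5) == pytest.approx(0.0)
        assert kappa_of_flip(0.0, 0.3) == pytest.approx(1.0)

    def test_calibration_solver_inverts_closed_form(self):
        for kappa in (0.2, 0.5, 0.9):
            for prev in (0.3, 114 / 149):
                eps = flip_probability_for_kappa(kappa, prev)
                assert kappa_of_flip(eps, prev) == pytest.approx(kappa, abs=1e-9)

    def test_empirical_kappa_hits_target_band(self):
        """Target 0.90 at n=5000 lands in [0.86, 0.94] for every pair
        against rater 1 — the agreement level of the emulated clinic."""
        rng = np.random.default_rng(12)
        latent = rng.random(5000)
        labels = simulate_clinicians(
            latent, n_raters=5, target_kappa=0.90, seed=7
        )
        for k in range(1, 5):
            emp = cohens_kappa(labels[0], labels[k])
            assert 0.86 <= emp <= 0.94

    def test_invalid_target_kappa(self):
        with pytest.raises(ValueError):
            flip_probability_for_kappa(0.0, 0.5)
        with pytest.raises(ValueError):
            flip_probability_for_kappa(1.5, 0.5)


class TestFollowup:
    def test_zero_noise_equals_gold_outcome(self):
        cohort = simulate_cohort(CohortParams(n=60, seed=2))
        fu = simulate_followup(cohort, noise_sd=0.0)
        assert np.array_equal(fu, cohort.gold_outcome)
        assert cohort.records[0].followup_ser_change_d_per_yr == pytest.approx(
            cohort.gold_outcome[0]
        )

    def test_followup_reproducible(self):
        cohort = simulate_cohort(CohortParams(n=60, seed=2))
        assert np.array_equal(
            simulate_followup(cohort, seed=9), simulate_followup(cohort, seed=9)
        )

    def test_progression_prevalence_matches_configuration(self, big_cohort):
        prev = big_cohort.gold_progression.mean()
        assert abs(prev - big_cohort.params.outcome_prevalence) < 0.03
        # and the observed (noisy) follow-up stays close too
        fu = simulate_followup(big_cohort, seed=3)
        assert abs(np.mean(fu <= -0.50) - big_cohort.params.outcome_prevalence) < 0.03


def _cohort_auc(effect_scale, n=2000, seed=33):
    params = CohortParams(n=n, seed=seed, effect_scale=effect_scale)
    cohort = simulate_cohort(params)
    totals = [
        score(r, MODEL1, eye_choice="random", seed=seed).total_score
        for r in cohort.records
    ]
    return roc(totals, cohort.gold_progression).auc


def test_auc_increases_with_effect_size():
    """Parameter recovery: a stronger configured factor-outcome coupling
    must yield better score discrimination of the gold outcome."""
    aucs = [_cohort_auc(e) for e in (0.5, 1.0, 2.0)]
    assert aucs[0] < aucs[1] < aucs[2]
    assert aucs[0] > 0.55  # even weak coupling beats chance


def test_label_coherence_saturates_at_extreme_effect_and_zero_noise():
    """With a near-deterministic outcome and noise-free follow-up the
    score's calibrated decisions track the gold outcome as closely as a
    three-band categorical score can: agreement rises with the effect
    size and settles well above chance.  The ceiling below 1.0 is
    structural — collapsing each continuous factor to 1/4/9 points
    cannot reproduce a continuous-hyperplane outcome exactly."""

    def agreement(effect):
        cohort = simulate_cohort(
            CohortParams(n=1000, seed=44, effect_scale=effect)
        )
        simulate_followup(cohort, noise_sd=0.0)
        totals = np.array(
            [score(r, MODEL1, seed=44).total_score for r in cohort.records]
        )
        r = roc(totals, cohort.gold_progression)
        conf = validate_against_outcome(
            totals > r.best_cutoff, cohort.gold_outcome
        )
        return conf.accuracy

    weak, strong = agreement(0.3), agreement(30.0)
    assert strong > weak
    assert strong >= 0.70


def test_validation_against_followup_tracks_generator(small_cohort):
    """MPRAS decisions vs simulated 1-year outcome give a sensible
    sensitivity/specificity pattern on the default cohort."""
    fu = simulate_followup(small_cohort, seed=1)
    totals = np.array(
        [score(r, MODEL1, seed=9).total_score for r in small_cohort.records]
    )
    cut = roc(totals, fu <= -0.50).best_cutoff
    conf = validate_against_outcome(totals > cut, fu)
    assert conf.sensitivity > 0.5 and conf.specificity > 0.5


def test_outcome_coefficients_can_be_restricted():
    coeffs = {f: 0.0 for f in DEFAULT_OUTCOME_COEFFS}
    coeffs[RiskFactor.CHANGE_SER_OR_AL] = 2.0
    cohort = simulate_cohort(
        CohortParams(n=500, seed=8, outcome_coeffs=coeffs)
    )
    chg = np.array(
        [
            (r.right_eye.ser_change_d_per_yr + r.left_eye.ser_change_d_per_yr)
            / 2
            for r in cohort.records
        ]
    )
    # propensity must be a decreasing function of the SER change alone
    order = np.argsort(chg)
    assert np.all(np.diff(cohort.latent_risk[order]) <= 1e-12)
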
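import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dirigwas import transition
from dirigwas.states import ExamRecord, build_state_sequences
from dirigwas.transition import (
    UnseenTimeLevelError,
    build_tpm,
    build_transition_rows,
    extract_response,
    fit_multinomial,
    fit_transition_models,
    fits_from_json,
    fits_to_json,
    lrt_time_effect,
)


def _sequences(state_lists):
    recs = []
    bp = {1: (110, 70), 2: (130, 85), 3: (150, 95)}
    for i, ss in enumerate(state_lists):
        for t, s in enumerate(ss, start=1):
            sbp, dbp = bp[s]
            recs.append(ExamRecord(f"s{i}", f"f{i}", t, sbp, dbp, False, i % 2, 0,
                                   40.0 + t))
    return build_state_sequences(recs)


def _intercept_rows(counts_by_prev):
    """Rows with given next-state counts per previous state."""
    rows = []
    for l, counts in counts_by_prev.items():
        for j, c in counts.items():
            for _ in range(c):
                rows.append({"subject_id": "x", "prev_state": l, "next_state": j,
                             "sex": 0, "smoke": 0, "age": 50.0, "time": 1})
    return pd.DataFrame(rows)


def test_rows_from_consecutive_pairs():
    seqs = _sequences([[1, 2, 2]])
    rows = build_transition_rows(seqs)
    assert list(zip(rows.prev_state, rows.next_state)) == [(1, 2), (2, 2)]
    # covariates at the earlier exam
    assert list(rows.time) == [1, 2]
    assert list(rows.age) == [41.0, 42.0]


def test_row_count_and_empty_input():
    seqs = _sequences([[1, 1, 2, 3]] * 10)
    assert len(build_transition_rows(seqs)) == 30
    assert len(build_transition_rows([])) == 0


def test_intercept_only_fit_matches_empirical_frequencies():
    rows = _intercept_rows({1: {1: 60, 2: 30, 3: 10}})
    fit = fit_multinomial(rows, 1, "intercept")
    assert fit.converged
    np.testing.assert_allclose(fit.predict_row(0, 0, 50, 1), [0.6, 0.3, 0.1],
                               atol=1e-8)


def test_degenerate_all_stay_hits_cap():
    rows = _intercept_rows({2: {2: 50}})
    fit = fit_multinomial(rows, 2, "intercept")
    probs = fit.predict_row(0, 0, 50, 1)
    assert probs[1] > 0.999
    assert np.all(probs > 0)  # cap keeps the empty categories positive
    assert np.all(np.abs(fit.coef) <= transition.COEF_CAP + 1e-12)


def test_gamma_recovery_within_3_se(rng):
    # simulate transitions out of state 1 from known coefficients
    n = 5000
    gamma = {2: np.array([-0.5, 0.4, 0.3, 0.02]),
             3: np.array([-1.5, 0.2, 0.5, 0.03])}
    sex = rng.integers(0, 2, n)
    smoke = rng.integers(0, 2, n)
    age = rng.uniform(30, 70, n)
    Z = np.column_stack([np.ones(n), sex, smoke, age])
    eta = np.column_stack([np.zeros(n), Z @ gamma[2], Z @ gamma[3]])
    P = np.exp(eta - eta.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    nxt = np.array([rng.choice([1, 2, 3], p=p) for p in P])
    rows = pd.DataFrame({"subject_id": "x", "prev_state": 1, "next_state": nxt,
                         "sex": sex, "smoke": smoke, "age": age, "time": 1})
    fit = fit_multinomial(rows, 1, "base")
    assert fit.converged
    se = fit.coef_se()
    truth = np.column_stack([gamma[2], gamma[3]])
    assert np.all(np.abs(fit.coef - truth) < 3 * se)


def test_loglik_is_local_maximum(rng):
    rows = _intercept_rows({1: {1: 40, 2: 25, 3: 12}})
    fit = fit_multinomial(rows, 1, "intercept")
    sub = rows[rows.prev_state == 1]
    from dirigwas.transition import _design_matrix, _multinom_negloglik_grad
    Z, _ = _design_matrix(sub, "intercept", [1])
    Yind = np.stack([(sub.next_state == c).to_numpy(float) for c in (1, 2, 3)], axis=1)
    nll_hat, _ = _multinom_negloglik_grad(fit.coef.ravel(), Z, Yind)
    for _ in range(50):
        pert = fit.coef.ravel() + rng.normal(scale=1e-3, size=fit.coef.size)
        nll_p, _ = _multinom_negloglik_grad(pert, Z, Yind)
        assert nll_p >= nll_hat - 1e-12


def test_lrt_identical_and_chisquare_tail():
    rows = _intercept_rows({1: {1: 30, 2: 20, 3: 10}})
    fit = fit_multinomial(rows, 1, "intercept")
    stat, df, p = lrt_time_effect(fit, fit)
    assert stat == 0.0 and p == 1.0
    assert stats.chi2.sf(5.99, 2) == pytest.approx(0.0500, abs=5e-4)


def test_lrt_rejects_non_nested():
    rows_a = _intercept_rows({1: {1: 30, 2: 20, 3: 10}})
    rows_b = _intercept_rows({1: {1: 31, 2: 20, 3: 10}})
    fa = fit_multinomial(rows_a, 1, "intercept")
    fb = fit_multinomial(rows_b, 1, "base")
    with pytest.raises(ValueError):
        lrt_time_effect(fb, fa)  # different row counts


def test_lrt_null_calibration(rng):
    # no true time effect: the LRT for the time term rejects ~5% of the time
    rejections = 0
    reps = 200
    for _ in range(reps):
        n = 300
        nxt = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
        rows = pd.DataFrame({
            "subject_id": "x", "prev_state": 1, "next_state": nxt,
            "sex": rng.integers(0, 2, n), "smoke": rng.integers(0, 2, n),
            "age": rng.uniform(30, 70, n), "time": rng.integers(1, 4, n),
        })
        full = fit_multinomial(rows, 1, "time")
        null = fit_multinomial(rows, 1, "base")
        _, _, p = lrt_time_effect(full, null)
        rejections += p < 0.05
    # binomial 99.9% band around 0.05 at 200 reps
    assert 0.005 <= rejections / reps <= 0.11


def test_tpm_uniform_when_gamma_zero():
    fits = {
        l: transition.TransitionModelFit(
            l, "intercept", ["intercept"], [j for j in (1, 2, 3) if j != l],
            np.zeros((1, 2)), 0.0, 1, [], True)
        for l in (1, 2, 3)
    }
    tpm = build_tpm(0, 0, 50, 1, fits)
    np.testing.assert_allclose(tpm, np.full((3, 3), 1 / 3), atol=1e-15)


def test_tpm_rows_sum_to_one_and_interior(cohort_responses):
    fits = cohort_responses["fits"]
    rows = cohort_responses["rows"]
    for r in rows.head(50).itertuples():
        tpm = build_tpm(r.sex, r.smoke, r.age, int(r.time), fits)
        np.testing.assert_allclose(tpm.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(tpm > 0) and np.all(tpm < 1)


def test_tpm_unseen_time_level_raises():
    rows = pd.DataFrame({
        "subject_id": "x", "prev_state": [1] * 60, "next_state": [1, 2, 3] * 20,
        "sex": 0, "smoke": 0, "age": 50.0, "time": [1, 2] * 30,
    })
    fits = {l: fit_multinomial(
        pd.concat([rows.assign(prev_state=l)]), l, "time") for l in (1, 2, 3)}
    with pytest.raises(UnseenTimeLevelError, match="3"):
        build_tpm(0, 0, 50, 3, fits)


def test_response_is_row_of_tpm(cohort_responses):
    seqs = cohort_responses["sequences"]
    fits = cohort_responses["fits"]
    for seq in seqs[:25]:
        resp = extract_response(seq, fits)
        last = seq.last
        tpm = build_tpm(last.sex, last.smoke, last.age, last.exam, fits)
        np.testing.assert_allclose(resp.y, tpm[seq.last.state - 1], atol=1e-12)
        assert resp.conditioning_state == seq.last.state
        assert resp.y.sum() == pytest.approx(1.0, abs=1e-12)


def test_single_exam_subject_gets_response():
    seqs = _sequences([[2]])
    rows = _intercept_rows({1: {1: 5, 2: 3, 3: 2}, 2: {1: 2, 2: 6, 3: 2},
                            3: {1: 1, 2: 2, 3: 7}})
    fits = {l: fit_multinomial(rows, l, "intercept") for l in (1, 2, 3)}
    resp = extract_response(seqs[0], fits)
    np.testing.assert_allclose(resp.y, [0.2, 0.6, 0.2], atol=1e-7)


def test_time_selection_prefers_base_without_time_effect(cohort_responses):
    # generator has no time effect, so LRT selection should mostly keep "base";
    # at minimum the selected model must nest it with a valid LRT
    rows = cohort_responses["rows"]
    fits = fit_transition_models(rows, select_time=True)
    for l, f in fits.items():
        assert f.formula in ("base", "time", "age_time")
        assert f.converged


def test_fit_serialization_round_trip(cohort_responses):
    fits = cohort_responses["fits"]
    back = fits_from_json(fits_to_json(fits))
    for l in (1, 2, 3):
        np.testing.assert_allclose(back[l].coef, fits[l].coef)
        assert back[l].formula == fits[l].formula
        p1 = fits[l].predict_row(1, 0, 55.0, 1)
        p2 = back[l].predict_row(1, 0, 55.0, 1)
        np.testing.assert_allclose(p1, p2)
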
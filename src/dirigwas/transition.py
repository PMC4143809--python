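"""Multistate transition model for longitudinal hypertension states.

For each previous state l a generalized-logit (baseline-category multinomial)
model is fitted to the observed one-step transitions,

    log(y_lj / y_ll) = z' gamma_lj,   j != l,

with the staying probability y_ll as baseline.  Covariates z are sex,
smoking status and age at the earlier exam, optionally augmented by a
categorical examination-time effect or an age-by-time interaction; the time
term can be selected per previous state by likelihood-ratio test.  The three
fitted models define a 3x3 transition probability matrix (TPM) per subject,
and the subject's compositional response is the TPM row indexed by the last
observed state, evaluated at the last exam's covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .states import StateSequence

STATES = (1, 2, 3)

#: Transition-model shapes used by default when LRT selection is disabled:
#: age-by-time interaction out of state 1, a time main effect out of state 2,
#: and no time term out of state 3.
DEFAULT_FORMULAS = {1: "age_time", 2: "time", 3: "base"}

FORMULAS = ("intercept", "base", "time", "age_time")

#: Bound on multinomial coefficients during optimization; keeps TPM entries
#: strictly inside (0, 1) when a transition category is empty.
COEF_CAP = 30.0


class UnseenTimeLevelError(ValueError):
    """A prediction-time exam index was not among the fitted time levels."""


@dataclass
class TransitionModelFit:
    """Fitted generalized-logit model for transitions out of one state.

    ``coef`` has one row per design column and one column per non-baseline
    destination state (ordered as ``dest_states``); the baseline category
    j = ``prev_state`` has implicit zero coefficients.
    """

    prev_state: int
    formula: str
    colnames: list[str]
    dest_states: list[int]
    coef: np.ndarray
    loglik: float
    n_obs: int
    time_levels: list[int]
    converged: bool
    vcov: np.ndarray | None = None  # inverse observed information, theta layout

    @property
    def n_params(self) -> int:
        return int(self.coef.size)

    def coef_se(self) -> np.ndarray:
        """Standard errors shaped like ``coef`` (d x K)."""
        if self.vcov is None:
            raise ValueError("no covariance available for this fit")
        return np.sqrt(np.diag(self.vcov)).reshape(self.coef.shape)

    def design_row(self, sex: float, smoke: float, age: float, time: int) -> np.ndarray:
        return _design_row(self.formula, sex, smoke, age, time, self.time_levels)

    def predict_row(self, sex: float, smoke: float, age: float, time: int) -> np.ndarray:
        """Transition probabilities (to states 1,2,3) for one covariate vector."""
        z = self.design_row(sex, smoke, age, time)
        eta = {j: float(z @ self.coef[:, m]) for m, j in enumerate(self.dest_states)}
        eta[self.prev_state] = 0.0
        mx = max(eta.values())
        ex = {j: np.exp(eta[j] - mx) for j in STATES}
        tot = sum(ex.values())
        return np.array([ex[j] / tot for j in STATES])


@dataclass
class ResponseVector:
    """3-simplex response of one subject: a row of the subject's TPM."""

    subject_id: str
    family_id: str
    conditioning_state: int
    y: np.ndarray = field(repr=False)


def build_transition_rows(sequences: Iterable[StateSequence]) -> pd.DataFrame:
    """One row per consecutive exam pair, covariates taken at the earlier exam.

    The ``time`` column is the exam index of the earlier exam, treated
    downstream as a categorical factor.
    """
    rows = []
    for seq in sequences:
        for prev, nxt in zip(seq.exams[:-1], seq.exams[1:]):
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "prev_state": prev.state,
                    "next_state": nxt.state,
                    "sex": prev.sex,
                    "smoke": prev.smoke,
                    "age": prev.age,
                    "time": prev.exam,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "prev_state", "next_state", "sex", "smoke", "age", "time"],
    )


def _design_row(formula: str, sex: float, smoke: float, age: float, time: int,
                time_levels: Sequence[int]) -> np.ndarray:
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}")
    if formula == "intercept":
        return np.array([1.0])
    base = [1.0, float(sex), float(smoke), float(age)]
    if formula == "base":
        return np.array(base)
    if time not in time_levels:
        raise UnseenTimeLevelError(
            f"time level {time} not among fitted levels {list(time_levels)}"
        )
    # treatment coding: first fitted level is the reference
    extra = []
    for lev in time_levels[1:]:
        ind = 1.0 if time == lev else 0.0
        extra.append(ind if formula == "time" else ind * float(age))
    return np.array(base + extra)


def _design_matrix(df: pd.DataFrame, formula: str,
                   time_levels: Sequence[int]) -> tuple[np.ndarray, list[str]]:
    Z = np.stack([
        _design_row(formula, r.sex, r.smoke, r.age, int(r.time), time_levels)
        for r in df.itertuples()
    ])
    if formula == "intercept":
        return Z, ["intercept"]
    names = ["intercept", "sex", "smoke", "age"]
    if formula == "time":
        names += [f"time[{lev}]" for lev in time_levels[1:]]
    elif formula == "age_time":
        names += [f"age:time[{lev}]" for lev in time_levels[1:]]
    return Z, names


def _multinom_negloglik_grad(theta: np.ndarray, Z: np.ndarray, Yind: np.ndarray):
    # theta flat (d*K,); Yind n x (K+1) one-hot with column 0 = baseline
    n, d = Z.shape
    K = Yind.shape[1] - 1
    B = theta.reshape(d, K)
    eta = Z @ B                              # n x K, baseline linear predictor = 0
    full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    mx = full.max(axis=1, keepdims=True)
    ex = np.exp(full - mx)
    P = ex / ex.sum(axis=1, keepdims=True)   # n x (K+1)
    ll = float(np.sum(np.log(np.maximum(P[Yind.astype(bool)], 1e-300))))
    G = Z.T @ (P[:, 1:] - Yind[:, 1:])       # d x K gradient of -loglik
    return -ll, G.ravel()


def _multinom_hessian(theta: np.ndarray, Z: np.ndarray, Yind: np.ndarray) -> np.ndarray:
    """Hessian of the negative multinomial log-likelihood.

    Blocks [a, b] = Z' diag(p_a (delta_ab - p_b)) Z, rearranged to the
    interleaved (d x K row-major) layout of theta/gradient.
    """
    n, d = Z.shape
    K = Yind.shape[1] - 1
    B = theta.reshape(d, K)
    full = np.concatenate([np.zeros((n, 1)), Z @ B], axis=1)
    ex = np.exp(full - full.max(axis=1, keepdims=True))
    P = (ex / ex.sum(axis=1, keepdims=True))[:, 1:]           # n x K
    Hb = np.empty((K, K, d, d))
    for a in range(K):
        for b in range(K):
            w = P[:, a] * ((a == b) - P[:, b])
            Hb[a, b] = (Z * w[:, None]).T @ Z
    return Hb.transpose(2, 0, 3, 1).reshape(d * K, d * K)


def _multinom_newton_polish(theta: np.ndarray, Z: np.ndarray, Yind: np.ndarray,
                            tol: float = 1e-9, max_iter: int = 50) -> np.ndarray:
    """Full Newton steps on the multinomial log-likelihood, clipped to the cap."""
    d = Z.shape[1]
    K = Yind.shape[1] - 1
    for _ in range(max_iter):
        nll, g = _multinom_negloglik_grad(theta, Z, Yind)
        at_bound = np.abs(theta) >= COEF_CAP - 1e-9
        if np.linalg.norm(np.where(at_bound, 0.0, g), np.inf) < tol:
            break
        H = _multinom_hessian(theta, Z, Yind)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(d * K), -g)
        except np.linalg.LinAlgError:
            break
        gnorm = np.linalg.norm(g, np.inf)
        moved = False
        t = 1.0
        for _ in range(20):
            cand = np.clip(theta + t * step, -COEF_CAP, COEF_CAP)
            nll_c, g_c = _multinom_negloglik_grad(cand, Z, Yind)
            # near the optimum the objective change is below float resolution,
            # so accept on gradient-norm contraction as well
            if np.isfinite(nll_c) and (np.linalg.norm(g_c, np.inf) < gnorm
                                       or nll_c < nll - 1e-12):
                theta, moved = cand, True
                break
            t *= 0.5
        if not moved:
            break
    return theta


def fit_multinomial(rows: pd.DataFrame, prev_state: int,
                    formula: str = "base") -> TransitionModelFit:
    """Fit the generalized-logit model for transitions out of ``prev_state``.

    Maximizes the multinomial log-likelihood by L-BFGS-B with analytic
    gradient; coefficients are capped at |gamma| <= 30 so that empty
    destination categories stay finite.
    """
    sub = rows[rows["prev_state"] == prev_state]
    if len(sub) == 0:
        raise ValueError(f"no observed transitions out of state {prev_state}")
    time_levels = sorted(int(t) for t in sub["time"].unique())
    Z, names = _design_matrix(sub, formula, time_levels)
    dest = [j for j in STATES if j != prev_state]
    cats = [prev_state] + dest
    Yind = np.stack([(sub["next_state"] == c).to_numpy(float) for c in cats], axis=1)

    d, K = Z.shape[1], len(dest)
    x0 = np.zeros(d * K)
    res = optimize.minimize(
        _multinom_negloglik_grad, x0, args=(Z, Yind), jac=True,
        method="L-BFGS-B", bounds=[(-COEF_CAP, COEF_CAP)] * (d * K),
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    x = _multinom_newton_polish(res.x, Z, Yind)
    coef = x.reshape(d, K)
    # converged if the projected gradient (zero at active bounds) is tiny
    nll, g = _multinom_negloglik_grad(x, Z, Yind)
    at_bound = np.abs(x) >= COEF_CAP - 1e-9
    proj = np.where(at_bound, 0.0, g)
    converged = bool(np.linalg.norm(proj, np.inf) < 1e-8)
    try:
        vcov = np.linalg.inv(_multinom_hessian(x, Z, Yind))
    except np.linalg.LinAlgError:
        vcov = None
    return TransitionModelFit(
        prev_state=prev_state,
        formula=formula,
        colnames=names,
        dest_states=dest,
        coef=coef,
        loglik=-float(nll),
        n_obs=len(sub),
        time_levels=time_levels,
        converged=converged,
        vcov=vcov,
    )


def lrt_time_effect(fit_full: TransitionModelFit,
                    fit_null: TransitionModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair of transition models.

    Returns (statistic, df, p).  The models must be fitted to the same rows
    (same previous state and observation count) and be nested.
    """
    if fit_full.prev_state != fit_null.prev_state or fit_full.n_obs != fit_null.n_obs:
        raise ValueError("LRT requires models fitted to identical rows")
    df = fit_full.n_params - fit_null.n_params
    if df < 0 or not set(fit_null.colnames) <= set(fit_full.colnames):
        raise ValueError("models are not nested (null terms not a subset of full)")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    if df == 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def fit_transition_models(rows: pd.DataFrame, select_time: bool = True,
                          alpha: float = 0.05,
                          formulas: Mapping[int, str] | None = None,
                          ) -> dict[int, TransitionModelFit]:
    """Fit all three per-previous-state models.

    With ``select_time`` the time term is chosen per previous state by LRT at
    level ``alpha`` among {none, categorical time, age-by-time interaction},
    keeping the candidate with the smaller LRT p-value when both reject.
    Otherwise the shapes in ``formulas`` (default ``DEFAULT_FORMULAS``) are
    used as-is.
    """
    fits: dict[int, TransitionModelFit] = {}
    for l in STATES:
        if select_time:
            base = fit_multinomial(rows, l, "base")
            best, best_p = base, None
            for cand in ("time", "age_time"):
                try:
                    fit_c = fit_multinomial(rows, l, cand)
                except UnseenTimeLevelError:
                    continue
                _, df, p = lrt_time_effect(fit_c, base)
                if df > 0 and p < alpha and (best_p is None or p < best_p):
                    best, best_p = fit_c, p
            fits[l] = best
        else:
            shape = (formulas or DEFAULT_FORMULAS)[l]
            fits[l] = fit_multinomial(rows, l, shape)
    return fits


def build_tpm(sex: float, smoke: float, age: float, time: int,
              fits: Mapping[int, TransitionModelFit]) -> np.ndarray:
    """Per-subject 3x3 transition probability matrix.

    Every row is evaluated at the same covariate vector; row l comes from the
    model for transitions out of state l.  Raises
    :class:`UnseenTimeLevelError` when ``time`` was not a fitted level of a
    row's model.
    """
    if set(fits) != set(STATES):
        raise ValueError("fits for all three previous states are required")
    tpm = np.stack([fits[l].predict_row(sex, smoke, age, time) for l in STATES])
    return tpm


def extract_response(seq: StateSequence, fits: Mapping[int, TransitionModelFit],
                     clamp_time: bool = True) -> ResponseVector:
    """Compositional response: the TPM row of the subject's last observed state.

    Covariates are taken at the last retained exam.  With ``clamp_time`` the
    exam index is clamped into each model's fitted time-level range (a
    subject's final exam index typically exceeds the largest index observed
    as the earlier member of a transition pair).
    """
    last = seq.last
    y = np.empty(3)
    s = seq.last.state
    fit = fits[s]
    t = last.exam
    if clamp_time and fit.time_levels:
        t = min(max(t, fit.time_levels[0]), fit.time_levels[-1])
    y = fit.predict_row(last.sex, last.smoke, last.age, t)
    return ResponseVector(subject_id=seq.subject_id, family_id=seq.family_id,
                          conditioning_state=s, y=y)


def responses_to_frame(responses: Sequence[ResponseVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in responses],
            "family_id": [r.family_id for r in responses],
            "conditioning_state": [r.conditioning_state for r in responses],
            "y1": [r.y[0] for r in responses],
            "y2": [r.y[1] for r in responses],
            "y3": [r.y[2] for r in responses],
        }
    )


def fits_to_json(fits: Mapping[int, TransitionModelFit]) -> str:
    payload = {
        str(l): {
            "prev_state": f.prev_state,
            "formula": f.formula,
            "colnames": f.colnames,
            "dest_states": f.dest_states,
            "coef": f.coef.tolist(),
            "loglik": f.loglik,
            "n_obs": f.n_obs,
            "time_levels": f.time_levels,
            "converged": f.converged,
        }
        for l, f in fits.items()
    }
    return json.dumps(payload, indent=2)


def fits_from_json(text: str) -> dict[int, TransitionModelFit]:
    payload = json.loads(text)
    return {
        int(l): TransitionModelFit(
            prev_state=d["prev_state"],
            formula=d["formula"],
            colnames=list(d["colnames"]),
            dest_states=list(d["dest_states"]),
            coef=np.asarray(d["coef"], float),
            loglik=float(d["loglik"]),
            n_obs=int(d["n_obs"]),
            time_levels=list(d["time_levels"]),
            converged=bool(d["converged"]),
        )
        for l, d in payload.items()
    }
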
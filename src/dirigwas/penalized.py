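"""Penalized Dirichlet regression for gene-level SNP selection.

All SNPs in a gene enter one Dirichlet regression and are shrunk jointly by
a ridge/lasso mixture controlled by a mixing weight c in [0, 1] and an
overall weight kappa >= 0:

    pl(eta) = l(eta; Y, G) - c*kappa * sum_l ||eta_.l||_2^2
                           - (1-c)*kappa * sum_l ||eta_.l||_1

where eta_.l is the 3-vector of coefficients of predictor l across the
Dirichlet components.  c = 1 gives a ridge penalty, c = 0 a lasso; both sums
run over the SNP rows only — the intercept row (and family-contrast rows
under the adjusted model) is never penalized.  The objective is maximized by
proximal-gradient iteration: a gradient ascent step on the log-likelihood
followed by the closed-form elastic-net proximal map (elementwise
soft-thresholding for the L1 part, multiplicative shrinkage for the
quadratic part), with backtracking so the objective never decreases.  SNP
dosage columns are standardized before penalization and coefficients are
reported on both scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dirichlet import N_COMPONENTS, _loglik_parts, compress_simplex, family_contrasts

DEFAULT_C_GRID = (0.0, 0.3, 0.5, 0.7, 1.0)
DEFAULT_SELECTION_TOL = 1e-6


@dataclass
class PenaltyConfig:
    """Grids and tolerances for the penalized fits."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    kappa: float = 1.0
    selection_tol: float = DEFAULT_SELECTION_TOL
    max_iter: int = 5000
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if any(not (0.0 <= c <= 1.0) for c in self.c_grid):
            raise ValueError("c values must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


@dataclass
class PenalizedFit:
    """Solution of one penalized Dirichlet regression.

    ``eta`` is (1 + p [+ F-1]) x 3 on the standardized-predictor scale with
    the intercept in row 0; ``eta_original`` is the same solution mapped back
    to the raw dosage scale.  ``penalized_mask`` flags the rows the penalty
    applies to.
    """

    rownames: list[str]
    eta: np.ndarray
    eta_original: np.ndarray
    penalized_mask: np.ndarray
    c: float
    kappa: float
    objective: float
    loglik: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(repr=False, default=None)

    @property
    def group_norms(self) -> np.ndarray:
        """Euclidean norm of each penalized predictor's coefficient triple."""
        norms = np.linalg.norm(self.eta, axis=1)
        return norms[self.penalized_mask]


def penalty_value(eta: np.ndarray, penalized_mask: np.ndarray,
                  c: float, kappa: float) -> float:
    """c*kappa * sum ||eta_.l||_2^2 + (1-c)*kappa * sum ||eta_.l||_1 over penalized rows."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    E = eta[penalized_mask]
    return float(c * kappa * np.sum(E ** 2) + (1 - c) * kappa * np.sum(np.abs(E)))


def penalized_objective(eta: np.ndarray, Y: np.ndarray, G: np.ndarray,
                        c: float, kappa: float,
                        penalized_mask: np.ndarray | None = None) -> float:
    """Penalized log-likelihood; equals the plain log-likelihood when kappa = 0.

    ``G`` includes the intercept column; ``penalized_mask`` defaults to
    everything but row 0.
    """
    eta = np.asarray(eta, float)
    if penalized_mask is None:
        penalized_mask = np.ones(eta.shape[0], bool)
        penalized_mask[0] = False
    logY = np.log(np.asarray(Y, float))
    ll, _, _ = _loglik_parts(eta.reshape(-1, order="F"), np.asarray(G, float), logY)
    return ll - penalty_value(eta, penalized_mask, c, kappa)


def _prox_elastic(x: np.ndarray, t: float, c: float, kappa: float) -> np.ndarray:
    """Proximal map of t * (c*kappa*x^2 + (1-c)*kappa*|x|), elementwise."""
    soft = np.sign(x) * np.maximum(np.abs(x) - t * (1 - c) * kappa, 0.0)
    return soft / (1.0 + 2.0 * t * c * kappa)


def _standardize(G_snp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = G_snp.mean(axis=0)
    sd = G_snp.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (G_snp - mean) / sd, mean, sd


def fit_penalized(Y: np.ndarray, G_snp: np.ndarray, snp_names: Sequence[str],
                  c: float, kappa: float,
                  fam_X: np.ndarray | None = None,
                  fam_names: Sequence[str] | None = None,
                  config: PenaltyConfig | None = None,
                  eta0: np.ndarray | None = None) -> PenalizedFit:
    """Maximize the penalized Dirichlet log-likelihood for one gene.

    ``G_snp`` is the n x p matrix of minor-allele dosages for the gene's
    SNPs (no intercept column); family contrasts, when given (adjusted
    model), are appended unpenalized.  Exact zeros are attainable whenever
    c < 1.  Non-convergence at ``max_iter`` returns the fit flagged, with
    the iteration count.
    """
    cfg = config or PenaltyConfig()
    Y = compress_simplex(np.asarray(Y, float))
    logY = np.log(Y)
    Gs, mean, sd = _standardize(np.asarray(G_snp, float))
    p = Gs.shape[1]
    cols = [np.ones((Gs.shape[0], 1)), Gs]
    rownames = ["intercept"] + list(snp_names)
    mask = [False] + [True] * p
    if fam_X is not None and fam_X.shape[1] > 0:
        cols.append(fam_X)
        rownames += list(fam_names or [f"fam{k}" for k in range(fam_X.shape[1])])
        mask += [False] * fam_X.shape[1]
    G = np.concatenate(cols, axis=1)
    penalized_mask = np.array(mask)
    M = G.shape[1]

    if eta0 is None:
        eta = np.zeros((M, N_COMPONENTS))
        eta[0, :] = np.log(np.maximum(Y.mean(axis=0) * 3.0, 1e-3))
    else:
        eta = np.array(eta0, float)

    def smooth(e: np.ndarray):
        ll, g, _ = _loglik_parts(e.reshape(-1, order="F"), G, logY)
        return ll, g.reshape(M, N_COMPONENTS, order="F")

    def obj(e: np.ndarray, ll: float) -> float:
        return ll - penalty_value(e, penalized_mask, c, kappa)

    ll, grad = smooth(eta)
    cur = obj(eta, ll)
    trace = [cur]
    t = 1.0 / max(1.0, Y.shape[0] / 10.0)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        accepted = False
        for _ in range(60):
            cand = eta + t * grad
            cand_pen = cand.copy()
            cand_pen[penalized_mask] = _prox_elastic(cand[penalized_mask], t, c, kappa)
            ll_c, grad_c = smooth(cand_pen)
            new = obj(cand_pen, ll_c)
            if np.isfinite(new) and new >= cur:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        rel = abs(new - cur) / (abs(cur) + 1.0)
        eta, ll, grad, cur = cand_pen, ll_c, grad_c, new
        trace.append(cur)
        t *= 1.2  # cautious step-size recovery
        if rel < cfg.rel_tol:
            converged = True
            break

    # map back to the raw dosage scale
    eta_orig = eta.copy()
    eta_orig[1:1 + p] = eta[1:1 + p] / sd[:, None]
    eta_orig[0] = eta[0] - (eta[1:1 + p] * (mean / sd)[:, None]).sum(axis=0)
    return PenalizedFit(
        rownames=rownames,
        eta=eta,
        eta_original=eta_orig,
        penalized_mask=penalized_mask,
        c=c,
        kappa=kappa,
        objective=cur,
        loglik=ll,
        n_iter=it,
        converged=converged,
        objective_trace=np.array(trace),
    )


def count_selected(fit: PenalizedFit, tol: float | None = None) -> int:
    """Number of penalized coefficients with |eta_lj| above tolerance.

    Counted on the standardized-predictor scale; intercept and family rows
    are excluded.
    """
    tol = DEFAULT_SELECTION_TOL if tol is None else tol
    return int(np.sum(np.abs(fit.eta[fit.penalized_mask]) > tol))


def count_selected_groups(fit: PenalizedFit, tol: float | None = None) -> int:
    """Number of SNPs with any nonzero coefficient (group-level count)."""
    tol = DEFAULT_SELECTION_TOL if tol is None else tol
    return int(np.sum(np.any(np.abs(fit.eta[fit.penalized_mask]) > tol, axis=1)))


def kkt_violation(fit: PenalizedFit, Y: np.ndarray, G_snp: np.ndarray,
                  fam_X: np.ndarray | None = None) -> float:
    """Largest lasso KKT violation at c = 0: max over zero coefficients of
    |score| - kappa (negative means all conditions hold)."""
    Y = compress_simplex(np.asarray(Y, float))
    Gs, _, _ = _standardize(np.asarray(G_snp, float))
    cols = [np.ones((Gs.shape[0], 1)), Gs]
    if fam_X is not None and fam_X.shape[1] > 0:
        cols.append(fam_X)
    G = np.concatenate(cols, axis=1)
    M = G.shape[1]
    _, g, _ = _loglik_parts(fit.eta.reshape(-1, order="F"), G, np.log(Y))
    score = g.reshape(M, N_COMPONENTS, order="F")
    pen_score = score[fit.penalized_mask]
    pen_eta = fit.eta[fit.penalized_mask]
    thr = (1 - fit.c) * fit.kappa
    zero = np.abs(pen_eta) <= DEFAULT_SELECTION_TOL
    if not np.any(zero):
        return -np.inf
    return float(np.max(np.abs(pen_score[zero])) - thr)


def selection_path(Y: np.ndarray, G_snp: np.ndarray, snp_names: Sequence[str],
                   kappa: float, c_grid: Sequence[float] = DEFAULT_C_GRID,
                   family_ids: Sequence | None = None,
                   config: PenaltyConfig | None = None,
                   label: str = "gene") -> tuple[pd.DataFrame, list[PenalizedFit]]:
    """Penalized fits across the c grid, summarized one row per c.

    Columns mirror the usual selection report: data label, number of SNPs,
    c, kappa, number of coefficients selected, number of SNP groups
    selected, iterations to convergence.
    """
    fam_X = fam_names = None
    if family_ids is not None:
        fam_X, fam_names = family_contrasts(family_ids)
    rows = []
    fits = []
    for c in c_grid:
        try:
            fit = fit_penalized(Y, G_snp, snp_names, c, kappa,
                                fam_X=fam_X, fam_names=fam_names, config=config)
        except (ValueError, np.linalg.LinAlgError):
            rows.append({"data": label, "n_snps": np.shape(G_snp)[1], "c": c,
                         "kappa": kappa, "n_selected": np.nan,
                         "n_groups_selected": np.nan, "iterations": np.nan,
                         "converged": False})
            fits.append(None)
            continue
        tol = (config or PenaltyConfig()).selection_tol
        rows.append({
            "data": label,
            "n_snps": np.shape(G_snp)[1],
            "c": c,
            "kappa": kappa,
            "n_selected": count_selected(fit, tol),
            "n_groups_selected": count_selected_groups(fit, tol),
            "iterations": fit.n_iter,
            "converged": fit.converged,
        })
        fits.append(fit)
    return pd.DataFrame(rows), fits


def coefficient_path_frame(fits: Sequence[PenalizedFit]) -> pd.DataFrame:
    """Long-format coefficient table across fits (raw-scale coefficients)."""
    rows = []
    for fit in fits:
        if fit is None:
            continue
        for i, name in enumerate(fit.rownames):
            for j in range(N_COMPONENTS):
                rows.append({"c": fit.c, "kappa": fit.kappa, "predictor": name,
                             "component": j + 1,
                             "coef": fit.eta_original[i, j],
                             "coef_std_scale": fit.eta[i, j],
                             "penalized": bool(fit.penalized_mask[i])})
    return pd.DataFrame(rows)
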
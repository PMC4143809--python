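"""Dirichlet regression with log link for 3-simplex responses.

The response y_i = (y_i1, y_i2, y_i3) lies in the open simplex and is
modelled as Dirichlet with concentration parameters linked to covariates,

    log lambda_ij = s_i' beta_j,   j = 1, 2, 3,

in the "common" parametrization: all three components carry a free
coefficient vector, no reference category.  Two model shapes are used for
single-SNP scans: M1 with intercept and minor-allele dosage, and M2 adding
pedigree (family) as a fixed categorical via treatment contrasts.  The null
hypothesis of no association, H0: beta = (beta_1, beta_2, beta_3) = 0 for the
dosage coefficients, is tested with a 3-df Wald statistic using the
observed-information covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

N_COMPONENTS = 3


class SimplexError(ValueError):
    """Response rows are not strictly inside the simplex."""


def compress_simplex(Y: np.ndarray) -> np.ndarray:
    """Shrink responses toward the simplex barycenter: y' = (y(n-1) + 1/3)/n.

    Applied when any component touches the boundary (within 1e-10 of 0 or 1);
    the Dirichlet has support only on the open simplex.
    """
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    if np.any(Y <= 1e-10) or np.any(Y >= 1 - 1e-10):
        return (Y * (n - 1) + 1.0 / 3.0) / n
    return Y


def dirichlet_loglik(Y: np.ndarray, Lambda: np.ndarray) -> float:
    """Dirichlet log-likelihood of simplex rows Y under concentrations Lambda.

    sum_i [ lgamma(Lambda_i) - sum_j lgamma(lambda_ij)
            + sum_j (lambda_ij - 1) log y_ij ],  Lambda_i = sum_j lambda_ij.
    """
    Y = np.asarray(Y, float)
    Lam = np.asarray(Lambda, float)
    if np.any(Y <= 0) or np.any(Y >= 1):
        raise SimplexError(
            "response rows must be strictly inside the simplex; "
            "apply compress_simplex() first"
        )
    if np.any(Lam <= 0):
        raise ValueError("concentration parameters must be positive")
    tot = Lam.sum(axis=1)
    return float(
        np.sum(special.gammaln(tot))
        - np.sum(special.gammaln(Lam))
        + np.sum((Lam - 1.0) * np.log(Y))
    )


def _loglik_parts(theta: np.ndarray, S: np.ndarray, logY: np.ndarray,
                  hess: bool = False):
    """Log-likelihood, gradient and (optionally) Hessian in theta = vec(B).

    B is M x 3 (column j = beta_j); theta is column-major (component blocks).
    """
    n, M = S.shape
    B = theta.reshape(M, N_COMPONENTS, order="F")
    Lam = np.exp(np.clip(S @ B, -300, 300))        # n x 3
    tot = Lam.sum(axis=1)
    ll = float(np.sum(special.gammaln(tot)) - np.sum(special.gammaln(Lam))
               + np.sum((Lam - 1.0) * logY))
    C = special.digamma(tot)[:, None] - special.digamma(Lam) + logY   # n x 3
    W = Lam * C                                   # n x 3
    grad = (S.T @ W).reshape(M * N_COMPONENTS, order="F")
    if not hess:
        return ll, grad, None
    pg_tot = special.polygamma(1, tot)            # n
    pg = special.polygamma(1, Lam)                # n x 3
    H = np.empty((M * N_COMPONENTS, M * N_COMPONENTS))
    for j in range(N_COMPONENTS):
        for k in range(j, N_COMPONENTS):
            w = Lam[:, j] * Lam[:, k] * pg_tot
            if j == k:
                w = w + W[:, j] - Lam[:, j] ** 2 * pg[:, j]
            blk = (S * w[:, None]).T @ S
            H[j * M:(j + 1) * M, k * M:(k + 1) * M] = blk
            if k != j:
                H[k * M:(k + 1) * M, j * M:(j + 1) * M] = blk.T
    return ll, grad, H


@dataclass
class DirichletFit:
    """Maximum-likelihood Dirichlet regression fit.

    ``coef`` is M x 3 (one column per component); ``vcov`` is the
    observed-information covariance of theta = vec(coef) in component-major
    order.
    """

    colnames: list[str]
    coef: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    model: str = "M1"

    def lambda_matrix(self, S: np.ndarray) -> np.ndarray:
        return np.exp(S @ self.coef)

    def coef_indices(self, name: str) -> np.ndarray:
        """Flat theta indices of covariate ``name`` across the 3 components."""
        M = len(self.colnames)
        i = self.colnames.index(name)
        return np.array([i + j * M for j in range(N_COMPONENTS)])


@dataclass
class WaldResult:
    statistic: float
    df: int
    pvalue: float
    labels: list[str] = field(default_factory=list)


def _start_values(Y: np.ndarray, S: np.ndarray, colnames: Sequence[str]) -> np.ndarray:
    # method-of-moments intercepts: match mean and a rough precision
    m = Y.mean(axis=0)
    v = Y.var(axis=0).mean()
    prec = max((m.mean() * (1 - m.mean())) / max(v, 1e-6) - 1.0, 1.0)
    M = S.shape[1]
    B = np.zeros((M, N_COMPONENTS))
    try:
        i0 = list(colnames).index("intercept")
    except ValueError:
        i0 = 0
    B[i0, :] = np.log(np.maximum(m * prec, 1e-3))
    return B.reshape(M * N_COMPONENTS, order="F")


def fit_dirichlet(Y: np.ndarray, S: np.ndarray, colnames: Sequence[str],
                  model: str = "M1", max_iter: int = 200,
                  gtol: float = 1e-6, theta0: np.ndarray | None = None
                  ) -> DirichletFit:
    """Fit the Dirichlet regression by Newton's method with line search.

    Falls back to L-BFGS-B with analytic gradient when a Newton step is not
    an ascent direction.  The covariance is the inverse observed information
    (negative inverse Hessian) at the optimum.  ``theta0`` (flat,
    component-major) warm-starts the iteration.
    """
    Y = compress_simplex(np.asarray(Y, float))
    S = np.asarray(S, float)
    rank = np.linalg.matrix_rank(S)
    if rank < S.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(S, mode="economic", pivoting=True)
        bad = [colnames[i] for i in sorted(piv[rank:])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    logY = np.log(Y)
    theta = (_start_values(Y, S, colnames) if theta0 is None
             else np.asarray(theta0, float).copy())
    ll, g, _ = _loglik_parts(theta, S, logY)
    converged = False
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        if np.linalg.norm(g, np.inf) < gtol:
            converged = True
            break
        _, _, H = _loglik_parts(theta, S, logY, hess=True)
        # Newton direction on the concave problem; regularize if needed
        try:
            step = np.linalg.solve(-H + 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            step = g
        if g @ step <= 0:
            step = g
        t = 1.0
        for _ in range(60):
            cand = theta + t * step
            ll_c, g_c, _ = _loglik_parts(cand, S, logY)
            if np.isfinite(ll_c) and ll_c >= ll + 1e-4 * t * (g @ step):
                theta, ll, g = cand, ll_c, g_c
                break
            t *= 0.5
        else:
            break
    if not converged:
        res = optimize.minimize(
            lambda th: tuple(-v for v in _loglik_parts(th, S, logY)[:2]),
            theta, jac=True, method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = res.x
        ll, g, _ = _loglik_parts(theta, S, logY)
        converged = bool(np.linalg.norm(g, np.inf) < max(gtol, 1e-4))
        it += int(res.nit)
    _, _, H = _loglik_parts(theta, S, logY, hess=True)
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(-H)
        converged = False
    M = S.shape[1]
    return DirichletFit(
        colnames=list(colnames),
        coef=theta.reshape(M, N_COMPONENTS, order="F"),
        vcov=vcov,
        loglik=ll,
        n_obs=Y.shape[0],
        converged=converged,
        n_iter=it,
        model=model,
    )


def wald_test(fit: DirichletFit, name: str = "dosage") -> WaldResult:
    """Joint Wald test that covariate ``name`` has zero effect on all components."""
    idx = fit.coef_indices(name)
    b = np.concatenate([fit.coef.reshape(-1, order="F")[idx]])
    V = fit.vcov[np.ix_(idx, idx)]
    try:
        W = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular sub-covariance for Wald test") from exc
    if W < 0:
        raise ValueError("negative Wald statistic: covariance not PSD")
    df = len(idx)
    labels = [f"{name}[{j + 1}]" for j in range(N_COMPONENTS)]
    return WaldResult(statistic=W, df=df, pvalue=float(stats.chi2.sf(W, df)),
                      labels=labels)


def family_contrasts(family_ids: Sequence, min_size: int = 2
                     ) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded pedigree contrasts; largest family is the reference.

    Families smaller than ``min_size`` are pooled into the reference level to
    avoid rank problems.  Returns an n x (F-1) matrix and column labels; a
    single (effective) family yields a zero-column matrix, so the adjusted
    model degenerates to the base model.
    """
    fam = pd.Series(list(family_ids), dtype="object")
    counts = fam.value_counts()
    pooled = set(counts[counts < min_size].index)
    eff = fam.where(~fam.isin(pooled), other="_ref_pool_")
    counts_eff = eff.value_counts()
    ref = counts_eff.index[0]  # value_counts sorts by count desc (ties: first seen)
    levels = sorted(str(l) for l in counts_eff.index if l != ref)
    X = np.zeros((len(fam), len(levels)))
    eff_str = eff.astype(str)
    for k, lev in enumerate(levels):
        X[:, k] = (eff_str == lev).to_numpy(float)
    return X, [f"fam[{lev}]" for lev in levels]


def _scan_design(dosage: np.ndarray, fam_X: np.ndarray | None,
                 fam_names: list[str] | None, model: str
                 ) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(dosage), dosage]
    names = ["intercept", "dosage"]
    if model == "M2" and fam_X is not None and fam_X.shape[1] > 0:
        cols.extend(fam_X.T)
        names.extend(fam_names or [])
    return np.stack(cols, axis=1), names


def snp_scan(responses: pd.DataFrame, genotypes, models: Sequence[str] = ("M1", "M2"),
             sig_threshold: float = 5e-8, min_family_size: int = 2) -> pd.DataFrame:
    """Per-SNP Dirichlet-regression Wald scan.

    ``responses`` is the frame produced by the transition stage (columns
    subject_id, family_id, y1..y3); ``genotypes`` is a
    :class:`dirigwas.qc.GenotypeMatrix` aligned by subject id.  Subjects with
    a missing dosage at a marker are dropped for that marker only.  Returns
    one row per marker with a p-value column per requested model and
    convergence flags; markers whose fit fails to converge get NaN p-values.
    """
    resp_ids = list(responses["subject_id"].astype(str))
    geno_ids = list(map(str, genotypes.samples))
    orphans = sorted(set(resp_ids) - set(geno_ids))
    if orphans:
        raise ValueError(f"subjects with responses but no genotypes: {orphans[:10]}")
    order = [geno_ids.index(s) for s in resp_ids]
    D = genotypes.dosage[order, :]
    Y = compress_simplex(responses[["y1", "y2", "y3"]].to_numpy(float))
    fam_X, fam_names = family_contrasts(responses["family_id"], min_size=min_family_size)

    # null fits (no dosage) provide warm starts for every marker
    null_coef: dict[str, np.ndarray] = {}
    for m in models:
        S0, names0 = _scan_design(np.zeros(len(Y)), fam_X, fam_names, m)
        S0 = np.delete(S0, 1, axis=1)  # drop the dosage column
        try:
            nf = fit_dirichlet(Y, S0, [n for i, n in enumerate(names0) if i != 1],
                               model=m)
            null_coef[m] = nf.coef
        except (ValueError, np.linalg.LinAlgError):
            null_coef[m] = None

    out: dict[str, list] = {
        "marker_id": [], "chrom": [], "pos": [], "minor_allele": [], "maf": [],
    }
    for m in models:
        out[f"p_{m}"] = []
        out[f"converged_{m}"] = []
    out["significant"] = []

    markers = genotypes.markers
    for k in range(D.shape[1]):
        d = D[:, k]
        keep = ~np.isnan(d)
        dk = d[keep]
        freq = float(np.mean(dk) / 2.0) if dk.size else np.nan
        maf = min(freq, 1 - freq) if np.isfinite(freq) else np.nan
        out["marker_id"].append(markers["id"].iloc[k])
        out["chrom"].append(markers["chrom"].iloc[k])
        out["pos"].append(markers["pos"].iloc[k])
        if "minor_allele" in markers.columns:
            out["minor_allele"].append(markers["minor_allele"].iloc[k])
        elif "alt" in markers.columns:
            out["minor_allele"].append(markers["alt"].iloc[k])
        else:
            out["minor_allele"].append("")
        out["maf"].append(maf)
        pvals = {}
        for m in models:
            p, conv = np.nan, False
            if dk.size and np.nanstd(dk) > 0:
                S, names = _scan_design(dk, fam_X[keep], fam_names, m)
                theta0 = None
                if null_coef.get(m) is not None:
                    start = np.insert(null_coef[m], 1, 0.0, axis=0)
                    theta0 = start.reshape(-1, order="F")
                try:
                    fit = fit_dirichlet(Y[keep], S, names, model=m, theta0=theta0)
                    if fit.converged:
                        res = wald_test(fit, "dosage")
                        p, conv = res.pvalue, True
                except (ValueError, np.linalg.LinAlgError):
                    pass
            out[f"p_{m}"].append(p)
            out[f"converged_{m}"].append(conv)
            pvals[m] = p
        finite = [v for v in pvals.values() if np.isfinite(v)]
        out["significant"].append(bool(finite and min(finite) < sig_threshold))
    return pd.DataFrame(out)
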
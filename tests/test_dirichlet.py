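import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from dirigwas.dirichlet import (
    DirichletFit,
    SimplexError,
    _loglik_parts,
    compress_simplex,
    dirichlet_loglik,
    family_contrasts,
    fit_dirichlet,
    snp_scan,
    wald_test,
)
from dirigwas.qc import GenotypeMatrix
import pandas as pd


def _naive_loglik(Y, Lam):
    total = 0.0
    for y, lam in zip(Y, Lam):
        total += math.lgamma(sum(lam))
        for yj, lj in zip(y, lam):
            total += -math.lgamma(lj) + (lj - 1) * math.log(yj)
    return total


def test_loglik_uniform_density():
    y = np.array([[0.2, 0.3, 0.5]])
    assert dirichlet_loglik(y, np.ones((1, 3))) == pytest.approx(math.log(2), abs=1e-14)


def test_loglik_simple_density():
    y = np.array([[0.5, 0.25, 0.25]])
    lam = np.array([[2.0, 1.0, 1.0]])
    assert dirichlet_loglik(y, lam) == pytest.approx(math.log(3), abs=1e-14)


def test_loglik_matches_naive_sum(rng):
    Y = rng.dirichlet([2, 3, 1.5], size=20)
    Lam = rng.uniform(0.5, 5.0, size=(20, 3))
    assert dirichlet_loglik(Y, Lam) == pytest.approx(_naive_loglik(Y, Lam), abs=1e-10)


def test_loglik_rejects_boundary():
    with pytest.raises(SimplexError):
        dirichlet_loglik(np.array([[0.0, 0.5, 0.5]]), np.ones((1, 3)))


def test_compress_simplex_moves_boundary_inside():
    Y = np.array([[1.0, 0.0, 0.0], [0.5, 0.25, 0.25]])
    Yc = compress_simplex(Y)
    assert np.all(Yc > 0) and np.all(Yc < 1)
    np.testing.assert_allclose(Yc.sum(axis=1), 1.0, atol=1e-12)
    # interior matrices pass through untouched
    np.testing.assert_array_equal(compress_simplex(Y[1:]), Y[1:])


def test_gradient_matches_central_differences(rng):
    for _ in range(10):
        n = 15
        Y = rng.dirichlet([1.5, 2.0, 1.0], size=n)
        S = np.column_stack([np.ones(n), rng.normal(size=n)])
        th = rng.normal(scale=0.4, size=6)
        _, g, _ = _loglik_parts(th, S, np.log(Y))
        eps = 1e-6
        for i in range(6):
            e = np.zeros(6)
            e[i] = eps
            num = (_loglik_parts(th + e, S, np.log(Y))[0]
                   - _loglik_parts(th - e, S, np.log(Y))[0]) / (2 * eps)
            assert abs(num - g[i]) / (abs(num) + 1e-8) < 1e-6


def test_intercept_recovery_null_data(rng):
    n = 1000
    Y = rng.dirichlet([2, 2, 2], size=n)
    fit = fit_dirichlet(Y, np.ones((n, 1)), ["intercept"])
    assert fit.converged
    se = np.sqrt(np.diag(fit.vcov))
    assert np.all(np.abs(fit.coef.ravel(order="F") - math.log(2)) < 3 * se)


def test_slope_recovery(rng):
    n = 2000
    g = rng.binomial(2, 0.3, size=n).astype(float)
    beta = np.array([0.5, 0.0, -0.5])
    lam = np.exp(np.log(2) + np.outer(g, beta))
    Y = np.stack([rng.dirichlet(l) for l in lam])
    S = np.column_stack([np.ones(n), g])
    fit = fit_dirichlet(Y, S, ["intercept", "dosage"])
    assert fit.converged
    idx = fit.coef_indices("dosage")
    se = np.sqrt(np.diag(fit.vcov))[idx]
    assert np.all(np.abs(fit.coef[1] - beta) < 3 * se)
    # MLE dominates the generating parameters
    truth = np.vstack([np.full(3, np.log(2)), beta])
    ll_truth = dirichlet_loglik(compress_simplex(Y), np.exp(S @ truth))
    assert fit.loglik >= ll_truth


def test_loglik_is_local_maximum(rng):
    n = 300
    Y = rng.dirichlet([2, 1.5, 2.5], size=n)
    S = np.column_stack([np.ones(n), rng.normal(size=n)])
    fit = fit_dirichlet(Y, S, ["intercept", "x"])
    th = fit.coef.reshape(-1, order="F")
    ll_hat, _, _ = _loglik_parts(th, S, np.log(compress_simplex(Y)))
    for _ in range(100):
        pert = th + rng.normal(scale=1e-2, size=th.size)
        ll_p, _, _ = _loglik_parts(pert, S, np.log(compress_simplex(Y)))
        assert ll_p <= ll_hat + 1e-10


def test_wald_zero_beta_and_chisq_tail():
    M = 2
    coef = np.zeros((M, 3))
    fit = DirichletFit(colnames=["intercept", "dosage"], coef=coef,
                       vcov=np.eye(M * 3), loglik=0.0, n_obs=10,
                       converged=True, n_iter=1)
    res = wald_test(fit, "dosage")
    assert res.statistic == 0.0 and res.pvalue == 1.0
    # W = 3 on identity covariance for unit coefficients
    fit.coef[1, :] = 1.0
    res = wald_test(fit, "dosage")
    assert res.statistic == pytest.approx(3.0)
    assert res.df == 3
    assert res.pvalue == pytest.approx(stats.chi2.sf(3.0, 3), abs=1e-12)
    assert res.pvalue == pytest.approx(0.3916, abs=5e-4)


def test_wald_singular_covariance_raises():
    fit = DirichletFit(colnames=["intercept", "dosage"],
                       coef=np.ones((2, 3)), vcov=np.zeros((6, 6)),
                       loglik=0.0, n_obs=10, converged=True, n_iter=1)
    with pytest.raises(ValueError):
        wald_test(fit, "dosage")


def test_family_contrasts_shapes():
    X, names = family_contrasts(["a"] * 6)
    assert X.shape == (6, 0)
    X, names = family_contrasts(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    assert X.shape == (9, 2)
    assert set(np.unique(X)) <= {0.0, 1.0}
    assert np.all(X.sum(axis=1) <= 1)


def test_small_families_pooled_into_reference():
    X, names = family_contrasts(["big"] * 5 + ["solo1", "solo2"], min_size=2)
    # singletons pool with the reference: they get no indicator of their own
    assert X.shape[1] <= 1


def test_family_relabeling_invariance(rng):
    n = 120
    fam = np.repeat([f"f{i}" for i in range(12)], 10)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    Y = rng.dirichlet([2, 2, 2], size=n)
    relabeled = np.array([f"zz_{f}" for f in fam])

    def fit_m2(labels):
        X, names = family_contrasts(labels)
        S = np.column_stack([np.ones(n), g, X])
        return fit_dirichlet(Y, S, ["intercept", "dosage"] + names, model="M2")

    f1, f2 = fit_m2(fam), fit_m2(relabeled)
    np.testing.assert_allclose(f1.coef[1], f2.coef[1], atol=1e-6)
    p1 = wald_test(f1, "dosage").pvalue
    p2 = wald_test(f2, "dosage").pvalue
    assert p1 == pytest.approx(p2, rel=1e-6)


def test_m2_degenerates_to_m1_with_single_family(rng):
    n = 150
    g = rng.binomial(2, 0.4, size=n).astype(float)
    Y = rng.dirichlet([1.5, 2, 2.5], size=n)
    S1 = np.column_stack([np.ones(n), g])
    X, _ = family_contrasts(["only"] * n)
    S2 = np.column_stack([S1, X])
    f1 = fit_dirichlet(Y, S1, ["intercept", "dosage"])
    f2 = fit_dirichlet(Y, S2, ["intercept", "dosage"], model="M2")
    np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-10)


def _toy_genotypes(rng, n, p, sample_ids):
    d = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    markers = pd.DataFrame({"id": [f"m{k}" for k in range(p)], "chrom": "3",
                            "pos": np.arange(p) + 1, "ref": "A", "alt": "B"})
    return GenotypeMatrix(samples=sample_ids, markers=markers, dosage=d)


def test_scan_shapes_and_pvalue_range(rng):
    n, p = 120, 15
    ids = [f"s{i}" for i in range(n)]
    geno = _toy_genotypes(rng, n, p, ids)
    resp = pd.DataFrame({"subject_id": ids, "family_id": ["f"] * n})
    Y = rng.dirichlet([2, 2, 2], size=n)
    resp[["y1", "y2", "y3"]] = Y
    scan = snp_scan(resp, geno, models=("M1",))
    assert len(scan) == p
    pv = scan["p_M1"].to_numpy()
    assert np.all((pv > 0) & (pv <= 1))


def test_scan_rejects_orphan_subjects(rng):
    geno = _toy_genotypes(rng, 10, 3, [f"s{i}" for i in range(10)])
    resp = pd.DataFrame({"subject_id": ["other"], "family_id": ["f"],
                         "y1": [0.3], "y2": [0.3], "y3": [0.4]})
    with pytest.raises(ValueError, match="other"):
        snp_scan(resp, geno, models=("M1",))


def test_scan_drops_missing_dosage_per_marker_and_flags_monomorphic(rng):
    n = 100
    ids = [f"s{i}" for i in range(n)]
    geno = _toy_genotypes(rng, n, 3, ids)
    geno.dosage[:10, 0] = np.nan       # partial missing: still testable
    geno.dosage[:, 1] = 1.0            # monomorphic: no dosage variance
    resp = pd.DataFrame({"subject_id": ids, "family_id": ["f"] * n})
    resp[["y1", "y2", "y3"]] = rng.dirichlet([2, 2, 2], size=n)
    scan = snp_scan(resp, geno, models=("M1",))
    assert np.isfinite(scan["p_M1"].iloc[0])
    assert not scan["converged_M1"].iloc[1]
    assert np.isnan(scan["p_M1"].iloc[1])


def test_scan_strong_effect_is_minimum(rng):
    n, p = 400, 25
    ids = [f"s{i}" for i in range(n)]
    geno = _toy_genotypes(rng, n, p, ids)
    g = geno.dosage[:, 0]
    lam = np.exp(np.log(2) + np.outer(g, [1.0, 0.0, -1.0]))
    Y = np.stack([rng.dirichlet(l) for l in lam])
    resp = pd.DataFrame({"subject_id": ids, "family_id": ["f"] * n})
    resp[["y1", "y2", "y3"]] = Y
    scan = snp_scan(resp, geno, models=("M1",))
    assert scan["p_M1"].idxmin() == 0
    assert scan["significant"].iloc[0]
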
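"""Linear mixed models with crossed random intercepts.

Fits the Gaussian model

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma^2 I)

where each Z_k is the indicator matrix of a grouping factor (individual,
plot, year) and the factors may be fully crossed.  The variance ratios
theta_k = sigma_k^2 / sigma^2 are profiled out of the (restricted)
likelihood through the penalized-least-squares representation: for a
given theta the random effects and fixed effects solve one sparse
augmented normal system, and the criterion

    log|A(theta)| + log|Rx'Rx| + (n - p) (1 + log(2 pi pwrss / (n - p)))

(REML; the ML version uses n in place of n - p and drops the fixed-effect
determinant) is minimised over theta >= 0 with L-BFGS-B.  Sparse LU
factorisations keep each evaluation cheap even with thousands of random
levels, which is what makes replicate-based parameter-recovery testing
affordable.

Wald confidence intervals use sigma^2 (Rx'Rx)^{-1}; variance components
are reported as (variance, sd) without intervals, matching the summary
layout of the analysis tables.  AIC is always computed from the ML
criterion (refit when the primary fit is REML) so that fixed-effect
structures can be compared.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .design import ModelSpec, build_design
from .results import FitResult

_LOG2PI = np.log(2 * np.pi)


def _indicator(codes: np.ndarray) -> tuple[sp.csr_matrix, int]:
    levels, idx = np.unique(codes, return_inverse=True)
    n, q = len(codes), len(levels)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, q)
    )
    return Z, q


class _PLS:
    """Penalized least squares workspace for one dataset."""

    def __init__(self, y, X, factors: dict[str, np.ndarray]):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.names = list(factors)
        Zs, self.qs = [], []
        for codes in factors.values():
            Z, q = _indicator(np.asarray(codes))
            Zs.append(Z)
            self.qs.append(q)
        self.Z = sp.hstack(Zs, format="csr") if Zs else sp.csr_matrix((self.n, 0))
        self.q = sum(self.qs)
        self.ZtZ = (self.Z.T @ self.Z).tocsc()
        self.ZtX = np.asarray(self.Z.T @ self.X)
        self.Zty = np.asarray(self.Z.T @ self.y)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.block = np.repeat(np.arange(len(self.qs)), self.qs)

    def solve(self, sqrt_theta: np.ndarray):
        lam = sqrt_theta[self.block] if self.q else np.zeros(0)
        A = sp.diags(lam) @ self.ZtZ @ sp.diags(lam) + sp.eye(self.q, format="csc")
        lu = splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
        logdet_A = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        B = lam[:, None] * self.ZtX  # q x p
        a = lam * self.Zty
        AinvB = lu.solve(B) if self.q else B
        Ainva = lu.solve(a) if self.q else a
        S = self.XtX - B.T @ AinvB
        rhs = self.Xty - B.T @ Ainva
        try:
            beta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            # degenerate designs (e.g. one observation per random level on
            # noiseless data) make S singular; fall back to a least-norm fit
            beta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        u = Ainva - AinvB @ beta
        fitted = self.X @ beta + (self.Z @ (lam * u) if self.q else 0.0)
        pwrss = float(np.sum((self.y - fitted) ** 2) + np.sum(u**2))
        return beta, u, lam, S, pwrss, logdet_A

    def deviance(self, sqrt_theta: np.ndarray, reml: bool) -> float:
        beta, u, lam, S, pwrss, logdet_A = self.solve(sqrt_theta)
        pwrss = max(pwrss, 1e-300)
        if reml:
            nmp = self.n - self.p
            sign, logdet_S = np.linalg.slogdet(S)
            return logdet_A + logdet_S + nmp * (1 + np.log(2 * np.pi * pwrss / nmp))
        return logdet_A + self.n * (1 + np.log(2 * np.pi * pwrss / self.n))


def fit_lmm(
    df: pd.DataFrame,
    spec: ModelSpec,
    reml: bool = True,
    zero_offset: float | None = None,
) -> FitResult:
    """Fit a crossed random-intercepts LMM described by ``spec``.

    ``spec.transform == 'log'`` fits the natural log of the response;
    ``zero_offset`` is added inside the log for zero responses only (the
    count of such rows is logged in the result metadata).
    """
    y = df[spec.response].astype(float).to_numpy()
    n_zero = 0
    if spec.transform == "log":
        n_zero = int(np.sum(y == 0))
        if zero_offset is not None:
            y = np.where(y == 0, y + zero_offset, y)
        if np.any(y <= 0):
            raise ValueError("log transform requires positive response")
        y = np.log(y)
    X, names = build_design(df, spec)
    factors = {r: df[r].to_numpy() for r in spec.random}
    return _fit_arrays(
        y, X, names, factors, reml=reml, extra_meta={"n_zero_offset_rows": n_zero}
    )


def _fit_arrays(
    y, X, names, factors, reml=True, extra_meta=None
) -> FitResult:
    pls = _PLS(y, X, factors)
    k = len(pls.qs)

    def objective(s):
        return pls.deviance(np.abs(s), reml)

    if k:
        res = optimize.minimize(
            objective,
            x0=np.full(k, 1.0),
            method="L-BFGS-B",
            bounds=[(0.0, None)] * k,
            options={"ftol": 1e-12, "gtol": 1e-8},
        )
        s_hat = np.abs(res.x)
    else:
        s_hat = np.zeros(0)

    beta, u, lam, S, pwrss, logdet_A = pls.solve(s_hat)
    dof = pls.n - pls.p if reml else pls.n
    sigma2 = pwrss / dof
    try:
        cov_beta = sigma2 * np.linalg.inv(S)
    except np.linalg.LinAlgError:
        cov_beta = sigma2 * np.linalg.pinv(S)
    se = np.sqrt(np.diag(cov_beta))
    z = norm.ppf(0.975)
    p = 2 * norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf))
    fe = pd.DataFrame(
        {
            "estimate": beta,
            "ci_low": beta - z * se,
            "ci_high": beta + z * se,
            "p": p,
        },
        index=names,
    )
    var_k = s_hat**2 * sigma2
    re = pd.DataFrame(
        {"variance": np.r_[var_k, sigma2], "sd": np.sqrt(np.r_[var_k, sigma2])},
        index=list(pls.names) + ["residual"],
    )
    singular = [nm for nm, v in zip(pls.names, var_k) if v < 1e-10]
    if singular:
        warnings.warn(f"singular random-effect fit, variance ~0 for {singular}")

    dev = pls.deviance(s_hat, reml)
    # AIC must come from the ML criterion so fixed-effect structures compare
    if reml and k:
        res_ml = optimize.minimize(
            lambda s: pls.deviance(np.abs(s), False),
            x0=np.where(s_hat > 0, s_hat, 0.1),
            method="L-BFGS-B",
            bounds=[(0.0, None)] * k,
            options={"ftol": 1e-12},
        )
        ml_dev = float(res_ml.fun)
    else:
        ml_dev = float(pls.deviance(s_hat, False))
    n_par = pls.p + k + 1
    aic = ml_dev + 2 * n_par
    meta = {
        "reml": reml,
        "converged": True,
        "ml_deviance": ml_dev,
        "n_params": n_par,
        "singular": singular,
    }
    meta.update(extra_meta or {})
    return FitResult(
        fixed_effects=fe,
        random_effects=re,
        aic=float(aic),
        n_obs=pls.n,
        n_groups={nm: int(q) for nm, q in zip(pls.names, pls.qs)},
        loglike=-0.5 * dev,
        metadata=meta,
    )
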
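"""Dense REML fitter for linear mixed models with crossed/nested random
intercepts and optionally group-specific residual variances.

The restricted log-likelihood is maximized by L-BFGS-B over the logs of
the variance components, with an analytic gradient.  Fixed effects are
profiled out (GLS at the current covariance).  The log parameterization
keeps every component positive; a component driven to the lower bound is
effectively zero.

This is deliberately a direct dense implementation — covariance matrices
here are at most a few thousand observations — chosen for transparency
and easy verification against naive likelihood evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelResult:
    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    cov_beta: np.ndarray
    variance_components: dict[str, float]
    reml_loglik: float
    converged: bool
    n_obs: int

    def wald_contrast(self, contrast: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and two-sided normal p-value of c'beta."""
        from scipy import stats
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        if se == 0:
            return est, 0.0, 1.0 if est == 0 else 0.0
        z = est / se
        return est, se, float(2.0 * stats.norm.sf(abs(z)))


def _group_sum_rows(mat: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum rows of ``mat`` by group label; label -1 rows are ignored."""
    out = np.zeros((n_groups,) + mat.shape[1:])
    valid = labels >= 0
    np.add.at(out, labels[valid], mat[valid])
    return out


class _RemlProblem:
    def __init__(self, y, X, random_factors, resid_groups):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n = len(self.y)
        if self.X.shape[0] != self.n:
            raise ValueError("X and y size mismatch")
        self.p = self.X.shape[1]
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.factor_names = list(random_factors)
        self.factor_labels = []
        self.factor_ngroups = []
        for name in self.factor_names:
            lab = np.asarray(random_factors[name])
            if lab.shape != (self.n,):
                raise ValueError(f"labels for {name!r} have wrong shape")
            lab = lab.astype(np.int64)
            self.factor_labels.append(lab)
            self.factor_ngroups.append(int(lab.max()) + 1 if (lab >= 0).any() else 0)
        if resid_groups is None:
            resid_groups = np.zeros(self.n, dtype=np.int64)
        self.resid_labels = np.asarray(resid_groups, dtype=np.int64)
        self.n_resid = int(self.resid_labels.max()) + 1
        self.resid_masks = [self.resid_labels == r for r in range(self.n_resid)]
        self.k = len(self.factor_names) + self.n_resid
        # precompute dense relationship matrices Z Z' per factor
        self.A = []
        for lab, q in zip(self.factor_labels, self.factor_ngroups):
            Z = np.zeros((self.n, q))
            valid = lab >= 0
            Z[np.flatnonzero(valid), lab[valid]] = 1.0
            self.A.append(Z @ Z.T)

    def build_v(self, sig2: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for r, mask in enumerate(self.resid_masks):
            V[np.diag_indices(self.n)] += np.where(mask, sig2[len(self.factor_names) + r], 0.0)
        for u, A in enumerate(self.A):
            if sig2[u] != 0:
                V += sig2[u] * A
        return V

    def neg_loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        sig2 = np.exp(theta)
        V = self.build_v(sig2)
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        Vi = linalg.cho_solve(cf, np.eye(self.n), check_finite=False)
        W = Vi @ self.X                      # V^-1 X
        C = self.X.T @ W                     # X' V^-1 X
        try:
            cC = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet_c = 2.0 * np.log(np.diag(cC[0])).sum()
        Viy = Vi @ self.y
        beta = linalg.cho_solve(cC, self.X.T @ Viy, check_finite=False)
        r = self.y - self.X @ beta
        Py = Vi @ r
        quad = float(r @ Py)
        ll = -0.5 * (logdet_v + logdet_c + quad
                     + (self.n - self.p) * _LOG2PI)
        grad = np.empty(self.k)
        WC = linalg.cho_solve(cC, W.T, check_finite=False).T   # W C^-1
        for u, (lab, q) in enumerate(zip(self.factor_labels, self.factor_ngroups)):
            if q == 0:
                grad[u] = 0.0
                continue
            # tr(Vi A_u)
            T = _group_sum_rows(Vi, lab, q)                   # Z' Vi
            valid = lab >= 0
            tr_vi = float(T[lab[valid], np.flatnonzero(valid)].sum())
            # tr(C^-1 W' A_u W) with W' A_u W = S' S, S = Z' W
            S = _group_sum_rows(W, lab, q)
            Sc = _group_sum_rows(WC, lab, q)
            tr_c = float((S * Sc).sum())
            gs = np.bincount(lab[valid], weights=Py[valid], minlength=q)
            quad_u = float((gs ** 2).sum())
            grad[u] = -0.5 * (tr_vi - tr_c - quad_u) * sig2[u]
        diag_vi = np.diag(Vi)
        diag_wcw = np.einsum("ij,ij->i", WC, W)
        for r_i, mask in enumerate(self.resid_masks):
            tr_p = float((diag_vi - diag_wcw)[mask].sum())
            quad_r = float((Py[mask] ** 2).sum())
            j = len(self.factor_names) + r_i
            grad[j] = -0.5 * (tr_p - quad_r) * sig2[j]
        return -ll, -grad

    def gls(self, sig2: np.ndarray):
        V = self.build_v(sig2)
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        Vi_X = linalg.cho_solve(cf, self.X, check_finite=False)
        C = self.X.T @ Vi_X
        cov_beta = np.linalg.inv(C)
        beta = cov_beta @ (Vi_X.T @ self.y)
        return beta, cov_beta


def fit_reml(y: np.ndarray, X: np.ndarray,
             random_factors: dict[str, np.ndarray],
             resid_groups: np.ndarray | None = None,
             beta_names: list[str] | None = None,
             theta0: np.ndarray | None = None,
             tol: float = 1e-8, max_iter: int = 500) -> MixedModelResult:
    """REML fit of ``y = X beta + sum_u Z_u b_u + e``.

    Parameters
    ----------
    random_factors
        Mapping factor name -> integer group labels per observation; a
        label of -1 removes the factor's effect for that observation
        (used e.g. for random effects switched off for parents).
    resid_groups
        Optional integer labels for group-specific residual variances
        (a diagonal variance structure); None fits one residual variance.
    """
    prob = _RemlProblem(y, X, random_factors, resid_groups)
    vary = float(np.var(prob.y)) or 1.0
    default0 = np.full(prob.k, np.log(vary / max(prob.k, 2)))
    bounds = [(np.log(vary) - 25.0, np.log(vary) + 6.0)] * prob.k
    starts = [default0, default0 + 1.0]
    if theta0 is not None:
        starts.insert(0, np.clip(np.asarray(theta0, float), bounds[0][0], bounds[0][1]))
    best = None
    for attempt, start in enumerate(starts):
        res = optimize.minimize(
            prob.neg_loglik_grad, start, jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success:
            break
    if not best.success:
        warnings.warn(f"REML optimizer did not report convergence: {best.message}")
    sig2 = np.exp(best.x)
    # components negligible relative to the response variance are zero
    sig2 = np.where(sig2 <= vary * 1e-7, 0.0, sig2)
    sig2_fit = np.maximum(sig2, np.exp(bounds[0][0]))
    beta, cov_beta = prob.gls(sig2_fit)
    names = (beta_names if beta_names is not None
             else [f"x{j}" for j in range(prob.p)])
    vc = {name: float(s) for name, s in zip(prob.factor_names, sig2)}
    if prob.n_resid == 1:
        vc["residual"] = float(sig2[-1])
    else:
        for r in range(prob.n_resid):
            vc[f"residual[{r}]"] = float(sig2[len(prob.factor_names) + r])
    out = MixedModelResult(
        beta=beta, beta_se=np.sqrt(np.diag(cov_beta)), beta_names=list(names),
        cov_beta=cov_beta, variance_components=vc,
        reml_loglik=float(-best.fun), converged=bool(best.success), n_obs=prob.n)
    out.theta = best.x  # warm-start handle for refits on related designs
    return out


def reml_loglik(y, X, random_factors, sig2_factors, sig2_resid,
                resid_groups=None) -> float:
    """Restricted log-likelihood at given variance components (utility for
    verification against independent optimizers)."""
    prob = _RemlProblem(y, X, random_factors, resid_groups)
    sig2 = np.concatenate([np.atleast_1d(np.asarray(sig2_factors, float)),
                           np.atleast_1d(np.asarray(sig2_resid, float))])
    nll, _ = prob.neg_loglik_grad(np.log(np.maximum(sig2, 1e-300)))
    return -nll
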
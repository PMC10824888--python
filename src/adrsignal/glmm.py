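"""Generalized linear mixed models by restricted pseudo-likelihood.

The estimation scheme is the doubly iterative linearisation used for GLMMs in
pharmacoepidemiology and elsewhere: at the current estimates the Poisson or
binomial model is expanded to first order, producing a working response

    z = eta + (y - mu) / (d mu / d eta)      with weights  w = Var(y | b)^-1 (d mu/d eta)^2

which behaves like a linear mixed model ``z = X beta + Z b + e`` with known
heteroscedastic error variance ``1/w``.  That working model is fitted by REML,
the random effects are re-predicted (BLUPs), the expansion point is updated,
and the cycle repeats until the fixed effects and variance components are
stable ("restricted pseudo-likelihood", RSPL).

The random-effect structure supported here is the one screening needs: each
random term is a per-group (per-ADR) coefficient on a supplied covariate, so
its design matrix has one column per group and the marginal covariance of the
working model is block diagonal by group.  All linear algebra exploits that:
the REML objective and its analytic gradient cost O(J s^3) for J groups of s
rows.  Variance components can be shared across groups (one parameter per
term, the default) or free per group (``var_structure="by_group"``).

Prediction standard errors for mixed combinations ``l_f' beta + l_r' b`` come
from the inverse of the mixed-model-equations coefficient matrix, i.e. the
covariance of ``(beta_hat - beta, b_hat - b)``, which is what a 95% interval
for an ADR-specific PRR/ROR requires.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "GLMM",
    "GLMMResults",
    "WorkingFit",
    "linearize",
    "reml_working_fit",
    "GlmmError",
    "ConvergenceError",
]

MU_FLOOR = 1e-8          # floor for conditional means / binomial variances
GAMMA_FLOOR = 1e-10      # variance components below this are treated as zero


class GlmmError(RuntimeError):
    pass


class ConvergenceError(GlmmError):
    """Raised when the outer RSPL loop or the inner REML optimizer fails.

    Carries the iteration trace in ``.trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


def linearize(family: str, y, eta, exposure, eps: float = MU_FLOOR):
    """First-order working response and weights at linear predictor ``eta``.

    Poisson/log with offset ``o = log(exposure)`` (``eta`` includes ``o``):
    ``mu = exp(eta)``, ``z = (eta - o) + (y - mu)/mu``, ``w = mu``.
    Binomial/logit with trials ``m = exposure``: ``p = expit(eta)``,
    ``z = eta + (y/m - p)/(p(1-p))``, ``w = m p (1-p)``.
    """
    y = np.asarray(y, float)
    eta = np.asarray(eta, float)
    exposure = np.asarray(exposure, float)
    if family == "poisson":
        mu = np.exp(eta)
        if np.any(mu < eps):
            warnings.warn("conditional mean underflow; flooring at eps", RuntimeWarning)
            mu = np.maximum(mu, eps)
        z = (eta - np.log(exposure)) + (y - mu) / mu
        w = mu
    elif family == "binomial":
        p = expit(eta)
        v = p * (1.0 - p)
        if np.any(v < eps):
            warnings.warn("binomial variance underflow; flooring at eps", RuntimeWarning)
            v = np.maximum(v, eps)
        z = eta + (y / exposure - p) / v
        w = exposure * v
    else:
        raise ValueError(f"unknown family {family!r}")
    return z, w


# ---------------------------------------------------------------------------
# working linear mixed model, REML


@dataclass
class WorkingFit:
    beta: np.ndarray            # (p,)
    gamma: np.ndarray           # (K, J) variance components (expanded)
    gamma_params: np.ndarray    # raw optimizer parameters ((K,) or (K*J,))
    blups: np.ndarray           # (K, J)
    cov_beta: np.ndarray        # (p, p)
    Vinv: np.ndarray            # (J, S, S) inverse marginal covariance blocks
    Vir: np.ndarray             # (J, S) V^-1 (z - X beta)
    neg2reml: float
    scale: float = 1.0
    objective_trace: list = field(default_factory=list)
    n_inner_iter: int = 0


def _neg2reml_parts(gam, z, w, X, terms):
    """-2 restricted log-likelihood of the working LMM and reusable pieces.

    All inputs are grid shaped: z, w (J,S); X (J,S,p); terms (K,J,S);
    gam (K,J).  Returns the objective, its gradient stacked as (K,J), and
    the quantities needed for estimates and predictions.
    """
    J, S, p = X.shape
    K = terms.shape[0]
    V = np.zeros((J, S, S))
    idx = np.arange(S)
    V[:, idx, idx] = 1.0 / w
    for k in range(K):
        zt = terms[k]
        V += gam[k][:, None, None] * zt[:, :, None] * zt[:, None, :]
    Vinv = np.linalg.inv(V)
    _, logdetV = np.linalg.slogdet(V)
    ViX = np.einsum("jab,jbp->jap", Vinv, X)
    XtViX = np.einsum("jap,jaq->pq", X, ViX)
    XtViz = np.einsum("jap,ja->p", ViX, z)
    Sb = np.linalg.inv(XtViX)
    beta = Sb @ XtViz
    r = z - X @ beta
    Vir = np.einsum("jab,jb->ja", Vinv, r)
    quad = float(np.einsum("ja,ja->", r, Vir))
    _, logdetXtViX = np.linalg.slogdet(XtViX)
    neg2 = float(logdetV.sum() + logdetXtViX + quad)
    # gradient wrt each gamma_kj: tr(P Vdot) - r'P Vdot P r  with Vdot = z_kj z_kj'
    grads = np.empty((K, J))
    for k in range(K):
        zt = terms[k]
        Viz = np.einsum("jab,jb->ja", Vinv, zt)
        t_quad = np.einsum("ja,ja->j", zt, Viz)               # z'V^-1 z
        u = np.einsum("jap,ja->jp", ViX, zt)                  # X_j'V_j^-1 z_kj
        t_fix = np.einsum("jp,pq,jq->j", u, Sb, u)
        t_res = np.einsum("ja,ja->j", zt, Vir) ** 2
        grads[k] = t_quad - t_fix - t_res
    return neg2, grads, beta, Sb, Vinv, Vir


def _expand_gamma(params, K, J, var_structure):
    if var_structure == "shared":
        return np.repeat(np.asarray(params, float)[:, None], J, axis=1)
    return np.asarray(params, float).reshape(K, J)


def reml_working_fit(z, w, X, terms, var_structure: str = "shared",
                     gamma0=0.1, estimate_scale: bool = False,
                     inner_tol: float = 1e-10, maxiter: int = 500) -> WorkingFit:
    """REML fit of the working linear mixed model.

    Variance components are maximised by bound-constrained quasi-Newton
    (L-BFGS-B, analytic gradient, lower bound 0); fixed effects and BLUPs
    then solve the mixed-model equations at the optimum.  With
    ``estimate_scale`` the residual scale phi of the pseudo-model is profiled
    out instead of being fixed at 1.
    """
    z = np.asarray(z, float)
    w = np.asarray(w, float)
    X = np.asarray(X, float)
    terms = np.asarray(terms, float)
    J, S, p = X.shape
    K = terms.shape[0]
    n = J * S

    if K == 0:
        # plain weighted least squares
        Xf = X.reshape(n, p)
        wf = w.reshape(n)
        zf = z.reshape(n)
        XtWX = Xf.T @ (wf[:, None] * Xf)
        Sb = np.linalg.inv(XtWX)
        beta = Sb @ (Xf.T @ (wf * zf))
        r = z - X @ beta
        scale = 1.0
        if estimate_scale:
            scale = float((wf * (zf - Xf @ beta) ** 2).sum() / (n - p))
            Sb = Sb * scale
        Vinv = np.zeros((J, S, S))
        Vinv[:, np.arange(S), np.arange(S)] = w / scale
        return WorkingFit(beta, np.zeros((0, J)), np.zeros(0), np.zeros((0, J)),
                          Sb, Vinv, np.einsum("jab,jb->ja", Vinv, r),
                          neg2reml=np.nan, scale=scale)

    n_par = K if var_structure == "shared" else K * J
    x0 = np.broadcast_to(np.asarray(gamma0, float).ravel(), (n_par,)).astype(float).copy()
    trace: list[float] = []
    last_value = [np.inf]

    if not estimate_scale:
        def objective(params):
            gam = _expand_gamma(params, K, J, var_structure)
            neg2, grads = _neg2reml_parts(gam, z, w, X, terms)[:2]
            g = grads.sum(axis=1) if var_structure == "shared" else grads.ravel()
            last_value[0] = neg2
            return neg2, g
        jac = True
    else:
        def objective(params):  # phi profiled out; numeric gradient
            gam = _expand_gamma(params, K, J, var_structure)
            val = _profiled_neg2(gam, z, w, X, terms)
            last_value[0] = val
            return val
        jac = None

    res = minimize(objective, x0, jac=jac, method="L-BFGS-B",
                   bounds=[(0.0, None)] * n_par,
                   callback=lambda xk: trace.append(last_value[0]),
                   options=dict(maxiter=maxiter, ftol=inner_tol, gtol=1e-9))
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise ConvergenceError(
            f"inner REML optimizer did not converge: {res.message}", trace)

    gam = _expand_gamma(res.x, K, J, var_structure)
    neg2, _, beta, Sb, Vinv, Vir = _neg2reml_parts(gam, z, w, X, terms)
    scale = 1.0
    if estimate_scale:
        r = z - X @ beta
        quad = float(np.einsum("ja,jab,jb->", r, Vinv, r))
        scale = quad / (n - p)
        gam = gam * scale
        Sb = Sb * scale
        Vinv = Vinv / scale
        Vir = Vir / scale
        neg2 = _profiled_neg2(gam / scale, z, w, X, terms)
    blups = np.empty((K, J))
    for k in range(K):
        blups[k] = gam[k] * np.einsum("ja,ja->j", terms[k], Vir)
    blups[gam < GAMMA_FLOOR] = 0.0
    return WorkingFit(beta, gam, res.x, blups, Sb, Vinv, Vir, neg2,
                      scale=scale, objective_trace=trace, n_inner_iter=res.nit)


def _profiled_neg2(gam, z, w, X, terms):
    """REML criterion with the residual scale profiled out."""
    J, S, p = X.shape
    n = J * S
    neg2, _, beta, Sb, Vinv, _ = _neg2reml_parts(gam, z, w, X, terms)
    r = z - X @ beta
    quad = float(np.einsum("ja,jab,jb->", r, Vinv, r))
    logdet_part = neg2 - quad
    phi = quad / (n - p)
    return logdet_part + (n - p) * (1.0 + np.log(phi))


# ---------------------------------------------------------------------------
# the model object


class GLMM:
    """Poisson or binomial mixed model with per-group random coefficients.

    Parameters
    ----------
    y : array (n,)
        Event counts, one row per (group, stratum) cell.
    exposure : array (n,)
        Poisson: denominator entering as offset ``log(exposure)``;
        binomial: number of trials.
    X : array (n, p)
        Fixed-effect design.
    groups : array (n,)
        Group label (the ADR) of each row.  Every group must contain the
        same number of rows.
    random_terms : dict name -> array (n,)
        Each entry defines one random term: a per-group coefficient on the
        given covariate (1s for a random intercept).
    family : {"poisson", "binomial"}
    var_structure : {"shared", "by_group"}
        One variance component per term, or one per term and group.
    scale_fixed : bool
        Keep the pseudo-model residual scale at 1 (the exact-family
        assumption).  If False the scale is profiled in the REML step.
    """

    def __init__(self, y, exposure, X, groups, random_terms=None,
                 family: str = "poisson", var_structure: str = "shared",
                 scale_fixed: bool = True, fixed_names=None):
        if family not in ("poisson", "binomial"):
            raise ValueError(f"unknown family {family!r}")
        if var_structure not in ("shared", "by_group"):
            raise ValueError(f"unknown var_structure {var_structure!r}")
        self.family = family
        self.var_structure = var_structure
        self.scale_fixed = scale_fixed
        y = np.asarray(y, float)
        exposure = np.asarray(exposure, float)
        X = np.atleast_2d(np.asarray(X, float))
        n, p = X.shape
        if not (len(y) == len(exposure) == n):
            raise ValueError("y, exposure and X must have matching rows")
        groups = np.asarray(groups)
        if len(groups) != n:
            raise ValueError("groups must have one entry per row")
        self.fixed_names = list(fixed_names) if fixed_names is not None else [
            f"x{i}" for i in range(p)]
        if len(self.fixed_names) != p:
            raise ValueError("fixed_names length must match X columns")
        self._check_rank(X)

        random_terms = dict(random_terms or {})
        self.term_names = list(random_terms)
        self.group_names, codes = np.unique(groups, return_inverse=True)
        J = len(self.group_names)
        counts = np.bincount(codes)
        if len(set(counts)) > 1:
            raise ValueError("all groups must contain the same number of rows")
        S = int(counts[0])
        order = np.lexsort((np.arange(n), codes))
        self._order = order              # original row -> grid position
        self._grid_shape = (J, S)
        self.y = y[order].reshape(J, S)
        self.exposure = exposure[order].reshape(J, S)
        self.X = X[order].reshape(J, S, p)
        self.terms = np.stack(
            [np.asarray(random_terms[name], float)[order].reshape(J, S)
             for name in self.term_names]) if self.term_names else np.zeros((0, J, S))

    @staticmethod
    def _check_rank(X):
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        if diag.size and (diag < 1e-10 * diag[0]).any():
            j = int(piv[int(np.argmax(diag < 1e-10 * diag[0]))])
            raise ValueError(f"fixed-effect design is rank deficient; "
                             f"column {j} is aliased")

    # -- RSPL outer loop ----------------------------------------------------

    def fit(self, gamma_start: float = 0.1, maxiter: int = 100,
            tol: float = 1e-8, inner_tol: float = 1e-12) -> "GLMMResults":
        J, S = self._grid_shape
        K = len(self.term_names)
        beta = self._init_beta()
        b = np.zeros((K, J))
        gamma_params = np.full(K if self.var_structure == "shared" else K * J,
                               gamma_start)
        trace = []
        converged = False
        wf = None
        for it in range(maxiter):
            eta = self._eta(beta, b)
            z, w = linearize(self.family, self.y, eta, self.exposure)
            wf = reml_working_fit(z, w, self.X, self.terms,
                                  var_structure=self.var_structure,
                                  gamma0=gamma_params,
                                  estimate_scale=not self.scale_fixed,
                                  inner_tol=inner_tol)
            old = np.concatenate([beta, np.atleast_1d(gamma_params)])
            new = np.concatenate([wf.beta, np.atleast_1d(wf.gamma_params)])
            delta = float(np.max(np.abs(new - old) / (np.abs(old) + 1e-2))) if old.size else 0.0
            beta, b, gamma_params = wf.beta, wf.blups, wf.gamma_params
            trace.append({"iter": it, "beta": beta.copy(),
                          "gamma": np.atleast_1d(gamma_params).copy(),
                          "neg2reml": wf.neg2reml, "delta": delta})
            if delta < tol:
                converged = True
                break
            # stall detection: the fixed point can oscillate at the inner
            # optimizer's precision floor; accept once the REML objective and
            # all parameters are stable far below statistical precision
            if it >= 5 and delta < 1e-5:
                f_now, f_prev = trace[-1]["neg2reml"], trace[-2]["neg2reml"]
                if abs(f_now - f_prev) < 1e-9 * (1.0 + abs(f_now)):
                    converged = True
                    break
        if not converged:
            raise ConvergenceError(
                f"RSPL outer loop did not converge in {maxiter} iterations "
                f"(last delta={trace[-1]['delta']:.3g})", trace)
        eta = self._eta(beta, b)
        z, w = linearize(self.family, self.y, eta, self.exposure)
        return GLMMResults(self, wf, z, w, trace, converged=True)

    def _init_beta(self):
        """Fixed-effects-only IRLS starting values."""
        J, S = self._grid_shape
        p = self.X.shape[2]
        beta = np.zeros(p)
        off = np.log(self.exposure) if self.family == "poisson" else 0.0
        Xf = self.X.reshape(J * S, p)
        for _ in range(50):
            eta = off + self.X @ beta
            z, w = linearize(self.family, self.y, eta, self.exposure)
            wf = w.reshape(-1)
            zf = z.reshape(-1)
            XtWX = Xf.T @ (wf[:, None] * Xf)
            new = np.linalg.solve(XtWX, Xf.T @ (wf * zf))
            if np.max(np.abs(new - beta) / (np.abs(beta) + 1e-2)) < 1e-10:
                beta = new
                break
            beta = new
        return beta

    def _eta(self, beta, b):
        off = np.log(self.exposure) if self.family == "poisson" else 0.0
        eta = off + self.X @ beta
        for k in range(len(self.term_names)):
            eta = eta + self.terms[k] * b[k][:, None]
        return eta


class GLMMResults:
    """Fitted state: estimates, variance components, BLUPs, prediction SEs."""

    def __init__(self, model: GLMM, wf: WorkingFit, z, w, trace, converged):
        self.model = model
        self.params = wf.beta
        self.gamma = wf.gamma                     # (K, J)
        self.blups = wf.blups                     # (K, J)
        self.scale = wf.scale
        self.converged = converged
        self.n_outer_iter = len(trace)
        self.trace = trace
        self._Sb = wf.cov_beta
        self._Vinv = wf.Vinv
        self._Vir = wf.Vir
        self._z = z
        self._w = w
        self._ViX = np.einsum("jab,jbp->jap", wf.Vinv, model.X)

    # -- basic accessors ----------------------------------------------------

    def cov_params(self) -> np.ndarray:
        return self._Sb

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self._Sb))

    @property
    def vcomp(self) -> dict:
        out = {}
        for k, name in enumerate(self.model.term_names):
            g = self.gamma[k]
            out[name] = float(g[0]) if self.model.var_structure == "shared" else g.copy()
        return out

    @property
    def random_effects(self) -> pd.DataFrame:
        return pd.DataFrame(self.blups.T, index=self.model.group_names,
                            columns=self.model.term_names)

    # -- prediction of mixed combinations ------------------------------------

    def _u(self, k):
        """X_j' V_j^-1 z_kj for every group j: (J, p)."""
        return np.einsum("jap,ja->jp", self._ViX, self.model.terms[k])

    def predict_combo(self, lf, random=None):
        """Estimate and prediction SE of ``lf' beta + sum coef * b[term, group]``.

        ``random`` maps ``(term_name, group_label)`` to a coefficient.  The SE
        is the square root of the corresponding quadratic form in the inverse
        mixed-model-equations coefficient matrix.
        """
        lf = np.asarray(lf, float)
        if lf.shape != self.params.shape:
            raise ValueError("fixed coefficient vector has wrong length")
        random = dict(random or {})
        est = float(lf @ self.params)
        var = float(lf @ self._Sb @ lf)
        keys = []
        for (term, group), coef in random.items():
            if term not in self.model.term_names:
                raise KeyError(f"unknown random term {term!r}")
            jmatch = np.nonzero(self.model.group_names == group)[0]
            if not len(jmatch):
                raise KeyError(f"unknown group {group!r}")
            keys.append((self.model.term_names.index(term), int(jmatch[0]), coef))
        for k, j, coef in keys:
            est += coef * self.blups[k, j]
            g = self.gamma[k, j]
            u = self._u(k)[j]
            var += 2 * coef * float(-(lf @ self._Sb @ u) * g)
        for k, j, ck in keys:
            gk = self.gamma[k, j]
            uk = self._u(k)[j]
            for k2, j2, ck2 in keys:
                g2 = self.gamma[k2, j2]
                u2 = self._u(k2)[j2]
                c22 = float(uk @ self._Sb @ u2) * gk * g2
                if j == j2:
                    zk = self.model.terms[k][j]
                    z2 = self.model.terms[k2][j2]
                    c22 += (gk if (k == k2) else 0.0) - gk * float(
                        zk @ self._Vinv[j] @ z2) * g2
                var += ck * ck2 * c22
        return est, float(np.sqrt(max(var, 0.0)))

    def group_combos(self, lf, term: str) -> pd.DataFrame:
        """Vectorised ``lf' beta + b[term, j]`` with prediction SE for all groups."""
        lf = np.asarray(lf, float)
        k = self.model.term_names.index(term)
        g = self.gamma[k]
        zt = self.model.terms[k]
        u = self._u(k)                                   # (J, p)
        zViz = np.einsum("ja,jab,jb->j", zt, self._Vinv, zt)
        c22 = g - g * zViz * g + g * np.einsum("jp,pq,jq->j", u, self._Sb, u) * g
        c12 = -(u @ self._Sb) * g[:, None]               # (J, p)
        var = float(lf @ self._Sb @ lf) + 2 * (c12 @ lf) + c22
        est = float(lf @ self.params) + self.blups[k]
        return pd.DataFrame({"group": self.model.group_names, "estimate": est,
                             "se": np.sqrt(np.clip(var, 0.0, None))})

    # -- dense cross-checks ---------------------------------------------------

    def joint_cov(self) -> np.ndarray:
        """Dense inverse of the mixed-model-equations coefficient matrix.

        Column order: fixed effects, then per term the J group coefficients.
        Intended for small problems and validation; the screening paths use
        the equivalent blockwise formulas.
        """
        model = self.model
        J, S = model._grid_shape
        p = model.X.shape[2]
        K = len(model.term_names)
        n = J * S
        Xf = model.X.reshape(n, p)
        wf = self._w.reshape(n)
        Z = np.zeros((n, K * J))
        for k in range(K):
            for j in range(J):
                Z[j * S:(j + 1) * S, k * J + j] = model.terms[k, j]
        Ginv = np.diag(1.0 / np.maximum(self.gamma.reshape(K * J), GAMMA_FLOOR))
        W = wf / self.scale
        C = np.block([
            [Xf.T @ (W[:, None] * Xf), Xf.T @ (W[:, None] * Z)],
            [Z.T @ (W[:, None] * Xf), Z.T @ (W[:, None] * Z) + Ginv],
        ])
        return np.linalg.inv(C)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"{self.model.family} mixed model (restricted pseudo-likelihood)",
            f"groups: {len(self.model.group_names)}   "
            f"rows: {self.model.y.size}   outer iterations: {self.n_outer_iter}",
            "fixed effects:",
        ]
        for name, est, se in zip(self.model.fixed_names, self.params, self.bse()):
            lines.append(f"  {name:<16} {est: .6g}  (se {se:.6g})")
        lines.append("variance components:")
        for name, g in self.vcomp.items():
            if np.ndim(g) == 0:
                lines.append(f"  {name:<16} {g:.6g}")
            else:
                lines.append(f"  {name:<16} per-group, mean {np.mean(g):.6g}")
        if not self.model.scale_fixed:
            lines.append(f"residual scale: {self.scale:.6g}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "family": self.model.family,
            "fixed_names": self.model.fixed_names,
            "beta": self.params.tolist(),
            "beta_se": self.bse().tolist(),
            "gamma": {name: (v.tolist() if np.ndim(v) else v)
                      for name, v in self.vcomp.items()},
            "scale": self.scale,
            "converged": self.converged,
            "n_outer_iter": self.n_outer_iter,
            "trace": [{"iter": t["iter"], "neg2reml": t["neg2reml"],
                       "delta": t["delta"]} for t in self.trace],
            "blups": {name: self.blups[k].tolist()
                      for k, name in enumerate(self.model.term_names)},
            "groups": [str(g) for g in self.model.group_names],
        }
        return json.dumps(payload)
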
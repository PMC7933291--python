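"""Bivariate (and univariate) GREML by average-information REML.

The model treats one trait measured in two populations as two traits: with
phenotypes stacked population-1-first,

    V = sum_k [ Vg1_k A11_k   C_k A12_k ]  +  [ Ve1 I    0    ]
              [ C_k A21_k   Vg2_k A22_k ]     [  0    Ve2 I   ]

where A_k is the k-th genomic relationship matrix over the combined sample.
No individual appears in both populations, so the residual cross-population
covariance is identically zero.  V is linear in every parameter, which makes
the REML score and average-information (AI) matrix exact and cheap given an
explicit projection matrix P.

Per accepted iteration the REML log-likelihood never decreases: an AI step
that leaves the feasible region or lowers the likelihood is halved up to
five times, then replaced by an EM step for the variance components (with a
damped AI step for the unconstrained covariances, which an EM update cannot
move off zero).  Variance components are bounded below at 1e-6 of the
phenotypic variance; the genetic covariance C is unconstrained, so the
derived r_g may exceed 1 in small samples.  The inverse AI matrix at
convergence is the sampling covariance matrix of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.linalg.lapack import dpotrf, dpotri
from scipy.stats import chi2

from .rg_diff import var_rg_delta

__all__ = [
    "BivariateModel",
    "GREMLFit",
    "reml_fit",
    "univariate_fit",
    "derive_rg",
    "wald_test",
    "reml_loglik",
]


@dataclass
class BivariateModel:
    """Stacked two-population variance-component model.

    ``y``: phenotypes, population 1 rows first; ``X``: fixed-effect design
    (population intercepts + covariates); ``grms``: one combined-sample
    n x n relationship matrix per genetic component; ``n1``: number of
    population-1 rows (``n1 == len(y)`` gives the univariate model).
    """

    y: np.ndarray
    X: np.ndarray
    grms: Sequence[np.ndarray]
    n1: int

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n or any(a.shape != (n, n) for a in self.grms):
            raise ValueError("dimensions of y, X and GRMs do not conform")
        if not 0 < self.n1 <= n:
            raise ValueError("n1 must lie in (0, n]")

    @property
    def n2(self) -> int:
        return len(self.y) - self.n1


@dataclass
class GREMLFit:
    param_names: list[str]
    estimates: np.ndarray
    sampling_cov: np.ndarray
    logL: float
    iterations: int
    converged: bool
    boundary: np.ndarray  # per-parameter: pinned at the lower bound
    n1: int
    n2: int
    n_components: int
    trace: list[float] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def subcov(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.param_names.index(n) for n in names]
        return self.sampling_cov[np.ix_(idx, idx)]


class _Problem:
    """Precomputed blocks and parameter bookkeeping for one REML fit."""

    def __init__(self, model: BivariateModel):
        self.y = np.asarray(model.y, dtype=float)
        # fixed effects enter only through their column space; an orthonormal
        # basis makes the REML logL invariant to reparameterization and
        # handles rank-deficient designs (e.g. a covariate already spanned)
        x = np.asarray(model.X, dtype=float)
        from scipy.linalg import qr

        q, r = qr(x, mode="economic", pivoting=False)[:2] if x.shape[1] == 1 else qr(
            x, mode="economic", pivoting=True
        )[:2]
        tol = np.abs(r).max() * max(x.shape) * np.finfo(float).eps
        rank = int(np.sum(np.abs(np.diag(r)) > tol))
        self.X = np.ascontiguousarray(q[:, :rank])
        self.grms = [np.asarray(a, dtype=float) for a in model.grms]
        self.n1 = model.n1
        self.n = len(self.y)
        self.n2 = self.n - self.n1
        self.K = len(self.grms)
        self.bivariate = self.n2 > 0
        # parameter layout: per component (vg1, vg2, c) or (vg); then ve(s)
        self.names: list[str] = []
        self.kinds: list[tuple[str, int]] = []
        for k in range(self.K):
            if self.bivariate:
                self.names += [f"Vg1_{k + 1}", f"Vg2_{k + 1}", f"C_{k + 1}"]
                self.kinds += [("vg1", k), ("vg2", k), ("c", k)]
            else:
                self.names += [f"Vg_{k + 1}"]
                self.kinds += [("vg1", k)]
        self.names += ["Ve1", "Ve2"] if self.bivariate else ["Ve"]
        self.kinds += [("ve1", -1), ("ve2", -1)] if self.bivariate else [("ve1", -1)]
        self.q = len(self.names)
        self.is_variance = np.array([kind != "c" for kind, _ in self.kinds])
        vp1 = self.y[: self.n1].var(ddof=1)
        vp2 = self.y[self.n1:].var(ddof=1) if self.bivariate else vp1
        self.floor = np.array(
            [1e-6 * (vp1 if kind in ("vg1", "ve1") else vp2) for kind, _ in self.kinds]
        )
        self.vp = (vp1, vp2)

    def start_neutral(self) -> np.ndarray:
        vp1, vp2 = self.vp
        theta = np.zeros(self.q)
        for i, (kind, _) in enumerate(self.kinds):
            if kind == "vg1":
                theta[i] = vp1 / (2 * self.K)
            elif kind == "vg2":
                theta[i] = vp2 / (2 * self.K)
            elif kind == "ve1":
                theta[i] = vp1 / 2
            elif kind == "ve2":
                theta[i] = vp2 / 2
        return theta

    def start_he(self) -> np.ndarray:
        """Haseman-Elston warm start: regress phenotype cross-products on
        the corresponding GRM blocks (off-diagonal entries only)."""
        theta = self.start_neutral()
        if self.K == 0:
            return theta
        X = self.X
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        r = self.y - X @ beta
        n1 = self.n1
        blocks = [("vg1", np.s_[:n1], np.s_[:n1])]
        if self.bivariate:
            blocks += [("vg2", np.s_[n1:], np.s_[n1:]), ("c", np.s_[:n1], np.s_[n1:])]
        for kind, s1, s2 in blocks:
            prods = np.outer(r[s1], r[s2])
            preds = [a[s1, s2] for a in self.grms]
            if s1 == s2:
                iu = np.triu_indices(prods.shape[0], 1)
                yv = prods[iu]
                Zv = np.stack([p[iu] for p in preds], axis=1)
            else:
                yv = prods.ravel()
                Zv = np.stack([p.ravel() for p in preds], axis=1)
            try:
                est, *_ = np.linalg.lstsq(Zv, yv, rcond=None)
            except np.linalg.LinAlgError:
                continue
            for k in range(self.K):
                i = [j for j, kd in enumerate(self.kinds) if kd == (kind, k)]
                if i:
                    theta[i[0]] = est[k]
        # sanitise: keep variances positive and residuals consistent
        for pop, (kindv, kinde) in enumerate((("vg1", "ve1"), ("vg2", "ve2"))):
            iv = [i for i, (kd, _) in enumerate(self.kinds) if kd == kindv]
            ie = [i for i, (kd, _) in enumerate(self.kinds) if kd == kinde]
            if not iv or not ie:
                continue
            vp = self.vp[pop]
            for i in iv:
                theta[i] = min(max(theta[i], 0.05 * vp / self.K), 0.95 * vp)
            theta[ie[0]] = max(vp - theta[iv].sum() if len(iv) else vp / 2, 0.05 * vp)
        ic = [i for i, (kd, _) in enumerate(self.kinds) if kd[0] == "c"]
        for i in ic:
            k = self.kinds[i][1]
            v1 = theta[self.names.index(f"Vg1_{k + 1}")]
            v2 = theta[self.names.index(f"Vg2_{k + 1}")]
            cap = 0.9 * np.sqrt(v1 * v2)
            theta[i] = float(np.clip(theta[i], -cap, cap))
        return theta

    def build_v(self, theta: np.ndarray) -> np.ndarray:
        n1 = self.n1
        v = np.zeros((self.n, self.n))
        for i, (kind, k) in enumerate(self.kinds):
            t = theta[i]
            if kind == "vg1":
                v[:n1, :n1] += t * self.grms[k][:n1, :n1]
            elif kind == "vg2":
                v[n1:, n1:] += t * self.grms[k][n1:, n1:]
            elif kind == "c":
                v[:n1, n1:] += t * self.grms[k][:n1, n1:]
                v[n1:, :n1] += t * self.grms[k][n1:, :n1]
            elif kind == "ve1":
                v[:n1, :n1] += t * np.eye(n1)
            elif kind == "ve2":
                v[n1:, n1:] += t * np.eye(self.n2)
        return v

    def vi_dot(self, i: int, vec: np.ndarray) -> np.ndarray:
        kind, k = self.kinds[i]
        n1 = self.n1
        out = np.zeros_like(vec)
        if kind == "vg1":
            out[:n1] = self.grms[k][:n1, :n1] @ vec[:n1]
        elif kind == "vg2":
            out[n1:] = self.grms[k][n1:, n1:] @ vec[n1:]
        elif kind == "c":
            out[:n1] = self.grms[k][:n1, n1:] @ vec[n1:]
            out[n1:] = self.grms[k][n1:, :n1] @ vec[:n1]
        elif kind == "ve1":
            out[:n1] = vec[:n1]
        elif kind == "ve2":
            out[n1:] = vec[n1:]
        return out

    def trace_pvi(self, i: int, p: np.ndarray) -> float:
        kind, k = self.kinds[i]
        n1 = self.n1
        if kind == "vg1":
            return float(np.sum(p[:n1, :n1] * self.grms[k][:n1, :n1]))
        if kind == "vg2":
            return float(np.sum(p[n1:, n1:] * self.grms[k][n1:, n1:]))
        if kind == "c":
            return 2.0 * float(np.sum(p[:n1, n1:] * self.grms[k][:n1, n1:]))
        if kind == "ve1":
            return float(np.trace(p[:n1, :n1]))
        return float(np.trace(p[n1:, n1:]))

    def decompose(self, theta: np.ndarray):
        """Return (logL, P, Py) or None if V(theta) is not positive definite."""
        v = np.asfortranarray(self.build_v(theta))  # LAPACK-native layout
        c, info = dpotrf(v, lower=1, overwrite_a=1)
        if info != 0:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        vinv, info = dpotri(c, lower=1, overwrite_c=1)
        if info != 0:
            return None
        vl = np.tril(vinv)
        d = np.diag(vl).copy()
        vinv = vl + vl.T
        np.fill_diagonal(vinv, d)
        w = vinv @ self.X
        xtvx = self.X.T @ w
        try:
            cf = cho_factor(xtvx)
        except np.linalg.LinAlgError:
            return None
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        p = vinv - w @ cho_solve(cf, w.T)  # symmetric by construction up to rounding
        py = p @ self.y
        logl = -0.5 * (logdet_v + logdet_x + float(self.y @ py))
        return logl, p, py


def reml_loglik(model: BivariateModel, theta: np.ndarray) -> float:
    """The explicit REML log-likelihood (constant terms dropped) at ``theta``.

    -2 logL = log|V| + log|X'V^-1 X| + y'Py.  Used by the direct-maximization
    oracle tests as well as internally.
    """
    prob = _Problem(model)
    dec = prob.decompose(np.asarray(theta, dtype=float))
    if dec is None:
        return -np.inf
    return dec[0]


def reml_fit(
    model: BivariateModel,
    max_iter: int = 100,
    tol: float = 1e-4,
    start: str = "neutral",
    verbose: bool = False,
) -> GREMLFit:
    """Maximize the REML likelihood by AI-REML with EM fallback.

    Convergence requires both |delta logL| < ``tol`` and a maximum relative
    parameter change < ``tol``.  Non-convergence after ``max_iter`` is
    flagged on the returned fit, never silent.
    """
    prob = _Problem(model)
    if prob.n < prob.X.shape[1] + prob.q:
        raise ValueError("fewer observations than fixed effects + variance parameters")
    theta = prob.start_he() if start == "he" else prob.start_neutral()
    dec = prob.decompose(theta)
    if dec is None:
        raise np.linalg.LinAlgError("V is not positive definite at the starting values")
    logl, p, py = dec
    trace = [logl]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = np.stack([prob.vi_dot(i, py) for i in range(prob.q)], axis=1)
        score = np.array(
            [-0.5 * (prob.trace_pvi(i, p) - float(py @ u[:, i])) for i in range(prob.q)]
        )
        pu = p @ u
        ai = 0.5 * (u.T @ pu)
        ai = (ai + ai.T) / 2.0

        accepted = None
        # active set: variances pinned at the floor whose score points
        # further down stay fixed this iteration
        pinned = prob.is_variance & (theta <= prob.floor * (1 + 1e-9)) & (score < 0)
        free = ~pinned
        # AI step with halving
        try:
            delta = np.zeros(prob.q)
            delta[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(6):  # full step + up to 5 halvings
                cand = _clamp(prob, theta + step * delta)
                dec = prob.decompose(cand)
                if dec is not None and dec[0] >= logl - 1e-10:
                    accepted = (cand, dec)
                    break
                step /= 2.0
        if accepted is None:
            # EM for the variance components, damped AI for covariances
            cand = theta.copy()
            for i in range(prob.q):
                if prob.is_variance[i] and free[i]:
                    cand[i] = theta[i] + 2.0 * theta[i] ** 2 * score[i] / prob.n
            lam = 1.0
            for _ in range(8):
                try:
                    d = np.zeros(prob.q)
                    aif = ai[np.ix_(free, free)]
                    d[free] = np.linalg.solve(
                        aif + lam * np.diag(np.diag(aif)), score[free]
                    )
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                trial = cand.copy()
                for i in range(prob.q):
                    if not prob.is_variance[i]:
                        trial[i] = theta[i] + d[i]
                trial = _clamp(prob, trial)
                dec = prob.decompose(trial)
                if dec is not None and dec[0] >= logl - 1e-8:
                    accepted = (trial, dec)
                    break
                lam *= 10.0
            if accepted is None:
                cand = _clamp(prob, cand)
                dec = prob.decompose(cand)
                if dec is not None:
                    accepted = (cand, dec)
        if accepted is None:
            break  # cannot improve; will be flagged unless already converged

        new_theta, (new_logl, p, py) = accepted
        scale = np.maximum(np.abs(theta), 1e-4 * max(prob.vp))
        rel_change = float(np.max(np.abs(new_theta - theta) / scale))
        dlogl = new_logl - logl
        theta, logl = new_theta, new_logl
        trace.append(logl)
        if verbose:
            print(f"iter {it}: logL={logl:.6f} dlogL={dlogl:.2e} max rel change={rel_change:.2e}")
        if abs(dlogl) < tol and rel_change < tol:
            converged = True
            break

    # sampling covariance from the AI matrix at the optimum
    u = np.stack([prob.vi_dot(i, py) for i in range(prob.q)], axis=1)
    ai = 0.5 * (u.T @ (p @ u))
    ai = (ai + ai.T) / 2.0
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((prob.q, prob.q), np.nan)
    boundary = prob.is_variance & (theta <= prob.floor * (1 + 1e-9))
    return GREMLFit(
        param_names=prob.names,
        estimates=theta,
        sampling_cov=cov,
        logL=logl,
        iterations=it,
        converged=converged,
        boundary=boundary,
        n1=prob.n1,
        n2=prob.n2,
        n_components=prob.K,
        trace=trace,
    )


def _clamp(prob: _Problem, theta: np.ndarray) -> np.ndarray:
    out = theta.copy()
    out[prob.is_variance] = np.maximum(out[prob.is_variance], prob.floor[prob.is_variance])
    return out


def univariate_fit(
    y: np.ndarray,
    X: np.ndarray,
    grms: Sequence[np.ndarray],
    **options,
) -> GREMLFit:
    """Single-population GREML: components Vg_k plus one residual variance."""
    model = BivariateModel(y=np.asarray(y, float), X=np.asarray(X, float),
                           grms=list(grms), n1=len(y))
    return reml_fit(model, **options)


def derive_rg(fit: GREMLFit, component: int = 1) -> dict:
    """r_g = C / sqrt(Vg1 Vg2) for one component, h^2 per population, with SEs.

    The r_g standard error evaluates the sampling-variance expression for a
    ratio of variance components (delta method on the fit's sampling
    covariance); h^2 SEs use the same machinery on Vg/(Vg+Ve).
    """
    if fit.n2 == 0:
        raise ValueError("derive_rg requires a bivariate fit")
    k = component
    vg1, vg2, c = fit[f"Vg1_{k}"], fit[f"Vg2_{k}"], fit[f"C_{k}"]
    out: dict = {"Vg1": vg1, "Vg2": vg2, "C": c}
    if vg1 <= 0 or vg2 <= 0:
        out.update({"rg": np.nan, "rg_se": np.nan, "defined": False})
    else:
        rg = c / np.sqrt(vg1 * vg2)
        names = [f"Vg1_{k}", f"Vg2_{k}", f"C_{k}"]
        var = var_rg_delta(np.array([vg1, vg2, c]), fit.subcov(names))
        out.update({"rg": rg, "rg_se": float(np.sqrt(max(var, 0.0))), "defined": True})
    for pop in (1, 2):
        vgs = [f"Vg{pop}_{j + 1}" for j in range(fit.n_components)]
        ve = f"Ve{pop}"
        s = sum(fit[n] for n in vgs)
        e = fit[ve]
        h2 = s / (s + e)
        grad = np.r_[np.full(len(vgs), e / (s + e) ** 2), -s / (s + e) ** 2]
        cov = fit.subcov(vgs + [ve])
        out[f"h2_pop{pop}"] = h2
        out[f"h2_pop{pop}_se"] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return out


def derive_h2(fit: GREMLFit) -> dict:
    """h^2 = sum_k Vg_k / (sum_k Vg_k + Ve) with SE, for a univariate fit."""
    if fit.n2 != 0:
        raise ValueError("derive_h2 is for univariate fits; use derive_rg")
    vgs = [f"Vg_{j + 1}" for j in range(fit.n_components)]
    s = sum(fit[n] for n in vgs)
    e = fit["Ve"]
    h2 = s / (s + e)
    grad = np.r_[np.full(len(vgs), e / (s + e) ** 2), -s / (s + e) ** 2]
    cov = fit.subcov(vgs + ["Ve"])
    return {"h2": h2, "h2_se": float(np.sqrt(max(grad @ cov @ grad, 0.0))), "Ve": e}


def wald_test(estimate: float, se: float, null_value: float = 1.0) -> tuple[float, float]:
    """Wald chi-square test of ``estimate == null_value``; returns (chi2, p)."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    stat = ((estimate - null_value) / se) ** 2
    return float(stat), float(chi2.sf(stat, df=1))
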
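"""Independent oracles shared by the GREML tests.

The REML oracle maximizes the explicit restricted log-likelihood
numerically (multi-start Nelder-Mead plus a bounded quasi-Newton polish
over the same feasible region: variance components floored at 1e-6 of the
phenotypic variance, genetic covariance free).  It shares nothing with the
AI-REML iteration beyond the likelihood definition itself.
"""

import numpy as np
from scipy.optimize import minimize

import crosspop as cp


def reml_oracle_loglik(model: cp.BivariateModel) -> float:
    """Best REML log-likelihood found by direct numerical maximization."""
    vp1 = model.y[: model.n1].var(ddof=1)
    vp2 = model.y[model.n1:].var(ddof=1)
    lo = np.array([1e-6 * vp1, 1e-6 * vp2, -np.inf, 1e-6 * vp1, 1e-6 * vp2])
    bounds = [(lo[i], None) if np.isfinite(lo[i]) else (None, None) for i in range(5)]

    def neg(theta):
        l = cp.reml_loglik(model, theta)
        return 1e8 if not np.isfinite(l) else -l

    starts = [
        [0.3, 0.3, 0.1, 0.7, 0.7],
        [0.5, 0.4, 0.3, 0.5, 0.6],
        [0.2, 0.2, 0.0, 0.8, 0.8],
        [0.7, 1e-5, 0.1, 0.3, 0.9],
        [1e-5, 0.7, 0.1, 0.9, 0.3],
    ]
    best = np.inf
    for x0 in starts:
        r = minimize(neg, x0, method="Nelder-Mead",
                     options=dict(xatol=1e-9, fatol=1e-11, maxiter=40000, maxfev=40000))
        if np.all(r.x >= lo - 1e-12):  # only feasible optima count
            best = min(best, r.fun)
        x = np.maximum(r.x, np.where(np.isfinite(lo), lo, -np.inf))
        r2 = minimize(neg, x, method="L-BFGS-B", bounds=bounds,
                      options=dict(ftol=1e-15, gtol=1e-12))
        best = min(best, r2.fun)
    return -best


def tiny_instance(seed: int, n_per_pop: int = 30, m: int = 100):
    """A tiny two-population GREML problem with its population-specific GRM."""
    from crosspop.pipeline import _simulate_polymorphic, _stack

    model = cp.PopulationModel(n_pop1=n_per_pop, n_pop2=n_per_pop, m=m, seed=seed)
    arch = cp.TraitArchitecture(m_causal=m // 2, rg_true=0.7, h2_pop1=0.5, h2_pop2=0.4)
    ds, y = _simulate_polymorphic(model, arch)
    grm = cp.compute_grm(ds, mode="specific")
    biv, _ = _stack(ds, y, [grm.matrix])
    return biv
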
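"""Sampling variance/covariance of r_g estimates and the difference test.

r_g = C / sqrt(Vg1 Vg2) is a smooth function of three variance-component
estimates, so its sampling variance follows from their joint sampling
covariance.  Two routes are implemented and kept deliberately separate:

* the explicit six-term bracket for var(r_hat_g) and nine-term bracket for
  cov(r_hat_g1, r_hat_g2) in terms of the component variances/covariances
  (coefficients 1/4 on variance-variance terms, 1/2 on variance-covariance
  cross terms, 1 on the C-C term), with parameters replaced by their
  estimates; and
* the generic delta method, gradient' * Sigma * gradient with
  gradient = (-r_g/(2 Vg1), -r_g/(2 Vg2), 1/sqrt(Vg1 Vg2)).

The two are the same algebraic object; the test suite asserts agreement to
1e-12, which guards the term-by-term transcription.  At C = 0 the bracket's
1/C^2 factors cancel against r_g^2 analytically; both functions switch to
the closed-form limit var = var(C_hat)/(Vg1 Vg2) (and the delta gradient,
which needs no limit) rather than dividing by zero.

The difference between two SNP sets fitted jointly is tested with
chi^2(1) = (r1 - r2)^2 / (var(r1) + var(r2) - 2 cov(r1, r2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = [
    "ComponentMoments",
    "var_rg",
    "var_rg_delta",
    "cov_rg_pair",
    "cov_rg_pair_delta",
    "chisq_diff_test",
    "rg_difference_report",
]

_C_TOL = 1e-10  # |C| below this (relative to sqrt(Vg1*Vg2)) uses the C->0 limit


@dataclass
class ComponentMoments:
    """Point estimates and joint sampling covariance of a two-set fit.

    ``estimates`` holds (Vg1_s, Vg2_s, C_s) for set s = 1, 2 in the order
    [Vg1_1, Vg2_1, C_1, Vg1_2, Vg2_2, C_2]; ``cov`` is their 6 x 6 sampling
    covariance (a slice of the joint AI-REML sampling_cov).
    """

    estimates: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.estimates.shape != (6,) or self.cov.shape != (6, 6):
            raise ValueError("expected 6 estimates and a 6x6 covariance")
        if not np.all(np.isfinite(self.estimates)) or not np.all(np.isfinite(self.cov)):
            raise ValueError("moments must be finite")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("sampling covariance must be symmetric")

    def set_params(self, s: int) -> np.ndarray:
        return self.estimates[3 * (s - 1): 3 * s]

    def set_cov(self, s: int) -> np.ndarray:
        i = slice(3 * (s - 1), 3 * s)
        return self.cov[i, i]

    def cross_cov(self) -> np.ndarray:
        """cov( (Vg1_1, Vg2_1, C_1), (Vg1_2, Vg2_2, C_2) ), a 3 x 3 block."""
        return self.cov[0:3, 3:6]


def _rg_grad(params: np.ndarray) -> np.ndarray:
    vg1, vg2, c = params
    rg = c / np.sqrt(vg1 * vg2)
    return np.array([-rg / (2 * vg1), -rg / (2 * vg2), 1.0 / np.sqrt(vg1 * vg2)])


def var_rg_delta(params: np.ndarray, cov: np.ndarray) -> float:
    """Generic delta-method var(r_hat_g); the independent cross-check route."""
    g = _rg_grad(np.asarray(params, float))
    return float(g @ np.asarray(cov, float) @ g)


def var_rg(params: np.ndarray, cov: np.ndarray) -> float:
    """The six-term sampling-variance bracket for r_hat_g, term by term.

    ``params`` = (Vg1, Vg2, C); ``cov`` their 3 x 3 sampling covariance.
    var(r_g) = r_g^2 [ var(Vg1)/(4 Vg1^2) + var(Vg2)/(4 Vg2^2) + var(C)/C^2
               + cov(Vg1,Vg2)/(2 Vg1 Vg2) - cov(Vg1,C)/(Vg1 C)
               - cov(Vg2,C)/(Vg2 C) ].
    """
    vg1, vg2, c = (float(x) for x in params)
    cov = np.asarray(cov, float)
    if vg1 <= 0 or vg2 <= 0:
        raise ValueError("var_rg requires Vg1 > 0 and Vg2 > 0")
    if abs(c) < _C_TOL * np.sqrt(vg1 * vg2):
        # analytic C -> 0 limit: r_g^2 * var(C)/C^2 -> var(C)/(Vg1 Vg2)
        return float(cov[2, 2] / (vg1 * vg2))
    rg2 = c * c / (vg1 * vg2)
    bracket = (
        cov[0, 0] / (4 * vg1 * vg1)
        + cov[1, 1] / (4 * vg2 * vg2)
        + cov[2, 2] / (c * c)
        + cov[0, 1] / (2 * vg1 * vg2)
        - cov[0, 2] / (vg1 * c)
        - cov[1, 2] / (vg2 * c)
    )
    return float(rg2 * bracket)


def cov_rg_pair_delta(moments: ComponentMoments) -> float:
    """Delta-method cov(r_hat_g1, r_hat_g2); the independent cross-check route."""
    g1 = _rg_grad(moments.set_params(1))
    g2 = _rg_grad(moments.set_params(2))
    return float(g1 @ moments.cross_cov() @ g2)


def cov_rg_pair(moments: ComponentMoments) -> float:
    """The nine-term sampling-covariance bracket between two SNP sets.

    cov(r1, r2) = r1 r2 [ cov(V11,V12)/(4 V11 V12) + cov(V11,V22)/(4 V11 V22)
        - cov(V11,C2)/(2 V11 C2) + cov(V21,V12)/(4 V21 V12)
        + cov(V21,V22)/(4 V21 V22) - cov(V21,C2)/(2 V21 C2)
        - cov(V12,C1)/(2 V12 C1) - cov(V22,C1)/(2 V22 C1)
        + cov(C1,C2)/(C1 C2) ]
    where Vps is the genetic variance in population p for SNP set s and Cs
    the cross-population genetic covariance of set s.
    """
    v11, v21, c1 = moments.set_params(1)
    v12, v22, c2 = moments.set_params(2)
    for v, lab in ((v11, "Vg1 set1"), (v21, "Vg2 set1"), (v12, "Vg1 set2"), (v22, "Vg2 set2")):
        if v <= 0:
            raise ValueError(f"cov_rg_pair requires positive genetic variances ({lab} = {v})")
    if abs(c1) < _C_TOL * np.sqrt(v11 * v21) or abs(c2) < _C_TOL * np.sqrt(v12 * v22):
        return cov_rg_pair_delta(moments)  # C -> 0 limit via the gradient form
    x = moments.cross_cov()  # rows: set-1 params, cols: set-2 params
    r1 = c1 / np.sqrt(v11 * v21)
    r2 = c2 / np.sqrt(v12 * v22)
    bracket = (
        x[0, 0] / (4 * v11 * v12)
        + x[0, 1] / (4 * v11 * v22)
        - x[0, 2] / (2 * v11 * c2)
        + x[1, 0] / (4 * v21 * v12)
        + x[1, 1] / (4 * v21 * v22)
        - x[1, 2] / (2 * v21 * c2)
        - x[2, 0] / (2 * v12 * c1)
        - x[2, 1] / (2 * v22 * c1)
        + x[2, 2] / (c1 * c2)
    )
    return float(r1 * r2 * bracket)


def chisq_diff_test(
    rg1: float, rg2: float, var1: float, var2: float, cov12: float
) -> tuple[float, float]:
    """chi^2(1) test of r_g1 == r_g2 from a joint fit; returns (chi2, p)."""
    var_diff = var1 + var2 - 2.0 * cov12
    if not var_diff > 0:
        raise ValueError(
            f"var(r1 - r2) = {var_diff} is not positive; the moments are inconsistent"
        )
    stat = (rg1 - rg2) ** 2 / var_diff
    return float(stat), float(chi2.sf(stat, df=1))


def rg_difference_report(moments: ComponentMoments) -> dict:
    """Full two-set comparison: r_g per set with SE, chi^2 and P_difference."""
    out = {}
    rgs, variances = [], []
    for s in (1, 2):
        vg1, vg2, c = moments.set_params(s)
        rg = c / np.sqrt(vg1 * vg2)
        var = var_rg(moments.set_params(s), moments.set_cov(s))
        out[f"rg_set{s}"] = float(rg)
        out[f"rg_set{s}_se"] = float(np.sqrt(max(var, 0.0)))
        rgs.append(float(rg))
        variances.append(var)
    cov12 = cov_rg_pair(moments)
    stat, p = chisq_diff_test(rgs[0], rgs[1], variances[0], variances[1], cov12)
    out.update({"cov_rg12": cov12, "chi2": stat, "p_difference": p})
    return out
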
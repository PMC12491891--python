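"""Bivariate-normal summary of the cost-effectiveness plane.

The incremental effectiveness dE (QALYs) and incremental cost dC (SEK) are
treated as bivariate normal — they are linear combinations of regression
coefficients, so this holds asymptotically by the central limit theorem.
All probabilities are then available analytically: the probability of
cost-effectiveness at threshold lambda is P(lambda*dE - dC > 0), a normal
CDF in the net monetary benefit, and the probability of dominance is an
orthant probability of the bivariate normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, multivariate_normal, norm

from .errors import ValidationError


@dataclass
class IncrementalResult:
    """(dE, dC) point estimates with their normal-theory uncertainty."""

    mean_e: float  # QALYs
    mean_c: float  # SEK
    se_e: float
    se_c: float
    rho: float = 0.0  # correlation of (dE, dC)

    def __post_init__(self) -> None:
        if self.se_e < 0 or self.se_c < 0:
            raise ValidationError("standard errors must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho {self.rho} outside [-1, 1]")

    @classmethod
    def from_confidence_intervals(
        cls,
        mean_e: float,
        ci_e: tuple[float, float],
        mean_c: float,
        ci_c: tuple[float, float],
        rho: float = 0.0,
        level: float = 0.95,
    ) -> "IncrementalResult":
        """Reconstruct from printed point estimates and CIs
        (SE = half-width / normal quantile; 1.96 at the 95% level)."""
        z = norm.ppf(0.5 + level / 2.0)
        return cls(
            mean_e=mean_e,
            se_e=(ci_e[1] - ci_e[0]) / 2.0 / z,
            mean_c=mean_c,
            se_c=(ci_c[1] - ci_c[0]) / 2.0 / z,
            rho=rho,
        )

    def nb_mean(self, lam: float) -> float:
        return lam * self.mean_e - self.mean_c

    def nb_sd(self, lam: float) -> float:
        var = (
            lam**2 * self.se_e**2
            + self.se_c**2
            - 2.0 * lam * self.rho * self.se_e * self.se_c
        )
        return float(np.sqrt(max(var, 0.0)))

    def ci_e(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return (self.mean_e - z * self.se_e, self.mean_e + z * self.se_e)

    def ci_c(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return (self.mean_c - z * self.se_c, self.mean_c + z * self.se_c)


@dataclass
class CEACCurve:
    """Cost-effectiveness acceptability curve on a threshold grid."""

    lambdas: np.ndarray
    prob_ce: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.prob_ce = np.asarray(self.prob_ce, dtype=float)
        if self.lambdas.shape != self.prob_ce.shape:
            raise ValidationError("lambda grid and probabilities differ in length")


def prob_cost_effective(inc: IncrementalResult, lam: float) -> float:
    """P(lambda*dE - dC > 0) under the bivariate-normal summary."""
    mu = inc.nb_mean(lam)
    sd = inc.nb_sd(lam)
    if sd == 0.0:
        return 0.5 if mu == 0.0 else float(mu > 0.0)
    return float(norm.cdf(mu / sd))


def prob_dominant(inc: IncrementalResult) -> float:
    """P(dE > 0 and dC < 0): the southeast-quadrant orthant probability."""
    if inc.se_e == 0.0 or inc.se_c == 0.0:
        pe = 0.5 if inc.mean_e == 0 else float(inc.mean_e > 0)
        pc = 0.5 if inc.mean_c == 0 else float(inc.mean_c < 0)
        if inc.se_e == 0.0 and inc.se_c == 0.0:
            return pe * pc
        if inc.se_e == 0.0:
            return pe * float(norm.cdf(-inc.mean_c / inc.se_c))
        return float(norm.cdf(inc.mean_e / inc.se_e)) * pc
    # P(dE > 0, dC < 0) = P(Z1 <= mean_e/se_e, Z2 <= -mean_c/se_c) for
    # standard normals with corr(Z1, Z2) = -rho (standardized for conditioning)
    r = float(np.clip(-inc.rho, -0.9999, 0.9999))
    upper = [inc.mean_e / inc.se_e, -inc.mean_c / inc.se_c]
    return float(
        multivariate_normal.cdf(upper, mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    )


def ceac(inc: IncrementalResult, lambdas: np.ndarray) -> CEACCurve:
    lambdas = np.asarray(lambdas, dtype=float)
    probs = np.array([prob_cost_effective(inc, lam) for lam in lambdas])
    return CEACCurve(lambdas=lambdas, prob_ce=probs)


def confidence_ellipse(inc: IncrementalResult, coverage: float) -> dict:
    """Coverage ellipse of the bivariate normal on the CE plane.

    Returns the center, the full lengths of the principal axes and the
    rotation (degrees, counterclockwise from the dE axis).
    """
    if not 0.0 <= coverage < 1.0:
        raise ValidationError("coverage must be in [0, 1)")
    cov = np.array(
        [
            [inc.se_e**2, inc.rho * inc.se_e * inc.se_c],
            [inc.rho * inc.se_e * inc.se_c, inc.se_c**2],
        ]
    )
    radius2 = chi2.ppf(coverage, df=2) if coverage > 0 else 0.0
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    angle = float(np.degrees(np.arctan2(eigvec[1, 0], eigvec[0, 0])))
    return {
        "center": (inc.mean_e, inc.mean_c),
        "width": float(2.0 * np.sqrt(radius2 * eigval[0])),
        "height": float(2.0 * np.sqrt(radius2 * eigval[1])),
        "angle_deg": angle,
        "coverage": coverage,
    }
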
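"""Closed-form value-of-information analysis.

Under the bivariate-normal summary of (dE, dC), the net monetary benefit
NB = lambda*dE - dC at threshold lambda is univariate normal, and the
expected value of perfect information per user is the unit normal loss
integral scaled by the NB standard deviation:

    EVPI = sigma_NB * L(|mu_NB| / sigma_NB),   L(z) = phi(z) - z*(1 - Phi(z)).

Partial perfect information on one component (dE or dC) uses the fact that
the conditional mean of NB given that component is linear in it, so the
same loss-integral formula applies with the slope-scaled marginal SD.
Population totals multiply the per-user value by the discounted number of
users over the adoption horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .cea_plane import IncrementalResult


@dataclass
class PopulationModel:
    """Adoption-population scaling: users per year over a fixed horizon,
    discounted annually.  ``timing='end'`` counts each year's users at the
    end of the year (years 1..H); ``'start'`` at the start (years 0..H-1)."""

    users_per_year: float = 988.0
    horizon_years: int = 5
    discount_rate: float = 0.03
    timing: str = "end"

    def __post_init__(self) -> None:
        if self.users_per_year <= 0 or self.horizon_years <= 0:
            raise ConfigurationError("population model must be positive")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.timing not in ("end", "start"):
            raise ConfigurationError(f"unknown timing {self.timing!r}")


@dataclass
class VOIResult:
    lam: float
    evpi_user: float
    evppi_e_user: float
    evppi_c_user: float
    n_discounted: float
    evpi_total: float
    evppi_e_total: float
    evppi_c_total: float


def unit_normal_loss(z) -> float | np.ndarray:
    """L(z) = phi(z) - z*(1 - Phi(z)), the expected shortfall of a standard
    normal below -z (equivalently E[(T - z)+])."""
    z = np.asarray(z, dtype=float)
    out = norm.pdf(z) - z * norm.sf(z)
    return float(out) if out.ndim == 0 else out


def evpi_per_user(inc: IncrementalResult, lam: float) -> float:
    """Expected opportunity loss per user of the current adopt/reject
    decision (the expected-NB maximizer)."""
    mu = inc.nb_mean(lam)
    sd = inc.nb_sd(lam)
    if sd == 0.0:
        return 0.0
    return float(sd * unit_normal_loss(abs(mu) / sd))


def evppi_per_user(inc: IncrementalResult, lam: float, component: str) -> float:
    """Expected value of perfect information on dE ('effect') or dC ('cost').

    E[NB | X] is linear in the learned component X with slope
    s = lambda - rho*se_c/se_e (effect) or s = lambda*rho*se_e/se_c - 1
    (cost); the opportunity loss then follows the univariate loss-integral
    formula with scale |s|*sd(X).
    """
    mu = inc.nb_mean(lam)
    if component == "effect":
        if inc.se_e == 0.0:
            return 0.0
        slope = lam - inc.rho * inc.se_c / inc.se_e
        scale = abs(slope) * inc.se_e
    elif component == "cost":
        if inc.se_c == 0.0:
            return 0.0
        slope = lam * inc.rho * inc.se_e / inc.se_c - 1.0
        scale = abs(slope) * inc.se_c
    else:
        raise ConfigurationError(f"unknown component {component!r}")
    if scale == 0.0:
        return 0.0
    return float(scale * unit_normal_loss(abs(mu) / scale))


def discounted_users(pop: PopulationModel) -> float:
    """Sum of annual user cohorts discounted to present."""
    offset = 1 if pop.timing == "end" else 0
    years = np.arange(pop.horizon_years) + offset
    return float(np.sum(pop.users_per_year / (1.0 + pop.discount_rate) ** years))


def breakeven_dev_cost(inc: IncrementalResult, lam: float, pop: PopulationModel) -> float:
    """One-off development cost at which adoption's expected net benefit
    crosses zero: per-user expected NB times discounted users."""
    return inc.nb_mean(lam) * discounted_users(pop)


def qaly_displacement_multiple(inc: IncrementalResult, lam: float) -> float:
    """How many QALYs the cost change displaces (saves) elsewhere in the
    health system per QALY gained by users: (-dC/lambda) / dE."""
    if inc.mean_e == 0:
        raise ConfigurationError("undefined for zero incremental effectiveness")
    return float((-inc.mean_c / lam) / inc.mean_e)


def voi_result(inc: IncrementalResult, lam: float, pop: PopulationModel) -> VOIResult:
    n = discounted_users(pop)
    evpi = evpi_per_user(inc, lam)
    ee = evppi_per_user(inc, lam, "effect")
    ec = evppi_per_user(inc, lam, "cost")
    return VOIResult(
        lam=lam,
        evpi_user=evpi,
        evppi_e_user=ee,
        evppi_c_user=ec,
        n_discounted=n,
        evpi_total=evpi * n,
        evppi_e_total=ee * n,
        evppi_c_total=ec * n,
    )


def voi_curve(
    inc: IncrementalResult, lambdas: np.ndarray, pop: PopulationModel
) -> pd.DataFrame:
    """Per-user and total EVPI/EVPPI over a threshold grid."""
    rows = [voi_result(inc, float(lam), pop).__dict__ for lam in np.asarray(lambdas)]
    return pd.DataFrame(rows)
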
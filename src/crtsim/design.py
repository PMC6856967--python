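"""Trial design: sample-size rule and the simulation condition grid.

The simulated trials are two-arm cluster randomized designs with a
continuous outcome analysed by a random-intercept model.  Clustering
inflates the variance of the treatment-effect estimate by the design
effect 1 + (n1 - 1) * rho, where n1 is the (constant) cluster size and
rho the intraclass correlation of the outcome.  The number of clusters
n2 is chosen per design cell so that the trial has the target power for
the treatment-received effect under full compliance; non-compliance is
deliberately ignored at the planning stage, mirroring common practice.

The study grid crosses three ICC values, three cluster sizes, two
levels of non-compliance (cluster vs subject) and six average
non-compliance probabilities: 3 * 3 * 2 * 6 = 108 conditions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import stats

from .compliance import ComplianceSpec

__all__ = [
    "DesignParams",
    "SimulationCondition",
    "required_clusters",
    "build_condition_grid",
    "grid_to_frame",
    "RHO_LEVELS",
    "N1_LEVELS",
    "NONCOMPLIANCE_LEVELS",
    "PBAR_LEVELS",
]

RHO_LEVELS: tuple[float, ...] = (0.025, 0.05, 0.1)
N1_LEVELS: tuple[int, ...] = (10, 20, 50)
NONCOMPLIANCE_LEVELS: tuple[str, ...] = ("cluster", "subject")
PBAR_LEVELS: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class DesignParams:
    """Fixed effects, variance components and sizes of one design cell.

    ``rho`` is the intraclass correlation of the outcome conditional on
    treatment received and the covariate; ``total_var`` is the total
    residual variance tau^2 + sigma^2 (1 by default, so beta1 = 0.2 is
    a standardized effect size).
    """

    rho: float
    n1: int
    n2: int
    beta0: float = 0.0
    beta1: float = 0.2
    beta2: float = 0.2
    total_var: float = 1.0
    alpha: float = 0.05
    power_target: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.n1 < 1:
            raise ValueError(f"n1 must be >= 1, got {self.n1}")
        if self.n2 < 2:
            raise ValueError(f"n2 must be >= 2, got {self.n2}")
        if self.total_var <= 0:
            raise ValueError("total_var must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError("power_target must be in (0, 1)")

    @property
    def tau2(self) -> float:
        """Between-cluster variance rho * total_var."""
        return self.rho * self.total_var

    @property
    def sigma2(self) -> float:
        """Within-cluster variance (1 - rho) * total_var."""
        return (1.0 - self.rho) * self.total_var

    @property
    def n_subjects(self) -> int:
        return self.n1 * self.n2


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation grid: a design plus a compliance spec."""

    design: DesignParams
    compliance: ComplianceSpec

    @property
    def condition_id(self) -> str:
        """Stable key derived from the factor levels."""
        d, c = self.design, self.compliance
        return f"rho{d.rho:g}_m{d.n1}_{c.level}_p{c.pbar:g}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.condition_id


def _ceil(x: float) -> int:
    # guard against values that are integers up to float noise
    return int(math.ceil(x - 1e-9))


def required_clusters(
    n1: int,
    rho: float,
    beta1: float = 0.2,
    total_var: float = 1.0,
    alpha: float = 0.05,
    power_target: float = 0.8,
    quantile_mode: str = "t-refined",
) -> int:
    """Number of clusters for the target power of the treatment test.

    Stage 1 solves the standard-normal approximation

        n2 = 4 * total_var * (1 + (n1 - 1) rho) / n1
             * ((z_{1-alpha/2} + z_{power}) / beta1)^2

    and rounds up.  With ``quantile_mode="t-refined"`` (default) the
    formula is then re-evaluated once with Student-t quantiles at
    df = n2 - 2 — acknowledging that the treatment effect is tested
    against a t reference with the number of clusters finite — and
    rounded up again.  ``quantile_mode="normal"`` stops after stage 1.

    Raises
    ------
    ValueError
        If ``rho`` is outside [0, 1) or ``beta1`` is zero.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if beta1 == 0:
        raise ValueError("beta1 must be nonzero")
    if n1 < 1:
        raise ValueError(f"n1 must be >= 1, got {n1}")
    if quantile_mode not in ("t-refined", "normal"):
        raise ValueError(f"unknown quantile_mode {quantile_mode!r}")

    design_effect = 1.0 + (n1 - 1) * rho
    base = 4.0 * total_var * design_effect / n1 / beta1**2
    q = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power_target)
    n2 = max(_ceil(base * q * q), 2)
    if quantile_mode == "t-refined":
        df = max(n2 - 2, 1)
        q = stats.t.ppf(1.0 - alpha / 2.0, df) + stats.t.ppf(power_target, df)
        n2 = max(_ceil(base * q * q), 2)
    return n2


def build_condition_grid(
    rho=None,
    n1=None,
    level=None,
    pbar=None,
    beta0: float = 0.0,
    beta1: float = 0.2,
    beta2: float = 0.2,
    total_var: float = 1.0,
    alpha: float = 0.05,
    power_target: float = 0.8,
    quantile_mode: str = "t-refined",
) -> list[SimulationCondition]:
    """Cartesian product of the factor levels, n2 filled in per cell.

    Factor arguments default to the full study levels; passing a list
    restricts or replaces that factor.  The grid is deterministically
    ordered by (rho, n1, level, pbar).
    """
    rho_levels = tuple(rho) if rho is not None else RHO_LEVELS
    n1_levels = tuple(n1) if n1 is not None else N1_LEVELS
    levels = tuple(level) if level is not None else NONCOMPLIANCE_LEVELS
    pbar_levels = tuple(pbar) if pbar is not None else PBAR_LEVELS
    for name, values in (
        ("rho", rho_levels),
        ("n1", n1_levels),
        ("level", levels),
        ("pbar", pbar_levels),
    ):
        if len(values) == 0:
            raise ValueError(f"factor list {name!r} is empty")

    conditions = []
    for r, m, lev, p in itertools.product(
        sorted(rho_levels), sorted(n1_levels), sorted(levels), sorted(pbar_levels)
    ):
        n2 = required_clusters(
            m, r, beta1=beta1, total_var=total_var, alpha=alpha,
            power_target=power_target, quantile_mode=quantile_mode,
        )
        design = DesignParams(
            rho=r, n1=m, n2=n2, beta0=beta0, beta1=beta1, beta2=beta2,
            total_var=total_var, alpha=alpha, power_target=power_target,
        )
        conditions.append(SimulationCondition(design, ComplianceSpec(lev, p)))
    return conditions


def grid_to_frame(conditions: list[SimulationCondition]) -> pd.DataFrame:
    """One row per condition, suitable for CSV export."""
    rows = []
    for cond in conditions:
        d, c = cond.design, cond.compliance
        rows.append(
            {
                "condition_id": cond.condition_id,
                "rho": d.rho,
                "n1": d.n1,
                "n2": d.n2,
                "level": c.level,
                "pbar": c.pbar,
                "beta0": d.beta0,
                "beta1": d.beta1,
                "beta2": d.beta2,
                "total_var": d.total_var,
            }
        )
    return pd.DataFrame(rows)
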
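"""Covariate-driven non-compliance model.

A trial arm can fail to deliver the intervention it was randomized to.
Here only two principal strata exist: compliers (receive whatever they
were assigned) and never-takers (never receive the intervention, even
when assigned to it).  Access to the intervention is restricted, so the
control arm cannot receive treatment: always-takers and defiers are
excluded by design.

Whether a subject is a never-taker is driven by a baseline covariate X.
The probability of being a never-taker is piecewise constant over the
tertiles of the standard-normal distribution of X: half the average
probability in the lowest tertile, the average in the middle, and one
and a half times the average in the highest.  The three bands carry
equal mass, so the marginal never-taker probability equals the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ComplianceSpec", "noncompliance_probability", "TERTILE_CUTOFFS"]

#: Standard-normal tertile boundaries z_{1/3} and z_{2/3} (~ -/+ 0.4307).
TERTILE_CUTOFFS: tuple[float, float] = (
    float(stats.norm.ppf(1.0 / 3.0)),
    float(stats.norm.ppf(2.0 / 3.0)),
)

#: Band multipliers applied to the average non-compliance probability.
TERTILE_MULTIPLIERS: tuple[float, float, float] = (0.5, 1.0, 1.5)


@dataclass(frozen=True)
class ComplianceSpec:
    """Level and strength of non-compliance in one simulation condition.

    Parameters
    ----------
    level
        ``"cluster"``: all subjects in a cluster share one compliance
        status, drawn from the cluster-level covariate.  ``"subject"``:
        each subject's status is drawn independently from their own
        covariate value.
    pbar
        Average probability of being a never-taker, in [0, 0.5].  The
        upper limit keeps the highest band's probability (1.5 * pbar)
        a valid probability.
    multipliers
        Band multipliers for the low/middle/high covariate tertiles.
        They must average to 1 so that the marginal never-taker
        probability equals ``pbar``.
    cutoffs
        Covariate values separating the bands (standard-normal tertile
        quantiles by default).
    """

    level: str
    pbar: float
    multipliers: tuple[float, float, float] = TERTILE_MULTIPLIERS
    cutoffs: tuple[float, float] = TERTILE_CUTOFFS

    def __post_init__(self) -> None:
        if self.level not in ("cluster", "subject"):
            raise ValueError(f"level must be 'cluster' or 'subject', got {self.level!r}")
        if not 0.0 <= self.pbar <= 0.5:
            raise ValueError(f"pbar must be in [0, 0.5], got {self.pbar}")
        if max(self.multipliers) * self.pbar > 1.0:
            raise ValueError("largest band probability exceeds 1")
        if abs(sum(self.multipliers) / 3.0 - 1.0) > 1e-12:
            raise ValueError("band multipliers must average to 1")
        if not self.cutoffs[0] < self.cutoffs[1]:
            raise ValueError("cutoffs must be increasing")


def noncompliance_probability(x, spec: ComplianceSpec):
    """Never-taker probability for covariate value(s) ``x``.

    Bands are left-closed: the middle band is [z_{1/3}, z_{2/3}).  The
    boundary convention is a measure-zero choice, fixed for determinism.
    Accepts scalars or arrays and returns the matching shape.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = spec.cutoffs
    m_low, m_mid, m_high = spec.multipliers
    out = np.where(x < lo, m_low, np.where(x < hi, m_mid, m_high)) * spec.pbar
    if out.ndim == 0:
        return float(out)
    return out
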
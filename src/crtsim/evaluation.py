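"""Monte-Carlo evaluation: estimand targets, summaries, study loop.

Each replication generates one trial and analyses it eight ways (four
approaches, each with and without the covariate) on the *same* dataset,
so approach contrasts are paired.  Four criteria summarize each
(condition x approach x covariate-variant) cell over the converged
replications:

* mean of the treatment-effect estimates, compared with the approach's
  target estimand — beta1 for AT, PP and IV, beta1 * (1 - pbar) for ITT
  (assignment only moves receipt for the compliers);
* empirical standard deviation of the estimates (efficiency);
* coverage: fraction of 95% intervals containing the target estimand;
* empirical power: fraction of two-sided p-values below alpha.

Monte-Carlo error for coverage/power is binomial, sqrt(p(1-p)/R).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import SimulationCondition
from .estimators import APPROACHES, FitResult, fit_approach
from .simulate import generate_trial, replication_rng

__all__ = [
    "target_estimand",
    "fit_replication",
    "summarize_condition",
    "summarize_fits_frame",
    "run_study",
    "DEFAULT_SEED",
    "DEFAULT_REPS",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20191003
DEFAULT_REPS = 5000

_FIT_COLUMNS = [
    "condition_id", "rep", "approach", "with_covariate", "estimate", "se",
    "ci_low", "ci_high", "p_value", "converged", "n_subjects_used",
    "n_clusters_used", "partial_F",
]


def target_estimand(approach: str, condition: SimulationCondition) -> float:
    """Population value each approach's mean estimate is compared with."""
    beta1 = condition.design.beta1
    if approach == "ITT":
        return beta1 * (1.0 - condition.compliance.pbar)
    if approach in ("AT", "PP", "IV"):
        return beta1
    raise ValueError(f"unknown approach {approach!r}")


def _fit_row(condition: SimulationCondition, rep: int, fit: FitResult) -> dict:
    return {
        "condition_id": condition.condition_id,
        "rep": rep,
        "approach": fit.approach,
        "with_covariate": fit.with_covariate,
        "estimate": fit.estimate,
        "se": fit.se,
        "ci_low": fit.ci_low,
        "ci_high": fit.ci_high,
        "p_value": fit.p_value,
        "converged": fit.converged,
        "n_subjects_used": fit.n_subjects_used,
        "n_clusters_used": fit.n_clusters_used,
        "partial_F": fit.first_stage.partial_F if fit.first_stage else np.nan,
    }


def fit_replication(
    condition: SimulationCondition,
    rep: int,
    base_seed: int,
    variants: Sequence[bool] = (True, False),
    approaches: Sequence[str] = APPROACHES,
    correction: str = "CR1",
) -> list[dict]:
    """Generate one trial and fit every requested approach/variant on it."""
    rng = replication_rng(base_seed, condition.condition_id, rep)
    data = generate_trial(condition, rng)
    rows = []
    for with_cov in variants:
        for approach in approaches:
            kwargs = {"correction": correction} if approach == "IV" else {}
            fit = fit_approach(approach, data, with_cov, **kwargs)
            if not fit.converged:
                logger.warning(
                    "non-converged fit: %s rep=%d approach=%s with_covariate=%s",
                    condition.condition_id, rep, approach, with_cov,
                )
            rows.append(_fit_row(condition, rep, fit))
    return rows


def summarize_condition(
    fits: Iterable[FitResult], condition: SimulationCondition, alpha: float = 0.05
) -> pd.DataFrame:
    """Per (approach x variant) performance summary of one condition's fits."""
    rows = [_fit_row(condition, -1, f) for f in fits]
    frame = pd.DataFrame(rows, columns=_FIT_COLUMNS)
    return summarize_fits_frame(frame, {condition.condition_id: condition}, alpha)


def summarize_fits_frame(
    fits: pd.DataFrame,
    conditions: dict[str, SimulationCondition],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collapse a per-replication fits table into performance summaries.

    Non-converged replications are excluded from all four metrics but
    counted (``n_reps`` vs ``n_converged``).  With no converged fits the
    metrics are NaN; with one, the SD is NaN.
    """
    out = []
    grouped = fits.groupby(["condition_id", "approach", "with_covariate"], sort=True)
    for (cid, approach, with_cov), grp in grouped:
        condition = conditions[cid]
        target = target_estimand(approach, condition)
        ok = grp[grp["converged"].astype(bool)]
        n_reps, n_conv = len(grp), len(ok)
        if n_conv == 0:
            mean = sd = cover = power = float("nan")
        else:
            est = ok["estimate"].to_numpy()
            mean = float(est.mean())
            sd = float(est.std(ddof=1)) if n_conv > 1 else float("nan")
            cover = float(
                ((ok["ci_low"] <= target) & (target <= ok["ci_high"])).mean()
            )
            power = float((ok["p_value"] < alpha).mean())
        out.append(
            {
                "condition_id": cid,
                "rho": condition.design.rho,
                "n1": condition.design.n1,
                "n2": condition.design.n2,
                "level": condition.compliance.level,
                "pbar": condition.compliance.pbar,
                "approach": approach,
                "with_covariate": with_cov,
                "target_estimand": target,
                "mean_estimate": mean,
                "sd_estimate": sd,
                "coverage": cover,
                "power": power,
                "n_reps": n_reps,
                "n_converged": n_conv,
            }
        )
    return pd.DataFrame(out)


def run_study(
    conditions: Sequence[SimulationCondition],
    reps: int,
    base_seed: int = DEFAULT_SEED,
    variants: Sequence[bool] = (True, False),
    approaches: Sequence[str] = APPROACHES,
    workers: int = 1,
    alpha: float = 0.05,
    correction: str = "CR1",
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the Monte-Carlo study over the given conditions.

    Returns ``(summary, fits)``: the performance table (one row per
    condition x approach x variant) and the per-replication fits table.
    Replication random streams are keyed on (base_seed, condition_id,
    rep), so results are identical for any ``workers`` value and any
    scheduling order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    units = [(cond, rep) for cond in conditions for rep in range(reps)]
    if workers != 1:
        chunks = Parallel(n_jobs=workers, batch_size=64)(
            delayed(fit_replication)(
                cond, rep, base_seed, variants, approaches, correction
            )
            for cond, rep in units
        )
    else:
        chunks = []
        last_cid = None
        for cond, rep in units:
            if progress and cond.condition_id != last_cid:
                logger.info("condition %s", cond.condition_id)
                last_cid = cond.condition_id
            chunks.append(
                fit_replication(cond, rep, base_seed, variants, approaches, correction)
            )
    fits = pd.DataFrame(
        [row for chunk in chunks for row in chunk], columns=_FIT_COLUMNS
    )
    by_id = {c.condition_id: c for c in conditions}
    summary = summarize_fits_frame(fits, by_id, alpha=alpha)
    return summary, fits
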
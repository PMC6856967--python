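"""The four analysis approaches: ITT, AT, PP and IV.

* ITT (intention to treat) regresses the outcome on the randomized arm
  Z, keeping every subject — it estimates the causal effect of
  assignment, which is attenuated to beta1 * (1 - pbar) under
  non-compliance.
* AT (as treated) regresses on treatment received D, keeping every
  subject; never-takers assigned to the intervention are analysed as
  controls.
* PP (per protocol) also regresses on D but first drops subjects with
  D != Z (intervention-arm never-takers; the control arm is fully
  retained since D = Z = 0 there).
* IV uses assignment as an instrument for receipt in two-stage least
  squares and estimates the complier average causal effect, with
  cluster-robust (Huber-White) standard errors.

ITT, AT and PP use the random-intercept REML fit; IV uses single-level
least squares with the clustering absorbed into the sandwich variance.
All approaches share one inference convention: two-sided z tests and
95% confidence intervals estimate +/- 1.96 * se, so coverage and power
summaries are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .lmm import fit_random_intercept_reml
from .simulate import TrialData

__all__ = [
    "APPROACHES",
    "FirstStageResult",
    "FitResult",
    "fit_itt",
    "fit_at",
    "fit_pp",
    "fit_iv",
    "fit_approach",
    "cluster_robust_covariance",
]

APPROACHES: tuple[str, ...] = ("ITT", "AT", "PP", "IV")

_Z975 = 1.96  # CI half-width multiplier, fixed by convention


@dataclass(frozen=True)
class FirstStageResult:
    """First-stage regression of receipt on assignment (IV only)."""

    alpha0: float  # intercept
    alpha1: float  # instrument coefficient (compliance rate in the trial)
    partial_F: float  # Wald F for the instrument; >= 10 means a strong instrument


@dataclass(frozen=True)
class FitResult:
    approach: str
    with_covariate: bool
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    n_subjects_used: int
    n_clusters_used: int
    first_stage: Optional[FirstStageResult] = None


def _failed_fit(approach: str, with_covariate: bool, n_subj: int, n_clus: int) -> FitResult:
    nan = float("nan")
    return FitResult(
        approach=approach, with_covariate=with_covariate, estimate=nan, se=nan,
        ci_low=nan, ci_high=nan, p_value=nan, converged=False,
        n_subjects_used=n_subj, n_clusters_used=n_clus,
    )


def _make_result(
    approach: str, with_covariate: bool, estimate: float, se: float,
    n_subj: int, n_clus: int, first_stage: Optional[FirstStageResult] = None,
) -> FitResult:
    z = estimate / se
    return FitResult(
        approach=approach, with_covariate=with_covariate,
        estimate=float(estimate), se=float(se),
        ci_low=float(estimate - _Z975 * se), ci_high=float(estimate + _Z975 * se),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        converged=True, n_subjects_used=n_subj, n_clusters_used=n_clus,
        first_stage=first_stage,
    )


def _fit_mixed(
    approach: str, y, treatment, x, clusters, with_covariate: bool
) -> FitResult:
    cols = [np.ones_like(y), np.asarray(treatment, dtype=float)]
    if with_covariate:
        cols.append(np.asarray(x, dtype=float))
    design = np.column_stack(cols)
    n_clus = np.unique(clusters).shape[0]
    try:
        fit = fit_random_intercept_reml(y, design, clusters)
    except ValueError:
        return _failed_fit(approach, with_covariate, len(y), n_clus)
    if not fit.converged:
        return _failed_fit(approach, with_covariate, len(y), n_clus)
    return _make_result(
        approach, with_covariate, fit.params[1], fit.bse[1], len(y), n_clus
    )


def fit_itt(data: TrialData, with_covariate: bool) -> FitResult:
    """Mixed model of Y on assignment Z (never reads C or D)."""
    return _fit_mixed("ITT", data.Y, data.Z, data.X, data.cluster_id, with_covariate)


def fit_at(data: TrialData, with_covariate: bool) -> FitResult:
    """Mixed model of Y on receipt D, all subjects retained."""
    return _fit_mixed("AT", data.Y, data.D, data.X, data.cluster_id, with_covariate)


def fit_pp(data: TrialData, with_covariate: bool) -> FitResult:
    """Mixed model of Y on D after dropping protocol deviators (D != Z).

    Clusters emptied by the exclusion are dropped.  If either arm
    retains fewer than two non-empty clusters, the result is flagged
    non-converged rather than raised, so summaries can count it.
    """
    keep = data.D == data.Z
    clusters = data.cluster_id[keep]
    kept_ids = np.unique(clusters)
    z_by_cluster = np.zeros(data.n_clusters, dtype=np.int64)
    z_by_cluster[data.cluster_id] = data.Z  # Z constant within cluster
    arm_counts = np.bincount(z_by_cluster[kept_ids], minlength=2)
    if arm_counts.min() < 2:
        return _failed_fit("PP", with_covariate, int(keep.sum()), kept_ids.shape[0])
    res = _fit_mixed(
        "PP", data.Y[keep], data.D[keep], data.X[keep], clusters, with_covariate
    )
    return replace(res, approach="PP")


def cluster_robust_covariance(design, residuals, clusters, correction: str = "CR1"):
    """Huber-White sandwich covariance with clustering.

    bread = (X'X)^{-1}; meat = sum over clusters g of s_g s_g' with
    score s_g = X_g' e_g.  ``correction="CR1"`` applies the familiar
    finite-sample factor G/(G-1) * (N-1)/(N-k); ``"none"`` omits it.
    With one subject per cluster this reduces to the HC1-style
    heteroskedasticity-robust estimator.

    ``residuals`` must be formed with the observed regressors (for
    two-stage least squares: observed D, not fitted D), while ``design``
    is the second-stage design whose cross-product forms the bread.
    """
    X = np.asarray(design, dtype=float)
    e = np.asarray(residuals, dtype=float).ravel()
    n, k = X.shape
    labels, idx = np.unique(np.asarray(clusters), return_inverse=True)
    g = labels.shape[0]
    bread = np.linalg.inv(X.T @ X)  # raises LinAlgError on rank deficiency
    scores = np.zeros((g, k))
    np.add.at(scores, idx, X * e[:, None])
    meat = scores.T @ scores
    if correction == "CR1":
        c = g / (g - 1.0) * (n - 1.0) / (n - k)
    elif correction == "none":
        c = 1.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    cov = c * bread @ meat @ bread
    return 0.5 * (cov + cov.T)


def fit_iv(
    data: TrialData,
    with_covariate: bool,
    correction: str = "CR1",
    classical_first_stage_F: bool = False,
) -> FitResult:
    """Two-stage least squares with Z instrumenting D.

    Stage 1 regresses D on Z (plus X when included); stage 2 regresses
    Y on the fitted receipt (plus X).  The coefficient on fitted D
    estimates the complier average causal effect.  Standard errors come
    from the cluster-robust sandwich with residuals evaluated at the
    observed D.  The first-stage partial F for the instrument is a
    cluster-robust Wald statistic by default (classical F by flag).
    """
    y = data.Y
    n = y.shape[0]
    n_clus = data.n_clusters
    exog = [np.ones(n)]
    if with_covariate:
        exog.append(data.X.astype(float))

    z1 = np.column_stack(exog[:1] + [data.Z.astype(float)] + exog[1:])
    alpha, *_ = np.linalg.lstsq(z1, data.D.astype(float), rcond=None)
    if abs(alpha[1]) < 1e-12:
        return _failed_fit("IV", with_covariate, n, n_clus)
    d_hat = z1 @ alpha

    s2 = np.column_stack(exog[:1] + [d_hat] + exog[1:])
    beta, *_ = np.linalg.lstsq(s2, y, rcond=None)
    s2_obs = np.column_stack(exog[:1] + [data.D.astype(float)] + exog[1:])
    resid = y - s2_obs @ beta
    try:
        cov = cluster_robust_covariance(s2, resid, data.cluster_id, correction)
    except np.linalg.LinAlgError:
        return _failed_fit("IV", with_covariate, n, n_clus)
    se = float(np.sqrt(cov[1, 1]))

    fs_resid = data.D - d_hat
    if classical_first_stage_F:
        dof = n - z1.shape[1]
        s2_fs = float(fs_resid @ fs_resid) / dof
        cov_fs = s2_fs * np.linalg.inv(z1.T @ z1)
    else:
        cov_fs = cluster_robust_covariance(z1, fs_resid, data.cluster_id, correction)
    se_a1 = float(np.sqrt(cov_fs[1, 1]))
    partial_f = float(np.inf) if se_a1 == 0.0 else float((alpha[1] / se_a1) ** 2)
    first_stage = FirstStageResult(
        alpha0=float(alpha[0]), alpha1=float(alpha[1]), partial_F=partial_f
    )
    if not np.isfinite(se) or se <= 0:
        return _failed_fit("IV", with_covariate, n, n_clus)
    return _make_result("IV", with_covariate, beta[1], se, n, n_clus, first_stage)


_FITTERS = {"ITT": fit_itt, "AT": fit_at, "PP": fit_pp, "IV": fit_iv}


def fit_approach(approach: str, data: TrialData, with_covariate: bool, **kwargs) -> FitResult:
    """Dispatch on the approach name (IV accepts extra keyword options)."""
    try:
        fitter = _FITTERS[approach]
    except KeyError:
        raise ValueError(f"unknown approach {approach!r}") from None
    if approach == "IV":
        return fitter(data, with_covariate, **kwargs)
    return fitter(data, with_covariate)
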
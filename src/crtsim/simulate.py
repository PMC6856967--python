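"""Generation of one simulated cluster randomized trial.

The outcome model is

    Y_ij = beta0 + beta1 * D_ij + beta2 * X_ij + u_j + e_ij,

with u_j ~ N(0, rho * total_var) between clusters and
e_ij ~ N(0, (1 - rho) * total_var) within, independent.  D_ij is the
treatment actually received: the product of the cluster's randomized
arm Z_j and the subject's complier status C_ij.  Because never-takers
assigned to the intervention have D = 0, their outcomes follow exactly
the same model as control subjects with the same covariate value —
the exclusion restriction holds by construction.

The covariate X drives non-compliance (see :mod:`crtsim.compliance`)
and has a direct effect beta2 on the outcome.  Under cluster-level
non-compliance X is a cluster-level variable (one standard-normal draw
per cluster); under subject-level non-compliance X = B_j + W_ij with
B_j ~ N(0, rho) and W_ij ~ N(0, 1 - rho), so X has unit marginal
variance and the same intraclass correlation as the outcome.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compliance import ComplianceSpec, noncompliance_probability
from .design import SimulationCondition

__all__ = [
    "TrialData",
    "draw_covariate",
    "assign_compliance",
    "generate_trial",
    "replication_rng",
    "ComplianceSpec",
    "noncompliance_probability",
]


@dataclass(frozen=True)
class TrialData:
    """One simulated trial, one row per subject (latents kept for tests).

    All per-subject arrays have length ``n1 * n2`` and are grouped by
    cluster (cluster 0 first).  ``u`` has length ``n2``.
    """

    cluster_id: np.ndarray  # int, per subject
    Z: np.ndarray  # 0/1 randomized arm, per subject (constant in cluster)
    X: np.ndarray  # covariate, per subject
    C: np.ndarray  # 0/1 complier indicator, per subject
    D: np.ndarray  # 0/1 treatment received = Z * C
    Y: np.ndarray  # outcome, per subject
    u: np.ndarray  # latent cluster effect, per cluster
    e: np.ndarray  # latent subject residual, per subject
    condition: SimulationCondition

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.u.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Observable columns only (latents are a testing aid)."""
        return pd.DataFrame(
            {
                "cluster_id": self.cluster_id,
                "Z": self.Z,
                "X": self.X,
                "C": self.C,
                "D": self.D,
                "Y": self.Y,
            }
        )


def replication_rng(base_seed: int, condition_id: str, rep_index: int) -> np.random.Generator:
    """Independent random stream for one (condition, replication) unit.

    The stream is keyed on (base_seed, crc32(condition_id), rep_index)
    through a SeedSequence, so serial and parallel executions — in any
    scheduling order — draw identical data.
    """
    key = zlib.crc32(condition_id.encode("utf-8"))
    ss = np.random.SeedSequence([int(base_seed), key, int(rep_index)])
    return np.random.default_rng(ss)


def draw_covariate(condition: SimulationCondition, rng: np.random.Generator) -> np.ndarray:
    """Per-subject covariate values consistent with the compliance level."""
    d = condition.design
    n1, n2 = d.n1, d.n2
    if condition.compliance.level == "cluster":
        x_cluster = rng.standard_normal(n2)
        return np.repeat(x_cluster, n1)
    between = rng.normal(0.0, math.sqrt(d.rho), size=n2)
    within = rng.normal(0.0, math.sqrt(1.0 - d.rho), size=n1 * n2)
    return np.repeat(between, n1) + within


def assign_compliance(
    condition: SimulationCondition, X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject complier indicators C (0 marks a never-taker).

    Under cluster-level non-compliance one Bernoulli draw per cluster
    (from the cluster's shared covariate value) sets the status of all
    its subjects; X must then be constant within clusters.
    """
    d = condition.design
    spec = condition.compliance
    n1, n2 = d.n1, d.n2
    if X.shape[0] != n1 * n2:
        raise ValueError("X length does not match the condition's n1 * n2")
    if spec.level == "cluster":
        x_by_cluster = X.reshape(n2, n1)
        if np.ptp(x_by_cluster, axis=1).max(initial=0.0) > 0.0:
            raise ValueError("cluster-level compliance requires X constant within clusters")
        p = noncompliance_probability(x_by_cluster[:, 0], spec)
        never = rng.random(n2) < p
        return np.repeat(1 - never.astype(np.int64), n1)
    p = noncompliance_probability(X, spec)
    never = rng.random(n1 * n2) < p
    return 1 - never.astype(np.int64)


def generate_trial(condition: SimulationCondition, rng: np.random.Generator) -> TrialData:
    """Simulate one full trial for the given condition.

    Steps, in fixed draw order for reproducibility: (1) randomize
    clusters 1:1 to arms (the intervention gets the extra cluster when
    n2 is odd; which physical clusters that is, is random); (2) draw the
    covariate; (3) assign compliance; (4) D = Z * C; (5) draw latents
    and assemble the outcome.
    """
    d = condition.design
    n1, n2 = d.n1, d.n2
    n_int = math.ceil(n2 / 2)
    z_cluster = np.zeros(n2, dtype=np.int64)
    z_cluster[rng.permutation(n2)[:n_int]] = 1

    X = draw_covariate(condition, rng)
    C = assign_compliance(condition, X, rng)

    cluster_id = np.repeat(np.arange(n2), n1)
    Z = z_cluster[cluster_id]
    D = Z * C
    u = rng.normal(0.0, math.sqrt(d.tau2), size=n2)
    e = rng.normal(0.0, math.sqrt(d.sigma2), size=n1 * n2)
    Y = d.beta0 + d.beta1 * D + d.beta2 * X + u[cluster_id] + e
    return TrialData(
        cluster_id=cluster_id, Z=Z, X=X, C=C, D=D, Y=Y, u=u, e=e, condition=condition
    )
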
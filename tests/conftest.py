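import numpy as np
import pytest

from crtsim import (
    ComplianceSpec,
    DesignParams,
    SimulationCondition,
    generate_trial,
    replication_rng,
    required_clusters,
)


@pytest.fixture(scope="session")
def make_condition():
    """Factory for a single simulation condition with sensible defaults."""

    def _make(rho=0.05, n1=20, level="cluster", pbar=0.3, n2=None, **design_kwargs):
        if n2 is None:
            n2 = required_clusters(
                n1,
                rho,
                beta1=design_kwargs.get("beta1", 0.2),
                total_var=design_kwargs.get("total_var", 1.0),
            )
        design = DesignParams(rho=rho, n1=n1, n2=n2, **design_kwargs)
        return SimulationCondition(design, ComplianceSpec(level, pbar))

    return _make


@pytest.fixture(scope="session")
def make_trial(make_condition):
    """Factory for one reproducible simulated trial."""

    def _make(rep=0, seed=20191003, **condition_kwargs):
        cond = make_condition(**condition_kwargs)
        rng = replication_rng(seed, cond.condition_id, rep)
        return generate_trial(cond, rng)

    return _make
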
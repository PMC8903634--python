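"""Shared fixtures: small synthetic cohorts and survival helpers."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irlncpair.io import ExpressionMatrix, SurvivalTable
from irlncpair.synthetic import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated cohort, shared read-only across tests."""
    cfg = SimulationConfig(seed=7)
    expr, ann, immune, truth = simulate_expression(cfg)
    return {"config": cfg, "expr": expr, "ann": ann, "immune": immune, "truth": truth}


@pytest.fixture
def toy_survival():
    """4-subject tie-free survival table with a binary covariate.

    The Cox partial likelihood for x = (1, 0, 1, 0), events at t = 1, 2 and
    censoring afterwards has the closed-form maximum beta = ln(2) / 2.
    """
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 0, 0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    x = pd.Series([1.0, 0.0, 1.0, 0.0], index=df.index, name="x")
    return SurvivalTable(df), x


def make_expression(values: np.ndarray, genes, samples, cohort=None, batch=None):
    """Convenience constructor for hand-built expression matrices."""
    vals = pd.DataFrame(values, index=genes, columns=samples)
    cohort = pd.Series(cohort if cohort is not None else "tumor", index=samples)
    batch = pd.Series(batch if batch is not None else "b0", index=samples)
    return ExpressionMatrix(vals, cohort, batch)


def exponential_survival(
    rng: np.random.Generator,
    lp: np.ndarray,
    samples,
    baseline: float = 2e-4,
    censor_max: float = 3650.0,
) -> SurvivalTable:
    """Exponential PH survival with uniform censoring for test cohorts."""
    rate = baseline * np.exp(np.asarray(lp, dtype=float))
    t_ev = rng.exponential(1.0 / rate)
    t_c = rng.uniform(0, censor_max, size=len(rate))
    df = pd.DataFrame(
        {
            "time": np.maximum(np.minimum(t_ev, t_c), 0.5),
            "event": (t_ev <= t_c).astype(int),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return SurvivalTable(df)
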
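"""Optional basic plot artifacts (KM curves, group box plots)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluate import km_estimate
from .io import SurvivalTable
from .stratify import RiskStratification


def km_plot(surv: SurvivalTable, strat: RiskStratification, path: str | Path) -> None:
    """Step plot of the two risk groups' Kaplan-Meier curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, ids, color in (
        ("high", strat.high_samples, "tab:red"),
        ("low", strat.low_samples, "tab:blue"),
    ):
        km = km_estimate(surv.subset(ids))
        ax.step([0, *km.times], [1.0, *km.survival], where="post", label=f"{grp} risk",
                color=color)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def group_boxplot(values: pd.Series, strat: RiskStratification, path: str | Path) -> None:
    """Box plot of a per-sample quantity split by risk group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hi = values.reindex(strat.high_samples).dropna()
    lo = values.reindex(strat.low_samples).dropna()
    fig, ax = plt.subplots(figsize=(3.5, 4))
    ax.boxplot([hi, lo], tick_labels=["high", "low"])
    ax.set_ylabel(values.name or "value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
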
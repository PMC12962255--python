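"""Tabular and graphical outputs for stress-test and premium runs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort import Cohort
from .stress import InsolvencyCurve, SolvencyTrajectory, StressScenario, simulate_household

__all__ = [
    "curves_frame",
    "trajectories_frame",
    "stress_summary",
    "plot_insolvency_curves",
]

# Line colors conventionally used for the three standard tests.
_SERIES_COLORS = ("tab:red", "tab:blue", "tab:green")


def curves_frame(curves: Sequence[InsolvencyCurve]) -> pd.DataFrame:
    """Long-format table ``scenario,month,insolvency_rate``."""
    rows = [
        {"scenario": c.scenario, "month": m + 1, "insolvency_rate": r}
        for c in curves
        for m, r in enumerate(c.rate_by_month)
    ]
    return pd.DataFrame(rows, columns=["scenario", "month", "insolvency_rate"])


def trajectories_frame(cohort: Cohort, scenario: StressScenario) -> pd.DataFrame:
    """Per-household monthly balances: ``id,month,balance,insolvent``."""
    rows = []
    for rec in cohort:
        traj = simulate_household(rec, scenario)
        for m, bal in enumerate(traj.monthly_balance, start=1):
            rows.append(
                {
                    "id": rec.id,
                    "month": m,
                    "balance": bal,
                    "insolvent": traj.first_insolvent_month is not None
                    and m >= traj.first_insolvent_month,
                }
            )
    return pd.DataFrame(rows, columns=["id", "month", "balance", "insolvent"])


def stress_summary(curves: Sequence[InsolvencyCurve], months: Sequence[int] = (3, 6)) -> dict:
    """Insolvency rates at selected months, per scenario."""
    out = {}
    for c in curves:
        out[c.scenario] = {
            f"month_{m}": c.rate_at(m) for m in months if m <= len(c.rate_by_month)
        }
    return out


def plot_insolvency_curves(
    curves: Sequence[InsolvencyCurve], path: str | Path, title: str = "Household insolvency under income loss"
) -> Path:
    """One series per scenario: month on x, cumulative insolvency rate on y."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, curve in enumerate(curves):
        months = range(1, len(curve.rate_by_month) + 1)
        color = _SERIES_COLORS[i] if i < len(_SERIES_COLORS) else None
        ax.plot(months, curve.rate_by_month, marker="o", color=color, label=curve.scenario)
    ax.set_xlabel("Months of income loss")
    ax.set_ylabel("Cumulative insolvency rate")
    ax.set_ylim(bottom=0)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
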
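"""Logarithmic electrolyte-leakage fits and per-time group comparison.

Seed-leachate conductivity rises with soaking time roughly as
``y = a + b*ln(t)``; each treatment group (control / water-soak / ultrasonic)
gets an OLS fit on log time, and groups are compared at each soaking time by
one-way ANOVA with SNK letters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import LetterGrouping, snk_letters

__all__ = [
    "ConductivityFit",
    "fit_log_model",
    "fit_groups",
    "compare_groups",
    "load_fixture_conductivity",
]


@dataclass
class ConductivityFit:
    group: str | None
    a: float  # intercept
    b: float  # slope on ln(t)
    r2: float
    n: int
    basis: str = "means"  # "means" | "replicates"

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a + self.b * np.log(t)


def fit_log_model(
    times_h,
    readings,
    group: str | None = None,
    base: float | None = None,
    basis: str = "means",
) -> ConductivityFit:
    """OLS of conductivity on log soaking time.

    ``base=None`` uses the natural log.  Constant readings give b=0 and, by
    convention, R²=0 (no variance explained).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(readings, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and readings must be 1-D and the same length")
    if np.any(t <= 0):
        raise ValueError("soaking times must be positive")
    if len(np.unique(t)) < 3:
        raise ValueError("at least 3 distinct times are required")
    x = np.log(t) if base is None else np.log(t) / np.log(base)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    return ConductivityFit(
        group=group, a=float(beta[0]), b=float(beta[1]), r2=r2, n=len(y), basis=basis
    )


def fit_groups(records: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Per-group logarithmic fits from a long table (group, time_h, conductivity)."""
    basis = "replicates" if "replicate" in records.columns else "means"
    rows = []
    for group, sub in records.groupby("group", sort=False):
        fit = fit_log_model(
            sub["time_h"].to_numpy(), sub["conductivity"].to_numpy(), group=group,
            base=base, basis=basis,
        )
        rows.append((group, fit.a, fit.b, fit.r2, fit.n, basis))
    return pd.DataFrame(rows, columns=["group", "a", "b", "r2", "n", "basis"])


def compare_groups(records: pd.DataFrame, alpha: float = 0.05) -> dict[float, LetterGrouping]:
    """Per soaking time: one-way ANOVA across groups and SNK letters.

    Requires replicate-level records (>=2 per group-time cell) with equal
    replication across groups at each time.
    """
    required = {"group", "time_h", "replicate", "conductivity"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    out: dict[float, LetterGrouping] = {}
    for time_h, sub in records.groupby("time_h"):
        counts = sub.groupby("group")["conductivity"].count()
        if (counts < 2).any():
            raise ValueError(f"time {time_h}: need >=2 replicates per group, got {counts.to_dict()}")
        if counts.nunique() != 1:
            raise ValueError(f"time {time_h}: unequal replication {counts.to_dict()}")
        n = int(counts.iloc[0])
        groups = list(counts.index)
        means = np.array([sub.loc[sub["group"] == g, "conductivity"].mean() for g in groups])
        sse = sum(
            float(((sub.loc[sub["group"] == g, "conductivity"] - means[i]) ** 2).sum())
            for i, g in enumerate(groups)
        )
        df_error = len(sub) - len(groups)
        mse = sse / df_error
        out[float(time_h)] = snk_letters(
            means, mse, df_error, n, alpha=alpha, labels=groups
        )
    return out


def load_fixture_conductivity() -> pd.DataFrame:
    """Published group x soaking-time conductivity means (three repetitions each)."""
    path = importlib.resources.files("sonoseed.data").joinpath("leachate_conductivity_means.csv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)
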
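"""Statistics for coculture growth assays and Western densitometry.

Growth assays count DiI-labeled transformed cells per 0.242 mm^2 microscopic
field after seven days of coculture; results are reported as percent of the
transformed-cells-plated-alone control (mean + SEM). Densitometry values are
band signals normalized to a loading control and scaled to a reference
condition. t-tests compare the raw measurements, not the percent values, to
avoid scaling the noise twice; percents are presentation-layer.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .stats import sem, student_t_test


class PercentOfControl(NamedTuple):
    percent_mean: float
    percent_sem: float
    p_value: float


def _validated(values: Sequence[float], name: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError(f"{name}: empty measurement vector")
    if np.isnan(x).any():
        raise ValueError(f"{name}: missing measurement")
    if (x < 0).any():
        raise ValueError(f"{name}: negative measurement")
    return x


def percent_of_control(
    treated: Sequence[float], control: Sequence[float]
) -> PercentOfControl:
    """Treated measurements as percent of the control mean, with SEM and p.

    Each treated replicate is scaled to ``100 * value / mean(control)``; the
    p-value is a two-tailed pooled-variance Student t-test between the raw
    treated and control measurements.
    """
    treated = _validated(treated, "treated")
    control = _validated(control, "control")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    percents = 100.0 * treated / control_mean
    p = student_t_test(treated, control).p
    return PercentOfControl(float(percents.mean()), sem(percents), p)


def densitometry_percent(
    signal: Sequence[float],
    loading: Sequence[float],
    reference_mean: float,
) -> np.ndarray:
    """Per-lane percent: 100 * (signal / loading control) / reference mean."""
    signal = _validated(signal, "signal")
    loading = _validated(loading, "loading")
    if signal.size != loading.size:
        raise ValueError("signal and loading must have the same number of lanes")
    if (loading == 0).any():
        lane = int(np.argmax(loading == 0))
        raise ValueError(f"loading control is zero in lane {lane}")
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    return 100.0 * (signal / loading) / reference_mean


def fold_vs_condition(a: Sequence[float], b: Sequence[float]) -> float:
    """Ratio of means, mean(a) / mean(b)."""
    a = _validated(a, "a")
    b = _validated(b, "b")
    mb = b.mean()
    if mb == 0:
        raise ValueError("denominator condition has zero mean")
    return float(a.mean() / mb)


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Read a ``condition<TAB>replicate<TAB>value`` table."""
    frame = pd.read_csv(path, sep="\t")
    expected = ["condition", "replicate", "value"]
    if list(frame.columns[:3]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    values = pd.to_numeric(frame["value"], errors="coerce")
    if values.isna().any():
        row = frame.loc[values.isna()].iloc[0]
        raise ValueError(
            f"{path}: non-numeric value for condition {row['condition']!r}, "
            f"replicate {row['replicate']!r}"
        )
    if (values < 0).any():
        row = frame.loc[values < 0].iloc[0]
        raise ValueError(
            f"{path}: negative value for condition {row['condition']!r}, "
            f"replicate {row['replicate']!r}"
        )
    frame["value"] = values
    return frame


def summarize_assay(table: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-condition summary: mean, SEM, percent of control, fold, and p.

    Every condition (including the control itself) is compared against the
    ``control`` condition; conditions entering the t-test need at least two
    replicates.
    """
    if control not in set(table["condition"]):
        raise ValueError(f"control condition {control!r} not present in the table")
    control_values = table.loc[table["condition"] == control, "value"].to_numpy()
    rows = []
    for condition, sub in table.groupby("condition", sort=False):
        values = sub["value"].to_numpy()
        if len(values) < 2 or len(control_values) < 2:
            raise ValueError(
                f"condition {condition!r} or control has fewer than 2 replicates"
            )
        pct = percent_of_control(values, control_values)
        rows.append({
            "condition": condition,
            "n": len(values),
            "mean": values.mean(),
            "sem": sem(values),
            "percent_of_control": pct.percent_mean,
            "percent_sem": pct.percent_sem,
            "fold_vs_control": fold_vs_condition(values, control_values),
            "p_vs_control": pct.p_value,
        })
    return pd.DataFrame(rows).set_index("condition")
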
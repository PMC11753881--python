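"""Diel EV-production statistics: per-cell series, phase net production, tests.

A diel table has one row per (replicate, sampling time) with matched cell
and EV concentrations.  The production statistic works on the EVs-per-cell
ratio at three chronological sampling points bracketing one light and one
dark phase — t1 just after lights-on, t2 just after lights-off, t3 just
after the next lights-on:

    light_net = (t2 - t1) / t1        dark_net = (t3 - t2) / t2

Both are dimensionless relative changes, invariant to any common rescaling
of the concentrations.  Replicate-level values feed a paired two-sided t
(dark vs light within replicate) or, for a division-arrest experiment, a
two-sample t on the dark-phase values between treatment arms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    InsufficientReplicatesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

# chronological sampling points used by the statistic (hours since first
# lights-on in a 14:10 cycle); 24.5 is ZT 0.5 of the next cycle
DEFAULT_T1_ZT = 0.5
DEFAULT_T2_ZT = 14.5
DEFAULT_T3_ZT = 24.5

DIEL_COLUMNS = (
    "replicate_id",
    "treatment",
    "zeitgeber_time",
    "cell_concentration",
    "ev_concentration",
)


@dataclass(frozen=True)
class PairedPhaseTest:
    """Paired comparison of dark vs light net production across replicates."""

    n: int
    mean_light: float
    sd_light: float
    mean_dark: float
    sd_dark: float
    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class TreatmentContrast:
    """Two-sample comparison of one phase's net production between arms."""

    phase: str
    n_control: int
    n_treated: int
    mean_control: float
    mean_treated: float
    t: float
    df: int
    p: float
    direction: str  # "treated_lower", "treated_higher" or "equal"
    degenerate: bool = False


def evs_per_cell_series(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """EVs-per-cell ratio per row plus a mean +- sd summary per time point.

    Returns ``(series, summary)``: the input rows with an added
    ``evs_per_cell`` column, and per (treatment, zeitgeber_time) the
    replicate count, mean and sample sd of the ratio.
    """
    if table.empty:
        raise EmptyInputError("diel table is empty")
    if (table["cell_concentration"] <= 0).any():
        bad = table.loc[table["cell_concentration"] <= 0]
        raise ValidationError(
            "zero or negative cell concentration at "
            f"{bad[['replicate_id', 'zeitgeber_time']].to_dict('records')[:3]}"
        )
    series = table.copy()
    series["evs_per_cell"] = series["ev_concentration"] / series["cell_concentration"]
    summary = (
        series.groupby(["treatment", "zeitgeber_time"], sort=True)["evs_per_cell"]
        .agg(n="size", mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return series, summary


def net_production(t1: float, t2: float, t3: float) -> Tuple[float, float]:
    """Relative net production per phase from three chronological ratios.

    ``light_net = (t2 - t1)/t1`` and ``dark_net = (t3 - t2)/t2``; requires
    t1 > 0 and t2 > 0.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValidationError(f"t1 and t2 must be positive, got t1={t1}, t2={t2}")
    return (t2 - t1) / t1, (t3 - t2) / t2


def phase_production(
    table: pd.DataFrame,
    t1_zt: float = DEFAULT_T1_ZT,
    t2_zt: float = DEFAULT_T2_ZT,
    t3_zt: float = DEFAULT_T3_ZT,
    match_tol_h: float = 0.25,
) -> pd.DataFrame:
    """Per-replicate phase net production from a diel table.

    For each (treatment, replicate) the EVs-per-cell ratios at the three
    sampling points (matched to ``zeitgeber_time`` within ``match_tol_h``
    hours) become t1..t3; replicates missing any point, or with a
    nonpositive t1/t2, are dropped with a logged count.  Intermediate
    sampling times in the table are ignored by the statistic.

    Returns columns ``treatment, replicate_id, t1, t2, t3, light_net,
    dark_net``.
    """
    series, _ = evs_per_cell_series(table)
    targets = {"t1": t1_zt, "t2": t2_zt, "t3": t3_zt}
    rows, dropped = [], 0
    for (treatment, rep), grp in series.groupby(["treatment", "replicate_id"]):
        vals = {}
        for name, zt in targets.items():
            hit = grp.loc[(grp["zeitgeber_time"] - zt).abs() <= match_tol_h]
            if len(hit) == 1:
                vals[name] = float(hit["evs_per_cell"].iloc[0])
            elif len(hit) > 1:
                vals[name] = float(hit["evs_per_cell"].mean())
        if len(vals) < 3 or vals["t1"] <= 0 or vals["t2"] <= 0:
            dropped += 1
            continue
        light, dark = net_production(vals["t1"], vals["t2"], vals["t3"])
        rows.append(
            {
                "treatment": treatment,
                "replicate_id": rep,
                "t1": vals["t1"],
                "t2": vals["t2"],
                "t3": vals["t3"],
                "light_net": light,
                "dark_net": dark,
            }
        )
    if dropped:
        logger.warning("dropped %d replicate(s) with undefined phase values", dropped)
    if not rows:
        raise EmptyInputError("no replicate had all three sampling points")
    return pd.DataFrame(rows)


def compare_phases(phase_table: pd.DataFrame) -> PairedPhaseTest:
    """Two-sided paired t of dark vs light net production across replicates.

    The difference series is dark_net - light_net within replicate; a
    constant nonzero difference (zero variance) is reported with p = 0 and
    the degenerate flag, a constant zero difference with t = 0, p = 1.
    """
    light = phase_table["light_net"].to_numpy(dtype=float)
    dark = phase_table["dark_net"].to_numpy(dtype=float)
    n = light.size
    if n < 2:
        raise InsufficientReplicatesError(f"paired test needs >= 2 replicates, got {n}")
    diff = dark - light
    base = dict(
        n=n,
        mean_light=float(light.mean()),
        sd_light=float(light.std(ddof=1)),
        mean_dark=float(dark.mean()),
        sd_dark=float(dark.std(ddof=1)),
        df=n - 1,
    )
    if diff.var(ddof=1) == 0:
        if diff.mean() == 0:
            return PairedPhaseTest(t=0.0, p=1.0, degenerate=True, **base)
        logger.warning("zero-variance nonzero paired difference; p reported as 0")
        return PairedPhaseTest(
            t=math.copysign(math.inf, diff.mean()), p=0.0, degenerate=True, **base
        )
    t, p = stats.ttest_rel(dark, light)
    return PairedPhaseTest(t=float(t), p=float(p), **base)


def treatment_contrast(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    phase: str = "dark",
) -> TreatmentContrast:
    """Two-sided two-sample Student's t on one phase's net production.

    ``phase`` selects ``dark_net`` (default) or ``light_net``.  Both arms
    need at least two replicates.
    """
    col = {"dark": "dark_net", "light": "light_net"}.get(phase)
    if col is None:
        raise ValidationError(f"phase must be 'dark' or 'light', got {phase!r}")
    a = control[col].to_numpy(dtype=float)
    b = treated[col].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates per arm, got {a.size} control / {b.size} treated"
        )
    delta = b.mean() - a.mean()
    direction = "equal" if delta == 0 else ("treated_higher" if delta > 0 else "treated_lower")
    base = dict(
        phase=phase,
        n_control=a.size,
        n_treated=b.size,
        mean_control=float(a.mean()),
        mean_treated=float(b.mean()),
        df=a.size + b.size - 2,
        direction=direction,
    )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if delta == 0:
            return TreatmentContrast(t=0.0, p=1.0, degenerate=True, **base)
        return TreatmentContrast(
            t=math.copysign(math.inf, delta), p=0.0, degenerate=True, **base
        )
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return TreatmentContrast(t=float(t), p=float(p), **base)
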
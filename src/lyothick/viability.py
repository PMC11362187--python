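"""Freeze-drying survival and storage-stability half-life analytics.

Viable counts C(t) (CFU/g) during accelerated storage are modelled as
first-order decay over an observation window [t_start, t_end]:

    C(t_end) = C(t_start) * exp(-(t_end - t_start) / lambda(t_m))

where lambda is a decay *time constant* (days) evaluated at the window
midpoint t_m.  Inverting gives the endpoint estimator

    lambda = (t_end - t_start) / (ln C(t_start) - ln C(t_end))

and the half-life t_half = ln(2) * lambda.  The estimator is deliberately
two-point: only the window endpoints enter, so windowed estimates such as
0-28 d ("month 1") and 28-56 d ("month 2") are independent of intermediate
sampling.  A log-linear least-squares fit over all points in a window is
provided as a labelled alternative, never the default.

Freeze-drying survival is the plated CFU/g after drying relative to the
initial viable-cell concentration (e.g. from flow cytometry), as a percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ViabilitySeries",
    "HalfLifeEstimate",
    "SurvivalResult",
    "decay_constant",
    "half_life",
    "windowed_half_lives",
    "fit_loglinear_half_life",
    "freeze_drying_survival",
    "read_viability_csv",
    "write_viability_csv",
]

LN2 = math.log(2.0)

#: Default observation windows in days: 0-1 month and 1-2 months, bound to
#: the storage sampling days 28 and 56 rather than calendar months.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 28.0), (28.0, 56.0))


@dataclass
class ViabilitySeries:
    """CFU/g time course for one batch under one storage condition."""

    times: np.ndarray
    counts: np.ndarray
    batch: str = ""
    condition: str = ""
    limit_of_detection: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be 1D arrays of equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts <= 0):
            raise ValueError("counts must be positive and finite")
        if np.any(self.counts <= self.limit_of_detection):
            below = self.times[self.counts <= self.limit_of_detection]
            raise ValueError(
                f"counts at t={below.tolist()} d are at or below the limit of detection "
                f"({self.limit_of_detection}); rejected rather than imputed"
            )

    def count_at(self, t: float) -> float:
        """Exact-match lookup of C(t); missing timepoints are an error."""
        idx = np.nonzero(self.times == t)[0]
        if idx.size == 0:
            raise KeyError(f"timepoint t={t} d not present in series (have {self.times.tolist()})")
        return float(self.counts[idx[0]])


@dataclass
class HalfLifeEstimate:
    """Windowed decay estimate: time constant lambda and half-life, in days."""

    t_start: float
    t_end: float
    lambda_days: float
    t_half_days: float
    batch: str = ""
    condition: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")

    @property
    def t_m(self) -> float:
        """Window midpoint (days)."""
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class SurvivalResult:
    """Freeze-drying survival as percent of the initial viable concentration."""

    survival_pct: float
    cfu_after: float
    initial_concentration: float
    flags: tuple[str, ...] = ()


def decay_constant(series: ViabilitySeries, t_start: float, t_end: float) -> float:
    """Endpoint decay time constant lambda (days) over [t_start, t_end].

    Returns +inf when the endpoint counts are equal (no decay) and a
    negative value when counts grew over the window; callers flag both via
    :func:`windowed_half_lives`.
    """
    if not t_end > t_start:
        raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
    c_start = series.count_at(t_start)
    c_end = series.count_at(t_end)
    denom = math.log(c_start) - math.log(c_end)
    if denom == 0.0:
        return math.inf
    return (t_end - t_start) / denom


def half_life(lambda_days: float) -> float:
    """Half-life t_half = ln(2) * lambda; infinity propagates."""
    return LN2 * lambda_days


def windowed_half_lives(
    series: ViabilitySeries,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
) -> list[HalfLifeEstimate]:
    """One :class:`HalfLifeEstimate` per observation window.

    Window endpoints must be sampled timepoints of the series (exact match).
    Estimates with equal endpoint counts are flagged ``no_decay`` (infinite
    half-life); growing counts are flagged ``growth`` (negative values).
    """
    out = []
    for t_start, t_end in windows:
        lam = decay_constant(series, t_start, t_end)
        flags: tuple[str, ...] = ()
        if math.isinf(lam):
            flags = ("no_decay",)
        elif lam < 0:
            flags = ("growth",)
        out.append(
            HalfLifeEstimate(
                t_start=t_start,
                t_end=t_end,
                lambda_days=lam,
                t_half_days=half_life(lam),
                batch=series.batch,
                condition=series.condition,
                flags=flags,
            )
        )
    return out


def fit_loglinear_half_life(
    series: ViabilitySeries, t_start: float, t_end: float
) -> HalfLifeEstimate:
    """Alternative estimator: least-squares fit of ln C(t) over the window.

    Uses every sampled point with t_start <= t <= t_end (at least two).
    Labelled ``loglinear_fit``; the endpoint estimator remains the default.
    """
    sel = (series.times >= t_start) & (series.times <= t_end)
    if sel.sum() < 2:
        raise ValueError(f"need >= 2 points in [{t_start}, {t_end}] d for a fit")
    t = series.times[sel]
    logc = np.log(series.counts[sel])
    slope, _ = np.polyfit(t, logc, 1)
    lam = math.inf if slope == 0 else -1.0 / slope
    flags = ["loglinear_fit"]
    if math.isinf(lam):
        flags.append("no_decay")
    elif lam < 0:
        flags.append("growth")
    return HalfLifeEstimate(
        t_start=float(t_start),
        t_end=float(t_end),
        lambda_days=lam,
        t_half_days=half_life(lam),
        batch=series.batch,
        condition=series.condition,
        flags=tuple(flags),
    )


def freeze_drying_survival(cfu_after: float, initial: float) -> SurvivalResult:
    """Survival percent = 100 * cfu_after / initial.

    Both quantities must already be expressed per the same mass/volume basis.
    Survival above 100% is returned but flagged.
    """
    if not cfu_after > 0 or not initial > 0:
        raise ValueError("cfu_after and initial must both be positive")
    pct = 100.0 * cfu_after / initial
    flags = ("above_initial",) if pct > 100.0 else ()
    return SurvivalResult(
        survival_pct=pct, cfu_after=cfu_after, initial_concentration=initial, flags=flags
    )


def read_viability_csv(path: str | Path) -> list[ViabilitySeries]:
    """Read ``time_days,cfu_per_g,batch,condition`` CSV into series.

    Rows are grouped by (batch, condition); times must be strictly
    increasing within each group.
    """
    df = pd.read_csv(path)
    required = {"time_days", "cfu_per_g", "batch", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability CSV {path} is missing columns: {sorted(missing)}")
    out = []
    for (batch, condition), grp in df.groupby(["batch", "condition"], sort=True):
        grp = grp.sort_values("time_days")
        out.append(
            ViabilitySeries(
                times=grp["time_days"].to_numpy(float),
                counts=grp["cfu_per_g"].to_numpy(float),
                batch=str(batch),
                condition=str(condition),
            )
        )
    return out


def write_viability_csv(series_list: list[ViabilitySeries], path: str | Path) -> None:
    """Write one or more series to the standard four-column CSV."""
    frames = [
        pd.DataFrame(
            {
                "time_days": s.times,
                "cfu_per_g": s.counts,
                "batch": s.batch,
                "condition": s.condition,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def half_lives_to_frame(estimates: list[HalfLifeEstimate]) -> pd.DataFrame:
    """Tabulate estimates as ``batch,condition,t_start,t_end,lambda_days,t_half_days,flags``."""
    return pd.DataFrame(
        {
            "batch": [e.batch for e in estimates],
            "condition": [e.condition for e in estimates],
            "t_start": [e.t_start for e in estimates],
            "t_end": [e.t_end for e in estimates],
            "lambda_days": [e.lambda_days for e in estimates],
            "t_half_days": [e.t_half_days for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
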
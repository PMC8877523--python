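"""Ensemble-level statistics of translocation experiments.

Works on the raw per-trial event table produced by
:func:`polytrans.mc.run_batch` (columns ``id``, ``trial``, ``outcome``,
``time``): time histograms with fixed binning, power-law tail fits, the
slowly decaying trapped population, outcome percentages resolved by the
sequence descriptors Q/Qh/Qmin, and population-percentile translocation
times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Bin widths (MCT) used in the reference analyses.
DT_TRANSLOCATION_PDF = 1600
DT_REJECTION_PDF = 20
DT_PERCENTILES = 400


@dataclass(frozen=True)
class TimePDF:
    """Histogram of absorption times on a fixed grid of bin centers ``k·δt``.

    Bin ``k`` covers ``[k·δt - δt/2, k·δt + δt/2)``; probabilities are
    counts normalized by ``total`` (by default the number of contributing
    events of the selected kind).
    """

    dt: float
    bin_centers: np.ndarray
    counts: np.ndarray
    total: int
    kind: str

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total

    @property
    def empty(self) -> bool:
        return self.total == 0


def _select_times(events: pd.DataFrame, kind: str) -> np.ndarray:
    return events.loc[events["outcome"] == kind, "time"].to_numpy()


def time_pdf(
    events: pd.DataFrame,
    kind: str = "translocated",
    dt: float = DT_TRANSLOCATION_PDF,
    normalization: str = "events",
) -> TimePDF:
    """Bin absorption times of one outcome kind.

    ``normalization="events"`` divides by the number of events of that kind
    (the convention for translocation/rejection-time PDFs);
    ``"attempts"`` divides by all rows of ``events``.
    """
    if dt < 1:
        raise ValueError("bin width dt must be >= 1 MCT")
    times = _select_times(events, kind)
    if times.size == 0:
        return TimePDF(dt, np.array([]), np.array([], dtype=int), 0, kind)
    k = ((times + dt / 2) // dt).astype(int)  # bin k covers [k*dt - dt/2, k*dt + dt/2)
    counts = np.bincount(k)
    centers = np.arange(len(counts)) * dt
    total = times.size if normalization == "events" else len(events)
    return TimePDF(dt, centers, counts, int(total), kind)


@dataclass(frozen=True)
class TailFit:
    """Least-squares slope of ``log P`` vs ``log t``."""

    slope: float
    stderr: float
    n_bins: int
    window: tuple[float, float]


def tail_exponent(
    pdf: TimePDF,
    window: tuple[float, float] = (1e4, 1e5),
    min_count: int = 5,
    min_bins: int = 5,
    skip_first_bin: bool = True,
) -> TailFit:
    """Fit the power-law tail exponent of a time PDF on log–log axes.

    Bins with fewer than ``min_count`` events are excluded (their log-counts
    are noise-dominated), as is the engagement-transient first bin.
    """
    if pdf.empty:
        raise ValueError("cannot fit the tail of an empty PDF")
    t1, t2 = window
    mask = (
        (pdf.bin_centers >= t1)
        & (pdf.bin_centers <= t2)
        & (pdf.counts >= min_count)
    )
    if skip_first_bin:
        mask &= pdf.bin_centers > 0
    if mask.sum() < min_bins:
        raise ValueError(
            f"only {int(mask.sum())} usable bins in window [{t1:g}, {t2:g}]; "
            f"need >= {min_bins}"
        )
    x = np.log(pdf.bin_centers[mask])
    y = np.log(pdf.probabilities[mask])
    fit = sps.linregress(x, y)
    return TailFit(float(fit.slope), float(fit.stderr), int(mask.sum()), (t1, t2))


@dataclass(frozen=True)
class TrappedCurve:
    """Fraction of engagement attempts not yet absorbed, vs time."""

    t: np.ndarray
    fraction: np.ndarray


def trapped_curve(events: pd.DataFrame, grid: Sequence[float] | None = None, tw: int | None = None) -> TrappedCurve:
    """Survival curve of the engaged population.

    Trapped trials carry ``time == tw`` and count as unabsorbed at every
    grid point below ``tw``.
    """
    times = events["time"].to_numpy()
    absorbed = (events["outcome"] != "trapped").to_numpy()
    if tw is None:
        tw = int(times.max()) if times.size else 1
    if grid is None:
        grid = np.unique(np.geomspace(1, tw, 200).astype(int))
    grid = np.asarray(grid, dtype=float)
    sorted_abs = np.sort(times[absorbed])
    n = len(times)
    frac = np.empty_like(grid)
    for i, g in enumerate(grid):
        frac[i] = 1.0 - np.searchsorted(sorted_abs, g, side="right") / n if n else 1.0
    return TrappedCurve(grid, frac)


def outcome_matrix(
    summaries: pd.DataFrame,
    grouping: tuple[str, str] = ("Qh", "Q"),
) -> pd.DataFrame:
    """Attempt-weighted outcome percentages per descriptor cell.

    ``summaries`` is the per-sequence frame from
    :meth:`polytrans.mc.BatchResult.summary_frame`; ``grouping`` picks the two
    descriptor columns, e.g. ``("Qh", "Q")`` or ``("Qmin", "Q")``.
    """
    for col in grouping:
        if col not in summaries.columns:
            raise KeyError(f"summaries lack descriptor column {col!r}")
    g = summaries.groupby(list(grouping), observed=True)[
        ["n_translocated", "n_rejected", "n_trapped", "trials"]
    ].sum()
    out = pd.DataFrame(
        {
            "pct_translocated": 100 * g["n_translocated"] / g["trials"],
            "pct_rejected": 100 * g["n_rejected"] / g["trials"],
            "pct_trapped": 100 * g["n_trapped"] / g["trials"],
            "n_attempts": g["trials"],
        }
    )
    return out.reset_index()


def percentile_times(
    events: pd.DataFrame,
    fractions: Sequence[float],
    dt: float = DT_PERCENTILES,
    n_attempts: int | None = None,
) -> pd.DataFrame:
    """Time for a given fraction of *all attempts* to have translocated.

    For each fraction ``f`` returns the smallest grid time ``k·δt`` at which
    the cumulative translocated fraction reaches ``f``; unreachable fractions
    (within the observed horizon) are reported as NaN.
    """
    if n_attempts is None:
        n_attempts = len(events)
    times = np.sort(_select_times(events, "translocated"))
    rows = []
    horizon = events["time"].max() if len(events) else 0
    max_k = int(math.ceil(horizon / dt)) + 1
    grid = np.arange(1, max_k + 1) * dt
    cum = np.searchsorted(times, grid, side="right") / n_attempts
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"fraction {f} outside (0, 1)")
        idx = np.searchsorted(cum, f)
        rows.append(
            {"fraction": f, "time": float(grid[idx]) if idx < len(grid) else math.nan}
        )
    return pd.DataFrame(rows)


def subensemble(
    frame: pd.DataFrame, predicate: Callable[[pd.DataFrame], pd.Series] | pd.Series
) -> pd.DataFrame:
    """Filtered view of a summary/record frame; composable."""
    mask = predicate(frame) if callable(predicate) else predicate
    return frame.loc[mask]
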
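"""Metropolis Monte Carlo engine for chain translocation.

One Monte Carlo time step (MCT) is one attempted whole-chain hop of one
monomer length, accepted or not; the chain starts engaged at offset
``x = 0`` with the pore filled.  A trial ends at the first arrival in an
absorbing offset (translocated at ``x = N+1``, rejected at ``x = -6``) or is
classified *trapped* after ``tw`` attempts with the chain still inside.
An absorption on the ``tw``-th attempt counts as absorbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .pore import DEFAULT_PROFILE, Direction, Landscape, PoreProfile, build_landscape
from .sequences import ChargeSequence

#: Default waiting time in MCT.
DEFAULT_WAITING_TIME = 160_000

OUTCOME_LABELS = {
    _kernels.TRANSLOCATED: "translocated",
    _kernels.REJECTED: "rejected",
    _kernels.TRAPPED: "trapped",
}


@dataclass(frozen=True)
class SimConfig:
    """Protocol of a simulation run."""

    tw: int = DEFAULT_WAITING_TIME
    direction: Direction = Direction.CIS_TO_TRANS
    profile: PoreProfile = DEFAULT_PROFILE
    seed: int = 0
    trials: int = 100

    def __post_init__(self) -> None:
        if self.tw < 1:
            raise ValueError("waiting time tw must be >= 1 MCT")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        object.__setattr__(self, "direction", Direction.coerce(self.direction))


@dataclass(frozen=True)
class TrialResult:
    """Outcome of a single seeded trial."""

    outcome: str  # translocated | rejected | trapped
    time: int  # MCT of absorption; equals tw when trapped
    final_offset: int
    seed: int


@dataclass(frozen=True)
class SequenceSummary:
    """Aggregate over the trials of one sequence.

    Rates are percentages of *all* trials; time statistics are conditional on
    the contributing outcome and NaN when that outcome never occurred.
    """

    sequence: ChargeSequence
    direction: Direction
    tw: int
    trials: int
    n_translocated: int
    n_rejected: int
    n_trapped: int
    mean_translocation_time: float
    sd_translocation_time: float
    mean_rejection_time: float
    sd_rejection_time: float

    @property
    def translocated_pct(self) -> float:
        return 100.0 * self.n_translocated / self.trials

    @property
    def rejected_pct(self) -> float:
        return 100.0 * self.n_rejected / self.trials

    @property
    def trapped_pct(self) -> float:
        return 100.0 * self.n_trapped / self.trials

    def as_record(self) -> dict:
        s = self.sequence
        return {
            "id": s.id,
            "sequence": str(s),
            "N": s.N,
            "Q": s.Q,
            "Qh": s.head_charge(),
            "Qmin": s.min_window_charge(),
            "direction": self.direction.value,
            "tw": self.tw,
            "trials": self.trials,
            "n_translocated": self.n_translocated,
            "n_rejected": self.n_rejected,
            "n_trapped": self.n_trapped,
            "mean_ttr": self.mean_translocation_time,
            "sd_ttr": self.sd_translocation_time,
            "mean_trej": self.mean_rejection_time,
            "sd_trej": self.sd_rejection_time,
        }


def _start_index(landscape: Landscape) -> int:
    return -landscape.x_reject  # x = 0 within the 0-based offset table


def run_trial(
    seq: ChargeSequence,
    landscape: Landscape,
    config: SimConfig,
    trial_seed: int,
) -> TrialResult:
    """Run one trial with an explicit seed (deterministic)."""
    seeds = np.asarray([int(trial_seed)], dtype=np.int64)
    out, times, finals = _kernels.run_trials_kernel(
        landscape.energies, int(config.tw), seeds, _start_index(landscape)
    )
    return TrialResult(
        OUTCOME_LABELS[int(out[0])],
        int(times[0]),
        int(finals[0]) + landscape.x_reject,
        int(trial_seed),
    )


def _conditional_stats(times: np.ndarray) -> tuple[float, float]:
    if times.size == 0:
        return (math.nan, math.nan)
    if times.size == 1:
        return (float(times[0]), math.nan)
    return (float(times.mean()), float(times.std(ddof=1)))


def run_trials(
    seq: ChargeSequence,
    config: SimConfig,
    landscape: Landscape | None = None,
    return_events: bool = False,
):
    """Run ``config.trials`` independent trials of one sequence.

    Per-trial seeds are derived counter-style from ``(config.seed,
    sequence-key, trial index)``, so results do not depend on how sequences
    are batched.  Returns the :class:`SequenceSummary`, plus the raw
    ``(outcome code, time)`` arrays when ``return_events`` is set.
    """
    if landscape is None:
        landscape = build_landscape(seq, config.direction, config.profile)
    seeds = _kernels.derive_trial_seeds(config.seed, seq.key(), config.trials)
    out, times, _ = _kernels.run_trials_kernel(
        landscape.energies, int(config.tw), seeds, _start_index(landscape)
    )
    summary = _summarize(seq, config, out, times)
    if return_events:
        return summary, (out, times)
    return summary


def _summarize(seq, config, out, times) -> SequenceSummary:
    tr_mask = out == _kernels.TRANSLOCATED
    rej_mask = out == _kernels.REJECTED
    mean_tr, sd_tr = _conditional_stats(times[tr_mask])
    mean_rej, sd_rej = _conditional_stats(times[rej_mask])
    return SequenceSummary(
        sequence=seq,
        direction=config.direction,
        tw=config.tw,
        trials=len(out),
        n_translocated=int(tr_mask.sum()),
        n_rejected=int(rej_mask.sum()),
        n_trapped=int((out == _kernels.TRAPPED).sum()),
        mean_translocation_time=mean_tr,
        sd_translocation_time=sd_tr,
        mean_rejection_time=mean_rej,
        sd_rejection_time=sd_rej,
    )


@dataclass
class BatchResult:
    """Summaries plus raw per-trial events for a batch of sequences."""

    summaries: list[SequenceSummary]
    events: pd.DataFrame  # columns: id, trial, outcome, time

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_record() for s in self.summaries])


def run_batch(
    sequences: Sequence[ChargeSequence],
    config: SimConfig,
    keep_events: bool = True,
) -> BatchResult:
    """Run every sequence under the same protocol.

    Results are identical to per-sequence :func:`run_trials` calls with the
    same master seed; raw events are retained for histogramming unless
    ``keep_events`` is disabled.
    """
    summaries: list[SequenceSummary] = []
    ev_codes: list[np.ndarray] = []
    ev_times: list[np.ndarray] = []
    ev_ids: list[str] = []
    for seq in sequences:
        landscape = build_landscape(seq, config.direction, config.profile)
        seeds = _kernels.derive_trial_seeds(config.seed, seq.key(), config.trials)
        out, times, _ = _kernels.run_trials_kernel(
            landscape.energies, int(config.tw), seeds, _start_index(landscape)
        )
        summaries.append(_summarize(seq, config, out, times))
        if keep_events:
            ev_codes.append(out)
            ev_times.append(times)
            ev_ids.extend([seq.id] * len(out))
    if keep_events and ev_codes:
        codes = np.concatenate(ev_codes)
        events = pd.DataFrame(
            {
                "id": pd.array(ev_ids, dtype="string"),
                "trial": np.concatenate(
                    [np.arange(len(c)) for c in ev_codes]
                ),
                "outcome": pd.Categorical.from_codes(
                    codes, categories=[OUTCOME_LABELS[i] for i in range(3)]
                ),
                "time": np.concatenate(ev_times),
            }
        )
    else:
        events = pd.DataFrame(
            {"id": pd.array([], dtype="string"), "trial": [], "outcome": [], "time": []}
        )
    return BatchResult(summaries, events)
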
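"""Numba-compiled inner loops of the Metropolis engine.

The hot loop runs one attempted whole-chain hop per Monte Carlo time step
(MCT): pick ±1 with probability 1/2, accept with the Metropolis probability
``min(1, exp(-ΔE))`` (the acceptance draw is skipped for downhill moves,
which changes the random stream but not the law), stop at the first arrival
in an absorbing offset or after ``tw`` attempts.

Trials are seeded individually with counter-derived 31-bit seeds, so runs are
order-independent, resumable, and a run with a larger ``tw`` is a pathwise
continuation of the shorter one.
"""

from __future__ import annotations

import numpy as np
import numba

# outcome codes shared with mc.py
TRANSLOCATED, REJECTED, TRAPPED = 0, 1, 2

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_MUL1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_MUL2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(z: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (uint64 in, uint64 out; wraps mod 2^64)."""
    with np.errstate(over="ignore"):
        z = (z + _SM_GAMMA).astype(np.uint64)
        z ^= z >> np.uint64(30)
        z = (z * _SM_MUL1).astype(np.uint64)
        z ^= z >> np.uint64(27)
        z = (z * _SM_MUL2).astype(np.uint64)
        z ^= z >> np.uint64(31)
    return z


def derive_trial_seeds(master_seed: int, sequence_key: int, n_trials: int, first_trial: int = 0) -> np.ndarray:
    """31-bit per-trial seeds from (master seed, sequence key, trial index)."""
    base = _splitmix64(
        np.uint64(np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF) << np.uint64(32))
        + np.uint64(sequence_key & 0xFFFFFFFF)
    )
    counters = base + np.arange(first_trial, first_trial + n_trials, dtype=np.uint64)
    return (_splitmix64(counters) & np.uint64(0x7FFFFFFF)).astype(np.int64)


@numba.njit(cache=True)
def _acceptance_tables(energies):  # pragma: no cover - numba
    m = energies.shape[0]  # N + 8 offsets, absorbers at 0 and m-1
    acc_f = np.zeros(m)
    acc_b = np.zeros(m)
    for j in range(1, m - 1):
        d = energies[j + 1] - energies[j]
        acc_f[j] = 1.0 if d <= 0.0 else np.exp(-d)
        d = energies[j - 1] - energies[j]
        acc_b[j] = 1.0 if d <= 0.0 else np.exp(-d)
    return acc_f, acc_b


@numba.njit(cache=True)
def run_trials_kernel(energies, tw, seeds, start_index):  # pragma: no cover - numba
    """Run one seeded trial per entry of ``seeds`` on a single landscape.

    Returns (outcome codes, absorption-attempt times, final offset indices).
    """
    m = energies.shape[0]
    acc_f, acc_b = _acceptance_tables(energies)
    n = seeds.shape[0]
    out = np.empty(n, dtype=np.int8)
    times = np.empty(n, dtype=np.int64)
    finals = np.empty(n, dtype=np.int64)
    for k in range(n):
        np.random.seed(seeds[k])
        j = start_index
        t = 0
        code = TRAPPED
        while t < tw:
            t += 1
            if np.random.random() < 0.5:
                a = acc_f[j]
                if a >= 1.0 or np.random.random() < a:
                    j += 1
            else:
                a = acc_b[j]
                if a >= 1.0 or np.random.random() < a:
                    j -= 1
            if j == 0:
                code = REJECTED
                break
            if j == m - 1:
                code = TRANSLOCATED
                break
        out[k] = code
        times[k] = t
        finals[k] = j
    return out, times, finals
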
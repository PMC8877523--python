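"""Bundled reference inputs.

Nine labelled benchmark sequences used throughout the tests and the
reproduction scripts: seven N = 20, Q = 8 polyampholytes with controlled
antagonistic-block structure (a regular sequence, variants with one to three
``-1-1`` blocks, a ``-1-1-1`` block, and reversals probing the pore
asymmetry), plus the charged-residue reduction of the IDP integrase (IN)
fragment read from either end (N = 16, Q = 4).  Charges are in favorable
units; each entry carries the published per-sequence Monte Carlo statistics
(10,000 trials, cis→trans, waiting time 1.6×10⁵ MCT) used as calibration and
validation anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import ChargeSequence, parse_sequence

#: label -> (charge string, Qmin, Qh, mean ttr, sd ttr, success %, trapped %)
_BENCHMARK_ROWS: dict[str, tuple[str, int, int, float, float, float, float]] = {
    "a": ("11-111-111-111-111-111-111", 1, 3, 66, 18, 86, 0),
    "b": ("11-1-11111-1111-111-11-111", 1, 1, 1050, 860, 55, 0),
    "c": ("11-11-111-1111-11111-1-111", 1, 1, 340, 170, 66, 0),
    "d": ("11-1-11111-1-111-111-11111", -1, 1, 2250, 1590, 54, 0),
    "e": ("11-1-1111-1-11111-1-111111", 1, 1, 4270, 2490, 31, 0),
    "f": ("111-1-1-111-11111-11111-11", -1, 1, 69740, 45450, 34, 47),
    "g": ("111-11111-1111-1111-1-1-11", -1, 3, 1440, 1280, 99, 0),
    "h": ("11-1111-1-11 -111-1-111", -1, 3, 3670, 3460, 84, 0),
    "i": ("11-1-111-11-1-1111-111", -1, 1, 7070, 6360, 37, 0),
}


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark sequence with its published trial statistics."""

    sequence: ChargeSequence
    Qmin: int
    Qh: int
    mean_translocation_time: float
    sd_translocation_time: float
    success_pct: float
    trapped_pct: float


def benchmark_sequences() -> dict[str, BenchmarkRecord]:
    """The labelled benchmark set, parsed."""
    out = {}
    for label, (txt, qmin, qh, ttr, sd, succ, trap) in _BENCHMARK_ROWS.items():
        out[label] = BenchmarkRecord(
            parse_sequence(txt, label), qmin, qh, ttr, sd, succ, trap
        )
    return out


def benchmark_sequence(label: str) -> ChargeSequence:
    return benchmark_sequences()[label].sequence
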
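"""Charge sequences of polyampholytes.

A polyampholyte (PA) is modelled as an ordered string of unit charges
``+1``/``-1``.  Charges are expressed in *favorable units*: ``+1`` denotes the
charge species that the applied field drives through the pore in the chosen
engagement direction, ``-1`` the antagonistic species.  Index 0 is the *head*
— the first monomer to exit on the receiving side.

Descriptors used throughout the package:

``Q``
    net charge, sum of all charges.
``Qh``
    net charge of the first five monomers (the head block that initially
    fills the pore).
``Qmin``
    minimum net charge over every contiguous pore-length window of five
    monomers; the most antagonistic block the pore will ever hold.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

#: The pore holds five monomers; shorter chains cannot fill it at engagement.
MIN_LENGTH = 5

#: Window length (in monomers) of the pore interior, used for Qh and Qmin.
PORE_WINDOW = 5

#: Guard for exhaustive enumeration (2**N sequences).
MAX_ENUMERATION_N = 24


class SequenceError(ValueError):
    """Malformed charge-sequence input."""


@dataclass(frozen=True)
class ChargeSequence:
    """An ordered ±1 charge sequence with identity.

    Parameters
    ----------
    charges
        Charges in head-to-tail order, each ``+1`` or ``-1``.
    id
        Free-text label carried through all outputs.
    """

    charges: tuple[int, ...]
    id: str = ""

    def __post_init__(self) -> None:
        if any(c not in (-1, 1) for c in self.charges):
            bad = next(c for c in self.charges if c not in (-1, 1))
            raise SequenceError(f"charges must be +1 or -1, got {bad!r}")
        if len(self.charges) < MIN_LENGTH:
            raise SequenceError(
                f"sequence {self.id!r} has {len(self.charges)} charges; "
                f"at least {MIN_LENGTH} are needed to fill the pore"
            )

    # -- basic descriptors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.charges)

    def __iter__(self) -> Iterator[int]:
        return iter(self.charges)

    @property
    def N(self) -> int:
        """Number of charged monomers."""
        return len(self.charges)

    @property
    def Q(self) -> int:
        """Net charge (favorable units)."""
        return int(sum(self.charges))

    def head_charge(self, window: int = PORE_WINDOW) -> int:
        """Net charge ``Qh`` of the first ``window`` monomers at the head."""
        if window > self.N:
            raise SequenceError(f"window {window} exceeds sequence length {self.N}")
        return int(sum(self.charges[:window]))

    def min_window_charge(self, window: int = PORE_WINDOW) -> int:
        """Minimum net charge ``Qmin`` over all contiguous windows."""
        if window > self.N:
            raise SequenceError(f"window {window} exceeds sequence length {self.N}")
        arr = self.as_array()
        sums = np.convolve(arr, np.ones(window, dtype=np.int64), mode="valid")
        return int(sums.min())

    def reverse(self) -> "ChargeSequence":
        """The same chain engaged from the other end."""
        new_id = self.id[: -len("_rev")] if self.id.endswith("_rev") else self.id + "_rev"
        return ChargeSequence(self.charges[::-1], new_id)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.charges, dtype=np.int8)

    def key(self) -> int:
        """Deterministic 32-bit key of the charge pattern (seed derivation)."""
        bits = bytes(1 if c > 0 else 0 for c in self.charges)
        return zlib.crc32(bits + len(self.charges).to_bytes(4, "little"))

    def __str__(self) -> str:
        return format_sequence(self)


def format_sequence(seq: ChargeSequence) -> str:
    """Render a sequence as a ``1``/``-1`` token string."""
    return "".join("1" if c > 0 else "-1" for c in seq.charges)


def parse_sequence(text: str, id: str = "") -> ChargeSequence:
    """Parse a ``1``/``-1`` token string into a :class:`ChargeSequence`.

    Whitespace anywhere in the string is ignored (printed sequences
    occasionally contain stray spaces).  A ``-`` must be immediately followed
    by ``1``.
    """
    charges: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "1":
            charges.append(1)
            i += 1
        elif ch == "-":
            # allow whitespace between '-' and '1'?  No: the token is "-1".
            if i + 1 < n and text[i + 1] == "1":
                charges.append(-1)
                i += 2
            else:
                raise SequenceError(f"dangling '-' at position {i} in {text!r}")
        else:
            raise SequenceError(f"unexpected character {ch!r} at position {i} in {text!r}")
    return ChargeSequence(tuple(charges), id)


# -- enumeration and sampling ---------------------------------------------


def enumerate_charge_matrix(N: int) -> np.ndarray:
    """All ``2**N`` charge sequences as a ``(2**N, N)`` int8 array.

    Row ``m`` encodes integer ``m`` in binary with bit ``i`` giving monomer
    ``i`` (bit set → ``+1``).  Column 0 is the head.
    """
    if N > MAX_ENUMERATION_N:
        raise SequenceError(f"refusing to enumerate 2**{N} sequences (limit N={MAX_ENUMERATION_N})")
    codes = np.arange(2**N, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(N, dtype=np.uint32)) & 1
    return (bits.astype(np.int8) * 2 - 1).astype(np.int8)


def enumerate_sequences(N: int, allow_large: bool = False) -> Iterator[ChargeSequence]:
    """Yield every ±1 sequence of length ``N`` once, in binary-counting order."""
    if N < MIN_LENGTH:
        raise SequenceError(f"N={N} below minimum length {MIN_LENGTH}")
    if N > MAX_ENUMERATION_N and not allow_large:
        raise SequenceError(f"refusing to enumerate 2**{N} sequences without allow_large=True")
    for m in range(2**N):
        charges = tuple(1 if (m >> i) & 1 else -1 for i in range(N))
        yield ChargeSequence(charges, f"enum{N}_{m}")


def enumerate_with_charge(N: int, Q: int) -> list[ChargeSequence]:
    """All sequences of length ``N`` with exact net charge ``Q``.

    Enumerates positions of the antagonistic charges; the caller is expected
    to keep ``(N - Q) / 2`` small (there are ``C(N, (N-Q)/2)`` sequences).
    """
    _check_composition(N, Q)
    n_neg = (N - Q) // 2
    out = []
    for k, neg_positions in enumerate(itertools.combinations(range(N), n_neg)):
        charges = [1] * N
        for p in neg_positions:
            charges[p] = -1
        out.append(ChargeSequence(tuple(charges), f"Q{Q}_N{N}_{k}"))
    return out


def _check_composition(N: int, Q: int) -> None:
    if abs(Q) > N or (N - Q) % 2 != 0:
        raise SequenceError(f"net charge Q={Q} infeasible for N={N} (need |Q|<=N, Q≡N mod 2)")


def sample_sequences(
    N: int,
    count: int,
    seed: int,
    Q: int | None = None,
    id_prefix: str | None = None,
) -> list[ChargeSequence]:
    """Random charge sequences, reproducible from ``seed``.

    Unconstrained (``Q is None``): every site is independently ``+1`` or
    ``-1`` with probability 1/2.  Constrained: a uniformly random permutation
    of the fixed composition with exactly ``(N+Q)/2`` favorable charges, so
    every sample has net charge exactly ``Q``.
    """
    if N < MIN_LENGTH:
        raise SequenceError(f"N={N} below minimum length {MIN_LENGTH}")
    rng = np.random.default_rng(seed)
    if Q is None:
        mat = rng.integers(0, 2, size=(count, N), dtype=np.int8) * 2 - 1
        prefix = id_prefix or f"rand{N}"
    else:
        _check_composition(N, Q)
        base = np.concatenate(
            [np.ones((N + Q) // 2, dtype=np.int8), -np.ones((N - Q) // 2, dtype=np.int8)]
        )
        order = np.argsort(rng.random(size=(count, N)), axis=1)
        mat = base[order]
        prefix = id_prefix or f"rand{N}_Q{Q}"
    return [
        ChargeSequence(tuple(int(c) for c in row), f"{prefix}_{k}")
        for k, row in enumerate(mat)
    ]


# -- protein reduction -----------------------------------------------------

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ChargeMapping:
    """Amino-acid → charge mapping used to reduce a protein to its PA skeleton.

    ``table`` maps one-letter codes to ``+1`` (basic), ``-1`` (acidic) or
    ``0`` (dropped / neutral).  Histidine is dropped by default because its
    protonation state near neutral pH is ambiguous.
    """

    table: dict[str, int] = field(
        default_factory=lambda: {
            **{aa: 0 for aa in STANDARD_AA},
            "D": -1,
            "E": -1,
            "K": 1,
            "R": 1,
        }
    )

    def __post_init__(self) -> None:
        if set(self.table) != STANDARD_AA:
            missing = STANDARD_AA - set(self.table)
            extra = set(self.table) - STANDARD_AA
            raise SequenceError(f"mapping must cover the 20 standard codes (missing {sorted(missing)}, extra {sorted(extra)})")
        if any(v not in (-1, 0, 1) for v in self.table.values()):
            raise SequenceError("mapping values must be +1, -1 or 0 (drop)")

    def with_histidine(self, value: int) -> "ChargeMapping":
        return ChargeMapping({**self.table, "H": value})


DEFAULT_CHARGE_MAPPING = ChargeMapping()


def reduce_protein(
    aa_sequence: str,
    mapping: ChargeMapping | None = None,
    favorable_sign: int = 1,
    id: str = "",
) -> ChargeSequence:
    """Reduce a protein sequence to its charged residues, in favorable units.

    ``favorable_sign`` names the *physical* sign that is favorable for the
    planned translocation; residues of that sign become ``+1``.  E.g. an
    acidic protein driven as an anion uses ``favorable_sign=-1``.
    """
    if favorable_sign not in (-1, 1):
        raise SequenceError("favorable_sign must be +1 or -1")
    mapping = mapping or DEFAULT_CHARGE_MAPPING
    charges = []
    unknown = sorted(
        {ch for ch in aa_sequence.upper() if not ch.isspace() and ch not in STANDARD_AA}
    )
    if unknown:
        raise SequenceError(f"unknown residue code(s): {', '.join(unknown)}")
    for ch in aa_sequence.upper():
        if ch.isspace():
            continue
        v = mapping.table[ch]
        if v != 0:
            charges.append(v * favorable_sign)
    return ChargeSequence(tuple(charges), id)


# -- plain-text sequence files ---------------------------------------------


def read_sequence_file(path) -> list[ChargeSequence]:
    """Read sequences from a text file: one per line, optional ``id<TAB>`` prefix,
    ``#`` comment lines ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                label, body = line.split("\t", 1)
            else:
                label, body = f"seq{lineno}", line
            try:
                out.append(parse_sequence(body, label.strip()))
            except SequenceError as exc:
                raise SequenceError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_sequence_file(path, sequences: Iterable[ChargeSequence], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for seq in sequences:
            fh.write(f"{seq.id}\t{format_sequence(seq)}\n")
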
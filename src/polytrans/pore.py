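"""Free-energy landscape of a chain threading the α-hemolysin pore.

The pore is modelled as a one-dimensional channel of length 5 monomer sizes
(``a`` = 2 nm, one unit charge per monomer).  Small-ion free-energy
calculations for α-hemolysin under a +150 mV transmembrane potential provide
the per-charge free energy at seven axial sites ``s = -1, 0, ..., 5`` (units
of ``a``), separately for cations and for anions.  Outside the pore the cis
bulk is the zero of energy and the trans bulk sits at ``±V`` per unit charge,
``V = e·150 mV / kBT``.

The chain hops rigidly by one site at a time; its configuration is a single
integer offset ``x`` counting net forward hops since engagement.  The total
energy ``E(x)`` — the sum of per-monomer free energies — is precomputed for
every reachable offset in a :class:`Landscape`, which both the Metropolis
engine and the exact solver consume.

Conventions
-----------
* Engagement places five monomers in the pore (head at the far edge:
  site 4 for cis→trans, site 0 for trans→cis) plus the sixth monomer on the
  tabulated boundary site.
* Translocation is absorbed at ``x = N + 1`` (tail strictly past the pore on
  the receiving side); rejection at ``x = -6`` (head strictly past the pore
  on the engagement side).  Transient offsets are ``-5 .. N``.
* Under +150 mV the anion is the favorable species cis→trans and the cation
  is favorable trans→cis, so favorable-unit charges resolve to physical
  species per direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .sequences import ChargeSequence

#: Published per-ion free-energy magnitudes (kBT) under +150 mV, seven axial
#: positions listed from the trans side, each species relative to free
#: solution.  These are the raw literature values; the working profile below
#: reorients the axis cis→trans and references both species to the cis bulk.
TABULATED_CATION: tuple[float, ...] = (5.53, 6.98, 5.00, 4.65, 1.59, 2.32, 0.07)
TABULATED_ANION: tuple[float, ...] = (0.07, 3.35, 8.82, 9.08, 7.47, 7.00, 5.87)


def _cis_referenced(table: tuple[float, ...]) -> tuple[float, ...]:
    """Reorient a published row to run cis→trans and zero its cis-edge value.

    The published positions are listed from the trans side, and each row
    carries its own solution reference.  Reversing the row and subtracting
    the (new) first entry expresses it on the working convention: site index
    -1 (cis edge) .. 5 (trans edge), cis bulk = 0.  The resulting profiles
    join the bulk levels smoothly at both ends (cation trans edge 5.46 vs
    bulk +V; anion trans edge -5.80 vs bulk -V) and reproduce the field
    asymmetry of the pore: the anion's driving force is concentrated at the
    trans edge while the cation's is spread along the channel.
    """
    rev = table[::-1]
    return tuple(round(v - rev[0], 10) for v in rev)


#: Working site energies (kBT), sites s = -1 .. 5, cis bulk = 0.
CATION_SITE_ENERGIES: tuple[float, ...] = _cis_referenced(TABULATED_CATION)
ANION_SITE_ENERGIES: tuple[float, ...] = _cis_referenced(TABULATED_ANION)

#: e * 150 mV / kBT at 298 K: trans-bulk energy of a unit positive charge.
DEFAULT_TRANS_BULK_OFFSET = 5.84

N_SITES = 7  # tabulated axial sites s = -1 .. 5
SITE_MIN, SITE_MAX = -1, 5

X_REJECT_OFFSET = -6  # head fully retracted: rejection absorber


class Direction(str, enum.Enum):
    """Engagement direction through the asymmetric pore."""

    CIS_TO_TRANS = "cis2trans"
    TRANS_TO_CIS = "trans2cis"

    @classmethod
    def coerce(cls, value) -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            aliases = {
                "cis_to_trans": cls.CIS_TO_TRANS,
                "trans_to_cis": cls.TRANS_TO_CIS,
                "reverse": cls.TRANS_TO_CIS,
            }
            if value in aliases:
                return aliases[value]
            raise ValueError(f"unknown direction {value!r}")


@dataclass(frozen=True)
class PoreProfile:
    """Per-species site free energies plus the trans-bulk offset, in kBT."""

    cation: tuple[float, ...] = CATION_SITE_ENERGIES
    anion: tuple[float, ...] = ANION_SITE_ENERGIES
    trans_bulk_offset: float = DEFAULT_TRANS_BULK_OFFSET
    polarity_mV: float = 150.0

    def __post_init__(self) -> None:
        if len(self.cation) != N_SITES or len(self.anion) != N_SITES:
            raise ValueError(f"profiles need exactly {N_SITES} site values (sites -1..5)")
        if not np.isfinite(self.trans_bulk_offset):
            raise ValueError("trans_bulk_offset must be finite")

    def species_table(self, species: str) -> tuple[float, ...]:
        return self.cation if species == "cation" else self.anion

    def bulk_energy(self, species: str) -> float:
        """Trans-bulk energy per charge (cis bulk is the zero)."""
        v = self.trans_bulk_offset
        return v if species == "cation" else -v


DEFAULT_PROFILE = PoreProfile()


def favorable_species(direction: Direction) -> str:
    """Physical species driven through the pore in the given direction."""
    direction = Direction.coerce(direction)
    return "anion" if direction is Direction.CIS_TO_TRANS else "cation"


def resolve_species(q: int, direction: Direction) -> str:
    """Physical species of a favorable-unit charge ``q``."""
    fav = favorable_species(direction)
    if q > 0:
        return fav
    return "cation" if fav == "anion" else "anion"


def monomer_site(i: int, x: int, direction: Direction) -> int:
    """Axial site of monomer ``i`` at chain offset ``x``.

    cis→trans: ``s = (4 + x) - i`` (head exits toward larger s);
    trans→cis: ``s = i - x`` (head exits toward smaller s).
    """
    direction = Direction.coerce(direction)
    if direction is Direction.CIS_TO_TRANS:
        return (4 + x) - i
    return i - x


def monomer_energy(
    q: int,
    s: int,
    direction: Direction,
    profile: PoreProfile = DEFAULT_PROFILE,
) -> float:
    """Free energy (kBT) of a single favorable-unit charge ``q`` at site ``s``.

    The site axis is fixed to the pore for both directions: ``s < -1`` is the
    cis bulk (the energy zero) and ``s > 5`` the trans bulk at ``±V``.
    """
    species = resolve_species(q, direction)
    if s < SITE_MIN:
        return 0.0
    if s > SITE_MAX:
        return profile.bulk_energy(species)
    return profile.species_table(species)[s - SITE_MIN]


def chain_energy(
    seq: ChargeSequence,
    x: int,
    direction: Direction,
    profile: PoreProfile = DEFAULT_PROFILE,
) -> float:
    """Total chain energy at offset ``x`` by per-monomer summation."""
    return float(
        sum(
            monomer_energy(q, monomer_site(i, x, direction), direction, profile)
            for i, q in enumerate(seq)
        )
    )


@dataclass(frozen=True)
class Landscape:
    """Precomputed total energy E(x) for every offset of one engaged chain.

    Offsets run from the rejection absorber ``x = -6`` to the translocation
    absorber ``x = N + 1``; the transient set is ``-5 .. N``.
    """

    sequence: ChargeSequence
    direction: Direction
    profile: PoreProfile
    energies: np.ndarray  # length N + 8, index x + 6

    @property
    def N(self) -> int:
        return self.sequence.N

    @property
    def x_reject(self) -> int:
        return X_REJECT_OFFSET

    @property
    def x_translocate(self) -> int:
        return self.N + 1

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.x_reject, self.x_translocate + 1)

    @property
    def n_transient(self) -> int:
        return self.N + 6

    def energy(self, x: int) -> float:
        if not self.x_reject <= x <= self.x_translocate:
            raise ValueError(f"offset {x} outside landscape range")
        return float(self.energies[x - self.x_reject])


def build_landscape(
    seq: ChargeSequence,
    direction: Direction,
    profile: PoreProfile = DEFAULT_PROFILE,
) -> Landscape:
    """Vectorized construction of the full energy table E(x), x = -6 .. N+1."""
    direction = Direction.coerce(direction)
    N = seq.N
    x = np.arange(X_REJECT_OFFSET, N + 2)
    i = np.arange(N)
    if direction is Direction.CIS_TO_TRANS:
        sites = (4 + x)[:, None] - i[None, :]
    else:
        sites = i[None, :] - x[:, None]

    # Per-species lookup over clipped site index: [below-pore, sites -1..5, above-pore].
    energies = np.zeros(len(x))
    for q_sign, mask in ((1, seq.as_array() > 0), (-1, seq.as_array() < 0)):
        if not mask.any():
            continue
        species = resolve_species(q_sign, direction)
        # s below the pore is the cis bulk (zero), above it the trans bulk.
        lut = np.array([0.0, *profile.species_table(species), profile.bulk_energy(species)])
        idx = np.clip(sites - (SITE_MIN - 1), 0, N_SITES + 1)
        energies += lut[idx][:, mask].sum(axis=1)
    return Landscape(seq, direction, profile, energies)


# -- profile override files ------------------------------------------------


def read_profile_tsv(path, trans_bulk_offset: float | None = None) -> PoreProfile:
    """Read a site/cation/anion TSV (sites -1..5).  Lines starting ``#`` and a
    ``V<TAB>value`` row (trans-bulk offset) are honoured."""
    cat = {}
    an = {}
    v = trans_bulk_offset
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("site"):
                continue
            parts = line.split("\t")
            if parts[0] in ("V", "v", "trans_bulk_offset"):
                v = float(parts[1])
                continue
            s = int(parts[0])
            cat[s] = float(parts[1])
            an[s] = float(parts[2])
    sites = list(range(SITE_MIN, SITE_MAX + 1))
    if sorted(cat) != sites:
        raise ValueError(f"profile file {path} must tabulate sites {SITE_MIN}..{SITE_MAX}")
    kwargs = {}
    if v is not None:
        kwargs["trans_bulk_offset"] = v
    return PoreProfile(
        tuple(cat[s] for s in sites), tuple(an[s] for s in sites), **kwargs
    )


def write_profile_tsv(path, profile: PoreProfile = DEFAULT_PROFILE, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("site\tcation_kBT\tanion_kBT\n")
        fh.write(f"V\t{profile.trans_bulk_offset}\n")
        for k, s in enumerate(range(SITE_MIN, SITE_MAX + 1)):
            fh.write(f"{s}\t{profile.cation[k]}\t{profile.anion[k]}\n")
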
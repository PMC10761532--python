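"""Multimer genome species predicted by the replication-intermediate model.

A construct is a unit-length single-stranded genome flanked by two inverted
terminal repeats (ITRs).  Replication intermediates are head-to-head
concatemers, so a packaged genome carrying N ITRs contains N - 1 copies of
the gene of interest (GOI) and has length

    L(N) = N * I + (N - 1) * G

where I is the per-junction ITR contribution and G the internal gene segment
(G = unit_length - 2 * I).  Every species short enough to fit the capsid
capacity is considered packageable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

#: Per-junction ITR contribution (nt) consistent with the observed multimer
#: ladders (848 -> 1,566 and 1,320 -> 2,510 both imply I = 130).  The
#: canonical full ITR element is 145 nt; see :class:`ConstructDef`.
DEFAULT_ITR_JUNCTION_LENGTH = 130

#: Approximate packaging capacity of the capsid (nt).
DEFAULT_CAPACITY = 5200

#: Hard cap on the concatemer order explored during enumeration, so that
#: degenerate tiny constructs still terminate.
MAX_N_ITR = 50

EMPTY_LABEL = "empty"


@dataclass(frozen=True)
class ConstructDef:
    """A vector construct: unit genome geometry plus capsid capacity.

    Parameters
    ----------
    name
        Free-text label, e.g. ``"TTR-848"``.
    unit_length
        Length in nt of the complete 1GOI-2ITR genome, ITR to ITR inclusive.
    itr_junction_length
        Effective per-junction ITR contribution I in nt.  Defaults to 130,
        the value forced by the observed multimer ladders, rather than the
        145 nt of the full ITR element.
    capacity
        Maximum packageable length in nt.
    """

    name: str
    unit_length: int
    itr_junction_length: int = DEFAULT_ITR_JUNCTION_LENGTH
    capacity: int = DEFAULT_CAPACITY

    def __post_init__(self) -> None:
        if self.unit_length <= 2 * self.itr_junction_length:
            raise InvalidArgumentError(
                f"unit_length ({self.unit_length}) must exceed twice the ITR "
                f"junction length ({self.itr_junction_length}); internal gene "
                "segment would not be positive"
            )
        if self.itr_junction_length <= 0:
            raise InvalidArgumentError("itr_junction_length must be positive")
        if self.capacity <= 0:
            raise InvalidArgumentError("capacity must be positive")
        if self.capacity < self.unit_length:
            # legal but degenerate: not even the monomer fits
            logger.warning(
                "construct %s: capacity %d nt below unit length %d nt; "
                "no species will fit",
                self.name,
                self.capacity,
                self.unit_length,
            )
        if self.itr_junction_length != DEFAULT_ITR_JUNCTION_LENGTH:
            logger.warning(
                "construct %s uses ITR junction length %d nt; the multimer "
                "ladder calibration implies %d nt (full ITR element is 145 nt)",
                self.name,
                self.itr_junction_length,
                DEFAULT_ITR_JUNCTION_LENGTH,
            )

    @property
    def gene_length(self) -> int:
        """Internal gene segment G = unit_length - 2 I (nt)."""
        return self.unit_length - 2 * self.itr_junction_length


@dataclass(frozen=True)
class MultimerSpecies:
    """One packageable genome species (or the empty-capsid placeholder)."""

    n_itr: int
    n_goi: int
    nt_length: int
    label: str
    is_empty: bool = False

    def __post_init__(self) -> None:
        if self.is_empty:
            if self.nt_length != 0:
                raise InvalidArgumentError("empty species must have zero length")
        else:
            if self.n_itr < 2:
                raise InvalidArgumentError("filled species needs n_itr >= 2")
            if self.n_goi != self.n_itr - 1:
                raise InvalidArgumentError("n_goi must equal n_itr - 1")


EMPTY_SPECIES = MultimerSpecies(
    n_itr=0, n_goi=0, nt_length=0, label=EMPTY_LABEL, is_empty=True
)


def species_label(n_itr: int) -> str:
    """Canonical species label, e.g. ``"1GOI-2ITR"`` for n_itr = 2."""
    return f"{n_itr - 1}GOI-{n_itr}ITR"


def species_length(n_itr: int, construct: ConstructDef) -> int:
    """Packaged length L = N*I + (N-1)*G for a species with ``n_itr`` ITRs.

    ``n_itr = 1`` is the degenerate single-ITR case whose gene term vanishes.
    """
    if n_itr < 1:
        raise InvalidArgumentError(f"n_itr must be >= 1, got {n_itr}")
    i = construct.itr_junction_length
    return n_itr * i + (n_itr - 1) * construct.gene_length


def make_species(n_itr: int, construct: ConstructDef) -> MultimerSpecies:
    """Build the :class:`MultimerSpecies` with ``n_itr`` ITRs (n_itr >= 2)."""
    if n_itr < 2:
        raise InvalidArgumentError("a packaged species needs at least 2 ITRs")
    return MultimerSpecies(
        n_itr=n_itr,
        n_goi=n_itr - 1,
        nt_length=species_length(n_itr, construct),
        label=species_label(n_itr),
    )


def enumerate_species(construct: ConstructDef) -> list[MultimerSpecies]:
    """All packaged species fitting the capacity, ascending by length.

    Lengths increase strictly with N, so enumeration stops at the first
    species exceeding the capacity (bounded by :data:`MAX_N_ITR`).
    """
    out: list[MultimerSpecies] = []
    for n in range(2, MAX_N_ITR + 1):
        length = species_length(n, construct)
        if length > construct.capacity:
            break
        out.append(make_species(n, construct))
    return out


def full_species_list(construct: ConstructDef) -> list[MultimerSpecies]:
    """The empty-capsid species followed by all packaged species."""
    return [EMPTY_SPECIES, *enumerate_species(construct)]


def digest_to_units(
    species: MultimerSpecies, construct: ConstructDef
) -> list[int]:
    """Fragment lengths after a single-cutter digest (one site per GOI copy).

    Models the collapse of multimer genomes to unit-scale bands: the digest
    yields exactly ``n_goi`` fragments, with the two terminal sub-fragments
    merged into their flanking fragments.  The first fragment therefore
    carries both terminal ITR pieces (length = unit_length) and every other
    fragment has length unit_length - I.  Fragment lengths always sum to the
    species length.
    """
    if species.is_empty:
        raise InvalidArgumentError("cannot digest the empty species")
    i = construct.itr_junction_length
    g = construct.gene_length
    fragments = [2 * i + g]  # == unit_length
    fragments.extend([i + g] * (species.n_goi - 1))
    return fragments


def species_frame(species_list: list[MultimerSpecies]) -> pd.DataFrame:
    """Tabulate species as a DataFrame (label, n_itr, n_goi, nt_length)."""
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "n_itr": s.n_itr,
                "n_goi": s.n_goi,
                "nt_length": s.nt_length,
            }
            for s in species_list
        ],
        columns=["label", "n_itr", "n_goi", "nt_length"],
    )
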
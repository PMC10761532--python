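"""Particle mass prediction and per-species assignment windows.

The mass of a particle is the capsid shell mass (fixed VP1/VP2/VP3
stoichiometry) plus the mass of the packaged single-stranded genome,
inflated by a multiplicative counterion factor.  Each species gets a mass
window (predicted mass +/- a fractional half-width) used downstream to
assign single-ion masses; windows that would overlap are clipped at the
midpoint between adjacent predicted masses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import InvalidArgumentError
from .genome_model import MultimerSpecies

#: Mean residue mass of single-stranded DNA (Da/nt, free-acid form).  The
#: true value is sequence dependent; this is a standard average.
DEFAULT_AVG_NT_MASS = 308.9

#: Multiplicative inflation of genome mass from bound counterions (~4%).
DEFAULT_COUNTERION_FACTOR = 1.04

#: Fractional half-width of assignment windows.  +/-1.5% of the predicted
#: mass is ~3 standard deviations of single-ion mass error at the standard
#: noise preset, so windows capture species ions while leaving resolvable
#: inter-window gaps for partial genomes.
DEFAULT_WINDOW_HALF_WIDTH = 0.015


@dataclass(frozen=True)
class CapsidModel:
    """Capsid shell composition: VP subunit masses (Da) and counts."""

    vp1_mass: float
    vp2_mass: float
    vp3_mass: float
    vp1_count: int = 5
    vp2_count: int = 5
    vp3_count: int = 50

    def __post_init__(self) -> None:
        total = self.vp1_count + self.vp2_count + self.vp3_count
        if total != 60:
            raise InvalidArgumentError(
                f"VP counts must sum to 60 (T=1 icosahedron), got {total}"
            )
        for name in ("vp1_mass", "vp2_mass", "vp3_mass"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")


#: Approximate AAV8 capsid preset (subunit masses rounded to 0.1 kDa;
#: sequence-exact masses depend on serotype annotation and modifications).
AAV8_CAPSID_APPROX = CapsidModel(
    vp1_mass=81_600.0, vp2_mass=66_600.0, vp3_mass=59_800.0
)


@dataclass(frozen=True)
class MassModelParams:
    avg_nt_mass: float = DEFAULT_AVG_NT_MASS
    counterion_factor: float = DEFAULT_COUNTERION_FACTOR

    def __post_init__(self) -> None:
        if self.avg_nt_mass <= 0:
            raise InvalidArgumentError("avg_nt_mass must be positive")
        if self.counterion_factor < 1.0:
            raise InvalidArgumentError("counterion_factor must be >= 1")


@dataclass(frozen=True)
class MassWindow:
    """One row of the species mass table."""

    label: str
    nt_length: int
    predicted_mass: float
    window_low: float
    window_high: float
    is_empty: bool = False


@dataclass(frozen=True)
class SpeciesMassTable:
    """Per-species predicted masses and non-overlapping assignment windows.

    Rows are ordered by strictly increasing predicted mass; windows are
    half-open ``(low, high]`` so a mass on a shared boundary belongs to the
    lower-mass species.
    """

    rows: tuple[MassWindow, ...]

    def __post_init__(self) -> None:
        masses = [r.predicted_mass for r in self.rows]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise InvalidArgumentError(
                "predicted masses must be strictly increasing"
            )

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def row(self, label: str) -> MassWindow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "nt_length": r.nt_length,
                    "predicted_mass_da": r.predicted_mass,
                    "window_low_da": r.window_low,
                    "window_high_da": r.window_high,
                }
                for r in self.rows
            ],
            columns=[
                "label",
                "nt_length",
                "predicted_mass_da",
                "window_low_da",
                "window_high_da",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpeciesMassTable":
        rows = tuple(
            MassWindow(
                label=str(rec.label),
                nt_length=int(rec.nt_length),
                predicted_mass=float(rec.predicted_mass_da),
                window_low=float(rec.window_low_da),
                window_high=float(rec.window_high_da),
                is_empty=int(rec.nt_length) == 0,
            )
            for rec in frame.itertuples()
        )
        return cls(rows=rows)


def capsid_mass(capsid: CapsidModel) -> float:
    """Total shell mass in Da (weighted sum of subunit masses)."""
    return (
        capsid.vp1_count * capsid.vp1_mass
        + capsid.vp2_count * capsid.vp2_mass
        + capsid.vp3_count * capsid.vp3_mass
    )


def genome_mass(nt_length: int, params: MassModelParams) -> float:
    """Counterion-corrected ssDNA mass in Da for ``nt_length`` nucleotides."""
    if nt_length < 0:
        raise InvalidArgumentError("nt_length must be non-negative")
    return nt_length * params.avg_nt_mass * params.counterion_factor


def build_mass_table(
    species_list: list[MultimerSpecies],
    capsid: CapsidModel,
    params: MassModelParams,
    window_half_width: float = DEFAULT_WINDOW_HALF_WIDTH,
) -> SpeciesMassTable:
    """Predict masses and assignment windows for each species.

    ``species_list`` should include the empty species (from
    :func:`aavpack.genome_model.full_species_list`).  Windows are
    ``predicted * (1 +/- window_half_width)``, then clipped at the midpoint
    of adjacent predicted masses wherever they would overlap.
    """
    if window_half_width <= 0:
        raise InvalidArgumentError("window_half_width must be positive")
    shell = capsid_mass(capsid)
    ordered = sorted(species_list, key=lambda s: s.nt_length)
    rows = []
    for s in ordered:
        mass = shell + genome_mass(s.nt_length, params)
        rows.append(
            MassWindow(
                label=s.label,
                nt_length=s.nt_length,
                predicted_mass=mass,
                window_low=mass * (1.0 - window_half_width),
                window_high=mass * (1.0 + window_half_width),
                is_empty=s.is_empty,
            )
        )
    # clip overlapping neighbours at the midpoint of their predicted masses
    for i in range(len(rows) - 1):
        lo, hi = rows[i], rows[i + 1]
        if lo.window_high > hi.window_low:
            mid = 0.5 * (lo.predicted_mass + hi.predicted_mass)
            rows[i] = replace(lo, window_high=mid)
            rows[i + 1] = replace(hi, window_low=mid)
    return SpeciesMassTable(rows=tuple(rows))
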
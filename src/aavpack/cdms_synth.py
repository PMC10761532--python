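"""Synthetic charge-detection mass-spectrometry (CD-MS) single-ion events.

Each simulated ion carries a measured m/z and a measured charge; their
product is the derived single-particle mass.  The simulator draws species
multinomially from a mixture, gives every particle a charge from one shared
Gaussian (charges are empirically similar across genome lengths, so the
charge scale cancels out of abundance estimates), and adds independent
Gaussian errors to charge and m/z.

A mixture may contain the reserved component :data:`PARTIAL_LABEL` for
capsids holding DNA of intermediate, non-model mass; partial ions get a
true mass drawn uniformly from the gaps between species assignment windows
(shrunk by a noise margin so they stay unassignable after measurement
error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidArgumentError, IonParseError, SchemaError
from .mass_model import SpeciesMassTable

PARTIAL_LABEL = "partial"

#: Charge-uncertainty presets (elementary charges): standard trapping vs the
#: long-trapping high-resolution mode.
CHARGE_SIGMA_PRESETS = {"standard": 1.0, "high_resolution": 0.5}

#: Default mean particle charge (e).  No measured charge values are
#: available to anchor this; 240 e is chosen so that the standard preset
#: (charge sigma 1 e) yields a single-ion mass resolution near 100 FWHM,
#: the instrument's expected figure.  The value cancels out of all
#: abundance estimates.
DEFAULT_CHARGE_MEAN = 240.0

#: Spread of true particle charges around the mean (e).  Affects only the
#: charge axis, not derived masses (true m/z and true charge are consistent
#: per ion).
DEFAULT_CHARGE_SPREAD = 3.0

DEFAULT_MZ_CV = 0.002

#: Partial-genome true masses are kept this many single-ion mass standard
#: deviations away from window edges so measurement noise rarely pushes
#: them into a species window.
PARTIAL_EDGE_MARGIN_SD = 2.0

ION_COLUMNS = ["ion_id", "measured_mz", "measured_charge", "derived_mass"]


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth species fractions; must sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        vals = list(self.fractions.values())
        if any(v < 0 for v in vals):
            raise InvalidArgumentError("mixture fractions must be >= 0")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"mixture fractions must sum to 1 (got {total!r})"
            )

    @property
    def labels(self) -> list[str]:
        return list(self.fractions)

    @classmethod
    def from_abundances(cls, abundances: dict[str, float]) -> "MixtureSpec":
        """Normalize arbitrary non-negative abundances into a mixture."""
        total = sum(abundances.values())
        if total <= 0:
            raise InvalidArgumentError("abundances must have positive sum")
        return cls({k: v / total for k, v in abundances.items()})


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings for one simulated dataset.

    ``seed`` is mandatory: every dataset must be reproducible.
    """

    seed: int
    n_ions: int = 10_000
    charge_mean: float = DEFAULT_CHARGE_MEAN
    charge_spread: float = DEFAULT_CHARGE_SPREAD
    charge_sigma: float = CHARGE_SIGMA_PRESETS["standard"]
    mz_cv: float = DEFAULT_MZ_CV

    def __post_init__(self) -> None:
        if self.n_ions < 1:
            raise InvalidArgumentError("n_ions must be >= 1")
        if self.charge_mean <= 0:
            raise InvalidArgumentError("charge_mean must be positive")
        if self.charge_sigma < 0 or self.charge_spread < 0 or self.mz_cv < 0:
            raise InvalidArgumentError("noise scales must be non-negative")

    @property
    def mass_rel_sd(self) -> float:
        """First-order relative standard deviation of derived masses."""
        return math.hypot(self.charge_sigma / self.charge_mean, self.mz_cv)

    @classmethod
    def preset(cls, mode: str, seed: int, **kwargs) -> "SimConfig":
        if mode not in CHARGE_SIGMA_PRESETS:
            raise ConfigError(
                f"unknown acquisition mode {mode!r}; choose from "
                f"{sorted(CHARGE_SIGMA_PRESETS)}"
            )
        return cls(seed=seed, charge_sigma=CHARGE_SIGMA_PRESETS[mode], **kwargs)


@dataclass(frozen=True)
class IonEvent:
    """One single-ion measurement."""

    measured_mz: float
    measured_charge: float
    derived_mass: float
    true_species: str | None = None


def _partial_support(
    table: SpeciesMassTable, margin_sd: float, mass_rel_sd: float
) -> list[tuple[float, float]]:
    """Intervals between adjacent assignment windows available to partials."""
    intervals = []
    for lo, hi in zip(table.rows, table.rows[1:]):
        margin = margin_sd * mass_rel_sd * 0.5 * (lo.window_high + hi.window_low)
        a = lo.window_high + margin
        b = hi.window_low - margin
        if b > a:
            intervals.append((a, b))
        elif hi.window_low > lo.window_high:
            mid = 0.5 * (lo.window_high + hi.window_low)
            intervals.append((mid, mid))
    if not intervals:
        raise ConfigError(
            "mass table has no inter-window gaps; cannot place partial ions"
        )
    return intervals


def simulate_ions(
    mixture: MixtureSpec,
    mass_table: SpeciesMassTable,
    sim: SimConfig,
) -> list[IonEvent]:
    """Simulate ``sim.n_ions`` single-ion events from a species mixture.

    Species are drawn multinomially by mixture fraction; per ion the true
    charge is ``N(charge_mean, charge_spread)``, the measured charge adds
    ``N(0, charge_sigma)``, and the measured m/z is the true m/z scaled by
    ``1 + N(0, mz_cv)``.  Fully deterministic for a fixed seed.
    """
    known = set(mass_table.labels) | {PARTIAL_LABEL}
    unknown = [lab for lab in mixture.labels if lab not in known]
    if unknown:
        raise ConfigError(
            f"mixture species not present in mass table: {unknown}"
        )
    rng = np.random.default_rng(sim.seed)
    labels = mixture.labels
    probs = np.array([mixture.fractions[lab] for lab in labels])
    draws = rng.choice(len(labels), size=sim.n_ions, p=probs)

    true_mass = np.empty(sim.n_ions)
    for idx, lab in enumerate(labels):
        mask = draws == idx
        if not mask.any():
            continue
        if lab == PARTIAL_LABEL:
            intervals = _partial_support(
                mass_table, PARTIAL_EDGE_MARGIN_SD, sim.mass_rel_sd
            )
            widths = np.array([b - a for a, b in intervals])
            if widths.sum() > 0:
                p_int = widths / widths.sum()
            else:
                p_int = np.full(len(intervals), 1.0 / len(intervals))
            which = rng.choice(len(intervals), size=mask.sum(), p=p_int)
            u = rng.random(mask.sum())
            lows = np.array([intervals[i][0] for i in which])
            highs = np.array([intervals[i][1] for i in which])
            true_mass[mask] = lows + u * (highs - lows)
        else:
            true_mass[mask] = mass_table.row(lab).predicted_mass

    true_charge = rng.normal(sim.charge_mean, sim.charge_spread, sim.n_ions)
    true_charge = np.clip(true_charge, 1.0, None)
    measured_charge = true_charge + rng.normal(0.0, sim.charge_sigma, sim.n_ions)
    measured_mz = (true_mass / true_charge) * (
        1.0 + rng.normal(0.0, sim.mz_cv, sim.n_ions)
    )
    derived = measured_mz * measured_charge
    return [
        IonEvent(
            measured_mz=float(measured_mz[i]),
            measured_charge=float(measured_charge[i]),
            derived_mass=float(derived[i]),
            true_species=labels[draws[i]],
        )
        for i in range(sim.n_ions)
    ]


def events_frame(events: list[IonEvent], truth: bool = False) -> pd.DataFrame:
    """Tabulate events; ``truth`` adds the test-only true_species column."""
    frame = pd.DataFrame(
        {
            "ion_id": np.arange(len(events), dtype=int),
            "measured_mz": [e.measured_mz for e in events],
            "measured_charge": [e.measured_charge for e in events],
            "derived_mass": [e.derived_mass for e in events],
        },
        columns=ION_COLUMNS,
    )
    if truth:
        frame["true_species"] = [e.true_species for e in events]
    return frame


def write_ions(events: list[IonEvent], path, truth: bool = False) -> None:
    """Write events as CSV (12 significant digits)."""
    events_frame(events, truth=truth).to_csv(path, index=False, float_format="%.12g")


def read_ions(path) -> list[IonEvent]:
    """Read an ion-event CSV written by :func:`write_ions`."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in ION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"ion file {path} missing column(s): {missing}")
    has_truth = "true_species" in frame.columns
    events = []
    for i, rec in enumerate(frame.itertuples(index=False)):
        try:
            mz = float(rec.measured_mz)
            z = float(rec.measured_charge)
            mass = float(rec.derived_mass)
        except (TypeError, ValueError) as exc:
            raise IonParseError(f"unparseable ion event: {exc}", row=i + 2) from exc
        events.append(
            IonEvent(
                measured_mz=mz,
                measured_charge=z,
                derived_mass=mass,
                true_species=str(rec.true_species) if has_truth else None,
            )
        )
    return events


def estimate_resolution(events: list[IonEvent]) -> float:
    """Mass resolution (median mass / FWHM) of a single-species dataset.

    Peak width is estimated robustly via the median absolute deviation, so
    the estimate is usable even with a few outliers.
    """
    masses = np.array([e.derived_mass for e in events])
    if masses.size < 2:
        raise InvalidArgumentError("need at least two ions")
    med = float(np.median(masses))
    mad = float(np.median(np.abs(masses - med)))
    sigma = 1.4826 * mad
    if sigma <= 0:
        return math.inf
    return med / (2.3548 * sigma)
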
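"""Quantify subpopulations from CD-MS single-ion events.

Ions are assigned to model species by mass window membership (windows are
half-open ``(low, high]``; a mass sitting exactly on a shared boundary goes
to the lower-mass species).  Ions falling in no window — partial genomes,
or anything below half the empty-capsid mass or far above the top window —
are counted as unassigned, never dropped.  Relative abundances are ion
counts over the total ion count, so assigned plus unassigned always
conserves the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, InvalidArgumentError
from .cdms_synth import IonEvent
from .mass_model import SpeciesMassTable

UNASSIGNED_LABEL = "unassigned"

DEFAULT_BIN_WIDTH = 10_000.0  # Da; display only, never used for abundances


@dataclass(frozen=True)
class MassSpectrum:
    """Binned mass histogram for display/export."""

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts.astype(int),
            }
        )


@dataclass(frozen=True)
class SubpopulationQuant:
    """Per-species ion counts and relative abundances for one dataset."""

    labels: tuple[str, ...]
    ion_counts: dict[str, int]
    unassigned_count: int
    total_ions: int
    ion_labels: tuple[str, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        assigned = sum(self.ion_counts.values())
        if assigned + self.unassigned_count != self.total_ions:
            raise InvalidArgumentError("ion counts do not conserve total")

    def rel_abundance(self, label: str) -> float:
        if label == UNASSIGNED_LABEL:
            return self.unassigned_count / self.total_ions
        return self.ion_counts[label] / self.total_ions

    @property
    def rel_abundances(self) -> dict[str, float]:
        out = {lab: self.ion_counts[lab] / self.total_ions for lab in self.labels}
        out[UNASSIGNED_LABEL] = self.unassigned_count / self.total_ions
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": lab,
                "ion_count": self.ion_counts[lab],
                "rel_abundance": self.ion_counts[lab] / self.total_ions,
            }
            for lab in self.labels
        ]
        rows.append(
            {
                "label": UNASSIGNED_LABEL,
                "ion_count": self.unassigned_count,
                "rel_abundance": self.unassigned_count / self.total_ions,
            }
        )
        return pd.DataFrame(rows, columns=["label", "ion_count", "rel_abundance"])


def build_spectrum(
    events: list[IonEvent], bin_width: float = DEFAULT_BIN_WIDTH
) -> MassSpectrum:
    """Histogram derived masses, padding one empty bin on each side."""
    if not events:
        raise EmptyInputError("no ion events to histogram")
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")
    masses = np.array([e.derived_mass for e in events])
    lo = np.floor(masses.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(masses.max() / bin_width) * bin_width + bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(masses, bins=edges)
    return MassSpectrum(bin_edges=edges, counts=counts, bin_width=bin_width)


def assign_labels(
    events: list[IonEvent], mass_table: SpeciesMassTable
) -> np.ndarray:
    """Per-ion species label (or :data:`UNASSIGNED_LABEL`) by window lookup."""
    if not mass_table.rows:
        raise ConfigError("mass table is empty")
    masses = np.array([e.derived_mass for e in events])
    out = np.full(len(events), UNASSIGNED_LABEL, dtype=object)
    taken = np.zeros(len(events), dtype=bool)
    for row in mass_table.rows:  # ascending mass: lower species wins ties
        mask = ~taken & (masses > row.window_low) & (masses <= row.window_high)
        out[mask] = row.label
        taken |= mask
    return out


def assign_ions(
    events: list[IonEvent], mass_table: SpeciesMassTable
) -> SubpopulationQuant:
    """Window assignment and relative abundances for one dataset."""
    if not events:
        raise EmptyInputError("no ion events to assign")
    labels = assign_labels(events, mass_table)
    counts = {
        row.label: int(np.sum(labels == row.label)) for row in mass_table.rows
    }
    unassigned = int(np.sum(labels == UNASSIGNED_LABEL))
    return SubpopulationQuant(
        labels=tuple(mass_table.labels),
        ion_counts=counts,
        unassigned_count=unassigned,
        total_ions=len(events),
        ion_labels=tuple(labels),
    )


@dataclass(frozen=True)
class ChargeSummary:
    """Per-species measured-charge statistics and elevated-charge flags."""

    mean_charge: dict[str, float | None]
    sd_charge: dict[str, float | None]
    n_ions: dict[str, int]
    flagged: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": lab,
                    "n_ions": self.n_ions[lab],
                    "mean_charge": self.mean_charge[lab],
                    "sd_charge": self.sd_charge[lab],
                    "flagged": self.flagged[lab],
                }
                for lab in self.mean_charge
            ]
        )


def charge_summary(
    events: list[IonEvent],
    quant: SubpopulationQuant,
    empty_label: str | None = None,
    threshold_se: float = 3.0,
) -> ChargeSummary:
    """Per-species charge mean/s.d. and an elevated-charge flag.

    Incompletely packaged DNA would protrude and raise the measured charge,
    so any filled species whose mean charge exceeds the empty-capsid mean by
    more than ``threshold_se`` combined standard errors is flagged.  Species
    with no ions report absent statistics and are never flagged.
    """
    if len(quant.ion_labels) != len(events):
        raise InvalidArgumentError("quant does not correspond to these events")
    if empty_label is None:
        empty_label = quant.labels[0]
    charges = np.array([e.measured_charge for e in events])
    labels = np.array(quant.ion_labels, dtype=object)

    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    n: dict[str, int] = {}
    for lab in quant.labels:
        sel = charges[labels == lab]
        n[lab] = sel.size
        if sel.size == 0:
            mean[lab], sd[lab] = None, None
        else:
            mean[lab] = float(sel.mean())
            sd[lab] = float(sel.std(ddof=1)) if sel.size > 1 else 0.0

    flagged = {lab: False for lab in quant.labels}
    ref_mean, ref_sd, ref_n = mean[empty_label], sd[empty_label], n[empty_label]
    if ref_mean is not None and ref_n > 1:
        for lab in quant.labels:
            if lab == empty_label or mean[lab] is None or n[lab] < 2:
                continue
            se = np.hypot(sd[lab] / np.sqrt(n[lab]), ref_sd / np.sqrt(ref_n))
            if se > 0 and (mean[lab] - ref_mean) > threshold_se * se:
                flagged[lab] = True
    return ChargeSummary(mean_charge=mean, sd_charge=sd, n_ions=n, flagged=flagged)


def confusion_frame(
    events: list[IonEvent], quant: SubpopulationQuant
) -> pd.DataFrame:
    """True-vs-assigned species cross-tabulation (needs truth-tagged events)."""
    truths = [e.true_species for e in events]
    if any(t is None for t in truths):
        raise InvalidArgumentError("events lack true_species labels")
    return pd.crosstab(
        pd.Series(truths, name="true_species"),
        pd.Series(list(quant.ion_labels), name="assigned"),
    )
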
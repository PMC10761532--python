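"""Per-ITR termination probabilities and cross-method comparisons.

Packaging originates at one terminal ITR and may stop at any downstream
ITR: the species with N ITRs terminated at sequential ITR k = N - 1.  The
termination profile normalizes packaged-species abundances over packaged
species only — empty capsids and unassigned/partial ions are excluded from
the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    UndefinedProfileError,
    UndefinedRatioError,
)


@dataclass(frozen=True)
class TerminationProfile:
    """Probabilities that packaging terminated at sequential ITR k = 1..K."""

    probabilities: np.ndarray
    source: str = "cdms"
    construct: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size == 0:
            raise InvalidArgumentError("profile must be a non-empty 1-d vector")
        if (p < 0).any():
            raise InvalidArgumentError("probabilities must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("probabilities must sum to 1")

    @property
    def n_itrs(self) -> int:
        return int(self.probabilities.size)

    def probability(self, k: int) -> float:
        """Termination probability at the k-th sequential ITR (1-based)."""
        if not 1 <= k <= self.n_itrs:
            raise InvalidArgumentError(f"ITR index {k} out of range 1..{self.n_itrs}")
        return float(self.probabilities[k - 1])

    def standard_errors(self, total_count: int) -> np.ndarray:
        """Multinomial standard errors given the packaged-ion count."""
        if total_count < 1:
            raise InvalidArgumentError("total_count must be >= 1")
        p = self.probabilities
        return np.sqrt(p * (1.0 - p) / total_count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "itr_index": np.arange(1, self.n_itrs + 1),
                "termination_probability": self.probabilities,
                "source": self.source,
                "construct": self.construct,
            }
        )


@dataclass(frozen=True)
class ProfileComparison:
    """Entry-wise differences between two same-construct profiles."""

    abs_differences: np.ndarray
    total_variation: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "itr_index": np.arange(1, self.abs_differences.size + 1),
                "abs_difference": self.abs_differences,
            }
        )


def termination_profile(
    abundances: Sequence[float],
    source: str = "cdms",
    construct: str = "",
) -> TerminationProfile:
    """Normalize packaged-species abundances (counts or fractions) to a profile.

    ``abundances[k-1]`` is the abundance of the species with k + 1 ITRs,
    i.e. the one that terminated at sequential ITR k.  The caller must
    already have excluded empty capsids and unassigned ions.  Scale
    invariant: any positive rescaling of the input yields the same profile.
    """
    a = np.asarray(list(abundances), dtype=float)
    if a.size == 0:
        raise UndefinedProfileError("no packaged species supplied")
    if (a < 0).any():
        raise InvalidArgumentError("abundances must be >= 0")
    total = a.sum()
    if total <= 0:
        raise UndefinedProfileError("all packaged-species abundances are zero")
    return TerminationProfile(
        probabilities=a / total, source=source, construct=construct
    )


def abundance_ratio(
    profile: TerminationProfile | Sequence[float], k1: int, k2: int
) -> float:
    """Ratio p_{k1} / p_{k2}; identical for raw or normalized abundances."""
    if not isinstance(profile, TerminationProfile):
        profile = termination_profile(profile)
    denom = profile.probability(k2)
    if denom == 0:
        raise UndefinedRatioError(f"termination probability at ITR {k2} is zero")
    return profile.probability(k1) / denom


def compare_profiles(
    p: TerminationProfile, q: TerminationProfile
) -> ProfileComparison:
    """Per-ITR absolute differences and total variation distance."""
    if p.n_itrs != q.n_itrs:
        raise InvalidArgumentError(
            f"profiles have different lengths ({p.n_itrs} vs {q.n_itrs})"
        )
    if p.construct and q.construct and p.construct != q.construct:
        raise InvalidArgumentError("profiles belong to different constructs")
    diffs = np.abs(p.probabilities - q.probabilities)
    return ProfileComparison(
        abs_differences=diffs, total_variation=float(0.5 * diffs.sum())
    )


def fold_change(a: float, b: float) -> float:
    """Simple ratio a / b, e.g. empty-fraction fold change between systems."""
    if b == 0:
        raise UndefinedRatioError("fold change denominator is zero")
    return a / b


def format_percent(fraction: float) -> str:
    """Mixed-precision percentage: two decimals below 1%, one otherwise."""
    pct = 100.0 * fraction
    return f"{pct:.2f}%" if pct < 1.0 else f"{pct:.1f}%"


def profile_report(profile: TerminationProfile, total_count: int | None = None) -> str:
    """Human-readable termination profile listing."""
    lines = [
        f"Termination profile ({profile.source}"
        + (f", {profile.construct}" if profile.construct else "")
        + ")"
    ]
    ses = (
        profile.standard_errors(total_count) if total_count is not None else None
    )
    for k in range(1, profile.n_itrs + 1):
        entry = f"  ITR {k}: {format_percent(profile.probability(k))}"
        if ses is not None:
            entry += f" (se {100 * ses[k - 1]:.2f} pts)"
        lines.append(entry)
    return "\n".join(lines)
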
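"""Heavy/light pooling of CsCl gradient fractions and recovery QC.

After isopycnic ultracentrifugation a SIP sample is collected as ~12
fractions spanning the buoyant-density gradient.  Fractions falling in the
heavy window carry 13C-labelled DNA; fractions in the light window carry
unlabelled DNA.  Fractions outside both windows are not sequenced.  Samples
that recovered too little DNA across the gradient are excluded from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .errors import ConfigurationError, DataLossWarning, FormatError, ValidationError

__all__ = [
    "Fraction",
    "FractionProfile",
    "PoolWindows",
    "pool_fractions",
    "flag_low_recovery",
    "read_fraction_profiles",
]

EXPECTED_FRACTIONS = 12


class Fraction(NamedTuple):
    index: int  # 1-based position in the gradient
    density: float  # g/ml
    dna_conc: float  # ng/ul


@dataclass
class FractionProfile:
    """Per-fraction density and DNA concentration for one gradient."""

    sample_id: str
    fractions: list[Fraction]

    def __post_init__(self) -> None:
        self.fractions = [Fraction(int(i), float(d), float(c)) for i, d, c in self.fractions]
        indices = [f.index for f in self.fractions]
        if len(set(indices)) != len(indices):
            raise ValidationError(f"duplicate fraction_index in {self.sample_id!r}")
        for f in self.fractions:
            if f.density <= 0:
                raise ValidationError(
                    f"non-positive density {f.density} in {self.sample_id!r}"
                )
            if f.dna_conc < 0:
                raise ValidationError(
                    f"negative DNA concentration in {self.sample_id!r}"
                )
        if len(self.fractions) != EXPECTED_FRACTIONS:
            warnings.warn(
                f"{self.sample_id!r}: {len(self.fractions)} fractions, "
                f"expected {EXPECTED_FRACTIONS}",
                DataLossWarning,
                stacklevel=2,
            )

    def recovery(self, loaded_dna: float) -> float:
        """Proportion of loaded DNA recovered across all fractions.

        Assumes equal fraction volumes, so concentrations are proportional
        to mass.
        """
        if loaded_dna <= 0:
            raise ValidationError("loaded_dna must be positive")
        return sum(f.dna_conc for f in self.fractions) / loaded_dna


@dataclass(frozen=True)
class PoolWindows:
    """Closed buoyant-density intervals defining the heavy and light pools."""

    heavy: tuple[float, float] = (1.720, 1.735)
    light: tuple[float, float] = (1.700, 1.715)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("heavy", self.heavy), ("light", self.light)):
            if lo > hi:
                raise ConfigurationError(f"{name} window is empty: [{lo}, {hi}]")
        h_lo, h_hi = self.heavy
        l_lo, l_hi = self.light
        if h_lo <= l_hi and l_lo <= h_hi:
            raise ConfigurationError(
                f"heavy {self.heavy} and light {self.light} windows overlap"
            )


def pool_fractions(
    profile: FractionProfile, windows: PoolWindows | None = None
) -> dict[int, str]:
    """Assign each gradient fraction to 'heavy', 'light' or 'unassigned'.

    Both window boundaries are inclusive; the windows are validated disjoint
    so the assignment is a partition of the fractions.
    """
    if windows is None:
        windows = PoolWindows()
    out: dict[int, str] = {}
    for f in profile.fractions:
        if windows.heavy[0] <= f.density <= windows.heavy[1]:
            out[f.index] = "heavy"
        elif windows.light[0] <= f.density <= windows.light[1]:
            out[f.index] = "light"
        else:
            out[f.index] = "unassigned"
    return out


def flag_low_recovery(recovery: float, threshold: float = 0.35) -> bool:
    """True (exclude the sample) iff recovery is strictly below threshold."""
    if not 0.0 <= recovery <= 1.0:
        raise ValidationError(f"recovery must lie in [0, 1], got {recovery!r}")
    return recovery < threshold


def read_fraction_profiles(path: str | Path) -> dict[str, FractionProfile]:
    """Read a fraction-profile TSV: sample_id, fraction_index, density, dna_conc."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty fraction profile file: {path}") from exc
    required = ["sample_id", "fraction_index", "density", "dna_conc"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"fraction profile missing columns {missing}: {path}")
    profiles: dict[str, FractionProfile] = {}
    for sample_id, grp in frame.groupby("sample_id", sort=False):
        profiles[str(sample_id)] = FractionProfile(
            sample_id=str(sample_id),
            fractions=[
                Fraction(int(r.fraction_index), float(r.density), float(r.dna_conc))
                for r in grp.itertuples()
            ],
        )
    return profiles
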
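"""Reversed-phase TLC retention analysis.

A solute developed on an RP-18 plate with a water/organic mobile phase has a
retardation factor R_F in (0, 1). The Bate-Smith–Westall transform

    R_M = log10(1/R_F - 1)

is, for a congeneric series under reversed-phase conditions, linear in the
volume fraction C of the organic modifier:

    R_M = R_M0 + b * C

R_M0 (the intercept, i.e. R_M extrapolated to pure aqueous eluent) is the
chromatographic lipophilicity of the solute; the slope b tracks its specific
hydrophobic surface area. Their ratio

    C_0 = -R_M0 / b

is the modifier fraction at which R_M = 0, interpreted as hydrophobicity per
unit hydrophobic surface. This module implements the transform, the
replicate aggregation, the ordinary-least-squares extrapolation, and C_0.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDesignError,
    UndefinedValueError,
    ValidationError,
)

__all__ = [
    "RetentionMeasurement",
    "RetentionSeries",
    "ExtrapolationFit",
    "rf_to_rm",
    "rm_to_rf",
    "aggregate_replicates",
    "fit_retention",
    "compute_c0",
    "fits_to_frame",
]

#: Minimum number of distinct modifier levels needed for an extrapolation.
MIN_LEVELS = 3


@dataclass(frozen=True)
class RetentionMeasurement:
    """One spot: compound, modifier volume fraction, retardation factor."""

    compound_id: int | str
    c: float
    r_f: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.r_f < 1.0:
            raise ValidationError(
                f"r_f must lie in (0, 1); got {self.r_f!r} for compound "
                f"{self.compound_id!r} at c={self.c!r}"
            )
        if not 0.0 <= self.c < 1.0:
            raise ValidationError(
                f"modifier fraction c must lie in [0, 1); got {self.c!r} "
                f"for compound {self.compound_id!r}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass(frozen=True)
class RetentionSeries:
    """Replicate-averaged (c, R_M) points for one compound, c ascending."""

    compound_id: int | str
    c: tuple[float, ...]
    rm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.c) != len(self.rm):
            raise ValidationError("c and rm must have equal length")
        if any(b <= a for a, b in zip(self.c, self.c[1:])):
            raise ValidationError("c values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.c)


@dataclass(frozen=True)
class ExtrapolationFit:
    """OLS extrapolation of R_M to zero modifier for one compound.

    ``r_abs`` is the magnitude of the Pearson correlation — the convention of
    the source tables, which print positive r next to negative slopes — and
    ``r_signed`` keeps the signed value. ``c0`` is None when b = 0.
    """

    compound_id: int | str
    rm0: float
    b: float
    r_abs: float
    n: int
    c0: float | None
    r_signed: float

    def as_row(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "rm0": self.rm0,
            "b": self.b,
            "r": self.r_abs,
            "c0": self.c0,
        }


def rf_to_rm(r_f):
    """R_M = log10(1/R_F − 1); accepts a scalar or array, open-interval domain."""
    arr = np.asarray(r_f, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise UndefinedValueError(f"R_F must lie strictly in (0, 1); got {r_f!r}")
    out = np.log10(1.0 / arr - 1.0)
    return float(out) if np.isscalar(r_f) or arr.ndim == 0 else out


def rm_to_rf(rm):
    """Inverse transform R_F = 1 / (1 + 10^R_M); maps the real line into (0, 1)."""
    arr = np.asarray(rm, dtype=float)
    out = 1.0 / (1.0 + np.power(10.0, arr))
    return float(out) if np.isscalar(rm) or arr.ndim == 0 else out


def aggregate_replicates(
    measurements: Iterable[RetentionMeasurement],
    scale: str = "rf",
) -> list[RetentionSeries]:
    """Collapse replicate spots into one (c, R_M) series per compound.

    The reference procedure averages replicates on the R_F scale and then
    transforms the mean (``scale="rf"``). ``scale="rm"`` transforms each
    replicate first and averages R_M values — available for sensitivity
    checks; the two orders differ for asymmetric replicates because the
    transform is nonlinear.
    """
    if scale not in ("rf", "rm"):
        raise ValueError(f"scale must be 'rf' or 'rm', got {scale!r}")
    rows = [(m.compound_id, m.c, m.r_f) for m in measurements]
    if not rows:
        return []
    frame = pd.DataFrame(rows, columns=["compound_id", "c", "r_f"])
    series: list[RetentionSeries] = []
    for cid, grp in frame.groupby("compound_id", sort=True):
        if scale == "rf":
            agg = grp.groupby("c")["r_f"].mean().apply(rf_to_rm)
        else:
            agg = grp.assign(rm=grp["r_f"].map(rf_to_rm)).groupby("c")["rm"].mean()
        agg = agg.sort_index()
        series.append(
            RetentionSeries(cid, tuple(float(c) for c in agg.index), tuple(agg))
        )
    return series


def fit_retention(series: RetentionSeries) -> ExtrapolationFit:
    """OLS of R_M on the modifier fraction; intercept R_M0, slope b, C_0."""
    n = len(series)
    if n < MIN_LEVELS:
        raise InsufficientDesignError(
            f"compound {series.compound_id!r}: {n} distinct modifier level(s); "
            f"need at least {MIN_LEVELS}"
        )
    c = np.asarray(series.c)
    rm = np.asarray(series.rm)
    if np.ptp(c) == 0.0:
        raise DegenerateDesignError(
            f"compound {series.compound_id!r}: zero variance in modifier levels"
        )
    res = stats.linregress(c, rm)
    b = float(res.slope)
    rm0 = float(res.intercept)
    # flat noiseless series: r is 0/0; report perfect fit of the horizontal line
    r_signed = 0.0 if math.isnan(res.rvalue) else float(res.rvalue)
    c0 = None if b == 0.0 else compute_c0(rm0, b)
    return ExtrapolationFit(
        compound_id=series.compound_id,
        rm0=rm0,
        b=b,
        r_abs=abs(r_signed),
        n=n,
        c0=c0,
        r_signed=r_signed,
    )


def compute_c0(rm0: float, b: float) -> float:
    """C_0 = −R_M0 / b, the modifier fraction at which R_M crosses zero."""
    if b == 0.0:
        raise UndefinedValueError("C0 is undefined for zero slope b")
    return -rm0 / b


def fits_to_frame(fits: Sequence[ExtrapolationFit]) -> pd.DataFrame:
    """Export fits as a table with columns compound_id, rm0, b, r, c0."""
    return pd.DataFrame([f.as_row() for f in fits]).set_index("compound_id")
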
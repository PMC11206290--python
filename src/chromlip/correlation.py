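"""Pairwise linear correlations between lipophilicity measures and descriptors.

Each correlation is a simple OLS of y on x over a named compound subset,
reported as slope, intercept, signed Pearson r, and the two-sided p-value of
the slope (t distribution, n−2 df). Batteries of such fits — every predicted
logP against R_M0, and every molecular descriptor against R_M0, over the full
set and the three five-compound isomer series — are driven by a declarative
request list so that exactly the published equations are recomputed, no more.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DegenerateDesignError, DescriptorLookupError

__all__ = [
    "CorrelationFit",
    "BatteryRequest",
    "correlate",
    "correlation_battery",
    "parse_subset",
    "battery_requests_from_frame",
]


@dataclass(frozen=True)
class CorrelationFit:
    x_name: str
    y_name: str
    subset: tuple
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    significant: bool | None = None

    def equation(self, digits: int = 4) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (
            f"{self.y_name} = {self.slope:.{digits}f} {self.x_name} "
            f"{sign} {abs(self.intercept):.{digits}f}"
        )


@dataclass(frozen=True)
class BatteryRequest:
    x_name: str
    y_name: str
    subset: tuple


def parse_subset(text: str) -> tuple:
    """Parse a subset tag: '1-15' (inclusive range) or '1,2,5' (explicit ids)."""
    text = text.strip()
    if "-" in text and "," not in text:
        lo, hi = text.split("-")
        return tuple(range(int(lo), int(hi) + 1))
    return tuple(int(t) for t in text.split(","))


def correlate(
    x: pd.Series,
    y: pd.Series,
    subset: Sequence | None = None,
    x_name: str | None = None,
    y_name: str | None = None,
) -> CorrelationFit:
    """OLS of y on x restricted to ``subset`` (default: common index)."""
    ids = tuple(subset) if subset is not None else tuple(x.index)
    missing_x = [i for i in ids if i not in x.index]
    missing_y = [i for i in ids if i not in y.index]
    if missing_x or missing_y:
        raise AlignmentError(
            f"ids absent from x: {missing_x}; absent from y: {missing_y}"
        )
    if len(ids) < 3:
        raise AlignmentError(f"subset must contain at least 3 ids, got {len(ids)}")
    xv = x.loc[list(ids)].to_numpy(dtype=float)
    yv = y.loc[list(ids)].to_numpy(dtype=float)
    if np.ptp(xv) == 0.0:
        raise DegenerateDesignError(f"zero variance in x over subset {ids}")
    res = stats.linregress(xv, yv)
    return CorrelationFit(
        x_name=x_name or str(x.name),
        y_name=y_name or str(y.name),
        subset=ids,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(ids),
    )


def correlation_battery(
    data: pd.DataFrame,
    requests: Sequence[BatteryRequest],
    alpha: float = 0.05,
) -> list[CorrelationFit]:
    """Run a list of correlation requests against a columns-of-series table.

    Every fit is marked ``significant`` by a two-sided p < ``alpha`` test of
    the slope; no multiple-testing correction is applied across the battery.
    """
    fits = []
    for req in requests:
        for name in (req.x_name, req.y_name):
            if name not in data.columns:
                raise DescriptorLookupError(
                    f"series {name!r} not found; available: {list(data.columns)}"
                )
        fit = correlate(
            data[req.x_name], data[req.y_name], subset=req.subset,
            x_name=req.x_name, y_name=req.y_name,
        )
        fits.append(
            CorrelationFit(
                **{**fit.__dict__, "significant": fit.p_value < alpha}
            )
        )
    return fits


def battery_requests_from_frame(
    frame: pd.DataFrame, x_name: str = "rm0"
) -> list[BatteryRequest]:
    """Build requests from a declarative table with columns y, subset."""
    return [
        BatteryRequest(x_name=x_name, y_name=row.y, subset=parse_subset(row.subset))
        for row in frame.itertuples(index=False)
    ]


def fits_to_frame(fits: Sequence[CorrelationFit]) -> pd.DataFrame:
    """Battery results as a table mirroring the published equation listings."""
    return pd.DataFrame(
        {
            "y": [f.y_name for f in fits],
            "x": [f.x_name for f in fits],
            "subset": [f"{f.subset[0]}-{f.subset[-1]}" for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "r": [f.r for f in fits],
            "p_value": [f.p_value for f in fits],
            "n": [f.n for f in fits],
            "significant": [f.significant for f in fits],
        }
    )
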
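"""Calibration of R_M0 against reference standards.

Chromatographic R_M0 is a relative lipophilicity scale. Running reference
solutes with known literature partition coefficients (logP_lit) under the
same RP-TLC conditions gives a standards line

    logP_TLC = slope * R_M0 + intercept

fitted by ordinary least squares, which converts any compound's R_M0 into an
absolute logP estimate. Alongside slope/intercept the fit reports the usual
small-n regression statistics: Pearson r, residual standard error
s = sqrt(SSE / (n - 2)), the regression F statistic, and the two-sided
p-value of the slope (t distribution, n - 2 df).

``REFERENCE_CALIBRATION`` holds the published coefficient set for the
acetanilide … p,p'-DDT standard ladder; refitting from the rounded, printed
standards table reproduces its r to ~3e-5 but not the coefficients to all
four printed decimals (those were fitted on unrounded R_M0), so the printed
model is kept as a constant distinct from ``fit_calibration`` output.
"""

from __future__ import annotations

import json
import math
from collections.abc import Sequence
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDesignError

__all__ = [
    "CalibrationStandard",
    "CalibrationModel",
    "REFERENCE_CALIBRATION",
    "fit_calibration",
    "apply_calibration",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """A reference solute: name, literature logP, measured R_M0.

    ``b`` and ``r`` optionally carry the standard's own retention-line slope
    (volume-fraction scale) and correlation, when known.
    """

    name: str
    logp_lit: float
    rm0: float
    b: float | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.logp_lit):
            raise ValueError(f"logp_lit must be finite for standard {self.name!r}")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted (or published) standards line with its regression statistics.

    Statistics are ``None`` for a two-standard exact interpolation and for
    published reference models whose p-value was only reported as a bound.
    """

    slope: float
    intercept: float
    r: float | None
    s: float | None
    f_stat: float | None
    p_value: float | None
    n: int

    def predict(self, rm0):
        return apply_calibration(self, rm0)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CalibrationModel":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


#: Published standards-line coefficients (acetanilide, benzoic acid,
#: benzophenone, anthracene, p,p'-DDT; logP_lit 1.21-6.38). The source quotes
#: r = 0.9967, s = 0.1920, F = 459.32 and p < 0.001 for this line.
REFERENCE_CALIBRATION = CalibrationModel(
    slope=1.2838,
    intercept=0.2138,
    r=0.9967,
    s=0.1920,
    f_stat=459.32,
    p_value=None,
    n=5,
)


def fit_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationModel:
    """OLS of logP_lit on R_M0 across the standards.

    Two standards give an exact interpolation with r/s/F/p suppressed
    (``None``); three or more give the full statistics.
    """
    if len(standards) < 2:
        raise InsufficientDesignError(
            f"need at least 2 standards, got {len(standards)}"
        )
    x = np.array([s.rm0 for s in standards], dtype=float)
    y = np.array([s.logp_lit for s in standards], dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("standards have zero spread in rm0")
    n = len(standards)
    if n == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return CalibrationModel(
            slope=float(slope),
            intercept=float(y[0] - slope * x[0]),
            r=None,
            s=None,
            f_stat=None,
            p_value=None,
            n=2,
        )
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    s = math.sqrt(float(resid @ resid) / (n - 2))
    r2 = res.rvalue**2
    f_stat = math.inf if r2 == 1.0 else r2 * (n - 2) / (1.0 - r2)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        s=s,
        f_stat=float(f_stat),
        p_value=float(res.pvalue),
        n=n,
    )


def apply_calibration(model: CalibrationModel, rm0):
    """logP_TLC = slope * R_M0 + intercept; scalar or array."""
    arr = np.asarray(rm0, dtype=float)
    out = model.slope * arr + model.intercept
    return float(out) if np.isscalar(rm0) or arr.ndim == 0 else out
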
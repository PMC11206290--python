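"""Synthetic data generators mirroring the study's experimental design.

The raw plate measurements behind the published extrapolation parameters are
not deposited, so every raw-data code path is exercised on simulated inputs
that share the study's statistical structure:

* Retention: R_M values drawn from the linear model R_M = R_M0 + b·C with
  additive Gaussian noise on the R_M scale (where the model is linear), then
  back-transformed to R_F = 1/(1 + 10^R_M). The default design copies the
  experiment: acetone fractions 0.50–0.80 in 0.05 steps, triplicate spots.
  An alternative R_F-scale beta-noise mode exists for robustness testing.
* logP matrices with the fixture's factorial structure: three ring-fusion
  series × five substituents, additive substituent/series effects, and
  per-program offsets (most prediction programs in the study return
  identical values for the three isomers of a substituent, i.e. zero series
  effect).
* Calibration standards on a known line.

Every generator is a pure function of its parameters and seed.

Default effect sizes are calibrated to the magnitude of the bundled tables:
noise on R_M of sd 0.05 reproduces the observed |r| ≈ 0.99 retention lines;
substituent effects of a few tenths of a log unit match the spread of the
prediction matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import LogPMatrix
from .calibration import CalibrationStandard
from .errors import DegenerateDesignError, ValidationError
from .retention import RetentionMeasurement, rm_to_rf

__all__ = [
    "DEFAULT_C_DESIGN",
    "SyntheticTruth",
    "generate_retention_data",
    "generate_logp_matrix",
    "generate_standards",
]

#: Acetone volume fractions of the experimental design: 50-80 % (v/v) in 5 % steps.
DEFAULT_C_DESIGN: tuple[float, ...] = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80)

#: Program line-up and offsets (relative to the compound's true logP)
#: calibrated to the column structure of the bundled prediction matrix.
DEFAULT_PROGRAM_OFFSETS: dict[str, float] = {
    "iLOGP": -0.9,
    "XLOGP3": 0.4,
    "WLOGP": 0.2,
    "MLOGP": -0.6,
    "SILICOS-IT": -0.3,
    "LogP": 0.8,
    "milogP": 0.4,
    "logP": 0.1,
}

#: Substituent effects (log units) ordered as in the study:
#: dimethylaminopropyl lowest, N-methylpiperidinylethyl highest.
DEFAULT_SUBSTITUENT_EFFECTS: tuple[float, ...] = (0.0, -0.4, -0.2, 0.05, 0.3)

SUBSTITUENT_NAMES: tuple[str, ...] = (
    "dimethylaminobutyl",
    "dimethylaminopropyl",
    "pyrrolidinylethyl",
    "piperidinylethyl",
    "methylpiperidinylethyl",
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated compound's retention line."""

    compound_id: int | str
    true_rm0: float
    true_b: float
    noise_sd: float = 0.05
    c_design: tuple[float, ...] = DEFAULT_C_DESIGN
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        cs = tuple(self.c_design)
        if len(set(cs)) != len(cs):
            raise ValidationError("c_design values must be distinct")
        if any(not 0.0 <= c < 1.0 for c in cs):
            raise ValidationError("c_design values must lie in [0, 1)")
        if self.replicates < 1:
            raise ValidationError("replicates must be positive")


def generate_retention_data(
    truth: SyntheticTruth, noise_scale: str = "rm"
) -> list[RetentionMeasurement]:
    """Simulate plate spots for one compound under its true retention line.

    ``noise_scale="rm"`` (default) adds Normal(0, noise_sd²) on the R_M
    scale; ``"rf"`` perturbs R_F directly with a Beta distribution whose
    mean is the model R_F and whose spread is controlled by ``noise_sd``
    (interpreted as an approximate R_F standard deviation) — useful for
    robustness checks against misspecified noise.
    """
    if noise_scale not in ("rm", "rf"):
        raise ValueError(f"noise_scale must be 'rm' or 'rf', got {noise_scale!r}")
    rng = np.random.default_rng(truth.seed)
    out: list[RetentionMeasurement] = []
    tiny = 1e-12
    for c in truth.c_design:
        rm_true = truth.true_rm0 + truth.true_b * c
        for rep in range(1, truth.replicates + 1):
            if noise_scale == "rm":
                rm = rm_true + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd else 0.0)
                rf = rm_to_rf(rm)
            else:
                mu = rm_to_rf(rm_true)
                if truth.noise_sd == 0.0:
                    rf = mu
                else:
                    var = min(truth.noise_sd**2, 0.9 * mu * (1.0 - mu))
                    conc = mu * (1.0 - mu) / var - 1.0
                    rf = float(rng.beta(mu * conc, (1.0 - mu) * conc))
            if not tiny < rf < 1.0 - tiny:
                warnings.warn(
                    f"R_F numerically at the (0,1) boundary for compound "
                    f"{truth.compound_id!r} at c={c}; clipping"
                )
                rf = min(max(rf, tiny), 1.0 - tiny)
            out.append(
                RetentionMeasurement(
                    compound_id=truth.compound_id, c=float(c), r_f=float(rf),
                    replicate=rep,
                )
            )
    return out


def generate_logp_matrix(
    n_series: int = 3,
    n_substituents: int = 5,
    base: float = 5.0,
    substituent_effects: tuple[float, ...] | None = None,
    series_effects: tuple[float, ...] | None = None,
    program_offsets: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[LogPMatrix, pd.DataFrame]:
    """Simulate a compounds × programs logP matrix with factorial structure.

    value(compound, program) = base + substituent effect + series effect
    + program offset + Normal(0, noise_sd²). Compounds are numbered the way
    the study numbers its isomers: id = series·n_substituents + substituent
    position + 1, so substituent k appears as compounds k, k+5, k+10.

    Returns the matrix and a truth table (compound_id, series, substituent,
    true_logp = base + substituent effect + series effect).
    """
    sub = tuple(
        substituent_effects
        if substituent_effects is not None
        else DEFAULT_SUBSTITUENT_EFFECTS[:n_substituents]
    )
    ser = tuple(series_effects if series_effects is not None else (0.0,) * n_series)
    if len(sub) != n_substituents or len(ser) != n_series:
        raise ValidationError("effect tuples must match n_substituents / n_series")
    offs = dict(program_offsets if program_offsets is not None else DEFAULT_PROGRAM_OFFSETS)
    rng = np.random.default_rng(seed)
    ids, rows, truth_rows = [], [], []
    for s in range(n_series):
        for k in range(n_substituents):
            cid = s * n_substituents + k + 1
            true = base + sub[k] + ser[s]
            noise = rng.normal(0.0, noise_sd, size=len(offs)) if noise_sd else np.zeros(len(offs))
            rows.append([true + off + e for off, e in zip(offs.values(), noise)])
            ids.append(cid)
            truth_rows.append(
                {
                    "compound_id": cid,
                    "series": s,
                    "substituent": SUBSTITUENT_NAMES[k]
                    if k < len(SUBSTITUENT_NAMES)
                    else f"substituent_{k}",
                    "true_logp": true,
                }
            )
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"),
                         columns=list(offs))
    truth = pd.DataFrame(truth_rows).set_index("compound_id")
    return LogPMatrix(frame), truth


def generate_standards(
    true_slope: float = 1.28,
    true_intercept: float = 0.21,
    rm0_grid: tuple[float, ...] = (0.78, 1.16, 2.51, 3.33, 4.69),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationStandard]:
    """Simulate calibration standards on a known logP-vs-R_M0 line.

    The default R_M0 grid copies the bundled standard ladder.
    """
    if len(rm0_grid) < 2:
        raise ValidationError("need at least 2 grid points")
    if len(set(rm0_grid)) == 1:
        raise DegenerateDesignError("rm0 grid has zero spread")
    rng = np.random.default_rng(seed)
    out = []
    for i, rm0 in enumerate(rm0_grid):
        noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
        out.append(
            CalibrationStandard(
                name=f"synthetic-standard-{i + 1}",
                logp_lit=true_slope * rm0 + true_intercept + noise,
                rm0=float(rm0),
            )
        )
    return out
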
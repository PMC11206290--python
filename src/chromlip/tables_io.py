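"""Typed CSV readers/writers and the bundled study tables.

All tabular exchange uses UTF-8 CSV with a header row. Schemas:

* ``retention.csv`` — compound_id, modifier_value, modifier_unit
  ("fraction" | "percent"), r_f, replicate. Percent modifier values are
  rescaled to volume fractions on ingest; the canonical internal unit for
  modifier concentration is the volume fraction in [0, 1).
* ``standards.csv`` — name, logp_lit, rm0 [, b, r]. Slopes are stored on the
  volume-fraction scale.
* ``logp_matrix.csv`` — compound_id plus one column per prediction program.
* ``descriptors.csv`` / ``admet.csv`` — compound_id plus one column per
  descriptor field.

Numeric cells may use either the ASCII hyphen or the Unicode minus sign
(typeset tables routinely use the latter).

``load_study_tables`` returns the packaged data for the fifteen
diquinothiazine isomers (three ring-fusion series × five pharmacophore
substituents) and the five-standard calibration ladder: the 15 × 8 predicted
logP matrix with its printed consensus column, the retention extrapolation
parameters (R_M0, b, r, C_0), the standards, the published logP_TLC values,
molecular descriptor and ADMET tables, and the declarative correlation
battery encoding exactly the published regression rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationStandard
from .consensus import LogPMatrix
from .errors import SchemaError, ValidationError
from .retention import RetentionMeasurement

__all__ = [
    "read_retention_table",
    "write_retention_table",
    "read_standards",
    "read_logp_matrix",
    "read_descriptors",
    "read_admet",
    "FixtureBundle",
    "load_study_tables",
]

_RETENTION_COLUMNS = ["compound_id", "modifier_value", "modifier_unit", "r_f", "replicate"]


def _normalize_minus(frame: pd.DataFrame) -> pd.DataFrame:
    """Replace Unicode minus (U+2212) by ASCII hyphen in object columns."""
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].map(
                lambda v: v.replace("−", "-") if isinstance(v, str) else v
            )
    return frame


def _read_csv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    frame = _normalize_minus(frame)
    for col in numeric:
        if col in frame.columns:
            try:
                frame[col] = frame[col].astype(float)
            except ValueError as exc:
                raise ValidationError(f"{path}: non-numeric value in {col!r}: {exc}")
    return frame


def read_retention_table(
    path: str | Path, permissive: bool = False, default_unit: str | None = None
) -> list[RetentionMeasurement]:
    """Read raw retention measurements, converting percent modifier to fraction.

    Rows with R_F outside (0, 1) raise :class:`ValidationError` listing the
    offending row numbers; with ``permissive=True`` they are dropped with a
    warning instead. A file without a ``modifier_unit`` column is a schema
    error unless ``default_unit`` supplies the unit for every row.
    """
    required = list(_RETENTION_COLUMNS)
    if default_unit is not None:
        required.remove("modifier_unit")
    frame = _read_csv(path, required, ["modifier_value", "r_f", "replicate"])
    if "modifier_unit" not in frame.columns:
        frame["modifier_unit"] = default_unit
    units = frame["modifier_unit"].str.strip().str.lower()
    bad_units = sorted(set(units) - {"fraction", "percent"})
    if bad_units:
        raise ValidationError(f"{path}: unknown modifier_unit value(s) {bad_units}")
    c = np.where(units == "percent", frame["modifier_value"] / 100.0, frame["modifier_value"])

    bad = frame.index[(frame["r_f"] <= 0.0) | (frame["r_f"] >= 1.0)].tolist()
    if bad:
        rows = [i + 2 for i in bad]  # 1-based file rows incl. header
        if not permissive:
            raise ValidationError(
                f"{path}: r_f outside (0, 1) at file row(s) {rows}"
            )
        warnings.warn(f"{path}: dropping {len(bad)} row(s) with r_f outside (0, 1): {rows}")
        keep = ~frame.index.isin(bad)
        frame, c = frame[keep], c[keep]

    def _cid(v: str):
        v = v.strip()
        return int(v) if v.lstrip("-").isdigit() else v

    return [
        RetentionMeasurement(
            compound_id=_cid(row.compound_id),
            c=float(ci),
            r_f=float(row.r_f),
            replicate=int(float(row.replicate)),
        )
        for row, ci in zip(frame.itertuples(index=False), c)
    ]


def write_retention_table(measurements, path: str | Path) -> None:
    """Write measurements in the retention.csv schema (fraction units)."""
    frame = pd.DataFrame(
        {
            "compound_id": [m.compound_id for m in measurements],
            "modifier_value": [m.c for m in measurements],
            "modifier_unit": "fraction",
            "r_f": [m.r_f for m in measurements],
            "replicate": [m.replicate for m in measurements],
        }
    )
    frame.to_csv(path, index=False)


def read_standards(path: str | Path) -> list[CalibrationStandard]:
    frame = _read_csv(path, ["name", "logp_lit", "rm0"], ["logp_lit", "rm0", "b", "r"])

    def _opt(rec: dict, key: str):
        v = rec.get(key)
        return None if v is None or pd.isna(v) else float(v)

    return [
        CalibrationStandard(
            name=str(rec["name"]),
            logp_lit=float(rec["logp_lit"]),
            rm0=float(rec["rm0"]),
            b=_opt(rec, "b"),
            r=_opt(rec, "r"),
        )
        for rec in frame.to_dict("records")
    ]


def read_logp_matrix(path: str | Path, index_col: str = "compound_id") -> LogPMatrix:
    frame = pd.read_csv(path)
    if index_col not in frame.columns:
        raise SchemaError(f"{path}: missing required column(s) ['{index_col}']")
    frame = frame.set_index(index_col)
    # printed consensus columns ride along in the fixture file but are not programs
    frame = frame.drop(columns=[c for c in ("logp_average", "logp_sd") if c in frame.columns])
    return LogPMatrix(frame)


def read_descriptors(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, ["compound_id"], [])
    frame = frame.set_index("compound_id")
    frame.index = frame.index.astype(int)
    frame = frame.astype(float)
    counts = [c for c in ("heavy_atoms", "aromatic_heavy_atoms", "hba", "hbd",
                          "rotatable_bonds") if c in frame.columns]
    if (frame[counts] < 0).any().any():
        raise ValidationError(f"{path}: negative count descriptor")
    if "molar_mass" in frame.columns and (frame["molar_mass"] <= 0).any():
        raise ValidationError(f"{path}: molar_mass must be positive")
    if "tpsa" in frame.columns and (frame["tpsa"] < 0).any():
        raise ValidationError(f"{path}: tpsa must be nonnegative")
    return frame


def read_admet(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, ["compound_id"], [])
    frame = frame.set_index("compound_id")
    frame.index = frame.index.astype(int)
    frame = frame.astype(float)
    if "fraction_unbound" in frame.columns:
        fu = frame["fraction_unbound"]
        if ((fu < 0) | (fu > 1)).any():
            raise ValidationError(f"{path}: fraction_unbound outside [0, 1]")
    if "intestinal_absorption" in frame.columns:
        ia = frame["intestinal_absorption"]
        if ((ia < 0) | (ia > 100)).any():
            raise ValidationError(f"{path}: intestinal_absorption outside [0, 100]")
    return frame


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged study tables, parsed and typed."""

    compounds: pd.DataFrame            # id -> series, substituent
    logp_matrix: LogPMatrix            # 15 x 8 predictions
    printed_consensus: pd.DataFrame    # printed logp_average, logp_sd
    extrapolation: pd.DataFrame        # rm0, b, r, c0 per compound
    standards: tuple[CalibrationStandard, ...]
    logp_tlc: pd.DataFrame             # published calibrated values
    descriptors: pd.DataFrame
    admet: pd.DataFrame
    battery_logp: pd.DataFrame         # published logP-vs-RM0 equations
    battery_descriptors: pd.DataFrame  # published descriptor-vs-RM0 equations


def _data_path(name: str):
    return resources.files("chromlip.data").joinpath(name)


def load_study_tables() -> FixtureBundle:
    """Load the packaged tables for the 15 compounds and 5 standards."""
    with resources.as_file(_data_path(".")) as root:
        compounds = pd.read_csv(root / "compounds.csv").set_index("compound_id")
        matrix = read_logp_matrix(root / "logp_matrix.csv")
        printed = (
            pd.read_csv(root / "logp_matrix.csv")
            .set_index("compound_id")[["logp_average", "logp_sd"]]
        )
        extrapolation = pd.read_csv(root / "extrapolation.csv").set_index("compound_id")
        standards = tuple(read_standards(root / "standards.csv"))
        logp_tlc = pd.read_csv(root / "logp_tlc.csv").set_index("compound_id")
        descriptors = read_descriptors(root / "descriptors.csv")
        admet = read_admet(root / "admet.csv")
        battery_logp = pd.read_csv(root / "battery_logp.csv")
        battery_desc = pd.read_csv(root / "battery_descriptors.csv")
    return FixtureBundle(
        compounds=compounds,
        logp_matrix=matrix,
        printed_consensus=printed,
        extrapolation=extrapolation,
        standards=standards,
        logp_tlc=logp_tlc,
        descriptors=descriptors,
        admet=admet,
        battery_logp=battery_logp,
        battery_descriptors=battery_desc,
    )
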
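"""End-to-end report generation.

``run_pipeline`` chains the package's stages — retention extrapolation (when
raw plate data are supplied), calibration, consensus, correlation batteries,
cluster analyses, and drug-likeness screening — and writes one CSV/JSON/
Newick artifact per stage plus a run log. With no input overrides it runs on
the bundled study tables and reproduces the published result tables.

Outputs are deterministic: identical config + inputs + seed give
byte-identical files, and every artifact carries the hash of the
configuration that produced it on a leading ``# config_hash=`` comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import REFERENCE_CALIBRATION, apply_calibration, fit_calibration
from .clustering import compound_vectors, pairwise_distances, single_linkage, variable_vectors
from .consensus import consensus_table
from .correlation import battery_requests_from_frame, correlation_battery, fits_to_frame
from .druglikeness import verdict_grid
from .errors import ChromlipError
from .retention import aggregate_replicates, fit_retention, fits_to_frame as retention_frame
from .tables_io import load_study_tables, read_retention_table, read_standards

log = logging.getLogger("chromlip")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(ChromlipError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run; defaults reproduce the study."""

    retention_csv: str | None = None       # raw spots; None -> bundled extrapolation
    standards_csv: str | None = None       # None -> bundled standard ladder
    truth_json: str | None = None          # synthetic ground truth for recovery scoring
    modifier_unit: str = "fraction"        # fallback unit for unit-less retention files
    aggregation_scale: str = "rf"          # replicate averaging scale: rf | rm
    calibration_source: str = "refit"      # refit | printed-reference
    linkage: str = "single"
    standardize: bool = False
    include_average: bool = True
    significance: float = 0.05
    permissive: bool = False
    seed: int = 0
    output_dir: str = "chromlip-report"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance level must lie in (0, 1)")
        if self.calibration_source not in ("refit", "printed-reference"):
            raise ValueError("calibration_source must be 'refit' or 'printed-reference'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (where outputs land and how
        verbosely we log do not change the numbers)."""
        settings = asdict(self)
        settings.pop("output_dir")
        settings.pop("log_level")
        blob = json.dumps(settings, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    text = frame.to_csv(index=index, float_format="%.6g")
    path.write_text(f"# config_hash={cfg_hash}\n{text}", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a name → path map of the written artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    artifacts: dict[str, Path] = {}
    fixtures = load_study_tables()

    def stage(name):
        log.info("stage %s", name)

        def _run(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                log.error("stage %s failed: %s", name, exc)
                raise PipelineStageError(name, exc) from exc

        return _run

    # --- retention extrapolation -------------------------------------------
    def _retention():
        if config.retention_csv is None:
            return fixtures.extrapolation
        measurements = read_retention_table(
            config.retention_csv,
            permissive=config.permissive,
            default_unit=config.modifier_unit,
        )
        series = aggregate_replicates(measurements, scale=config.aggregation_scale)
        return retention_frame([fit_retention(s) for s in series])

    extrapolation = stage("retention")(_retention)
    path = out / "extrapolation.csv"
    _write(extrapolation, path, cfg_hash)
    artifacts["extrapolation"] = path

    # --- recovery scoring (synthetic runs only) ----------------------------
    if config.truth_json is not None:
        def _recovery():
            truth = pd.read_json(config.truth_json).set_index("compound_id")
            merged = extrapolation.join(truth, how="inner")
            merged["rm0_error"] = merged["rm0"] - merged["true_rm0"]
            merged["b_error"] = merged["b"] - merged["true_b"]
            return merged[["rm0", "true_rm0", "rm0_error", "b", "true_b", "b_error"]]

        rec = stage("recovery")(_recovery)
        path = out / "recovery.csv"
        _write(rec, path, cfg_hash)
        artifacts["recovery"] = path

    # --- calibration -------------------------------------------------------
    def _calibration():
        if config.calibration_source == "printed-reference":
            return REFERENCE_CALIBRATION
        standards = (
            read_standards(config.standards_csv)
            if config.standards_csv is not None
            else fixtures.standards
        )
        return fit_calibration(standards)

    model = stage("calibration")(_calibration)
    path = out / "calibration.json"
    path.write_text(
        json.dumps(
            {"config_hash": cfg_hash, **json.loads(model.to_json())}, indent=2
        )
        + "\n",
        encoding="utf-8",
    )
    artifacts["calibration"] = path

    tlc = pd.DataFrame(
        {"logp_tlc": apply_calibration(model, extrapolation["rm0"].to_numpy())},
        index=extrapolation.index,
    )
    path = out / "logp_tlc.csv"
    _write(tlc, path, cfg_hash)
    artifacts["logp_tlc"] = path

    # --- consensus ---------------------------------------------------------
    consensus = stage("consensus")(lambda: consensus_table(fixtures.logp_matrix))
    path = out / "consensus.csv"
    _write(consensus, path, cfg_hash)
    artifacts["consensus"] = path

    # --- correlation batteries ---------------------------------------------
    def _correlations():
        data = pd.concat(
            [
                fixtures.logp_matrix.frame,
                consensus["mean"].rename("logp_average"),
                extrapolation["rm0"],
                fixtures.descriptors,
            ],
            axis=1,
        )
        requests = battery_requests_from_frame(
            pd.concat([fixtures.battery_logp, fixtures.battery_descriptors])
        )
        return fits_to_frame(correlation_battery(data, requests, alpha=config.significance))

    battery = stage("correlations")(_correlations)
    path = out / "correlations.csv"
    _write(battery, path, cfg_hash, index=False)
    artifacts["correlations"] = path

    # --- cluster analyses --------------------------------------------------
    def _clusters():
        results = {}
        comp = compound_vectors(
            fixtures.logp_matrix, config.include_average, config.standardize
        )
        results["cluster_compounds"] = single_linkage(
            pairwise_distances(comp), method=config.linkage
        )
        var = variable_vectors(
            fixtures.logp_matrix, config.include_average, config.standardize
        )
        results["cluster_variables"] = single_linkage(
            pairwise_distances(var), method=config.linkage
        )
        mixed = pd.DataFrame(
            {
                "logp_average": consensus["mean"],
                "rm0": extrapolation["rm0"],
                "c0": extrapolation["c0"],
            }
        ).T
        results["cluster_parameters"] = single_linkage(
            pairwise_distances(mixed), method=config.linkage
        )
        return results

    dendrograms = stage("clustering")(_clusters)
    for name, dendro in dendrograms.items():
        nwk = out / f"{name}.nwk"
        nwk.write_text(f"[config_hash={cfg_hash}]\n{dendro.to_newick()}\n", encoding="utf-8")
        artifacts[f"{name}_newick"] = nwk
        path = out / f"{name}.csv"
        _write(dendro.merge_table(), path, cfg_hash, index=False)
        artifacts[name] = path

    # --- drug-likeness ------------------------------------------------------
    grid = stage("druglikeness")(
        lambda: verdict_grid(fixtures.descriptors, fixtures.logp_matrix)
    )
    path = out / "druglikeness.csv"
    _write(grid, path, cfg_hash)
    artifacts["druglikeness"] = path

    # --- run log ------------------------------------------------------------
    import numpy, scipy  # noqa: PLC0415 - versions for the run log

    log_path = out / "run_log.txt"
    log_path.write_text(
        "\n".join(
            [
                f"chromlip {__version__}",
                f"numpy {numpy.__version__}; scipy {scipy.__version__}; "
                f"pandas {pd.__version__}",
                f"config_hash {cfg_hash}",
                "config " + json.dumps(asdict(config), sort_keys=True),
                "artifacts " + ", ".join(sorted(p.name for p in artifacts.values())),
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    artifacts["run_log"] = log_path
    return artifacts
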
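"""Consensus logP across prediction programs.

Different logP predictors (atomistic, fragment, topological, physics-based)
disagree by half a log unit or more on fused polycyclic amines, so a common
summary is the consensus value: the arithmetic mean of the per-program
predictions, with the sample (n−1) standard deviation as the spread. The
compounds × programs matrix is held complete; the mean never includes a
previously computed consensus column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import IncompleteRowError, ValidationError

__all__ = ["LogPMatrix", "ConsensusLogP", "consensus_logp", "consensus_table"]


@dataclass(frozen=True)
class ConsensusLogP:
    """Per-compound consensus: mean, sample SD, and how many programs fed it."""

    compound_id: int | str
    mean: float
    sd: float
    n_programs: int


class LogPMatrix:
    """Compounds × programs matrix of predicted logP values.

    Wraps a DataFrame indexed by compound id with one column per program.
    Program names must be unique; by default every cell must be present.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate program names: {dupes}")
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate compound ids: {dupes}")
        self.frame = frame.astype(float)

    @classmethod
    def from_csv(cls, path: str | Path, index_col: str = "compound_id") -> "LogPMatrix":
        return cls(pd.read_csv(path).set_index(index_col))

    @property
    def compounds(self) -> list:
        return list(self.frame.index)

    @property
    def programs(self) -> list[str]:
        return list(self.frame.columns)

    def row(self, compound_id) -> pd.Series:
        return self.frame.loc[compound_id]

    def __len__(self) -> int:
        return len(self.frame)


def consensus_logp(
    matrix: LogPMatrix, compound_id, allow_missing: bool = False
) -> ConsensusLogP:
    """Arithmetic mean ± sample SD of one compound's program predictions.

    A missing cell raises :class:`IncompleteRowError` unless
    ``allow_missing`` is set, in which case the mean runs over the available
    programs (and ``n_programs`` reflects that).
    """
    row = matrix.row(compound_id)
    missing = row[row.isna()].index.tolist()
    if missing and not allow_missing:
        raise IncompleteRowError(
            f"compound {compound_id!r} has missing predictions: {missing}"
        )
    vals = row.dropna()
    if len(vals) == 0:
        raise IncompleteRowError(f"compound {compound_id!r} has no predictions")
    return ConsensusLogP(
        compound_id=compound_id,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        n_programs=int(len(vals)),
    )


def consensus_table(matrix: LogPMatrix, allow_missing: bool = False) -> pd.DataFrame:
    """Consensus for every compound; columns mean, sd, n_programs."""
    rows = [consensus_logp(matrix, cid, allow_missing) for cid in matrix.compounds]
    return pd.DataFrame(
        {
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "n_programs": [r.n_programs for r in rows],
        },
        index=pd.Index(matrix.compounds, name="compound_id"),
    )
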
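"""Agglomerative hierarchical clustering of compounds and lipophilicity measures.

The similarity analyses here follow the plain chemometric recipe: Euclidean
distances between raw (unstandardized) value vectors, merged by single
linkage — at each step the two clusters with the smallest minimum inter-point
distance join, so merge heights are nondecreasing and the first merge is
always the globally nearest pair. Dendrograms are held as an explicit merge
list and can be exported as Newick text (branch lengths are merge-height
differences) or a merge-table CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

__all__ = [
    "Dendrogram",
    "pairwise_distances",
    "single_linkage",
    "nearest_pair",
    "compound_vectors",
    "variable_vectors",
]


@dataclass(frozen=True)
class Dendrogram:
    """n−1 ordered merges over n labelled items."""

    items: tuple
    merges: tuple  # of (frozenset, frozenset, float height)
    _linkage: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def heights(self) -> tuple:
        return tuple(m[2] for m in self.merges)

    def cut(self, k: int) -> list[frozenset]:
        """Cut into k flat clusters (by merge height)."""
        labels = fcluster(self._linkage, t=k, criterion="maxclust")
        out: dict[int, set] = {}
        for item, lab in zip(self.items, labels):
            out.setdefault(int(lab), set()).add(item)
        return [frozenset(v) for _, v in sorted(out.items())]

    def to_newick(self) -> str:
        """Newick string; branch lengths are differences of merge heights."""
        n = len(self.items)
        Z = self._linkage
        text: dict[int, str] = {i: str(self.items[i]) for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for step, (a, b, h, _cnt) in enumerate(Z):
            a, b = int(a), int(b)
            la = height[a]
            lb = height[b]
            node = n + step
            text[node] = (
                f"({text[a]}:{h - la:.10g},{text[b]}:{h - lb:.10g})"
            )
            height[node] = float(h)
        return text[2 * n - 2] + ";"

    def merge_table(self) -> pd.DataFrame:
        rows = [
            {
                "step": i + 1,
                "members_a": "|".join(str(x) for x in sorted(a, key=str)),
                "members_b": "|".join(str(x) for x in sorted(b, key=str)),
                "height": h,
            }
            for i, (a, b, h) in enumerate(self.merges)
        ]
        return pd.DataFrame(rows)


def pairwise_distances(vectors: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix between the rows of ``vectors``.

    Rows are items, columns are coordinates; NaNs are rejected so every
    pair is compared on the full shared dimension.
    """
    if vectors.isna().any().any():
        bad = vectors.index[vectors.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing coordinates for items: {bad}")
    d = squareform(pdist(vectors.to_numpy(dtype=float)))
    return pd.DataFrame(d, index=vectors.index, columns=vectors.index)


def single_linkage(distances: pd.DataFrame, method: str = "single") -> Dendrogram:
    """Cluster a symmetric distance table; default single linkage.

    Complete/average/ward linkage are accepted for sensitivity analyses but
    single linkage is the validated default.
    """
    n = len(distances)
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")
    if not np.allclose(distances.to_numpy(), distances.to_numpy().T):
        raise ValidationError("distance table is not symmetric")
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    Z = linkage(condensed, method=method)
    items = tuple(distances.index)
    members: dict[int, frozenset] = {i: frozenset([items[i]]) for i in range(n)}
    merges = []
    for step, (a, b, h, _cnt) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb, float(h)))
        members[n + step] = fa | fb
    return Dendrogram(items=items, merges=tuple(merges), _linkage=Z)


def nearest_pair(vectors: pd.DataFrame) -> tuple:
    """The globally closest pair of items and their Euclidean distance.

    Ties are broken lexicographically on the (row-order) item index pair.
    """
    if len(vectors) < 2:
        raise ValidationError("need at least 2 items")
    d = pairwise_distances(vectors)
    items = list(d.index)
    best = None
    for i, j in combinations(range(len(items)), 2):
        dij = d.iat[i, j]
        if best is None or dij < best[2]:
            best = (items[i], items[j], float(dij))
    return best


def compound_vectors(
    matrix,
    include_average: bool = True,
    standardize: bool = False,
    average: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-compound logP vectors: the program columns, plus their consensus mean.

    ``matrix`` is a :class:`~chromlip.consensus.LogPMatrix`. The consensus
    column mirrors the published analysis, which clusters the per-program
    values together with their average; drop it with
    ``include_average=False``, or supply a precomputed/printed ``average``
    series to use instead of the full-precision column mean. ``standardize``
    z-scores each column (off by default — all coordinates already share the
    logP scale).
    """
    frame = matrix.frame.copy()
    if include_average:
        frame["logp_average"] = (
            average.reindex(frame.index) if average is not None else frame.mean(axis=1)
        )
    if standardize:
        frame = (frame - frame.mean()) / frame.std(ddof=1)
    return frame


def variable_vectors(
    matrix,
    include_average: bool = True,
    standardize: bool = False,
    average: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-variable vectors (programs as items, compounds as coordinates)."""
    return compound_vectors(matrix, include_average, standardize, average).T
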
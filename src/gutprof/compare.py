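"""Cross-sample comparison of functional profiles.

Samples are compared on their normalised profile vectors (percentages per
feature) with the Pearson product-moment correlation coefficient r; the
distance between two samples is 1 - r, so identical profiles are at
distance 0 and perfectly anti-correlated profiles at distance 2.  The
pairwise distance matrix feeds average-linkage (UPGMA) agglomerative
clustering; the resulting ultrametric tree orders the rows of the exported
heat-map matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from skbio import DistanceMatrix, TreeNode

from .exceptions import InconsistencyError, UndefinedCorrelationError

LINKAGES = ("average", "single", "complete")


@dataclass
class ProfileMatrix:
    """Samples x features matrix of nonnegative percentages."""

    data: pd.DataFrame  # index = sample ids, columns = feature labels

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("profile values must be nonnegative")

    @classmethod
    def from_profiles(
        cls, profiles: Mapping[str, Mapping[str, float]]
    ) -> "ProfileMatrix":
        """Align per-sample {feature: value} mappings on the union of
        features; a feature absent from a sample contributes 0."""
        df = pd.DataFrame.from_dict(profiles, orient="index").fillna(0.0)
        return cls(df.sort_index(axis=1))

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson r between two equal-length profile vectors.

    A constant vector has no defined correlation; that is an error here,
    never a silent 0 or NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("profile vectors must be 1-D and of equal length")
    if xa.size < 2:
        raise ValueError("profile vectors need at least 2 features")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = float(np.dot(xc, yc) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    return 1.0 - r


def distance_matrix(profiles: ProfileMatrix) -> DistanceMatrix:
    """Pairwise Pearson distances between all samples.

    Returns a validated symmetric, zero-diagonal matrix; a constant sample
    profile raises with the offending sample named.
    """
    samples = profiles.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    values = profiles.data.to_numpy(dtype=float)
    for sid, row in zip(samples, values):
        if np.ptp(row) == 0.0:
            raise UndefinedCorrelationError(
                f"sample {sid!r} has a constant profile; correlation undefined"
            )
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pearson_distance(values[i], values[j])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=samples)


def _linkage(dm: DistanceMatrix, linkage: str) -> np.ndarray:
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    return sch.linkage(dm.condensed_form(), method=linkage)


def hierarchical_tree(dm: DistanceMatrix, linkage: str = "average") -> TreeNode:
    """Agglomerative clustering of the distance matrix into a rooted tree.

    Under UPGMA (average linkage) the tree is ultrametric: a node whose
    children merged at distance d sits at height d/2, and every leaf is at
    height 0.  Branch lengths are height differences; the newick form is
    available via ``str(tree)`` or ``tree.write``.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    Z = _linkage(dm, linkage)
    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in ids]
    heights: list[float] = [0.0] * len(ids)
    for a, b, dist, _count in Z:
        left, right = nodes[int(a)], nodes[int(b)]
        h = dist / 2.0
        left.length = h - heights[int(a)]
        right.length = h - heights[int(b)]
        nodes.append(TreeNode(children=[left, right]))
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def leaf_order(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def heatmap_export(
    profiles: ProfileMatrix,
    tree: TreeNode,
    matrix_path: str | Path,
    newick_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the profile matrix with rows in tree leaf order (plus a
    companion newick file) and return the ordered frame.

    Values are passed through unchanged; ordering is a pure permutation.
    """
    order = leaf_order(tree)
    samples = set(profiles.samples)
    missing = [s for s in order if s not in samples]
    if missing or len(order) != len(samples):
        raise InconsistencyError(
            f"tree leaves do not match the sample set (unmatched: {missing})"
        )
    ordered = profiles.data.loc[order]
    ordered.to_csv(matrix_path, sep="\t", index_label="sample")
    if newick_path is not None:
        tree.write(str(newick_path))
    return ordered


def compare_profiles(
    profiles: Mapping[str, Mapping[str, float]] | ProfileMatrix,
    linkage: str = "average",
) -> tuple[DistanceMatrix, TreeNode]:
    """Distance matrix plus tree in one step."""
    pm = profiles if isinstance(profiles, ProfileMatrix) \
        else ProfileMatrix.from_profiles(profiles)
    dm = distance_matrix(pm)
    return dm, hierarchical_tree(dm, linkage)
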
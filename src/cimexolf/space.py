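"""Odorant-space geometry: distances, rankings, clustering, PCA, and
temporal-structure analysis.

Each odorant is embedded as the 6-vector of its mean responses across the
six sensillum types, so 104 odorants span a six-dimensional odorant space
with 104·103/2 = 5356 unordered pairs.  Euclidean distance in spikes/s
measures how discriminable two odorants are to the antenna.  On top of the
space this module provides:

* ranked closest/farthest pair lists;
* agglomerative clustering under between-group (unweighted pair-group
  average, UPGMA) linkage, the standard reading of "between-group linkage"
  in the statistics packages that coined the term;
* correlation-matrix PCA: sensillum columns are standardized to zero mean
  and unit variance and the 6×6 correlation matrix eigendecomposed, so each
  component's variance fraction is its eigenvalue over 6;
* a phasic/tonic index for PSTHs (late-window rate over early peak) and
  hierarchical clustering of PSTH bin-count vectors, which groups odorants
  by response time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateColumnError,
    InsufficientDataError,
    InvalidParameterError,
    SchemaError,
    UndefinedIndexError,
)
from .panel import SENSILLA
from .spikes import PSTH
from .tuning import ResponseMatrix


@dataclass
class OdorSpace:
    """Embedding of odorants as response vectors with pairwise distances."""

    odorant_ids: list[str]
    vectors: np.ndarray
    condensed: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.condensed = np.asarray(self.condensed, dtype=float)
        n = len(self.odorant_ids)
        if self.vectors.shape[0] != n:
            raise SchemaError("one vector per odorant required")
        if self.condensed.size != n * (n - 1) // 2:
            raise SchemaError("condensed distance size mismatch")

    @property
    def n_odorants(self) -> int:
        return len(self.odorant_ids)

    @property
    def n_pairs(self) -> int:
        return self.n_odorants * (self.n_odorants - 1) // 2

    @property
    def distance_matrix(self) -> pd.DataFrame:
        """Square symmetric distance matrix (spikes/s) as a DataFrame."""
        return pd.DataFrame(
            squareform(self.condensed),
            index=self.odorant_ids,
            columns=self.odorant_ids,
        )

    def distance(self, a: str, b: str) -> float:
        i, j = self.odorant_ids.index(a), self.odorant_ids.index(b)
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        n = self.n_odorants
        return float(self.condensed[n * i - i * (i + 1) // 2 + (j - i - 1)])


@dataclass
class ClusterTree:
    """Agglomerative merge history (a scipy linkage matrix with labels)."""

    linkage: np.ndarray
    labels: list[str]
    method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Assign leaves to ``k`` flat clusters."""
        assignment = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(assignment, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Export the tree (with merge heights as branch lengths)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the response matrix.

    ``variance_explained`` holds all component fractions (summing to 1);
    ``loadings`` and ``scores`` are trimmed to ``n_components``.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    n_components: int

    @property
    def cumulative_variance(self) -> float:
        """Fraction of total variance captured by the kept components."""
        return float(np.sum(self.variance_explained[: self.n_components]))


def build_space(matrix: ResponseMatrix) -> OdorSpace:
    """Embed every odorant as its 6-D response vector."""
    missing = set(SENSILLA) - set(matrix.mean.columns)
    if missing:
        raise SchemaError(f"matrix missing sensillum columns: {missing}")
    vectors = matrix.mean[list(SENSILLA)].values
    return OdorSpace(matrix.odorants, vectors, pdist(vectors))


def rank_pairs(
    space: OdorSpace, k: int, direction: str = "closest"
) -> pd.DataFrame:
    """Top-k odorant pairs by Euclidean distance.

    Sorted ascending for ``closest`` and descending for ``farthest``; ties
    are broken by the lexicographic pair id so the ranking is deterministic.
    The ``distance`` column is rounded to one decimal for reporting;
    ``distance_exact`` keeps full precision.
    """
    if direction not in ("closest", "farthest"):
        raise InvalidParameterError(f"unknown direction {direction!r}")
    if k <= 0:
        raise InvalidParameterError("k must be positive")
    if k > space.n_pairs:
        raise InvalidParameterError(f"k exceeds the {space.n_pairs} pairs")
    ids = space.odorant_ids
    n = len(ids)
    iu, ju = np.triu_indices(n, 1)
    df = pd.DataFrame(
        {
            "odorant_a": [min(ids[i], ids[j]) for i, j in zip(iu, ju)],
            "odorant_b": [max(ids[i], ids[j]) for i, j in zip(iu, ju)],
            "distance_exact": space.condensed,
        }
    )
    ascending = direction == "closest"
    df = df.sort_values(
        ["distance_exact", "odorant_a", "odorant_b"],
        ascending=[ascending, True, True],
        kind="mergesort",
    ).head(k)
    df["distance"] = df["distance_exact"].round(1)
    return df.reset_index(drop=True)[
        ["odorant_a", "odorant_b", "distance", "distance_exact"]
    ]


def hcluster(data, labels=None, method: str = "average") -> ClusterTree:
    """Agglomerative clustering under between-group average linkage.

    ``data`` may be an :class:`OdorSpace` (its Euclidean distances are
    used), a DataFrame of row profiles, or a 2-D array of row profiles
    (with optional ``labels``).  Between-group linkage is the unweighted
    average of all inter-cluster pairwise distances (UPGMA):
    ``d(A, B) = mean over a in A, b in B of d(a, b)``.
    """
    if isinstance(data, OdorSpace):
        condensed, labels = data.condensed, data.odorant_ids
        n = data.n_odorants
    else:
        if isinstance(data, pd.DataFrame):
            labels = list(data.index) if labels is None else list(labels)
            x = data.values
        else:
            x = np.asarray(data, dtype=float)
            if labels is None:
                labels = [str(i) for i in range(x.shape[0])]
        n = x.shape[0]
        if n < 2:
            raise InvalidParameterError("need at least 2 items to cluster")
        condensed = pdist(x)
    if not np.all(np.isfinite(condensed)):
        raise InvalidParameterError("non-finite distances")
    if n < 2:
        raise InvalidParameterError("need at least 2 items to cluster")
    z = hierarchy.linkage(condensed, method=method)
    return ClusterTree(z, list(labels), method=method)


def pca_space(matrix, n_components: int = 3) -> PCAResult:
    """Correlation-matrix PCA of odorants (observations) over sensilla.

    Columns are standardized (sample SD, ddof=1) and the correlation matrix
    eigendecomposed; component ``i`` explains ``eigenvalue_i / p`` of the
    variance where ``p`` is the number of sensilla.  Scores are the
    standardized data projected on the eigenvectors.  Loading signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    if isinstance(matrix, ResponseMatrix):
        df = matrix.mean
    else:
        df = pd.DataFrame(matrix)
    x = df.values.astype(float)
    n, p = x.shape
    if n < 7:
        raise InsufficientDataError("PCA requires at least 7 odorants")
    if not (1 <= n_components <= p):
        raise InvalidParameterError("n_components must be in [1, n_columns]")
    sd = x.std(axis=0, ddof=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise DegenerateColumnError(
            f"constant column(s): {[df.columns[i] for i in flat]}"
        )
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(p):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = z @ eigvecs
    comp_names = [f"PC{i + 1}" for i in range(p)]
    return PCAResult(
        loadings=pd.DataFrame(
            eigvecs[:, :n_components],
            index=df.columns,
            columns=comp_names[:n_components],
        ),
        scores=pd.DataFrame(
            scores[:, :n_components],
            index=df.index,
            columns=comp_names[:n_components],
        ),
        variance_explained=eigvals / p,
        n_components=n_components,
    )


class PhasicTonicResult(NamedTuple):
    index: float
    label: str


def phasic_tonic_index(
    psth: PSTH, tonic_threshold: float = 0.5
) -> PhasicTonicResult:
    """Score a 20-bin PSTH on the phasic-tonic axis.

    The index is the mean rate over the late window (bins 11-20, i.e.
    1-2 s after onset) divided by the peak rate during the stimulus (bins
    1-5), clipped to [0, 1].  A sustained (tonic) response keeps firing
    late and scores near 1; a burst-at-onset (phasic) response scores near
    0.  The label is ``tonic`` when the index reaches ``tonic_threshold``.
    """
    if psth.n_bins != 20:
        raise InvalidParameterError(
            "phasic/tonic index defined for the standard 20-bin PSTH"
        )
    rates = psth.rates
    peak = float(rates[:5].max())
    if peak == 0:
        raise UndefinedIndexError("no spikes during the stimulus bins")
    index = float(min(rates[10:].mean() / peak, 1.0))
    label = "tonic" if index >= tonic_threshold else "phasic"
    return PhasicTonicResult(index, label)


def temporal_cluster(psths, labels=None) -> ClusterTree:
    """Cluster PSTHs by their 100 ms bin-count vectors.

    All PSTHs must share the bin structure; clustering is Euclidean with
    between-group average linkage, so odorants group by response time
    course (phasic vs tonic) rather than by total spike count alone.
    """
    psths = list(psths)
    if len(psths) < 2:
        raise InvalidParameterError("need at least 2 PSTHs")
    first = psths[0]
    for p in psths[1:]:
        if (
            p.n_bins != first.n_bins
            or abs(p.bin_width - first.bin_width) > 1e-12
        ):
            raise InvalidParameterError("PSTH bin structures differ")
    x = np.vstack([p.counts for p in psths]).astype(float)
    return hcluster(x, labels=labels)
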
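"""Response matrix assembly, band statistics, class biases and tuning curves.

The central object is the odorant × sensillum matrix of mean
baseline-subtracted firing rates at a reference dose (1:100 v/v by
convention).  From it this module derives:

* the distribution of responses over strength bands (<50, [50,100],
  (100,150], (150,200], >200 spikes/s — the printed bands share their
  endpoints, so ties are assigned to the lower band to keep an exact
  partition);
* per-class response proportions (fraction of a chemical class driving at
  least one sensillum — or a given sensillum — above an excitatory
  threshold, 50 spikes/s by default);
* tuning curves (a sensillum's responses ordered strongest-at-center) and
  their kurtosis, the K value that quantifies tuning breadth: a high K
  means a narrowly tuned sensillum dominated by a few odorants.

Cells with mean response below 15 spikes/s are flagged non-responders;
the flag never alters the stored mean, filtering is left to callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    SchemaError,
    UndefinedKurtosisError,
)
from .panel import SENSILLA

NON_RESPONDER_THRESHOLD = 15.0
EXCITATORY_THRESHOLD = 50.0

BAND_LABELS = ("<50", "[50,100]", "(100,150]", "(150,200]", "(200,inf)")


@dataclass
class ResponseMatrix:
    """Odorant × sensillum mean response matrix with replicate statistics.

    ``mean``/``sem``/``n`` are aligned DataFrames indexed by odorant with
    sensillum columns; ``classes`` maps each odorant to its chemical class.
    """

    mean: pd.DataFrame
    sem: pd.DataFrame
    n: pd.DataFrame
    classes: pd.Series
    dose: str = "1:100 v/v"

    def __post_init__(self) -> None:
        if not (
            self.mean.shape == self.sem.shape == self.n.shape
            and list(self.mean.index) == list(self.sem.index) == list(self.n.index)
        ):
            raise SchemaError("mean, sem and n tables must align")
        missing = set(self.mean.index) - set(self.classes.index)
        if missing:
            raise SchemaError(f"odorants without class labels: {missing}")
        self.classes = self.classes.loc[self.mean.index]

    @property
    def odorants(self) -> list[str]:
        return list(self.mean.index)

    @property
    def sensilla(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def n_cells(self) -> int:
        return int(self.mean.size)

    @property
    def non_responder(self) -> pd.DataFrame:
        """Boolean mask of cells below the 15 spikes/s response criterion."""
        return self.mean < NON_RESPONDER_THRESHOLD

    @property
    def replicate_compliant(self) -> bool:
        """True when every cell carries at least six replicates."""
        return bool((self.n.values >= 6).all())


@dataclass
class TuningCurve:
    """One sensillum's responses arranged strongest-at-center."""

    sensillum: str
    odorant_order: list[str]
    ordered_rates: np.ndarray
    k: float | None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.ordered_rates = np.asarray(self.ordered_rates, dtype=float)


def build_response_matrix(
    records: pd.DataFrame, dose_label: str = "1:100 v/v"
) -> ResponseMatrix:
    """Aggregate a tidy replicate rate table into a ResponseMatrix.

    ``records`` needs columns odorant, odorant_class, sensillum,
    spikes_per_s (replicate is optional).  Cell mean is the arithmetic mean
    over replicates and SEM the sample SD over sqrt(n); a single replicate
    yields SEM 0 by convention.
    """
    required = {"odorant", "odorant_class", "sensillum", "spikes_per_s"}
    missing = required - set(records.columns)
    if missing:
        raise SchemaError(f"replicate table missing columns: {missing}")
    cls = records[["odorant", "odorant_class"]].drop_duplicates()
    dup = cls["odorant"].duplicated()
    if dup.any():
        raise SchemaError(
            "conflicting class labels for odorants: "
            f"{sorted(cls.loc[dup, 'odorant'])}"
        )
    grouped = records.groupby(["odorant", "sensillum"])["spikes_per_s"]
    mean = grouped.mean().unstack("sensillum")
    sem_tbl = grouped.sem(ddof=1).unstack("sensillum").fillna(0.0)
    n = grouped.size().unstack("sensillum")
    if mean.isna().any().any():
        holes = [tuple(ix) for ix in np.argwhere(mean.isna().values)]
        raise SchemaError(
            f"missing odorant-sensillum combinations at cells {holes}"
        )
    order = [s for s in SENSILLA if s in mean.columns] + [
        s for s in mean.columns if s not in SENSILLA
    ]
    mean, sem_tbl, n = mean[order], sem_tbl[order], n[order].astype(int)
    classes = cls.set_index("odorant")["odorant_class"]
    return ResponseMatrix(mean, sem_tbl, n, classes, dose=dose_label)


def band_distribution(matrix: ResponseMatrix) -> pd.DataFrame:
    """Partition all cells into response-strength bands.

    Returns a DataFrame indexed by band label with ``count`` and
    ``percent`` (one decimal) columns.  Shared endpoints go to the lower
    band: a cell at exactly 100 spikes/s counts in [50,100].
    """
    if matrix.n_cells == 0:
        raise InvalidParameterError("empty matrix")
    x = matrix.mean.values.ravel()
    counts = [
        int(np.sum(x < 50)),
        int(np.sum((x >= 50) & (x <= 100))),
        int(np.sum((x > 100) & (x <= 150))),
        int(np.sum((x > 150) & (x <= 200))),
        int(np.sum(x > 200)),
    ]
    percent = [round(100.0 * c / x.size, 1) for c in counts]
    return pd.DataFrame(
        {"count": counts, "percent": percent}, index=list(BAND_LABELS)
    )


def class_bias(
    matrix: ResponseMatrix,
    threshold: float = EXCITATORY_THRESHOLD,
    mode: str = "per_sensillum",
):
    """Fraction of each chemical class responding at or above a threshold.

    ``mode="per_sensillum"`` (default) returns a class × sensillum
    DataFrame of percentages: the share of the class's odorants whose mean
    response in that sensillum is >= threshold.  ``mode="max"`` returns a
    Series per class using the maximum response across sensilla, the
    whole-animal view.
    """
    if mode not in ("per_sensillum", "max"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    bad = set(matrix.classes.unique()) - set(_known_classes(matrix))
    if bad:
        raise SchemaError(f"unknown class labels: {bad}")
    hits = matrix.mean >= threshold
    groups = hits.groupby(matrix.classes)
    if mode == "max":
        return 100.0 * hits.any(axis=1).groupby(matrix.classes).mean()
    return 100.0 * groups.mean()


def _known_classes(matrix: ResponseMatrix):
    from .panel import CLASSES

    # panel vocabulary plus anything the caller declared — unknown labels
    # are those that are non-strings or empty
    labels = set(CLASSES) | {
        c for c in matrix.classes.unique() if isinstance(c, str) and c
    }
    return labels


def tuning_curve(matrix: ResponseMatrix, sensillum: str) -> TuningCurve:
    """Arrange one sensillum column strongest-at-center.

    Responses are sorted descending (ties broken by odorant id) and placed
    center-out: rank 1 at the center, rank 2 immediately left, rank 3
    immediately right, alternating outwards so the weakest responses sit at
    the edges.  The output is always a permutation of the column.
    """
    if sensillum not in matrix.mean.columns:
        raise SchemaError(f"no sensillum column {sensillum!r}")
    col = matrix.mean[sensillum]
    order = sorted(col.index, key=lambda od: (-col[od], od))
    n = len(order)
    center = n // 2
    positions = np.empty(n, dtype=int)
    for rank, _ in enumerate(order):
        step = (rank + 1) // 2
        positions[rank] = center - step if rank % 2 == 1 else center + step
    # rank 0 -> center, odd ranks fan left, even ranks fan right
    arranged_ids = [None] * n
    for rank, od in enumerate(order):
        arranged_ids[positions[rank]] = od
    rates = np.array([col[od] for od in arranged_ids], dtype=float)
    degenerate = bool(np.ptp(col.values) == 0)
    if degenerate or n < 4:
        k = None
    else:
        k = kurtosis_k(col.values)
    return TuningCurve(sensillum, arranged_ids, rates, k, degenerate)


def kurtosis_k(rates, excess: bool = True) -> float:
    """Tuning-breadth K value: sample kurtosis with small-sample correction.

    The default is the corrected sample *excess* kurtosis

    ``K = [n(n+1) / ((n-1)(n-2)(n-3))] * sum(((x - mean)/s)^4)
    - 3(n-1)^2 / ((n-2)(n-3))``

    (the convention of mainstream statistics packages; ~0 for Gaussian
    data).  ``excess=False`` returns the raw (Pearson) convention, which is
    the excess value plus 3.
    """
    x = np.asarray(rates, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("kurtosis requires at least 4 values")
    if np.ptp(x) == 0:
        raise UndefinedKurtosisError("kurtosis undefined for a constant vector")
    return float(stats.kurtosis(x, fisher=excess, bias=False))
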
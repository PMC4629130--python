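"""Replication of the reported summary statistics from a measured
response matrix.

The original 104-odorant × 6-sensillum table of recorded mean rates is
distributed as supplementary material of the source recordings and is not
bundled here.  Once transcribed to the package's matrix TSV format (see
:func:`cimexolf.io.write_response_matrix`) and placed at
``data/s1_response_matrix.tsv``, :func:`summarize_matrix` recomputes the
headline statistics of the original analysis: band counts, per-sensillum
K values, cumulative PCA variance over three components, and the extreme
odorant pairs.
"""

from __future__ import annotations

from pathlib import Path

from .io import read_response_matrix
from .space import build_space, pca_space, rank_pairs
from .tuning import band_distribution, kurtosis_k

MEASURED_MATRIX_PATH = Path("data") / "s1_response_matrix.tsv"


def load_measured_matrix(path=None):
    """Load the transcribed measured response matrix.

    Raises ``FileNotFoundError`` with transcription instructions when the
    table has not been provided.
    """
    path = Path(path) if path is not None else MEASURED_MATRIX_PATH
    if not path.exists():
        raise FileNotFoundError(
            f"measured response matrix not found at {path}; transcribe the "
            "supplementary odorant-by-sensillum rate table to matrix TSV "
            "(columns: odorant, class, Da, Db, Dg, C, E1, E2) to enable "
            "replication"
        )
    return read_response_matrix(path)


def summarize_matrix(matrix) -> dict:
    """Headline statistics of a full response matrix.

    Returns band counts/percentages, the K value per sensillum column, the
    cumulative variance captured by three principal components (percent),
    the top-10 closest and farthest pair tables, and pair/cell counts.
    """
    bands = band_distribution(matrix)
    space = build_space(matrix)
    pca = pca_space(matrix, n_components=3)
    k_values = {s: kurtosis_k(matrix.mean[s].values) for s in matrix.sensilla}
    return {
        "n_cells": matrix.n_cells,
        "n_pairs": space.n_pairs,
        "band_counts": bands["count"].to_dict(),
        "band_percent": bands["percent"].to_dict(),
        "k_values": k_values,
        "pca3_percent": 100.0 * pca.cumulative_variance,
        "closest_pairs": rank_pairs(space, 10, "closest"),
        "farthest_pairs": rank_pairs(space, 10, "farthest"),
        "space": space,
    }
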
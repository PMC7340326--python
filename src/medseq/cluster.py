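"""Z-score normalization, hierarchical clustering and heatmap export.

DMR read counts are standardized per row (region) across samples and
clustered agglomeratively; the rendered heatmap shows the Z-scores, so
samples from the same condition should form pure subtrees when the planted
(or real) methylation differences dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class ZScoreMatrix:
    """Row-standardized counts; zero-variance rows are zeroed and flagged."""

    values: pd.DataFrame
    zero_variance: np.ndarray  # boolean per row


def zscore_rows(count_matrix: pd.DataFrame) -> ZScoreMatrix:
    """Standardize each row to mean 0, sd 1 (population sd).

    Requires >= 2 columns.  Constant rows cannot be standardized; they
    become all-zero and are flagged.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("Z-scoring requires at least two columns")
    values = count_matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population (n) sd
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    if flat.any():
        logger.warning("%d zero-variance rows zeroed in Z-score matrix", int(flat.sum()))
    return ZScoreMatrix(
        pd.DataFrame(z, index=count_matrix.index, columns=count_matrix.columns), flat
    )


@dataclass
class ClusterResult:
    axis: str
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[int]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, assignment)}


def hierarchical_cluster(
    zmatrix: ZScoreMatrix,
    axis: str = "columns",
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Deterministic agglomerative clustering of rows or columns.

    Equal-distance merges resolve to the pair with the lower original
    index (the linkage algorithm's stable scan order), so the leaf order
    is reproducible.  NaNs are rejected naming the offending row.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    frame = zmatrix.values if axis == "rows" else zmatrix.values.T
    if frame.shape[0] < 2:
        raise ValueError(f"need >= 2 items on the {axis} axis to cluster")
    data = frame.to_numpy(dtype=float)
    bad = np.where(np.isnan(data).any(axis=1))[0]
    if bad.size:
        raise ValueError(f"NaN values in matrix at {frame.index[bad[0]]!r}")
    linkage = hierarchy.linkage(pdist(data, metric=metric), method=method)
    order = hierarchy.leaves_list(linkage).tolist()
    return ClusterResult(axis, list(frame.index.astype(str)), linkage, order)


def export_heatmap(
    zmatrix: ZScoreMatrix,
    path: str | Path,
    row_order: ClusterResult | None = None,
    col_order: ClusterResult | None = None,
) -> Path | None:
    """Render the Z-score heatmap (PNG/SVG) and write the plotted matrix
    as a sibling TSV so the image can be regenerated exactly."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if zmatrix.values.empty:
        logger.warning("empty matrix; no heatmap written")
        return None
    frame = zmatrix.values
    if row_order is not None:
        frame = frame.iloc[row_order.leaf_order]
    if col_order is not None:
        frame = frame.iloc[:, col_order.leaf_order]
    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    frame.to_csv(tsv_path, sep="\t", float_format="%.10g")

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * frame.shape[1] + 2), max(4, 0.08 * frame.shape[0] + 2))
    )
    lim = float(np.nanmax(np.abs(frame.to_numpy()))) or 1.0
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(frame.shape[1]))
    ax.set_xticklabels(frame.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{frame.shape[0]} regions")
    fig.colorbar(im, ax=ax, label="Z-score of read counts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
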
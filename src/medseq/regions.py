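"""Aggregation of site counts over annotated regions.

Tested region classes follow the promoter/gene-body/CpG-island scheme:
TSS windows (1 kb either side of the TSS), gene bodies (1 kb downstream of
the TSS to the TES) and CpG islands.  ``tss2kb`` aliases the TSS windows —
the 2 kb window surrounding the TSS used for per-gene read-count
summaries.  Counts are raw sums; normalization happens only inside the
statistics that need it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import RegionCatalog, SiteIndex
from .scoring import GroupedCounts, SiteCountProfile

logger = logging.getLogger(__name__)


@dataclass
class RegionCountMatrix:
    """Region-by-sample (or region-by-group) summed site counts.

    ``data`` holds one column per sample/group; ``meta`` holds kind, chrom,
    start, end and n_sites per region; ``totals`` holds each column's
    library total (the chi-squared denominator), not the column sum of the
    matrix.
    """

    kind: str
    data: pd.DataFrame
    meta: pd.DataFrame
    totals: dict[str, float]

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        out = pd.concat([self.meta, self.data], axis=1)
        out.index.name = "region_id"
        out.to_csv(path, sep="\t")


def _columns(
    profiles: Sequence[SiteCountProfile] | GroupedCounts,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    if isinstance(profiles, GroupedCounts):
        return profiles.counts, profiles.totals
    cols = {p.sample_id: p.counts for p in profiles}
    totals = {p.sample_id: p.library_total for p in profiles}
    if len(cols) != len(profiles):
        raise ValueError("duplicate sample ids among profiles")
    return cols, totals


def aggregate_regions(
    profiles: Sequence[SiteCountProfile] | GroupedCounts,
    site_index: SiteIndex,
    catalog: RegionCatalog,
    kind: str,
) -> RegionCountMatrix:
    """Sum per-site counts over every region of one kind.

    Per column, a region's count is the sum over indexed sites with anchor
    coordinate in [start, end); regions with no sites are retained with
    count 0.  Overlapping regions double-count by design — a site inside
    two genes' windows contributes to both.
    """
    regions = catalog.regions(kind)
    cols, totals = _columns(profiles)
    # prefix sums make each region lookup O(log n_sites)
    prefix = {name: np.concatenate([[0.0], np.cumsum(col)]) for name, col in cols.items()}
    rows = []
    meta_rows = []
    for region in regions:
        lo, hi = site_index.interval_slice(region.chrom, region.start, region.end)
        rows.append({name: prefix[name][hi] - prefix[name][lo] for name in cols})
        meta_rows.append(
            {
                "kind": kind,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_sites": hi - lo,
            }
        )
    index = pd.Index([r.region_id for r in regions], name="region_id")
    data = pd.DataFrame(rows, index=index, columns=list(cols))
    meta = pd.DataFrame(meta_rows, index=index)
    return RegionCountMatrix(kind, data, meta, dict(totals))


def tss_2kb_summary(
    profiles: Sequence[SiteCountProfile] | GroupedCounts,
    gene_id: str,
    site_index: SiteIndex,
    catalog: RegionCatalog,
) -> pd.Series:
    """Per-sample counts in one gene's 2 kb TSS window (boxplot-ready).

    Raises ``KeyError`` listing near-matching gene ids if the gene is
    unknown; an all-zero vector (no sites in the window) logs a warning.
    """
    region = catalog.lookup("tss2kb", gene_id)
    matrix = aggregate_regions(profiles, site_index, catalog, "tss2kb")
    row = matrix.data.loc[region.region_id]
    if matrix.meta.loc[region.region_id, "n_sites"] == 0:
        logger.warning("gene %s has no recognition sites in its TSS window", gene_id)
    row.name = gene_id
    return row
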
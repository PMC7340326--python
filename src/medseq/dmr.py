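"""Differentially methylated region (DMR) calling.

Two groups' read counts are compared by a Pearson chi-squared test on the
2x2 table of (counts in the tested unit) versus (all other counts in the
library), one degree of freedom, no continuity correction.  Multiple
testing is controlled by Bonferroni or Benjamini-Hochberg across all units
of one analysis.  Fold changes are ratios of library-size-normalized rates
with a pseudocount so zero counts stay finite.

Two calling modes mirror the two levels of the analysis:

* region mode — one test per annotated region (TSS window, gene body or
  CpG island);
* sliding-window mode — one test per recognition site genome-wide, after
  which maximal runs of consecutive significant sites with a common fold
  direction are binned and reported as DMRs when they reach at least 10
  sites, 100 bp, and the configured fold change (2- or 5-fold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import RegionCatalog, SiteIndex
from .regions import RegionCountMatrix
from .scoring import GroupedCounts

logger = logging.getLogger(__name__)

CORRECTIONS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


@dataclass(frozen=True)
class DMRTestConfig:
    """Thresholds of the DMR caller.

    ``min_sites`` and ``min_span_bp`` apply to sliding-window candidates
    only; ``fold_threshold`` applies everywhere.  ``site_gating`` chooses
    whether window-mode per-site significance uses corrected ("adjusted")
    or raw p-values.
    """

    correction: str = "bonferroni"
    alpha: float = 0.05
    min_sites: int = 10
    min_span_bp: int = 100
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    yates: bool = False
    site_gating: str = "adjusted"  # "adjusted" | "raw"

    def __post_init__(self) -> None:
        if self.correction not in CORRECTIONS:
            raise ValueError(f"correction must be one of {sorted(CORRECTIONS)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.site_gating not in ("adjusted", "raw"):
            raise ValueError("site_gating must be 'adjusted' or 'raw'")


@dataclass
class DMRRecord:
    """One tested region or binned window."""

    region_id: str
    kind: str
    chrom: str
    start: int
    end: int
    count_a: float
    total_a: float
    count_b: float
    total_b: float
    fold_change: float  # magnitude, >= 1
    direction: str  # "up" (B > A), "down", or "none"
    chi2_stat: float
    p_raw: float
    p_adj: float
    significant: bool
    n_sites: int
    span_bp: int
    degenerate: bool = False
    overlaps: dict = field(default_factory=dict)


class Chi2Result(NamedTuple):
    stat: float
    p: float
    degenerate: bool


def chi2_counts(
    count_a: float,
    total_a: float,
    count_b: float,
    total_b: float,
    yates: bool = False,
) -> Chi2Result:
    """Pearson chi-squared on [[a, A - a], [b, B - b]], 1 df.

    Counts are rounded half-to-even to integers first.  A table with an
    all-zero column (both counts 0, or both complements 0) has zero
    expected cells and is returned as (0, 1, degenerate).
    """
    a, b = float(np.rint(count_a)), float(np.rint(count_b))
    A, B = float(np.rint(total_a)), float(np.rint(total_b))
    if A <= 0 or B <= 0:
        raise ValueError("group totals must be positive")
    if a > A or b > B:
        raise ValueError("count exceeds its group total")
    if (a + b) == 0 or ((A - a) + (B - b)) == 0:
        return Chi2Result(0.0, 1.0, True)
    table = np.array([[a, A - a], [b, B - b]])
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return Chi2Result(float(stat), float(p), False)


def chi2_counts_vec(
    counts_a: np.ndarray, total_a: float, counts_b: np.ndarray, total_b: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized uncorrected Pearson chi-squared over many 2x2 tables.

    Returns (stat, p, degenerate); degenerate tables get stat 0, p 1.
    """
    a = np.rint(np.asarray(counts_a, dtype=float))
    b = np.rint(np.asarray(counts_b, dtype=float))
    A = float(np.rint(total_a))
    B = float(np.rint(total_b))
    if A <= 0 or B <= 0:
        raise ValueError("group totals must be positive")
    if np.any(a > A) or np.any(b > B):
        raise ValueError("count exceeds its group total")
    n = A + B
    col1 = a + b
    col2 = n - col1
    degenerate = (col1 == 0) | (col2 == 0)
    det = a * (B - b) - b * (A - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(degenerate, 0.0, n * det**2 / (A * B * col1 * col2))
    p = np.where(degenerate, 1.0, stats.chi2.sf(stat, df=1))
    return stat, p, degenerate


def adjust_pvalues(p_values: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(CORRECTIONS)}")
    return multipletests(p, method=CORRECTIONS[method])[1]


class Fold(NamedTuple):
    magnitude: float  # >= 1
    direction: str  # "up" (B > A), "down", "none"
    ratio: float  # signed ratio rate_B / rate_A


def normalized_fold(
    count_a: float,
    total_a: float,
    count_b: float,
    total_b: float,
    pseudocount: float = 0.5,
) -> Fold:
    """Library-size-normalized rate ratio with pseudocount.

    ratio = ((b + pc) / B) / ((a + pc) / A); the reported magnitude is
    max(ratio, 1/ratio) with the direction stored separately ("up" means
    group B exceeds group A).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    rate_a = (count_a + pseudocount) / total_a
    rate_b = (count_b + pseudocount) / total_b
    ratio = rate_b / rate_a
    if np.isclose(ratio, 1.0):
        return Fold(max(ratio, 1.0 / ratio), "none", ratio)
    direction = "up" if ratio > 1 else "down"
    return Fold(max(ratio, 1.0 / ratio), direction, ratio)


# ---------------------------------------------------------------------------
# Region mode


def call_region_dmrs(
    matrix: RegionCountMatrix,
    group_pair: tuple[str, str],
    config: DMRTestConfig = DMRTestConfig(),
) -> list[DMRRecord]:
    """Test every region of one kind between two groups.

    The 2x2 table is (region counts) vs (rest of the library) per group;
    correction runs across all regions of the kind; records come back
    sorted by adjusted p.  A record is significant iff p_adj <= alpha and
    fold magnitude >= fold_threshold.
    """
    group_a, group_b = group_pair
    for group in group_pair:
        if group not in matrix.data.columns:
            raise ValueError(f"group {group!r} not in region matrix")
    counts_a = matrix.data[group_a].to_numpy(dtype=float)
    counts_b = matrix.data[group_b].to_numpy(dtype=float)
    total_a = matrix.totals[group_a]
    total_b = matrix.totals[group_b]
    stat, p_raw, degenerate = chi2_counts_vec(counts_a, total_a, counts_b, total_b)
    p_adj = adjust_pvalues(p_raw, config.correction)
    records = []
    for i, region_id in enumerate(matrix.region_ids):
        fold = normalized_fold(
            counts_a[i], total_a, counts_b[i], total_b, config.pseudocount
        )
        meta = matrix.meta.iloc[i]
        significant = bool(
            p_adj[i] <= config.alpha
            and fold.magnitude >= config.fold_threshold
            and not degenerate[i]
        )
        records.append(
            DMRRecord(
                region_id=str(region_id),
                kind=matrix.kind,
                chrom=meta["chrom"],
                start=int(meta["start"]),
                end=int(meta["end"]),
                count_a=float(counts_a[i]),
                total_a=float(total_a),
                count_b=float(counts_b[i]),
                total_b=float(total_b),
                fold_change=fold.magnitude,
                direction=fold.direction,
                chi2_stat=float(stat[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                significant=significant,
                n_sites=int(meta["n_sites"]),
                span_bp=int(meta["end"] - meta["start"]),
                degenerate=bool(degenerate[i]),
            )
        )
    records.sort(key=lambda r: (r.p_adj, r.p_raw, r.region_id))
    return records


# ---------------------------------------------------------------------------
# Sliding-window mode


def sliding_window_dmrs(
    grouped: GroupedCounts,
    site_index: SiteIndex,
    group_pair: tuple[str, str],
    config: DMRTestConfig = DMRTestConfig(),
    catalog: RegionCatalog | None = None,
) -> list[DMRRecord]:
    """Genome-wide detection of runs of consecutive differential sites.

    Every indexed site is chi-squared tested between the two groups and
    gated at ``config.alpha`` on corrected p-values (or raw, by config).
    Maximal runs of gated sites that are consecutive in the index, on one
    chromosome, and share a fold direction become candidates; a candidate
    is reported iff it has >= min_sites sites, spans >= min_span_bp
    (last - first + 1), and its aggregated counts reach the fold
    threshold.  Each reported window's p_adj is its aggregate-count p
    Bonferroni-corrected by the number of candidate runs examined.
    """
    group_a, group_b = group_pair
    for group in group_pair:
        if group not in grouped.counts:
            raise ValueError(f"group {group!r} not in grouped counts")
    if site_index.n_sites == 0:
        return []
    counts_a = grouped.counts[group_a]
    counts_b = grouped.counts[group_b]
    total_a = grouped.totals[group_a]
    total_b = grouped.totals[group_b]
    _, p_raw, _ = chi2_counts_vec(counts_a, total_a, counts_b, total_b)
    p_gate = p_raw if config.site_gating == "raw" else adjust_pvalues(p_raw, config.correction)
    gated = p_gate <= config.alpha

    rate_a = (counts_a + config.pseudocount) / total_a
    rate_b = (counts_b + config.pseudocount) / total_b
    direction = np.sign(rate_b - rate_a)  # +1 up, -1 down, 0 breaks runs

    candidates: list[tuple[str, int, int]] = []  # (chrom, global lo, global hi)
    for chrom in site_index.chroms:
        lo, hi = site_index.chrom_range(chrom)
        run_start = None
        run_dir = 0.0
        for i in range(lo, hi + 1):
            ok = i < hi and gated[i] and direction[i] != 0
            if ok and run_start is not None and direction[i] == run_dir:
                continue
            if run_start is not None:
                candidates.append((chrom, run_start, i))
                run_start = None
            if ok:
                run_start = i
                run_dir = direction[i]
        # loop emits any open run at i == hi
    records = []
    n_candidates = max(len(candidates), 1)
    for chrom, lo, hi in candidates:
        n_sites = hi - lo
        base, _ = site_index.chrom_range(chrom)
        pos = site_index.positions[chrom]
        first = int(pos[lo - base])
        last = int(pos[hi - 1 - base])
        span = last - first + 1
        sum_a = float(counts_a[lo:hi].sum())
        sum_b = float(counts_b[lo:hi].sum())
        fold = normalized_fold(sum_a, total_a, sum_b, total_b, config.pseudocount)
        if n_sites < config.min_sites:
            continue
        if span < config.min_span_bp:
            continue
        if fold.magnitude < config.fold_threshold:
            continue
        stat, p, degenerate = chi2_counts(sum_a, total_a, sum_b, total_b)
        p_adj = min(1.0, p * n_candidates)
        record = DMRRecord(
            region_id=f"{chrom}:{first}-{last + 1}",
            kind="window",
            chrom=chrom,
            start=first,
            end=last + 1,
            count_a=sum_a,
            total_a=float(total_a),
            count_b=sum_b,
            total_b=float(total_b),
            fold_change=fold.magnitude,
            direction=fold.direction,
            chi2_stat=stat,
            p_raw=p,
            p_adj=p_adj,
            significant=bool(p_adj <= config.alpha and fold.magnitude >= config.fold_threshold),
            n_sites=n_sites,
            span_bp=span,
            degenerate=degenerate,
        )
        records.append(record)
    if catalog is not None:
        annotate_overlaps(records, catalog)
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def annotate_overlaps(dmrs: Sequence[DMRRecord], catalog: RegionCatalog) -> Sequence[DMRRecord]:
    """Record >= 1 bp half-open intersections with TSS/gene-body/island regions."""
    for dmr in dmrs:
        overlaps: dict[str, list[str]] = {}
        for kind in ("tss", "genebody", "cpg_island"):
            ids = [
                region.region_id
                for region in catalog.regions(kind)
                if region.chrom == dmr.chrom
                and region.start < dmr.end
                and dmr.start < region.end
            ]
            if ids:
                overlaps[kind] = ids
        dmr.overlaps = overlaps
    return dmrs


# ---------------------------------------------------------------------------
# Export


def dmrs_to_dataframe(dmrs: Sequence[DMRRecord]) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        row = {k: v for k, v in d.__dict__.items() if k != "overlaps"}
        row["overlaps"] = ";".join(
            f"{kind}:{','.join(ids)}" for kind, ids in d.overlaps.items()
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_dmr_bed(dmrs: Sequence[DMRRecord], path: str | Path) -> None:
    """BED6+ export: name, -log10 adjusted p as score, direction as strand column."""
    with open(path, "wt") as handle:
        for d in dmrs:
            score = -np.log10(max(d.p_adj, 1e-300))
            strand = "+" if d.direction == "up" else "-" if d.direction == "down" else "."
            overlaps = ";".join(f"{k}:{','.join(v)}" for k, v in d.overlaps.items()) or "."
            handle.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.region_id}\t{score:.3f}\t{strand}\t"
                f"{d.fold_change:.4f}\t{d.n_sites}\t{d.count_a:.3f}\t{d.count_b:.3f}\t"
                f"{overlaps}\n"
            )
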
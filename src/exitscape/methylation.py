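"""CpG methylation quantification from clone panels and pooled-count tables.

Two resolutions of bisulfite data are handled:

* **Clone panels** — per-molecule calls (one sequenced clone per row) over a
  fixed set of CpG positions, as drawn in lollipop diagrams of a promoter
  region.  Methylation of a region is the fraction of methylated calls over
  all clones at the region's positions, missing calls excluded.
* **CpG tables** — pooled methylated/total read counts per CpG dyad, as in
  bedGraph-style whole-genome bisulfite summaries.  Windows (promoters, or
  genome-wide tiles) are quantified by pooling counts over their CpGs.

Coordinates are 0-based half-open internally; clone-panel display positions
are 1-based on input and converted by the readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowAverage",
    "region_percent",
    "window_percent",
    "promoter_intervals",
    "promoter_average",
    "genome_average",
]

#: Clone-panel call encoding: 1.0 methylated, 0.0 unmethylated, NaN missing.
CALL_CODES = {"M": 1.0, "U": 0.0, ".": np.nan, "·": np.nan}


@dataclass(frozen=True)
class WindowAverage:
    """Unweighted mean of per-window methylation percentages."""

    percent: float  # NaN when no window was covered
    n_windows: int  # windows contributing (covered) to the mean


def _check_cpg_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos", "meth_count", "total_count"}
    if missing := required - set(table.columns):
        raise ValueError(f"CpG table missing columns: {sorted(missing)}")
    meth = table["meth_count"].to_numpy(dtype=float)
    total = table["total_count"].to_numpy(dtype=float)
    if (meth < 0).any() or (total < meth).any():
        raise ValueError("need total_count >= meth_count >= 0")
    if table.duplicated(subset=["chrom", "pos"]).any():
        # both strands of a dyad reported separately: collapse by summing
        table = (
            table.groupby(["chrom", "pos"], as_index=False)[
                ["meth_count", "total_count"]
            ].sum()
        )
    return table


def region_percent(panel: pd.DataFrame, region) -> float:
    """Percent methylation of a clone panel over a set of CpG positions.

    ``panel`` is a clone x position matrix (values 1 methylated, 0
    unmethylated, NaN missing); ``region`` the positions to score, which
    must all be columns of the panel.  Pools calls over all clones:
    100 * methylated / (methylated + unmethylated).  Returns NaN when no
    call is scorable.
    """
    region = list(region)
    missing = [p for p in region if p not in panel.columns]
    if missing:
        raise ValueError(f"region positions absent from panel: {missing[:5]}")
    calls = panel[region].to_numpy(dtype=float)
    n_scored = np.count_nonzero(~np.isnan(calls))
    if n_scored == 0:
        return float("nan")
    return 100.0 * np.nansum(calls) / n_scored


def window_percent(
    table: pd.DataFrame,
    window: tuple[str, int, int],
    min_coverage: int = 1,
    per_site: bool = False,
) -> float:
    """Percent methylation of CpGs inside a half-open genomic window.

    ``window`` is ``(chrom, start, end)``, 0-based half-open.  CpGs with
    ``total_count < min_coverage`` are ignored.  By default counts are
    pooled (coverage-weighted): 100 * sum(meth) / sum(total); with
    ``per_site`` the unweighted mean of per-CpG percentages is used
    instead.  Returns NaN when the window contains no eligible CpG.
    """
    chrom, start, end = window
    if not (isinstance(start, (int, np.integer)) and isinstance(end, (int, np.integer))):
        raise ValueError("window bounds must be integers")
    if start < 0 or start >= end:
        raise ValueError(f"malformed window [{start}, {end})")
    table = _check_cpg_table(table)
    sub = table[
        (table["chrom"] == chrom)
        & (table["pos"] >= start)
        & (table["pos"] < end)
        & (table["total_count"] >= min_coverage)
    ]
    if sub.empty:
        return float("nan")
    meth = sub["meth_count"].to_numpy(dtype=float)
    total = sub["total_count"].to_numpy(dtype=float)
    if per_site:
        return float(np.mean(100.0 * meth / total))
    return float(100.0 * meth.sum() / total.sum())


def promoter_intervals(
    genes: pd.DataFrame, upstream: int = 2000, chrom_sizes: dict | None = None
) -> pd.DataFrame:
    """Strand-aware upstream promoter windows for a set of genes.

    ``genes`` has columns ``gene_id``, ``chrom``, ``tss`` (0-based),
    ``strand``.  A + strand gene's promoter is ``[tss - upstream, tss)``;
    a - strand gene's is ``[tss, tss + upstream)``.  Windows are clipped to
    ``[0, chromosome length)`` when ``chrom_sizes`` is given; genes on
    chromosomes missing from ``chrom_sizes`` are rejected by id.
    """
    if upstream <= 0:
        raise ValueError("upstream must be > 0")
    required = {"gene_id", "chrom", "tss", "strand"}
    if missing := required - set(genes.columns):
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")

    rows = []
    for rec in genes.itertuples(index=False):
        if chrom_sizes is not None and rec.chrom not in chrom_sizes:
            raise ValueError(f"gene {rec.gene_id} on unknown chromosome {rec.chrom}")
        tss = int(rec.tss)
        if rec.strand == "+":
            start, end = tss - upstream, tss
        else:
            start, end = tss, tss + upstream
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, int(chrom_sizes[rec.chrom]))
        if start < end:
            rows.append((rec.chrom, start, end, rec.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def promoter_average(
    table: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 2000,
    min_coverage: int = 1,
    chrom_sizes: dict | None = None,
    per_site: bool = False,
) -> WindowAverage:
    """Mean methylation over all gene promoters.

    Quantifies each promoter window with :func:`window_percent` and takes
    the unweighted mean of the defined values; promoters with no covered
    CpG are excluded and the count of contributors reported.
    """
    promoters = promoter_intervals(genes, upstream, chrom_sizes)
    values = [
        window_percent(table, (r.chrom, int(r.start), int(r.end)), min_coverage, per_site)
        for r in promoters.itertuples(index=False)
    ]
    defined = [v for v in values if not np.isnan(v)]
    if not defined:
        return WindowAverage(float("nan"), 0)
    return WindowAverage(float(np.mean(defined)), len(defined))


def genome_average(
    table: pd.DataFrame,
    chrom_sizes: dict,
    tile: int = 50_000,
    min_coverage: int = 1,
    per_site: bool = False,
) -> WindowAverage:
    """Mean methylation over non-overlapping genome tiles.

    Each chromosome is partitioned into half-open tiles of ``tile`` bp
    anchored at position 0 (last tile truncated at the chromosome end);
    the unweighted mean of the defined per-tile percentages is returned.
    """
    if tile <= 0:
        raise ValueError("tile must be > 0")
    table = _check_cpg_table(table)
    if table.empty:
        return WindowAverage(float("nan"), 0)
    values = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, int(length), tile):
            v = window_percent(
                table, (chrom, start, min(start + tile, int(length))),
                min_coverage, per_site,
            )
            if not np.isnan(v):
                values.append(v)
    if not values:
        return WindowAverage(float("nan"), 0)
    return WindowAverage(float(np.mean(values)), len(values))
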
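"""Interval arithmetic for transcript and repeat annotations.

Computes the transposable-element (TE) composition of a transcript: the
fraction of its exonic bases covered by annotated repeat intervals, with an
optional per-class breakdown (RepeatMasker-style classes such as
``LINE/L1``, ``ERVK``, ``SINE/B2``).  Coordinates are 0-based half-open
(BED convention) throughout; overlap is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TeComposition", "merge_intervals", "te_fraction"]


@dataclass(frozen=True)
class TeComposition:
    """TE-derived share of a transcript's exonic bases."""

    fraction: float  # covered exonic bases / total exonic bases, in [0, 1]
    exon_bases: int
    covered_bases: int
    by_class: dict = field(default_factory=dict)  # class -> exonic bases
    multi_class_bases: int = 0  # bases attributed to >1 class (counted once)


def _check_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    if missing := required - set(intervals.columns):
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    start = intervals["start"].to_numpy(dtype=np.int64)
    end = intervals["end"].to_numpy(dtype=np.int64)
    if (start < 0).any():
        raise ValueError("negative interval start")
    if (start >= end).any():
        bad = intervals[start >= end].head()
        raise ValueError(f"start >= end in records:\n{bad}")
    return intervals


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Minimal disjoint interval set covering the same bases.

    Overlapping and abutting intervals on the same chromosome are merged;
    output is sorted by (chrom, start).  Name/strand columns are dropped
    (a merged interval has no single source record).
    """
    intervals = _check_intervals(intervals)
    if intervals.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, grp in intervals.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        cur_start = cur_end = None
        for s, e in zip(grp["start"].astype(int), grp["end"].astype(int)):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:  # overlap or abut
                cur_end = max(cur_end, e)
            else:
                rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
        rows.append((chrom, cur_start, cur_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total bases shared by two *merged* interval sets."""
    total = 0
    for chrom, ga in a.groupby("chrom"):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        sa = ga["start"].to_numpy(np.int64)
        ea = ga["end"].to_numpy(np.int64)
        sb = gb["start"].to_numpy(np.int64)
        eb = gb["end"].to_numpy(np.int64)
        # pairwise clipped overlap; merged inputs keep this quadratic form small
        ov = np.maximum(
            0,
            np.minimum(ea[:, None], eb[None, :]) - np.maximum(sa[:, None], sb[None, :]),
        )
        total += int(ov.sum())
    return total


def te_fraction(exons: pd.DataFrame, repeats: pd.DataFrame) -> TeComposition:
    """Fraction of exonic bases covered by repeat annotation.

    Exons and repeats are merged independently before coverage so that
    overlapping records are not double-counted; the total fraction counts
    each exonic base once no matter how many repeat classes cover it.
    When the repeat table carries a ``name`` column, a per-class breakdown
    is also computed (class = name prefix before the first ``/`` plus the
    full name, RepeatMasker-style: class of ``LINE/L1`` is ``LINE``), with
    bases covered by more than one class counted once in the total and
    reported via ``multi_class_bases``.
    """
    exons = _check_intervals(exons)
    if exons.empty:
        raise ValueError("empty exon set: TE fraction undefined")
    merged_exons = merge_intervals(exons)
    exon_bases = int((merged_exons["end"] - merged_exons["start"]).sum())

    if repeats.empty:
        return TeComposition(0.0, exon_bases, 0)
    repeats = _check_intervals(repeats)
    merged_repeats = merge_intervals(repeats)
    covered = _overlap_bases(merged_exons, merged_repeats)

    by_class: dict[str, int] = {}
    multi = 0
    if "name" in repeats.columns:
        classes = repeats["name"].astype(str).str.split("/").str[0]
        per_class_bases = 0
        for cls in sorted(classes.unique()):
            cls_cov = _overlap_bases(
                merged_exons, merge_intervals(repeats[classes == cls])
            )
            by_class[cls] = cls_cov
            per_class_bases += cls_cov
        multi = per_class_bases - covered  # bases claimed by >1 class
    return TeComposition(
        fraction=covered / exon_bases,
        exon_bases=exon_bases,
        covered_bases=covered,
        by_class=by_class,
        multi_class_bases=multi,
    )
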
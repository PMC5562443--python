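"""Candidate ranking and transient-induction calling over exit time courses.

Candidate transcripts are followed across a withdrawal time course (hours
after removal of self-renewal factors).  Three questions are answered:
which candidates are most highly expressed overall; how does expression
differ between reporter-sorted "high" (still naive) and "low" (exited)
fractions at a given time; and does a profile show the transient shape —
induced early, declining later — that marks a transition-phase transcript.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransientCall",
    "rank_by_expression",
    "fraction_differential",
    "detect_transient",
]


@dataclass(frozen=True)
class TransientCall:
    """Outcome of the transient-induction rule for one profile."""

    is_transient: bool
    peak_time: float  # hours; NaN when not transient or unevaluable
    status: str  # "ok" or "unevaluable"


def _check_course_frame(courses: pd.DataFrame) -> np.ndarray:
    """Validate a wide candidate x timepoint matrix; return the hour grid."""
    try:
        hours = np.asarray([float(c) for c in courses.columns])
    except (TypeError, ValueError) as exc:
        raise ValueError("columns must be numeric hours") from exc
    if hours.size and not (np.diff(hours) > 0).all():
        raise ValueError("timepoints must be strictly increasing")
    values = courses.to_numpy(dtype=float)
    if (values < 0).any() or not np.isfinite(values).all():
        raise ValueError("expression values must be finite and non-negative")
    if courses.index.duplicated().any():
        raise ValueError("duplicate candidate ids")
    return hours


def rank_by_expression(
    courses: pd.DataFrame, statistic: str = "mean"
) -> pd.DataFrame:
    """Rank candidates by expression across the whole time course.

    ``courses`` is a wide table: index = candidate id, one column per
    timepoint (header = hours), shared grid for all candidates.  Rank 1 is
    the highest.  ``statistic`` is ``"mean"`` (default: highest mean over
    the grid) or ``"min_rank"`` (best per-timepoint rank achieved).  Ties
    are broken by candidate id lexicographically and logged.

    Returns a frame indexed by candidate id with ``mean_expr`` and ``rank``.
    """
    _check_course_frame(courses)
    if courses.shape[1] == 0 or courses.shape[0] == 0:
        raise ValueError("empty time-course table")
    mean_expr = courses.mean(axis=1)
    if statistic == "mean":
        key = -mean_expr
    elif statistic == "min_rank":
        # best (smallest) rank the candidate attains at any single timepoint
        per_tp = courses.rank(axis=0, ascending=False, method="min")
        key = per_tp.min(axis=1)
    else:
        raise ValueError("statistic must be 'mean' or 'min_rank'")

    if key.duplicated().any():
        tied = sorted(key.index[key.duplicated(keep=False)])
        warnings.warn(
            f"ties broken lexicographically among candidates {tied}",
            stacklevel=2,
        )
    order = sorted(courses.index, key=lambda cid: (key[cid], str(cid)))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    out = pd.DataFrame({"mean_expr": mean_expr, "rank": ranks.reindex(courses.index)})
    out.index.name = "candidate_id"
    return out


def fraction_differential(high: float, low: float, pseudocount: float = 1.0) -> float:
    """Signed log2 ratio between sorted reporter-high and -low fractions.

    Returns ``log2((high + pc) / (low + pc))``; positive means higher
    expression in the reporter-high (naive) fraction.  Antisymmetric in its
    arguments and zero at equality for every pseudocount > 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if high < 0 or low < 0:
        raise ValueError("expression values must be non-negative")
    return math.log2((high + pseudocount) / (low + pseudocount))


def detect_transient(
    timepoints, values, decline_fraction: float = 0.6
) -> TransientCall:
    """Call a rise-then-fall (transiently induced) expression profile.

    A course is transient iff its maximum sits at an interior timepoint,
    strictly exceeds the first value, and the final value has declined to
    at most ``decline_fraction`` of the peak.  Courses with fewer than
    three timepoints are unevaluable rather than false.
    """
    if not 0 < decline_fraction < 1:
        raise ValueError("decline_fraction must be in (0, 1)")
    t = np.asarray(timepoints, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("timepoints and values must be 1-D and equal length")
    if t.size and not (np.diff(t) > 0).all():
        raise ValueError("timepoints must be strictly increasing")
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    if t.size < 3:
        return TransientCall(False, float("nan"), "unevaluable")

    i_peak = int(np.argmax(v))  # earliest maximum on ties
    peak = v[i_peak]
    is_transient = (
        0 < i_peak < t.size - 1
        and peak > v[0]
        and v[-1] <= decline_fraction * peak
    )
    return TransientCall(
        bool(is_transient), float(t[i_peak]) if is_transient else float("nan"), "ok"
    )
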
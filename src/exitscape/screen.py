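"""In-silico knockdown screen against two-state expression signatures.

The screen takes (i) a comparison of mean expression between two pluripotent
cell states — naive embryonic stem cells (ESC) and primed epiblast-derived
stem cells (EpiSC) — and (ii) a panel of per-knockdown differential tables,
and asks: when a gene is depleted, what fraction of each state's signature
genes moves, and in which direction?

Signature sets are genes strongly enriched (default ten-fold) in one state
over the other.  Each knockdown is scored on two signed axes, one per
signature set: +100 means every evaluable signature gene was significantly
up-regulated, -100 that every one was down-regulated.  The two axes span a
plane whose quadrants correspond to regulator archetypes: a self-renewal
factor (Stat3/Esrrb/Sox2/Klf4-like) loses ESC signature and gains EpiSC
signature when knocked down; an exit facilitator shows the opposite pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateSignatures",
    "ScreenScore",
    "ConcordanceReport",
    "IntersectResult",
    "QUADRANTS",
    "derive_signatures",
    "bh_adjust",
    "score_perturbation",
    "classify_quadrant",
    "validate_known_regulators",
    "intersect_de",
]

#: Quadrant labels on the (ESC axis, EpiSC axis) plane.
QUADRANTS = (
    "maintenance_like",
    "dual_requirement",
    "exit_facilitator_candidate",
    "epi_restraining",
    "null",
)


@dataclass(frozen=True)
class StateSignatures:
    """Disjoint state-enriched gene sets derived from a two-state comparison.

    ``set_a`` holds genes enriched in state A (ESC), ``set_b`` genes enriched
    in state B (EpiSC).  Disjointness is guaranteed by construction: a gene
    cannot exceed a >1 fold threshold in both directions.
    """

    set_a: frozenset
    set_b: frozenset
    fold_threshold: float

    def __post_init__(self) -> None:
        if self.set_a & self.set_b:
            raise ValueError("signature sets must be disjoint")


@dataclass(frozen=True)
class ScreenScore:
    """Signed two-axis effect of one perturbation.

    Axes are net percentages in [-100, +100]: 100 * (n_up - n_down) /
    n_evaluable within each signature set.  An axis is NaN when no signature
    gene of that set was present in the profile.
    """

    perturbation_id: str
    esc_axis: float
    epi_axis: float
    n_eval_a: int
    n_eval_b: int
    quadrant: str = "null"

    def __post_init__(self) -> None:
        for ax in (self.esc_axis, self.epi_axis):
            if not np.isnan(ax) and abs(ax) > 100:
                raise ValueError("axis out of [-100, 100]")
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")


@dataclass
class ConcordanceReport:
    """Agreement between observed quadrants and archetype expectations."""

    fraction: float  # NaN if nothing was evaluable
    n_evaluated: int
    mismatches: list = field(default_factory=list)  # (id, observed, expected)
    unevaluable: list = field(default_factory=list)


@dataclass
class IntersectResult:
    """Genes passing the differential-expression filter in every condition."""

    genes: frozenset
    directions: pd.DataFrame  # index gene_id, one direction column per table
    dropped: frozenset  # passed in >=1 condition but not retained


def _check_comparison(comparison: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "mean_a", "mean_b"}
    missing = required - set(comparison.columns)
    if missing:
        raise ValueError(f"comparison table missing columns: {sorted(missing)}")
    if comparison["gene_id"].duplicated().any():
        dups = comparison.loc[comparison["gene_id"].duplicated(), "gene_id"]
        raise ValueError(f"duplicate gene ids: {sorted(set(dups))[:5]}")
    means = comparison[["mean_a", "mean_b"]].to_numpy(dtype=float)
    if not np.isfinite(means).all() or (means < 0).any():
        raise ValueError("state means must be finite and non-negative")
    return comparison


def derive_signatures(
    comparison: pd.DataFrame,
    fold_threshold: float = 10.0,
    pseudocount: float = 0.0,
) -> StateSignatures:
    """Derive state-enriched signature sets from a two-state comparison.

    Parameters
    ----------
    comparison
        Table with columns ``gene_id``, ``mean_a``, ``mean_b`` (linear
        expression units, one row per gene).
    fold_threshold
        Enrichment ratio a gene must exceed (strictly) to enter a set;
        must be > 1.  Default 10, the classical ten-fold signature rule.
    pseudocount
        Added to both means before forming the ratio; with the default 0,
        genes at 0/0 are excluded and any x/0 gene (x > 0) is enriched.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    comparison = _check_comparison(comparison)

    a = comparison["mean_a"].to_numpy(dtype=float) + pseudocount
    b = comparison["mean_b"].to_numpy(dtype=float) + pseudocount
    genes = comparison["gene_id"].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        # x/0 -> inf (enriched), 0/0 -> nan (excluded)
        ratio_ab = np.where((a == 0) & (b == 0), np.nan, a / b)
    in_a = ratio_ab > fold_threshold
    in_b = (1.0 / ratio_ab) > fold_threshold
    return StateSignatures(
        set_a=frozenset(genes[in_a]),
        set_b=frozenset(genes[in_b]),
        fold_threshold=float(fold_threshold),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Returns adjusted values in the input order: ``q_i = min_{j: p_j >= p_i}
    (p_j * m / rank_j)`` capped at 1.  Each adjusted value is >= its raw
    value, and the sorted outputs are non-decreasing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _check_profile(profile: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Validate a per-knockdown table and say which significance column it carries."""
    if "gene_id" not in profile.columns or "fold_change" not in profile.columns:
        raise ValueError("profile needs gene_id and fold_change columns")
    has_p = "p_value" in profile.columns
    has_q = "q_value" in profile.columns
    if has_p == has_q:
        raise ValueError("profile must carry exactly one of p_value or q_value")
    if profile["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in profile")
    fc = profile["fold_change"].to_numpy(dtype=float)
    if (fc <= 0).any() or not np.isfinite(fc).all():
        raise ValueError("fold changes must be positive and finite")
    col = "p_value" if has_p else "q_value"
    sig = profile[col].to_numpy(dtype=float)
    if ((sig < 0) | (sig > 1)).any() or np.isnan(sig).any():
        raise ValueError(f"{col} must lie in [0, 1]")
    return profile, col


def _axis(
    sub: pd.DataFrame, fdr_cut: float, fc_up: float, fc_down: float
) -> tuple[float, int]:
    n_eval = len(sub)
    if n_eval == 0:
        return float("nan"), 0
    sig = sub["q"].to_numpy() < fdr_cut
    up = int((sig & (sub["fold_change"].to_numpy() > fc_up)).sum())
    down = int((sig & (sub["fold_change"].to_numpy() < fc_down)).sum())
    return 100.0 * (up - down) / n_eval, n_eval


def score_perturbation(
    profile: pd.DataFrame,
    signatures: StateSignatures,
    fdr_cut: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    perturbation_id: str | None = None,
    dead_zone: float = 0.0,
) -> ScreenScore:
    """Score one knockdown's signed effect on both signature sets.

    A signature gene counts "up" when its FDR-adjusted significance is below
    ``fdr_cut`` AND its fold change exceeds ``fc_up``; "down" with fold
    change below ``fc_down``.  Both criteria are conjunctive: a gene
    significant by FDR whose fold change sits inside (fc_down, fc_up)
    counts as unchanged.  Profiles carrying raw p-values are BH-adjusted
    over the whole profile first; profiles carrying precomputed q-values
    are taken as-is.  Signature genes absent from the profile are excluded
    from the denominator (reported via ``n_eval_a`` / ``n_eval_b``).
    """
    if not (fc_up > 1 > fc_down > 0):
        raise ValueError("need fc_up > 1 > fc_down > 0")
    profile, col = _check_profile(profile)
    if perturbation_id is None:
        perturbation_id = str(profile.attrs.get("perturbation_id", "perturbation"))

    work = profile[["gene_id", "fold_change"]].copy()
    work["q"] = (
        bh_adjust(profile["p_value"].to_numpy())
        if col == "p_value"
        else profile["q_value"].to_numpy(dtype=float)
    )

    esc_axis, n_a = _axis(
        work[work["gene_id"].isin(signatures.set_a)], fdr_cut, fc_up, fc_down
    )
    epi_axis, n_b = _axis(
        work[work["gene_id"].isin(signatures.set_b)], fdr_cut, fc_up, fc_down
    )
    score = ScreenScore(perturbation_id, esc_axis, epi_axis, n_a, n_b)
    return ScreenScore(
        perturbation_id, esc_axis, epi_axis, n_a, n_b,
        quadrant=classify_quadrant(score, dead_zone=dead_zone),
    )


def classify_quadrant(score: ScreenScore, dead_zone: float = 0.0) -> str:
    """Assign a quadrant label from the signed (ESC, EpiSC) axes.

    With ``dead_zone`` d >= 0, an axis within [-d, +d] (or undefined) makes
    the call "null".  Otherwise: ESC down / EpiSC up is the self-renewal
    maintenance pattern; both down is the dual-requirement (Oct4) pattern;
    ESC up / EpiSC down marks an exit-facilitator candidate (the screen's
    target, bottom-right of the plane); both up is epi-restraining.
    """
    if dead_zone < 0:
        raise ValueError("dead_zone must be >= 0")
    esc, epi = score.esc_axis, score.epi_axis
    if np.isnan(esc) or np.isnan(epi) or abs(esc) <= dead_zone or abs(epi) <= dead_zone:
        return "null"
    if esc < 0:
        return "maintenance_like" if epi > 0 else "dual_requirement"
    return "epi_restraining" if epi > 0 else "exit_facilitator_candidate"


def validate_known_regulators(
    scores, expectations: dict[str, str]
) -> ConcordanceReport:
    """Check observed quadrants of known regulators against archetypes.

    ``scores`` is an iterable of :class:`ScreenScore`; ``expectations`` maps
    perturbation id to the expected quadrant label.  Expected perturbations
    missing from ``scores`` are reported as unevaluable (with a warning)
    and excluded from the denominator.
    """
    by_id = {s.perturbation_id: s for s in scores}
    mismatches, unevaluable = [], []
    n_match = n_eval = 0
    for pid, expected in expectations.items():
        if expected not in QUADRANTS:
            raise ValueError(f"unknown expected quadrant {expected!r}")
        score = by_id.get(pid)
        if score is None:
            unevaluable.append(pid)
            continue
        n_eval += 1
        if score.quadrant == expected:
            n_match += 1
        else:
            mismatches.append((pid, score.quadrant, expected))
    if unevaluable:
        warnings.warn(
            f"{len(unevaluable)} expected perturbation(s) missing from scores: "
            f"{unevaluable}", stacklevel=2,
        )
    fraction = n_match / n_eval if n_eval else float("nan")
    return ConcordanceReport(fraction, n_eval, mismatches, unevaluable)


def intersect_de(
    tables: list[pd.DataFrame],
    p_cut: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.7,
    require_concordant: bool = True,
) -> IntersectResult:
    """Genes differentially expressed in every condition.

    Each table has columns ``gene_id``, ``fold_change``, ``adj_p``.  A gene
    is retained iff it passes ``adj_p < p_cut AND (fc > fc_up OR fc <
    fc_down)`` in every table; with ``require_concordant`` the direction
    (up/down) must also agree across tables.  A gene absent from any table
    is never retained.  The defaults are the cross-condition filter used to
    call genes changed both in self-renewal medium and shortly after its
    withdrawal.
    """
    if len(tables) < 2:
        raise ValueError("need at least two condition tables")
    if not (fc_up > 1 > fc_down > 0):
        raise ValueError("need fc_up > 1 > fc_down > 0")

    per_table = []
    for i, tab in enumerate(tables):
        required = {"gene_id", "fold_change", "adj_p"}
        if missing := required - set(tab.columns):
            raise ValueError(f"table {i} missing columns: {sorted(missing)}")
        if tab["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in table {i}")
        fc = tab["fold_change"].to_numpy(dtype=float)
        adj = tab["adj_p"].to_numpy(dtype=float)
        if (fc <= 0).any():
            raise ValueError(f"non-positive fold change in table {i}")
        if ((adj < 0) | (adj > 1)).any():
            raise ValueError(f"adj_p outside [0, 1] in table {i}")
        passing = (adj < p_cut) & ((fc > fc_up) | (fc < fc_down))
        direction = pd.Series(
            np.where(fc > fc_up, "up", "down"), index=tab["gene_id"]
        )[passing]
        per_table.append(direction)

    common = set(per_table[0].index)
    for d in per_table[1:]:
        common &= set(d.index)
    if require_concordant:
        common = {
            g for g in common if len({d[g] for d in per_table}) == 1
        }
    all_passing = set().union(*(set(d.index) for d in per_table))
    directions = pd.DataFrame(
        {f"condition_{i + 1}": d.reindex(sorted(common)) for i, d in enumerate(per_table)}
    )
    directions.index.name = "gene_id"
    return IntersectResult(
        genes=frozenset(common),
        directions=directions,
        dropped=frozenset(all_passing - common),
    )
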
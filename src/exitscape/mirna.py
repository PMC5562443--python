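"""Canonical miRNA seed-site scanning, escape analysis and reporter assays.

Seed matching follows the canonical site hierarchy: a site is a stretch of
the 3'UTR complementary to the miRNA seed (positions 2-7, numbered from the
5' end).  Extending the match to position 8 (``m8``) and/or an adenosine in
the target opposite miRNA position 1 (``A1`` — required to be A regardless
of the miRNA's first base) upgrades the site:

========  ==================================
8mer      m8 match and A1 adenosine
7mer-m8   m8 match only
7mer-A1   seed match plus A1 adenosine
6mer      seed match only
========  ==================================

This scanner is a deliberately simple canonical-seed matcher; it makes no
attempt at pattern/energy-based target prediction, so its site lists are
not comparable with heuristic predictors.  The module also checks pre-miRNA
terminal loops for the GGAG motif through which Lin28a recognises let-7
precursors (family members lacking it escape Lin28a control), and computes
fold repression from dual-luciferase reporter measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeedSite",
    "EscapeResult",
    "SITE_TYPES",
    "scan_seed_sites",
    "check_escape",
    "loop_motif",
    "fold_repression",
]

#: Site types, strongest first.
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed match in a UTR (0-based half-open coordinates)."""

    utr_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[
            self.site_type
        ]:
            raise ValueError("site span inconsistent with its type")


@dataclass
class EscapeResult:
    """Seed sites lost, retained and gained by a mutant UTR."""

    lost: list = field(default_factory=list)
    retained: list = field(default_factory=list)
    gained: list = field(default_factory=list)
    escape: bool = False  # True iff the wild UTR had sites and all were lost


def _to_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return seq


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def scan_seed_sites(utr: str, mirna: str, utr_id: str = "utr") -> list[SeedSite]:
    """All canonical seed sites of a miRNA in a sense-strand UTR.

    ``mirna`` is the mature sequence 5'->3' (>= 8 nt); DNA input (T) is
    accepted for both sequences and treated as RNA.  One site is reported
    per seed-match locus, typed by the strongest rule it satisfies
    (8mer > 7mer-m8 > 7mer-A1 > 6mer); coordinates cover the matched bases
    including the m8/A1 positions where present.
    """
    utr = _to_rna(utr, "UTR")
    mirna = _to_rna(mirna, "miRNA")
    if len(mirna) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")

    core = _revcomp(mirna[1:7])  # complement of seed positions 2-7
    m8_base = _RC[mirna[7]]  # target base pairing miRNA position 8
    sites = []
    i = utr.find(core)
    while i != -1:
        has_m8 = i > 0 and utr[i - 1] == m8_base
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(utr_id, i - 1, i + 7, "8mer")
        elif has_m8:
            site = SeedSite(utr_id, i - 1, i + 6, "7mer-m8")
        elif has_a1:
            site = SeedSite(utr_id, i, i + 7, "7mer-A1")
        else:
            site = SeedSite(utr_id, i, i + 6, "6mer")
        sites.append(site)
        i = utr.find(core, i + 1)

    for site in sites:  # self-check: every site re-validates by complementarity
        _validate_site(utr, mirna, site)
    return sites


def _validate_site(utr: str, mirna: str, site: SeedSite) -> None:
    seq = utr[site.start : site.end]
    if site.site_type == "8mer":
        ok = seq == _revcomp(mirna[1:8]) + "A"
    elif site.site_type == "7mer-m8":
        ok = seq == _revcomp(mirna[1:8])
    elif site.site_type == "7mer-A1":
        ok = seq == _revcomp(mirna[1:7]) + "A"
    else:
        ok = seq == _revcomp(mirna[1:7])
    if not ok:
        raise AssertionError(f"site failed re-validation: {site}")


def check_escape(wild_utr: str, mutant_utr: str, mirna: str) -> EscapeResult:
    """Compare seed sites between a wild-type UTR and a mutated reporter.

    Sites are aligned by position (reporter mutations are substitutions, so
    coordinates are shared).  A mutant that has lost every wild-type site
    is flagged ``escape`` — the behaviour of a reporter whose seed
    recognition site was disrupted.
    """
    wild = scan_seed_sites(wild_utr, mirna, "wild")
    mutant = scan_seed_sites(mutant_utr, mirna, "mutant")
    mut_by_pos = {(s.start, s.end, s.site_type) for s in mutant}
    wild_by_pos = {(s.start, s.end, s.site_type) for s in wild}
    lost = [s for s in wild if (s.start, s.end, s.site_type) not in mut_by_pos]
    retained = [s for s in wild if (s.start, s.end, s.site_type) in mut_by_pos]
    gained = [s for s in mutant if (s.start, s.end, s.site_type) not in wild_by_pos]
    return EscapeResult(
        lost=lost,
        retained=retained,
        gained=gained,
        escape=bool(wild) and not retained,
    )


def loop_motif(
    pre_mirna: str, loop_start: int, loop_end: int, motif: str = "GGAG"
) -> list[int]:
    """Occurrences of a recognition motif inside a pre-miRNA terminal loop.

    Returns 0-based start positions (in pre-miRNA coordinates) of every
    occurrence lying entirely within ``[loop_start, loop_end)``; matches
    straddling the loop boundary are not reported.  An empty list for the
    GGAG motif marks a precursor that escapes Lin28a regulation.
    """
    seq = _to_rna(pre_mirna, "pre-miRNA")
    motif = _to_rna(motif, "motif")
    if not 0 <= loop_start < loop_end <= len(seq):
        raise ValueError(
            f"loop [{loop_start}, {loop_end}) out of range for length {len(seq)}"
        )
    loop = seq[loop_start:loop_end]
    hits = []
    i = loop.find(motif)
    while i != -1:
        hits.append(loop_start + i)
        i = loop.find(motif, i + 1)
    return hits


def fold_repression(
    measurements: pd.DataFrame, aggregate: str = "mean"
) -> pd.DataFrame:
    """Per-construct fold repression from dual-luciferase measurements.

    ``measurements`` has columns ``construct_id``, ``condition`` (``mimic``
    or ``scramble``), ``firefly``, ``renilla`` and ``replicate``.  Each
    replicate's firefly reading is normalised by its Renilla co-transfection
    control; fold repression is the scramble-to-mimic ratio of the
    aggregated normalised activities (``aggregate`` = arithmetic ``"mean"``
    or ``"geometric"`` mean of replicate ratios).  Values above 1 indicate
    repression by the mimic.  Constructs missing a condition are reported
    with NaN fold repression and status ``unevaluable``.

    Returns a frame indexed by construct with ``fold_repression``,
    per-condition replicate counts and coefficients of variation.
    """
    required = {"construct_id", "condition", "firefly", "renilla"}
    if missing := required - set(measurements.columns):
        raise ValueError(f"luciferase table missing columns: {sorted(missing)}")
    if not measurements["condition"].isin(["mimic", "scramble"]).all():
        raise ValueError("condition must be 'mimic' or 'scramble'")
    readings = measurements[["firefly", "renilla"]].to_numpy(dtype=float)
    if (readings <= 0).any():
        raise ValueError("luminescence readings must be positive")
    if aggregate not in ("mean", "geometric"):
        raise ValueError("aggregate must be 'mean' or 'geometric'")

    work = measurements.copy()
    work["ratio"] = work["firefly"] / work["renilla"]
    rows = []
    for construct, grp in work.groupby("construct_id", sort=True):
        stats = {}
        for cond in ("scramble", "mimic"):
            ratios = grp.loc[grp["condition"] == cond, "ratio"].to_numpy()
            if ratios.size:
                center = (
                    float(np.mean(ratios))
                    if aggregate == "mean"
                    else float(np.exp(np.mean(np.log(ratios))))
                )
                cv = float(np.std(ratios) / np.mean(ratios)) if ratios.size > 1 else 0.0
            else:
                center, cv = float("nan"), float("nan")
            stats[cond] = (center, cv, ratios.size)
        evaluable = stats["scramble"][2] > 0 and stats["mimic"][2] > 0
        rows.append(
            {
                "construct_id": construct,
                "fold_repression": stats["scramble"][0] / stats["mimic"][0]
                if evaluable
                else float("nan"),
                "n_scramble": stats["scramble"][2],
                "n_mimic": stats["mimic"][2],
                "cv_scramble": stats["scramble"][1],
                "cv_mimic": stats["mimic"][1],
                "status": "ok" if evaluable else "unevaluable",
            }
        )
    return pd.DataFrame(rows).set_index("construct_id")
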
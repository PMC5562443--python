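"""Independent brute-force oracles used to cross-check the library.

Every function here is written as a direct, loop-based restatement of the
definition it checks, deliberately sharing no code with the package
implementation.
"""

from __future__ import annotations

import numpy as np


def score_axes_bruteforce(profile_rows, set_a, set_b, fdr_cut, fc_up, fc_down):
    """Gene-by-gene screen scoring.

    ``profile_rows`` is a list of (gene_id, fold_change, q_value) with
    q already adjusted.  Returns (esc_axis, epi_axis, n_a, n_b) with NaN
    axes for empty evaluable sets.
    """
    out = []
    for sig in (set_a, set_b):
        n_eval = up = down = 0
        for gene, fc, q in profile_rows:
            if gene not in sig:
                continue
            n_eval += 1
            if q < fdr_cut and fc > fc_up:
                up += 1
            elif q < fdr_cut and fc < fc_down:
                down += 1
        axis = float("nan") if n_eval == 0 else 100.0 * (up - down) / n_eval
        out.append((axis, n_eval))
    (esc, n_a), (epi, n_b) = out
    return esc, epi, n_a, n_b


def bh_bruteforce(p_values):
    """Step-up BH by the textbook definition: q_i = min_{j: p_j >= p_i} p_j*m/rank_j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running_min = min(running_min, p[i] * m / (rank_pos + 1))
        q[i] = min(running_min, 1.0)
    return q


def intersect_de_bruteforce(tables, p_cut, fc_up, fc_down, require_concordant):
    """Set-logic DE intersection; tables are lists of (gene, fc, adj_p)."""
    per_table = []
    for rows in tables:
        d = {}
        for gene, fc, adj_p in rows:
            if adj_p < p_cut and (fc > fc_up or fc < fc_down):
                d[gene] = "up" if fc > fc_up else "down"
        per_table.append(d)
    genes = set(per_table[0])
    for d in per_table[1:]:
        genes &= set(d)
    if require_concordant:
        genes = {g for g in genes if len({d[g] for d in per_table}) == 1}
    return genes


def window_percent_bruteforce(records, chrom, start, end, min_coverage):
    """Pooled window methylation by per-CpG scan.

    ``records`` is a list of (chrom, pos, meth, total); duplicated
    (chrom, pos) entries are summed (strand-collapsed) first.
    """
    pooled = {}
    for c, pos, meth, total in records:
        key = (c, pos)
        m0, t0 = pooled.get(key, (0, 0))
        pooled[key] = (m0 + meth, t0 + total)
    meth_sum = total_sum = 0
    for (c, pos), (meth, total) in pooled.items():
        if c == chrom and start <= pos < end and total >= min_coverage:
            meth_sum += meth
            total_sum += total
    if total_sum == 0:
        return float("nan")
    return 100.0 * meth_sum / total_sum


def te_fraction_bruteforce(exon_records, repeat_records):
    """Per-base boolean scan; records are (chrom, start, end)."""
    chroms = {c for c, _, _ in exon_records} | {c for c, _, _ in repeat_records}
    exon_bases = covered = 0
    for chrom in chroms:
        max_end = max(
            [e for c, _, e in exon_records if c == chrom]
            + [e for c, _, e in repeat_records if c == chrom]
        )
        is_exon = np.zeros(max_end, dtype=bool)
        is_rep = np.zeros(max_end, dtype=bool)
        for c, s, e in exon_records:
            if c == chrom:
                is_exon[s:e] = True
        for c, s, e in repeat_records:
            if c == chrom:
                is_rep[s:e] = True
        exon_bases += int(is_exon.sum())
        covered += int((is_exon & is_rep).sum())
    if exon_bases == 0:
        return float("nan")
    return covered / exon_bases


_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def seed_sites_bruteforce(utr, mirna):
    """Sliding-window canonical seed matcher.

    Checks the four site patterns at every UTR offset by direct string
    comparison against the reverse complement of the relevant miRNA
    positions; returns (start, end, type) tuples, strongest type per
    seed-match locus.
    """
    utr = utr.upper().replace("T", "U")
    mirna = mirna.upper().replace("T", "U")
    rc = lambda s: "".join(_RC[b] for b in reversed(s))
    seed6 = rc(mirna[1:7])  # pairs miRNA 2-7
    seed7 = rc(mirna[1:8])  # pairs miRNA 2-8
    sites = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != seed6:
            continue
        m8 = utr[i - 1 : i + 6] == seed7 if i >= 1 else False
        a1 = utr[i + 6 : i + 7] == "A"
        if m8 and a1:
            sites.append((i - 1, i + 7, "8mer"))
        elif m8:
            sites.append((i - 1, i + 6, "7mer-m8"))
        elif a1:
            sites.append((i, i + 7, "7mer-A1"))
        else:
            sites.append((i, i + 6, "6mer"))
    return sites
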
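"""Seeded generators for every input the analysis pipeline consumes.

Each generator returns machine-readable ground truth alongside its data, so
downstream recovery tests compare analysis output against planted truth
rather than against re-derived quantities.  A single root seed drives all
generators through named substreams: the stream for one generator is
independent of the others, so adding a generator never perturbs existing
outputs.

Defaults describe the study conditions the analyses assume: two cell
states with 182/131 genes ten-fold enriched on either side, knockdown
panels of four regulator archetypes (effect 4x on 60% of a signature set,
six replicates, multiplicative log-normal noise), a transiently induced
candidate peaking 12 h into withdrawal among flat/monotone decoys, clone
panels with ~40% methylation in one promoter region and near-zero in the
next, a genome whose focal transcript is ~76% TE-derived, and UTRs with
planted canonical seed sites for a let-7 family miRNA.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mirna import SeedSite, scan_seed_sites
from .screen import StateSignatures

__all__ = [
    "Archetype",
    "SimulationConfig",
    "TwoStateSim",
    "PanelSim",
    "TimecourseSim",
    "CloneSim",
    "GenomeSim",
    "UtrSim",
    "simulate_two_state",
    "simulate_knockdown_panel",
    "simulate_timecourse",
    "simulate_clone_panel",
    "simulate_genome",
    "simulate_utr",
    "simulate_luciferase",
]

#: Mature let-7g, the family member used as the default planted miRNA.
LET7G = "UGAGGUAGUAGUUUGUACAGUU"


@dataclass(frozen=True)
class Archetype:
    """A planted knockdown effect pattern.

    ``esc_effect`` / ``epi_effect`` give the direction (+1 up, -1 down,
    0 none) in which the archetype shifts genes of the ESC / EpiSC
    signature when knocked down; ``effect_size`` is the multiplicative
    shift applied to a ``hit_fraction`` of each affected set.
    """

    label: str
    esc_effect: int
    epi_effect: int
    effect_size: float = 4.0
    hit_fraction: float = 0.6

    def expected_quadrant(self) -> str:
        if self.esc_effect == 0 and self.epi_effect == 0:
            return "null"
        if self.esc_effect < 0:
            return "maintenance_like" if self.epi_effect > 0 else "dual_requirement"
        return "epi_restraining" if self.epi_effect > 0 else "exit_facilitator_candidate"


DEFAULT_ARCHETYPES = (
    Archetype("maintenance", -1, +1),  # Stat3/Esrrb/Sox2/Klf4-like
    Archetype("dual_requirement", -1, -1),  # Oct4-like
    Archetype("exit_facilitator", +1, -1),  # the screen's target pattern
    Archetype("null", 0, 0, effect_size=1.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Root configuration shared by all generators.

    The same ``seed`` reproduces every output bit-for-bit.  Fields are
    grouped by the generator that consumes them; unrelated generators
    ignore each other's fields.
    """

    seed: int = 0
    # two-state comparison
    n_genes: int = 1000
    n_signature_a: int = 182
    n_signature_b: int = 131
    signature_fold: float = 10.0
    base_expression: float = 100.0
    noise_sd: float = 0.2  # natural-log sd of multiplicative noise
    # knockdown panel
    archetypes: tuple = DEFAULT_ARCHETYPES
    n_replicates: int = 6
    # time course (values emulate replicate-mean RT-qPCR, hence lower noise)
    timepoints: tuple = (0.0, 6.0, 12.0, 24.0, 48.0)
    n_candidates: int = 16
    n_transient: int = 1
    fraction_hour: float = 24.0
    timecourse_noise_sd: float = 0.1
    # clone panel
    n_clones: int = 20
    clone_regions: tuple = (("region1", 10, 0.4), ("region2", 10, 0.05))
    clone_region_start: int = 1001  # 1-based display coordinate of first CpG
    clone_spacing: int = 30
    missing_rate: float = 0.0
    # genome / intervals / CpG table
    chrom_sizes: tuple = (("chr1", 300_000),)
    n_promoter_genes: int = 20
    promoter_upstream: int = 2000
    te_overlap_fraction: float = 0.764
    promoter_meth: float = 0.10
    background_meth: float = 0.70
    cpg_spacing: int = 150
    mean_coverage: float = 10.0
    # UTRs
    mirna: str = LET7G
    utr_length: int = 500
    planted_sites: tuple = (
        ("utr_dnmt3b", (("8mer", 200),)),
        ("utr_dnmt3a", (("7mer-m8", 120), ("7mer-A1", 350))),
        ("utr_empty", ()),
    )
    max_retries: int = 200
    # luciferase
    luciferase_fold: tuple = (("utr_dnmt3b", 2.8), ("utr_dnmt3a", 3.0), ("utr_empty", 1.0))
    luciferase_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.n_signature_a + self.n_signature_b > self.n_genes:
            raise ValueError("more signature genes than genes")
        if self.signature_fold <= 1:
            raise ValueError("signature_fold must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for a in self.archetypes:
            if not 0 < a.hit_fraction <= 1:
                raise ValueError(f"hit_fraction out of (0, 1] for {a.label}")
            if a.effect_size <= 0:
                raise ValueError(f"effect_size must be > 0 for {a.label}")
        for _, _, p in self.clone_regions:
            if not 0 <= p <= 1:
                raise ValueError("methylation probabilities must be in [0, 1]")
        if not 0 <= self.te_overlap_fraction <= 1:
            raise ValueError("te_overlap_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named substream: independent of every other stream under one seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# two-state comparison

@dataclass
class TwoStateSim:
    comparison: pd.DataFrame  # gene_id, mean_a, mean_b
    truth: StateSignatures


def simulate_two_state(config: SimulationConfig) -> TwoStateSim:
    """Two-state expression table with planted signature genes.

    Baseline expression is log-normal around ``base_expression``.  Each
    planted gene's enrichment fold is drawn strictly above
    ``signature_fold`` (fold * exp(Exp(0.5))), so with zero noise the
    derivation at the same threshold recovers the planted sets exactly.
    Observation noise is multiplicative log-normal with sd ``noise_sd``
    applied independently to both state means.
    """
    rng = _rng(config, "two_state")
    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])
    base = config.base_expression * np.exp(rng.normal(0.0, 0.8, size=n))

    idx = rng.permutation(n)
    ia = idx[: config.n_signature_a]
    ib = idx[config.n_signature_a : config.n_signature_a + config.n_signature_b]

    fold = np.ones(n)
    fold[ia] = config.signature_fold * np.exp(rng.exponential(0.5, size=ia.size))
    fold[ib] = config.signature_fold * np.exp(rng.exponential(0.5, size=ib.size))

    mean_a, mean_b = base.copy(), base.copy()
    mean_a[ia] = base[ia] * np.sqrt(fold[ia])
    mean_b[ia] = base[ia] / np.sqrt(fold[ia])
    mean_b[ib] = base[ib] * np.sqrt(fold[ib])
    mean_a[ib] = base[ib] / np.sqrt(fold[ib])

    mean_a = mean_a * np.exp(rng.normal(0.0, config.noise_sd, size=n))
    mean_b = mean_b * np.exp(rng.normal(0.0, config.noise_sd, size=n))

    comparison = pd.DataFrame(
        {"gene_id": genes, "mean_a": mean_a, "mean_b": mean_b}
    ).sort_values("gene_id", ignore_index=True)
    truth = StateSignatures(
        set_a=frozenset(genes[ia]),
        set_b=frozenset(genes[ib]),
        fold_threshold=config.signature_fold,
    )
    return TwoStateSim(comparison, truth)


# ---------------------------------------------------------------------------
# knockdown panel

@dataclass
class PanelSim:
    profiles: dict  # label -> DataFrame(gene_id, fold_change, p_value)
    expected_quadrants: dict  # label -> quadrant
    hit_genes: dict  # label -> frozenset of shifted genes


def simulate_knockdown_panel(
    config: SimulationConfig, signatures: StateSignatures
) -> PanelSim:
    """Per-knockdown differential tables for each planted archetype.

    For each archetype a ``hit_fraction`` of each signature set is shifted
    by ``effect_size`` in the planted direction.  Control and knockdown
    expression are drawn as ``n_replicates`` log-normal replicates; fold
    change is the ratio of replicate means and the p-value a Welch
    two-sample t-test on log expression.  Off-signature genes are never
    shifted, so false hits arise only from replicate noise.
    """
    rng = _rng(config, "knockdown_panel")
    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])
    gene_index = {g: i for i, g in enumerate(genes)}
    base = config.base_expression * np.exp(rng.normal(0.0, 0.8, size=n))
    sd = max(config.noise_sd, 1e-9)  # degenerate-noise guard for the t-test

    set_a = sorted(signatures.set_a & set(genes))
    set_b = sorted(signatures.set_b & set(genes))

    profiles, expected, hits = {}, {}, {}
    for arche in config.archetypes:
        shift = np.zeros(n)
        hit: set[str] = set()
        for members, direction in ((set_a, arche.esc_effect), (set_b, arche.epi_effect)):
            if direction == 0 or not members:
                continue
            k = max(1, round(arche.hit_fraction * len(members)))
            chosen = rng.choice(members, size=k, replace=False)
            hit |= {str(g) for g in chosen}
            rows = [gene_index[g] for g in chosen]
            shift[rows] = direction * np.log(arche.effect_size)

        log_base = np.log(base)
        ctrl = log_base[:, None] + rng.normal(0.0, sd, size=(n, config.n_replicates))
        kd = (
            (log_base + shift)[:, None]
            + rng.normal(0.0, sd, size=(n, config.n_replicates))
        )
        fold = np.exp(kd.mean(axis=1) - ctrl.mean(axis=1))
        p = stats.ttest_ind(kd, ctrl, axis=1, equal_var=False).pvalue
        profiles[arche.label] = pd.DataFrame(
            {"gene_id": genes, "fold_change": fold, "p_value": p}
        )
        profiles[arche.label].attrs["perturbation_id"] = arche.label
        expected[arche.label] = arche.expected_quadrant()
        hits[arche.label] = frozenset(hit)
    return PanelSim(profiles, expected, hits)


# ---------------------------------------------------------------------------
# time course

@dataclass
class TimecourseSim:
    courses: pd.DataFrame  # wide: index candidate_id, columns hours
    transient_ids: frozenset
    fractions: pd.DataFrame  # candidate_id x (high, low) at fraction_hour
    fraction_hour: float


#: Mean shape of a transiently induced candidate over the default grid:
#: low at withdrawal, peak by 12 h, declining well below the peak by 48 h.
_TRANSIENT_SHAPE = (1.0, 4.0, 8.0, 5.0, 2.0)


def simulate_timecourse(config: SimulationConfig) -> TimecourseSim:
    """Expression time courses with planted transient inducers among decoys.

    Decoys are flat, monotonically rising or monotonically falling; the
    planted transients follow a rise-then-fall mean shape.  All profiles
    get multiplicative log-normal noise and a per-candidate log-normal
    scale.  Paired reporter-high/low fraction values at ``fraction_hour``
    are also emitted: transients are enriched in the reporter-high (still
    naive) fraction, decoys are balanced.
    """
    if len(config.timepoints) < 3:
        raise ValueError("need at least 3 timepoints")
    rng = _rng(config, "timecourse")
    t = np.asarray(config.timepoints, dtype=float)
    n_t = t.size
    n = config.n_candidates
    if config.n_transient > n:
        raise ValueError("more transients than candidates")

    ids = np.array([f"cand{i:03d}" for i in range(n)])
    transient_ids = {str(c) for c in rng.choice(ids, size=config.n_transient, replace=False)}

    shape_grid = np.linspace(0, 1, n_t)
    shapes = {
        "flat": np.ones(n_t),
        # peri-implantation-marker-like steady induction
        "rising": 1.0 + 3.0 * shape_grid,
        # naive-marker-like rapid collapse after withdrawal
        "falling": 4.0 * np.exp(-t / max(t[-1] / 4.0, 1e-9)),
    }
    transient_shape = np.interp(
        t, np.linspace(t[0], t[-1], len(_TRANSIENT_SHAPE)), _TRANSIENT_SHAPE
    )

    rows, kinds = [], {}
    for cid in ids:
        scale = np.exp(rng.normal(np.log(50.0), 0.7))
        if cid in transient_ids:
            mean = transient_shape * scale
            kinds[cid] = "transient"
        else:
            kind = rng.choice(["flat", "rising", "falling"])
            mean = shapes[kind] * scale
            kinds[cid] = kind
        noise = np.exp(rng.normal(0.0, config.timecourse_noise_sd, size=n_t))
        rows.append(mean * noise)

    courses = pd.DataFrame(np.vstack(rows), index=ids, columns=t)
    courses.index.name = "candidate_id"

    i_frac = int(np.argmin(np.abs(t - config.fraction_hour)))
    high, low = [], []
    for cid in ids:
        level = courses.loc[cid].iloc[i_frac]
        ratio = 4.0 if cid in transient_ids else 1.0
        h = level * ratio * np.exp(rng.normal(0.0, config.timecourse_noise_sd))
        l = level * np.exp(rng.normal(0.0, config.timecourse_noise_sd))
        high.append(h)
        low.append(l)
    fractions = pd.DataFrame({"high": high, "low": low}, index=ids)
    fractions.index.name = "candidate_id"
    return TimecourseSim(courses, frozenset(transient_ids), fractions, float(t[i_frac]))


# ---------------------------------------------------------------------------
# clone panels

@dataclass
class CloneSim:
    panel: pd.DataFrame  # clones x positions; 1.0 / 0.0 / NaN
    regions: dict  # region name -> list of positions (panel columns)
    truth: dict  # region name -> planted methylation probability


def simulate_clone_panel(config: SimulationConfig) -> CloneSim:
    """Bisulfite clone panels with per-region methylation probabilities.

    Each call is an independent Bernoulli draw at its region's planted
    probability; an optional ``missing_rate`` masks calls at random
    (unscorable positions in a sequenced clone).
    """
    rng = _rng(config, "clone_panel")
    positions, regions, probs = [], {}, []
    pos = config.clone_region_start
    for name, n_cpg, p in config.clone_regions:
        region_pos = list(range(pos, pos + n_cpg * config.clone_spacing, config.clone_spacing))
        regions[name] = region_pos
        positions.extend(region_pos)
        probs.extend([p] * n_cpg)
        pos = region_pos[-1] + 4 * config.clone_spacing
    probs_arr = np.asarray(probs)

    calls = (
        rng.random(size=(config.n_clones, len(positions))) < probs_arr
    ).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(size=calls.shape) < config.missing_rate
        calls[mask] = np.nan

    panel = pd.DataFrame(
        calls,
        index=[f"clone{i:02d}" for i in range(config.n_clones)],
        columns=positions,
    )
    panel.index.name = "clone_id"
    truth = {name: p for name, _, p in config.clone_regions}
    return CloneSim(panel, regions, truth)


# ---------------------------------------------------------------------------
# genome: gene models, repeats, CpG table

@dataclass
class GenomeSim:
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    exons: pd.DataFrame  # focal transcript exons (chrom, start, end, name)
    repeats: pd.DataFrame  # chrom, start, end, name (class/family)
    cpg_table: pd.DataFrame  # chrom, pos, meth_count, total_count
    chrom_sizes: dict
    truth: dict  # te_fraction, promoter_meth, background_meth


_REPEAT_CLASSES = ("ERVK/IAPEz", "LINE/L1", "SINE/B2")


def simulate_genome(config: SimulationConfig) -> GenomeSim:
    """Gene models, a TE-laden focal transcript, and a CpG count table.

    The focal transcript's exons are covered by repeat intervals built to
    occupy exactly ``te_overlap_fraction`` of the exonic bases (truth
    recorded as the realised fraction), plus decoy repeats outside exons.
    CpG sites are laid down at regular spacing with Poisson-like coverage;
    sites inside promoter windows methylate at ``promoter_meth``, the rest
    at ``background_meth`` — the hypomethylated-promoter landscape of the
    naive state.
    """
    rng = _rng(config, "genome")
    chrom_sizes = dict(config.chrom_sizes)
    chrom, length = next(iter(chrom_sizes.items()))

    # gene models on random strands, away from chromosome edges
    tss = np.sort(
        rng.choice(
            np.arange(config.promoter_upstream, length - config.promoter_upstream),
            size=config.n_promoter_genes,
            replace=False,
        )
    )
    strands = rng.choice(["+", "-"], size=config.n_promoter_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:03d}" for i in range(config.n_promoter_genes)],
            "chrom": chrom,
            "tss": tss.astype(int),
            "strand": strands,
        }
    )

    # focal transcript: three exons; repeats tile a prefix of each exon so
    # the realised TE fraction equals the configured one up to 1 bp per exon
    exon_start = length // 2
    exon_lengths = (400, 250, 350)
    gap = 800
    exon_rows, repeat_rows = [], []
    pos = exon_start
    for i, el in enumerate(exon_lengths):
        exon_rows.append((chrom, pos, pos + el, f"exon{i + 1}"))
        covered = int(round(config.te_overlap_fraction * el))
        if covered > 0:
            cls = _REPEAT_CLASSES[i % len(_REPEAT_CLASSES)]
            repeat_rows.append((chrom, pos, pos + covered, cls))
        pos += el + gap
    # decoy repeats clear of the exons
    for j in range(5):
        start = int(rng.integers(0, exon_start - 2000))
        repeat_rows.append(
            (chrom, start, start + int(rng.integers(100, 500)),
             _REPEAT_CLASSES[j % len(_REPEAT_CLASSES)])
        )
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "name"])
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "name"])

    covered_total = sum(
        int(round(config.te_overlap_fraction * el)) for el in exon_lengths
    )
    true_te = covered_total / sum(exon_lengths)

    # promoter windows (strand-aware) for the methylation landscape
    promoters = []
    for rec in genes.itertuples(index=False):
        if rec.strand == "+":
            promoters.append((max(rec.tss - config.promoter_upstream, 0), rec.tss))
        else:
            promoters.append((rec.tss, min(rec.tss + config.promoter_upstream, length)))

    cpg_pos = np.arange(50, length, config.cpg_spacing)
    in_promoter = np.zeros(cpg_pos.size, dtype=bool)
    for s, e in promoters:
        in_promoter |= (cpg_pos >= s) & (cpg_pos < e)
    p_meth = np.where(in_promoter, config.promoter_meth, config.background_meth)
    total = rng.poisson(config.mean_coverage, size=cpg_pos.size) + 1
    meth = rng.binomial(total, p_meth)
    cpg_table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": cpg_pos.astype(int),
            "meth_count": meth.astype(int),
            "total_count": total.astype(int),
        }
    )
    truth = {
        "te_fraction": true_te,
        "promoter_meth": config.promoter_meth,
        "background_meth": config.background_meth,
    }
    return GenomeSim(genes, exons, repeats, cpg_table, chrom_sizes, truth)


# ---------------------------------------------------------------------------
# UTRs with planted seed sites

@dataclass
class UtrSim:
    sequences: dict  # utr_id -> RNA sequence
    truth: list  # planted SeedSite records
    mutants: dict  # utr_id -> seed-disrupted copy (only for UTRs with sites)
    mirna: str


def _site_sequence(mirna: str, site_type: str) -> str:
    from .mirna import _revcomp  # shared complement tables

    if site_type == "8mer":
        return _revcomp(mirna[1:8]) + "A"
    if site_type == "7mer-m8":
        return _revcomp(mirna[1:8])
    if site_type == "7mer-A1":
        return _revcomp(mirna[1:7]) + "A"
    if site_type == "6mer":
        return _revcomp(mirna[1:7])
    raise ValueError(f"unknown site type {site_type!r}")


def simulate_utr(config: SimulationConfig) -> UtrSim:
    """UTR sequences with planted canonical seed sites and mutant copies.

    Background sequence is rejection-sampled until it is free of spurious
    seed matches for the configured miRNA, then site sequences of the
    requested types are written in at the requested positions; the whole
    sequence is re-scanned and rejected if the scan differs from the
    planted truth (a planted site's flanks can create extra matches).
    Each UTR with at least one planted site also gets a mutant copy with
    two seed-pairing bases substituted in every site, re-scanned to
    confirm all sites are lost.
    """
    rng = _rng(config, "utr")
    mirna = config.mirna.upper().replace("T", "U")
    sequences, truth, mutants = {}, [], {}
    bases = np.array(list("ACGU"))
    swap = {"A": "C", "C": "A", "G": "U", "U": "G"}  # non-complementary change

    for utr_id, plants in config.planted_sites:
        wanted = [
            SeedSite(utr_id, pos, pos + len(_site_sequence(mirna, st)), st)
            for st, pos in plants
        ]
        for site in wanted:
            if site.end > config.utr_length:
                raise ValueError(f"planted site {site} exceeds UTR length")

        accepted = None
        for _ in range(config.max_retries):
            seq = list(rng.choice(bases, size=config.utr_length))
            for (st, pos), site in zip(plants, wanted):
                seq[site.start : site.end] = _site_sequence(mirna, st)
            candidate = "".join(seq)
            found = scan_seed_sites(candidate, mirna, utr_id)
            if {(s.start, s.end, s.site_type) for s in found} == {
                (s.start, s.end, s.site_type) for s in wanted
            }:
                accepted = candidate
                break
        if accepted is None:
            raise RuntimeError(
                f"rejection sampling failed for {utr_id} after "
                f"{config.max_retries} retries"
            )
        sequences[utr_id] = accepted
        truth.extend(wanted)

        if wanted:
            mut = list(accepted)
            for site in wanted:
                for offset in (1, 3):  # two seed-pairing positions
                    i = site.start + offset
                    mut[i] = swap[mut[i]]
            mutant = "".join(mut)
            remaining = scan_seed_sites(mutant, mirna, utr_id)
            if any(
                (s.start, s.end, s.site_type)
                in {(w.start, w.end, w.site_type) for w in wanted}
                for s in remaining
            ):
                raise RuntimeError(f"seed disruption failed for {utr_id}")
            mutants[utr_id] = mutant
    return UtrSim(sequences, truth, mutants, mirna)


# ---------------------------------------------------------------------------
# dual-luciferase measurements

def simulate_luciferase(config: SimulationConfig) -> pd.DataFrame:
    """Dual-luciferase reporter table with planted fold repression.

    Scramble-condition firefly/Renilla ratios sit near 1; mimic-condition
    ratios are divided by each construct's planted fold repression.
    Replicate noise is multiplicative log-normal with coefficient of
    variation ``luciferase_cv`` on both channels.
    """
    rng = _rng(config, "luciferase")
    sd = np.sqrt(np.log1p(config.luciferase_cv**2))
    rows = []
    for construct, fold in config.luciferase_fold:
        for condition in ("scramble", "mimic"):
            level = 1.0 if condition == "scramble" else 1.0 / fold
            for rep in range(1, config.n_replicates + 1):
                renilla = 1000.0 * np.exp(rng.normal(0.0, sd))
                firefly = 1000.0 * level * np.exp(rng.normal(0.0, sd))
                rows.append((construct, condition, firefly, renilla, rep))
    return pd.DataFrame(
        rows, columns=["construct_id", "condition", "firefly", "renilla", "replicate"]
    )
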
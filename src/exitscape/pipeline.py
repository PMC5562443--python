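"""Stage orchestration: one config, validated inputs, a combined report.

The pipeline runs any subset of the analysis stages over a shared input
directory.  The ``simulate`` stage writes every input the other stages
read (plus planted-truth files with a ``_truth`` suffix); the analysis
stages are independent of one another and all consume the input
directory, so a failing stage never blocks its peers.  Outputs are
deterministic for a fixed config: every file carries the tool version,
seed and config digest in its provenance header, and re-running an
identical config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synthetic
from .dynamics import detect_transient, fraction_differential, rank_by_expression
from .intervals import te_fraction
from .methylation import genome_average, promoter_average, region_percent
from .mirna import check_escape, fold_repression, scan_seed_sites
from .screen import (
    classify_quadrant,
    derive_signatures,
    score_perturbation,
    validate_known_regulators,
)

logger = logging.getLogger("exitscape")

ALL_STAGES = ("simulate", "screen", "dynamics", "methylation", "annotation", "mirna")


@dataclass
class RunConfig:
    """Pipeline run configuration (see :func:`RunConfig.from_yaml`)."""

    seed: int = 0
    out_dir: Path = Path("exitscape_out")
    input_dir: Path | None = None  # default: <out_dir>/inputs
    stages: tuple = ALL_STAGES
    params: dict = field(default_factory=dict)  # per-stage parameter blocks

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed", "out_dir", "input_dir", "stages"}
        kwargs = {k: raw[k] for k in known if k in raw}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        params = {k: v for k, v in raw.items() if k not in known}
        return cls(params=params, **kwargs)

    @property
    def inputs(self) -> Path:
        return self.input_dir if self.input_dir is not None else self.out_dir / "inputs"

    def digest(self) -> str:
        blob = repr(
            (self.seed, sorted(self.stages), sorted(self.params.items(), key=str))
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self, stage: str) -> list[str]:
        return [
            f"exitscape {__version__}",
            f"stage={stage}",
            f"seed={self.seed}",
            f"config_digest={self.digest()}",
        ]


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)  # (file, message)

    @property
    def ok(self) -> bool:
        return not self.errors


#: Input files each analysis stage reads, with their required columns
#: (None = non-tabular or validated by a dedicated reader).
_STAGE_INPUTS = {
    "screen": {
        "state_comparison.tsv": {"gene_id", "mean_a", "mean_b"},
    },
    "dynamics": {"timecourses.tsv": {"candidate_id"}},
    "methylation": {
        "clone_panel.tsv": None,
        "cpg_table.tsv": {"chrom", "start", "end", "meth_count", "total_count"},
        "gene_models.tsv": {"gene_id", "chrom", "tss", "strand"},
        "chrom_sizes.tsv": {"chrom", "length"},
    },
    "annotation": {"exons.bed": None, "repeats.bed": None},
    "mirna": {"utrs.fasta": None, "luciferase.tsv": {
        "construct_id", "condition", "firefly", "renilla"}},
}


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Header-level validation of every input a selected stage will read."""
    report = ValidationReport()
    inputs = config.inputs
    for stage in config.stages:
        for fname, columns in _STAGE_INPUTS.get(stage, {}).items():
            path = inputs / fname
            if not path.exists():
                report.errors.append((str(path), "missing input file"))
                continue
            if columns is None:
                continue
            try:
                header = io.read_tsv(path, nrows=0)
            except Exception as exc:  # unreadable / malformed
                report.errors.append((str(path), f"unreadable: {exc}"))
                continue
            missing = columns - set(header.columns)
            if missing:
                report.errors.append(
                    (str(path), f"missing columns: {sorted(missing)}")
                )
    # value-level spot checks that headers cannot catch
    cpg = inputs / "cpg_table.tsv"
    if "methylation" in config.stages and cpg.exists():
        try:
            table = io.read_cpg_table(cpg)
            bad = table[(table["meth_count"] < 0)
                        | (table["total_count"] < table["meth_count"])]
            for idx in bad.index[:5]:
                report.errors.append(
                    (str(cpg), f"record {idx}: invalid meth/total counts")
                )
        except Exception as exc:
            report.errors.append((str(cpg), str(exc)))
    return report


# ---------------------------------------------------------------------------
# simulate stage

def _write_inputs(config: RunConfig) -> None:
    sim_params = dict(config.params.get("simulate", {}))
    sim_params["seed"] = config.seed
    if "archetypes" in sim_params:
        sim_params["archetypes"] = tuple(
            synthetic.Archetype(**a) for a in sim_params["archetypes"]
        )
    for key in ("chrom_sizes", "clone_regions", "planted_sites", "luciferase_fold",
                "timepoints"):
        if key in sim_params:
            sim_params[key] = _tuplize(sim_params[key])
    sim = synthetic.SimulationConfig(**sim_params)
    prov = config.provenance("simulate")
    inputs = config.inputs

    two_state = synthetic.simulate_two_state(sim)
    io.write_tsv(two_state.comparison, inputs / "state_comparison.tsv", prov)
    io.write_gene_set(two_state.truth.set_a, inputs / "signature_a_truth.txt", prov)
    io.write_gene_set(two_state.truth.set_b, inputs / "signature_b_truth.txt", prov)

    panel = synthetic.simulate_knockdown_panel(sim, two_state.truth)
    for label, profile in panel.profiles.items():
        io.write_tsv(profile, inputs / "profiles" / f"{label}.tsv", prov)
    io.write_tsv(
        pd.DataFrame(
            sorted(panel.expected_quadrants.items()),
            columns=["perturbation_id", "expected_quadrant"],
        ),
        inputs / "archetypes_truth.tsv", prov,
    )

    tc = synthetic.simulate_timecourse(sim)
    io.write_timecourses(
        tc.courses, inputs / "timecourses.tsv", tc.fractions, tc.fraction_hour, prov
    )
    io.write_gene_set(tc.transient_ids, inputs / "transient_truth.txt", prov)

    clones = synthetic.simulate_clone_panel(sim)
    io.write_clone_panel(clones.panel, inputs / "clone_panel.tsv", prov)
    io.write_tsv(
        pd.DataFrame(
            [
                (name, min(pos), max(pos), clones.truth[name])
                for name, pos in clones.regions.items()
            ],
            columns=["region", "first_pos", "last_pos", "true_probability"],
        ),
        inputs / "clone_regions_truth.tsv", prov,
    )

    genome = synthetic.simulate_genome(sim)
    io.write_tsv(genome.genes, inputs / "gene_models.tsv", prov)
    io.write_bed(genome.exons, inputs / "exons.bed", prov)
    io.write_bed(genome.repeats, inputs / "repeats.bed", prov)
    io.write_cpg_table(genome.cpg_table, inputs / "cpg_table.tsv", prov)
    io.write_tsv(
        pd.DataFrame(
            genome.chrom_sizes.items(), columns=["chrom", "length"]
        ),
        inputs / "chrom_sizes.tsv", prov,
    )
    io.write_tsv(
        pd.DataFrame([genome.truth]), inputs / "genome_truth.tsv", prov
    )

    utrs = synthetic.simulate_utr(sim)
    io.write_fasta(utrs.sequences, inputs / "utrs.fasta")
    io.write_fasta(utrs.mutants, inputs / "utr_mutants.fasta")
    io.write_fasta({"mirna": utrs.mirna}, inputs / "mirna.fasta")
    io.write_tsv(
        pd.DataFrame(
            [(s.utr_id, s.start, s.end, s.site_type) for s in utrs.truth],
            columns=["utr_id", "start", "end", "site_type"],
        ),
        inputs / "seed_sites_truth.tsv", prov,
    )

    io.write_tsv(synthetic.simulate_luciferase(sim), inputs / "luciferase.tsv", prov)


def _tuplize(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_tuplize(x) for x in obj)
    return obj


# ---------------------------------------------------------------------------
# analysis stages

def _run_screen(config: RunConfig, out: Path) -> str:
    p = config.params.get("screen", {})
    comparison = io.read_state_comparison(config.inputs / "state_comparison.tsv")
    signatures = derive_signatures(
        comparison,
        fold_threshold=p.get("fold_threshold", 10.0),
        pseudocount=p.get("pseudocount", 0.0),
    )
    prov = config.provenance("screen")
    io.write_gene_set(signatures.set_a, out / "signature_a.txt", prov)
    io.write_gene_set(signatures.set_b, out / "signature_b.txt", prov)

    rows, scores = [], []
    profile_dir = config.inputs / "profiles"
    for path in sorted(profile_dir.glob("*.tsv")):
        profile = io.read_perturbation_profile(path)
        score = score_perturbation(
            profile, signatures,
            fdr_cut=p.get("fdr_cut", 0.05),
            fc_up=p.get("fc_up", 2.0),
            fc_down=p.get("fc_down", 0.5),
            dead_zone=p.get("dead_zone", 0.0),
        )
        scores.append(score)
        rows.append(dataclasses.asdict(score))
    table = pd.DataFrame(rows)
    io.write_tsv(table, out / "screen_scores.tsv", prov)

    summary = [f"{len(signatures.set_a)}/{len(signatures.set_b)} signature genes"]
    truth_path = config.inputs / "archetypes_truth.tsv"
    if truth_path.exists():
        expectations = dict(
            io.read_tsv(truth_path)[["perturbation_id", "expected_quadrant"]]
            .itertuples(index=False)
        )
        report = validate_known_regulators(scores, expectations)
        io.write_tsv(
            pd.DataFrame(
                report.mismatches, columns=["perturbation_id", "observed", "expected"]
            ),
            out / "screen_mismatches.tsv", prov,
        )
        summary.append(
            f"archetype concordance {report.fraction:.2f} over {report.n_evaluated}"
        )
    # text score plane: one line per perturbation
    plane = [
        f"{s.perturbation_id:>20s}  ESC {s.esc_axis:+7.2f}  EpiSC {s.epi_axis:+7.2f}"
        f"  -> {s.quadrant}"
        for s in scores
    ]
    (out / "score_plane.txt").write_text(
        "\n".join([f"# {line}" for line in prov] + plane) + "\n"
    )
    return "; ".join(summary)


def _run_dynamics(config: RunConfig, out: Path) -> str:
    p = config.params.get("dynamics", {})
    courses, fractions, hour = io.read_timecourses(config.inputs / "timecourses.tsv")
    ranking = rank_by_expression(courses, statistic=p.get("statistic", "mean"))
    rows = []
    t = np.array(courses.columns, dtype=float)
    for cid in courses.index:
        call = detect_transient(t, courses.loc[cid].to_numpy(),
                                decline_fraction=p.get("decline_fraction", 0.6))
        frac = (
            fraction_differential(
                fractions.loc[cid, "high"], fractions.loc[cid, "low"],
                pseudocount=p.get("pseudocount", 1.0),
            )
            if fractions is not None
            else float("nan")
        )
        rows.append(
            {
                "candidate_id": cid,
                "mean_expr": ranking.loc[cid, "mean_expr"],
                "rank": int(ranking.loc[cid, "rank"]),
                "frac_log2": frac,
                "is_transient": call.is_transient,
                "peak_time": call.peak_time,
            }
        )
    table = pd.DataFrame(rows).sort_values("rank")
    io.write_tsv(table, out / "dynamics.tsv", config.provenance("dynamics"))
    n_trans = int(table["is_transient"].sum())
    return f"{len(table)} candidates ranked; {n_trans} transient"


def _run_methylation(config: RunConfig, out: Path) -> str:
    p = config.params.get("methylation", {})
    prov = config.provenance("methylation")
    panel = io.read_clone_panel(config.inputs / "clone_panel.tsv")
    regions_path = config.inputs / "clone_regions_truth.tsv"
    rows = []
    if regions_path.exists():
        for rec in io.read_tsv(regions_path).itertuples(index=False):
            positions = [c for c in panel.columns
                         if rec.first_pos <= c <= rec.last_pos]
            rows.append(
                {"window": rec.region,
                 "percent": region_percent(panel, positions),
                 "kind": "clone_region"}
            )
    else:
        rows.append(
            {"window": "all_positions",
             "percent": region_percent(panel, list(panel.columns)),
             "kind": "clone_region"}
        )

    table = io.read_cpg_table(config.inputs / "cpg_table.tsv")
    genes = io.read_tsv(config.inputs / "gene_models.tsv")
    sizes = dict(
        io.read_tsv(config.inputs / "chrom_sizes.tsv")[["chrom", "length"]]
        .itertuples(index=False)
    )
    min_cov = p.get("min_coverage", 1)
    upstream = p.get("upstream", 2000)
    tile = p.get("tile", 50_000)
    prom = promoter_average(table, genes, upstream, min_cov, sizes)
    gen = genome_average(table, sizes, tile, min_cov)
    rows.append({"window": f"promoters_{upstream}bp", "percent": prom.percent,
                 "kind": f"promoter_average(n={prom.n_windows})"})
    rows.append({"window": f"tiles_{tile}bp", "percent": gen.percent,
                 "kind": f"genome_average(n={gen.n_windows})"})
    io.write_tsv(pd.DataFrame(rows), out / "methylation.tsv", prov)
    return f"promoter {prom.percent:.1f}% vs genome {gen.percent:.1f}%"


def _run_annotation(config: RunConfig, out: Path) -> str:
    exons = io.read_bed(config.inputs / "exons.bed")
    repeats = io.read_bed(config.inputs / "repeats.bed")
    comp = te_fraction(exons, repeats)
    rows = [{"feature": "total", "bases": comp.covered_bases,
             "fraction_of_exonic": comp.fraction}]
    rows += [
        {"feature": cls, "bases": b, "fraction_of_exonic": b / comp.exon_bases}
        for cls, b in sorted(comp.by_class.items())
    ]
    io.write_tsv(pd.DataFrame(rows), out / "te_composition.tsv",
                 config.provenance("annotation"))
    return f"TE fraction {100 * comp.fraction:.1f}% of {comp.exon_bases} exonic bases"


def _run_mirna(config: RunConfig, out: Path) -> str:
    prov = config.provenance("mirna")
    utrs = io.read_fasta(config.inputs / "utrs.fasta")
    mirna = next(iter(io.read_fasta(config.inputs / "mirna.fasta").values()))
    site_rows = []
    for utr_id, seq in sorted(utrs.items()):
        for s in scan_seed_sites(seq, mirna, utr_id):
            site_rows.append(
                {"utr_id": s.utr_id, "start": s.start, "end": s.end,
                 "site_type": s.site_type}
            )
    io.write_tsv(pd.DataFrame(site_rows,
                              columns=["utr_id", "start", "end", "site_type"]),
                 out / "seed_sites.tsv", prov)

    escape_rows = []
    mutants_path = config.inputs / "utr_mutants.fasta"
    if mutants_path.exists():
        for utr_id, mut_seq in sorted(io.read_fasta(mutants_path).items()):
            res = check_escape(utrs[utr_id], mut_seq, mirna)
            escape_rows.append(
                {"utr_id": utr_id, "lost": len(res.lost),
                 "retained": len(res.retained), "gained": len(res.gained),
                 "escape": res.escape}
            )
    io.write_tsv(pd.DataFrame(escape_rows,
                              columns=["utr_id", "lost", "retained", "gained",
                                       "escape"]),
                 out / "escape.tsv", prov)

    luc = io.read_luciferase(config.inputs / "luciferase.tsv")
    rep = fold_repression(luc)
    io.write_tsv(rep.reset_index(), out / "fold_repression.tsv", prov)
    n_escape = sum(r["escape"] for r in escape_rows)
    return (f"{len(site_rows)} seed sites; {n_escape} escape mutants; "
            f"{len(rep)} reporter constructs")


_STAGE_RUNNERS = {
    "screen": _run_screen,
    "dynamics": _run_dynamics,
    "methylation": _run_methylation,
    "annotation": _run_annotation,
    "mirna": _run_mirna,
}


def run(config: RunConfig) -> dict:
    """Execute the selected stages; return {stage: summary-or-error}.

    The ``simulate`` stage runs first and writes the shared input
    directory; analysis stages then run in declaration order.  A failed
    stage is recorded and its peers still run; if ``simulate`` itself
    fails, stages that would read its outputs are skipped.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, str] = {}
    simulate_ok = True
    if "simulate" in config.stages:
        try:
            _write_inputs(config)
            n_files = sum(1 for p in config.inputs.rglob("*") if p.is_file())
            results["simulate"] = f"{n_files} input files written"
        except Exception as exc:
            logger.exception("simulate stage failed")
            results["simulate"] = f"ERROR: {exc}"
            simulate_ok = False

    report = validate_inputs(config)
    if not report.ok and simulate_ok:
        for path, msg in report.errors:
            logger.error("input validation: %s: %s", path, msg)

    for stage in config.stages:
        if stage == "simulate":
            continue
        if not simulate_ok:
            results[stage] = "SKIPPED: simulate stage failed"
            continue
        try:
            results[stage] = _STAGE_RUNNERS[stage](config, config.out_dir)
        except Exception as exc:
            logger.exception("stage %s failed", stage)
            results[stage] = f"ERROR: {exc}"

    lines = [f"# {line}" for line in config.provenance("report")]
    lines += [f"{stage}: {summary}" for stage, summary in results.items()]
    (config.out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return results
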
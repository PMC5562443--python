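"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: TSV with a header row; lines starting with ``#`` are
provenance/comment lines and are skipped on read; BED is 0-based
half-open; clone panels are matrices with ``M`` / ``U`` / ``.`` cells and
1-based display positions as column headers (converted to integers on
read); CpG tables are bedGraph-like (chrom, start, end = start + 1,
meth_count, total_count).  FASTA goes through Biopython.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .methylation import CALL_CODES

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_state_comparison",
    "read_perturbation_profile",
    "read_de_table",
    "read_timecourses",
    "read_clone_panel",
    "write_clone_panel",
    "read_cpg_table",
    "write_cpg_table",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_luciferase",
    "write_gene_set",
    "read_gene_set",
]


def read_tsv(path, **kwargs) -> pd.DataFrame:
    # restrict NA tokens so quadrant labels like "null" survive as strings
    kwargs.setdefault("keep_default_na", False)
    kwargs.setdefault("na_values", ["", "NaN", "nan"])
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None = None,
              index: bool = False, float_format: str = "%.10g") -> None:
    """Write a TSV, optionally prefixed with ``#``-commented provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index, float_format=float_format)
    path.write_text(buf.getvalue())


def read_state_comparison(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"gene_id", "mean_a", "mean_b"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_perturbation_profile(path, perturbation_id: str | None = None) -> pd.DataFrame:
    df = read_tsv(path)
    if "gene_id" not in df.columns or "fold_change" not in df.columns:
        raise ValueError(f"{path}: needs gene_id and fold_change columns")
    if ("p_value" in df.columns) == ("q_value" in df.columns):
        raise ValueError(f"{path}: needs exactly one of p_value / q_value")
    df.attrs["perturbation_id"] = perturbation_id or Path(path).stem
    return df


def read_de_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"gene_id", "fold_change", "adj_p"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_timecourses(path) -> tuple[pd.DataFrame, pd.DataFrame | None, float | None]:
    """Wide time-course TSV: candidate_id, one column per hour.

    Optional paired sorted-fraction columns named ``high@H`` / ``low@H``
    (H in hours) are split off and returned separately as
    ``(courses, fractions, hour)``; ``fractions`` is None when absent.
    """
    df = read_tsv(path).set_index("candidate_id")
    frac_cols = [c for c in df.columns if "@" in str(c)]
    fractions, hour = None, None
    if frac_cols:
        hours = {float(str(c).split("@")[1]) for c in frac_cols}
        if len(hours) != 1:
            raise ValueError(f"{path}: fraction columns must share one hour")
        hour = hours.pop()
        fractions = pd.DataFrame(
            {str(c).split("@")[0]: df[c] for c in frac_cols}
        )
        if set(fractions.columns) != {"high", "low"}:
            raise ValueError(f"{path}: fraction columns must be high@H and low@H")
        df = df.drop(columns=frac_cols)
    df.columns = [float(c) for c in df.columns]
    return df, fractions, hour


def write_timecourses(sim_courses: pd.DataFrame, path,
                      fractions: pd.DataFrame | None = None,
                      fraction_hour: float | None = None,
                      header_lines: list[str] | None = None) -> None:
    out = sim_courses.copy()
    out.columns = [f"{float(c):g}" for c in out.columns]
    if fractions is not None:
        out[f"high@{fraction_hour:g}"] = fractions["high"]
        out[f"low@{fraction_hour:g}"] = fractions["low"]
    write_tsv(out.reset_index(), path, header_lines)


def read_clone_panel(path) -> pd.DataFrame:
    """Clone matrix with M/U/. cells; display positions converted to int."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    try:
        df.columns = [int(c) for c in df.columns]
    except ValueError as exc:
        raise ValueError(f"{path}: column headers must be integer positions") from exc
    bad = set(np.unique(df.to_numpy().astype(str))) - set(CALL_CODES) - {"nan"}
    if bad:
        raise ValueError(f"{path}: invalid call codes {sorted(bad)}")
    panel = df.apply(lambda col: col.map(CALL_CODES))
    panel.index.name = "clone_id"
    return panel.astype(float)


def write_clone_panel(panel: pd.DataFrame, path,
                      header_lines: list[str] | None = None) -> None:
    coded = panel.copy()
    for col in coded.columns:
        coded[col] = np.where(
            np.isnan(panel[col]), ".", np.where(panel[col] > 0.5, "M", "U")
        )
    write_tsv(coded.reset_index(), path, header_lines)


def read_cpg_table(path) -> pd.DataFrame:
    """bedGraph-like TSV: chrom, start, end (= start + 1), meth, total."""
    df = read_tsv(path)
    required = {"chrom", "start", "end", "meth_count", "total_count"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if ((df["end"] - df["start"]) != 1).any():
        raise ValueError(f"{path}: CpG records must be single-base (end = start + 1)")
    out = df.rename(columns={"start": "pos"})[
        ["chrom", "pos", "meth_count", "total_count"]
    ]
    return out


def write_cpg_table(table: pd.DataFrame, path,
                    header_lines: list[str] | None = None) -> None:
    out = table.copy()
    out["start"] = out["pos"]
    out["end"] = out["pos"] + 1
    write_tsv(
        out[["chrom", "start", "end", "meth_count", "total_count"]],
        path, header_lines,
    )


def read_bed(path) -> pd.DataFrame:
    """BED3/4/6 (0-based half-open); name/strand kept when present."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
        rec = {"chrom": fields[0], "start": int(fields[1]), "end": int(fields[2])}
        if len(fields) >= 4:
            rec["name"] = fields[3]
        if len(fields) >= 6:
            rec["strand"] = fields[5]
        rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"]
                        ).dropna(axis=1, how="all")


def write_bed(intervals: pd.DataFrame, path,
              header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for rec in intervals.itertuples(index=False):
            fields = [str(rec.chrom), str(int(rec.start)), str(int(rec.end))]
            if hasattr(rec, "name"):
                fields.append(str(rec.name))
            if hasattr(rec, "strand"):
                fields += ["0", str(rec.strand)]
            fh.write("\t".join(fields) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_luciferase(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"construct_id", "condition", "firefly", "renilla"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_gene_set(genes, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {line}" for line in header_lines or []]
    lines += sorted(str(g) for g in genes)
    path.write_text("\n".join(lines) + "\n")


def read_gene_set(path) -> frozenset:
    return frozenset(
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
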
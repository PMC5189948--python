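"""Table readers and report writers shared by all pipeline stages.

TSV is the canonical dialect; CSV is accepted by sniffing the delimiter.
Gene identifiers are opaque case-sensitive strings.  Reports are written
with a deterministic column order and floats at 6 significant digits, so a
rerun with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import csv
import math
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .decay_kinetics import DecayTimecourse, HalfLifeEstimate
from .qpcr_quant import CtRecord, CtTable, QuantResult
from .transcriptome_sets import FoldChangeTable, OverlapResult

__all__ = [
    "read_fold_change_table",
    "read_fold_changes_xlsx",
    "read_decay_table",
    "read_ct_table",
    "write_overlap_report",
    "write_halflife_report",
    "write_quant_report",
    "write_fold_change_table",
    "write_decay_table",
    "write_ct_table",
]

OVERLAP_COLUMNS = (
    "set1_label", "set2_label", "direction", "n1", "n2", "N", "k_observed",
    "null_mean", "null_sd", "z", "n_mc", "seed", "method",
)


def _sniff_sep(path: Path) -> str:
    sample = path.read_text().splitlines()
    for line in sample:
        if not line.startswith("#"):
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: no data lines found")


def _read_frame(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), comment="#")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_fold_change_table(
    path: str | os.PathLike,
    comparison_label: str | None = None,
    pseudocount: float = 0.0,
) -> FoldChangeTable:
    """Load a fold-change table, or compute one from paired expression columns.

    Accepts either ``gene_id, fold_change`` or
    ``gene_id, expr_stress, expr_control`` (ratio computed with the given
    pseudocount).  Duplicate gene identifiers are an error naming the gene
    and line; rows with missing or non-positive ratios are excluded and
    counted in ``FoldChangeTable.n_excluded``.
    """
    path = Path(path)
    df = _read_frame(path)
    _require_columns(df, ["gene_id"], path)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        gene = dup.iloc[0]
        # +2: header line plus 1-based indexing
        line = int(dup.index[0]) + 2
        raise ValueError(f"{path}: duplicate gene_id {gene!r} (line {line})")
    label = comparison_label if comparison_label is not None else path.stem

    if "fold_change" in df.columns:
        fc = pd.to_numeric(df["fold_change"], errors="coerce")
        ok = fc.notna() & np.isfinite(fc) & (fc > 0)
        entries = dict(zip(df.loc[ok, "gene_id"].astype(str), fc[ok].astype(float)))
        return FoldChangeTable(label, entries, n_excluded=int((~ok).sum()))

    _require_columns(df, ["expr_stress", "expr_control"], path)
    from .transcriptome_sets import compute_fold_changes

    stress = dict(zip(df["gene_id"].astype(str),
                      pd.to_numeric(df["expr_stress"], errors="coerce")))
    control = dict(zip(df["gene_id"].astype(str),
                       pd.to_numeric(df["expr_control"], errors="coerce")))
    stress = {g: float(v) for g, v in stress.items() if pd.notna(v)}
    control = {g: float(v) for g, v in control.items() if pd.notna(v)}
    return compute_fold_changes(stress, control, pseudocount, comparison_label=label)


def read_fold_changes_xlsx(
    path: str | os.PathLike,
    sheet: str | int = 0,
    gene_column: str = "gene_id",
    fold_change_column: str = "fold_change",
    comparison_label: str | None = None,
) -> FoldChangeTable:
    """Thin adapter for spreadsheet-deposited fold-change tables.

    Column names vary between depositions, so the gene and ratio columns are
    given explicitly.  Rows with non-numeric or non-positive ratios are
    excluded and counted, as in :func:`read_fold_change_table`.
    """
    path = Path(path)
    df = pd.read_excel(path, sheet_name=sheet)
    _require_columns(df, [gene_column, fold_change_column], path)
    fc = pd.to_numeric(df[fold_change_column], errors="coerce")
    ok = fc.notna() & np.isfinite(fc) & (fc > 0)
    label = comparison_label if comparison_label is not None else f"{path.stem}:{sheet}"
    entries = dict(zip(df.loc[ok, gene_column].astype(str), fc[ok].astype(float)))
    return FoldChangeTable(label, entries, n_excluded=int((~ok).sum()))


def read_decay_table(path: str | os.PathLike) -> DecayTimecourse:
    """Load a shut-off time course: ``time_min`` plus one column per replicate.

    A leading ``# condition=NAME`` comment line sets the condition label.
    """
    path = Path(path)
    condition = path.stem
    for line in path.read_text().splitlines():
        if line.startswith("#") and "condition=" in line:
            condition = line.split("condition=", 1)[1].strip()
        if not line.startswith("#"):
            break
    df = _read_frame(path)
    _require_columns(df, ["time_min"], path)
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValueError(f"{path}: no replicate columns (rep1, rep2, ...)")
    return DecayTimecourse(
        condition_label=condition,
        times=df["time_min"].to_numpy(dtype=float),
        intensities=df[rep_cols].to_numpy(dtype=float).T,
    )


def read_ct_table(path: str | os.PathLike) -> CtTable:
    """Load a Ct table: ``sample, target, role, ct1[, ct2, ct3, ...]``."""
    path = Path(path)
    df = _read_frame(path)
    _require_columns(df, ["sample", "target", "role", "ct1"], path)
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    records = []
    for _, row in df.iterrows():
        cts = tuple(
            float(row[c]) for c in ct_cols if pd.notna(row[c])
        )
        records.append(
            CtRecord(str(row["sample"]), str(row["target"]), cts, str(row["role"]))
        )
    return CtTable(tuple(records))


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isinf(value):
            return "inf"
        return f"{value:.6g}"
    return str(value)


def _write_rows(
    path: str | os.PathLike,
    header: Sequence[str],
    rows: Iterable[Sequence[object]],
    force: bool,
) -> None:
    path = Path(path)
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty report")
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def write_overlap_report(
    results: Sequence[OverlapResult], path: str | os.PathLike, force: bool = False
) -> None:
    rows = [
        (
            r.set1_label, r.set2_label, r.direction, r.n1, r.n2, r.N,
            r.k_observed, r.null_mean, r.null_sd,
            "degenerate" if r.degenerate else r.z, r.n_mc, r.seed, r.method,
        )
        for r in results
    ]
    _write_rows(path, OVERLAP_COLUMNS, rows, force)


def write_halflife_report(
    estimates: Sequence[tuple[str, HalfLifeEstimate]],
    path: str | os.PathLike,
    force: bool = False,
) -> None:
    header = ("condition", "t_half_min", "k_per_min", "r_squared",
              "n_replicates", "flags")
    rows = [
        (label, e.t_half, e.decay_rate_k, e.r_squared, e.n_replicates,
         ";".join(e.flags) or "-")
        for label, e in estimates
    ]
    _write_rows(path, header, rows, force)


def write_quant_report(
    results: Sequence[QuantResult], path: str | os.PathLike, force: bool = False
) -> None:
    header = ("sample", "target", "value", "basis", "uncertainty")
    rows = []
    for r in results:
        sample, _, target = r.label.partition(":")
        rows.append((sample, target or "-", r.value, r.basis, r.uncertainty))
    _write_rows(path, header, rows, force)


def write_fold_change_table(
    table: FoldChangeTable, path: str | os.PathLike, force: bool = False
) -> None:
    rows = sorted(table.entries.items())
    _write_rows(path, ("gene_id", "fold_change"), rows, force)


def write_decay_table(
    tc: DecayTimecourse, path: str | os.PathLike, force: bool = False
) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    header = ["time_min"] + [f"rep{i + 1}" for i in range(tc.n_replicates)]
    with open(path, "w", newline="") as fh:
        fh.write(f"# condition={tc.condition_label}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for j, t in enumerate(tc.times):
            writer.writerow([_fmt(float(t))] + [_fmt(float(v)) for v in tc.intensities[:, j]])


def write_ct_table(
    table: CtTable, path: str | os.PathLike, force: bool = False
) -> None:
    n_ct = max(len(r.ct_values) for r in table.records)
    header = ["sample", "target", "role"] + [f"ct{i + 1}" for i in range(n_ct)]
    rows = []
    for r in table.records:
        cts = list(r.ct_values) + [""] * (n_ct - len(r.ct_values))
        rows.append([r.sample_label, r.target_label, r.role] + cts)
    _write_rows(path, header, rows, force)
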
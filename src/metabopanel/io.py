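"""Readers and writers for peak tables, behavior tables and result artifacts.

Interchange format is delimited text (comma by default, tab accepted).
A peak-table file carries six metadata columns (sample_id, group, role,
dilution, dilution_stage, injection_order) followed by one numeric column
per metabolite.  Retention time / m/z annotation travels in an optional
companion table.  An optional minimal mwTab reader maps the
``MS_METABOLITE_DATA`` block of a Metabolomics Workbench deposition onto a
:class:`~metabopanel.peaktable.PeakTable`.

Result records (DEM tables, marker tables, correlation tables, ...) are
written one delimited file per kind, columns in the order of the published
table layouts, plus a machine-readable JSON summary at full precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .peaktable import Metabolite, PeakTable, SampleMeta

META_COLUMNS = ("sample_id", "group", "role", "dilution", "dilution_stage",
                "injection_order")

#: significant digits used in human-readable report files
REPORT_SIGDIGITS = 6


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t", ",": ",", "\t": "\t"}.get(
            dialect, dialect)
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_peak_table(
    path: str | Path,
    dialect: str | None = None,
    metabolite_info: str | Path | None = None,
    stage: str = "raw",
) -> PeakTable:
    """Read a delimited peak-table file.

    Raises :class:`SchemaError` for a missing metadata column or duplicate
    sample id, :class:`ParseError` for a non-numeric or negative area,
    naming the offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect))
    for col in META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"peak table {path}: missing metadata column "
                              f"{col!r}")
    met_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not met_cols:
        raise SchemaError(f"peak table {path}: no metabolite columns")
    ids = df["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"peak table {path}: duplicate sample_id {dup}")

    areas = np.empty((len(df), len(met_cols)))
    for j, col in enumerate(met_cols):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise ParseError(
                f"peak table {path}: non-numeric area at row "
                f"{int(bad[0]) + 2}, column {col!r}")
        if stage != "log":
            neg = np.nonzero(vals < 0)[0]
            if neg.size:
                raise ParseError(
                    f"peak table {path}: negative area at row "
                    f"{int(neg[0]) + 2}, column {col!r}")
        areas[:, j] = vals

    samples = [
        SampleMeta(
            sample_id=str(r.sample_id),
            group=str(r.group),
            role=str(r.role),
            dilution=float(r.dilution),
            dilution_stage=str(r.dilution_stage),
            injection_order=int(r.injection_order),
        )
        for r in df.itertuples()
    ]

    annot = {}
    if metabolite_info is not None:
        info = pd.read_csv(Path(metabolite_info),
                           sep=_delimiter(Path(metabolite_info), dialect))
        for r in info.itertuples():
            annot[str(r.name)] = (float(getattr(r, "rt", math.nan)),
                                  float(getattr(r, "mz", math.nan)))
    metabolites = [
        Metabolite(c, *(annot.get(c, (math.nan, math.nan)))) for c in met_cols
    ]
    return PeakTable(samples, metabolites, areas, stage=stage)


def write_peak_table(table: PeakTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_delimiter(path, None), index=False)
    return path


def read_behavior_table(path: str | Path, dialect: str | None = None):
    """Read per-animal FST records (one row per animal, wide weeks)."""
    from .phenotype import FstRecord  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect))
    needed = ["animal_id", "arm"] + [
        f"{b}_w{w}" for b in ("immobility", "swimming", "climbing")
        for w in (0, 3, 6)
    ]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"behavior table {path}: missing column {col!r}")
    records = []
    for r in df.itertuples():
        records.append(FstRecord(
            animal_id=str(r.animal_id),
            arm=str(r.arm),
            immobility=(r.immobility_w0, r.immobility_w3, r.immobility_w6),
            swimming=(r.swimming_w0, r.swimming_w3, r.swimming_w6),
            climbing=(r.climbing_w0, r.climbing_w3, r.climbing_w6),
        ))
    return records


def write_behavior_table(records, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        row = {"animal_id": r.animal_id, "arm": r.arm}
        for b in ("immobility", "swimming", "climbing"):
            for w, v in zip((0, 3, 6), getattr(r, b)):
                row[f"{b}_w{w}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_delimiter(path, None), index=False)
    return path


# -- result records -------------------------------------------------------

#: column order per record kind, mirroring the published table layouts
_RESULT_COLUMNS = {
    "DemRecord": ["rt", "metabolite", "p_value", "p_adjusted", "fc",
                  "is_dem", "contrast"],
    "MarkerResult": ["metabolite", "auc", "fc", "direction", "cutoff",
                     "sensitivity_at_cutoff", "specificity_at_cutoff",
                     "ci_low", "ci_high", "passes_gate"],
    "CorrelationRecord": ["metabolite", "r", "p_value", "p_bh",
                          "significant", "flagged"],
    "ImportanceRecord": ["rank", "metabolite", "importance"],
    "PhenotypeLabel": ["animal_id", "label", "rationale"],
}

_KIND_FILENAMES = {
    "DemRecord": "dem_table",
    "MarkerResult": "marker_table",
    "CorrelationRecord": "correlation_table",
    "ImportanceRecord": "importance_table",
    "PhenotypeLabel": "phenotype_labels",
}


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    kind = type(records[0]).__name__
    cols = _RESULT_COLUMNS.get(kind)
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    if kind == "MarkerResult":
        df["ci_low"] = [r.ci95[0] for r in records]
        df["ci_high"] = [r.ci95[1] for r in records]
        df = df.drop(columns=["ci95"], errors="ignore")
    if cols:
        df = df[[c for c in cols if c in df.columns]]
    return df


def _round_sig(x, digits: int = REPORT_SIGDIGITS):
    if isinstance(x, float) and math.isfinite(x) and x != 0:
        return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
    return x


def write_result_tables(
    results: dict[str, Sequence], out_dir: str | Path
) -> list[Path]:
    """Write one delimited file per result kind plus a JSON summary.

    ``results`` maps a label (e.g. a contrast name) to a list of records of
    one dataclass kind.  Human-readable CSVs are rounded to 6 significant
    digits; the JSON summary keeps full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict[str, list] = {}
    for label, records in results.items():
        records = list(records)
        if records:
            kind = type(records[0]).__name__
            df = _records_to_frame(records)
        else:
            kind, df = "empty", pd.DataFrame()
        stem = _KIND_FILENAMES.get(kind, kind.lower())
        path = out_dir / f"{stem}_{label.replace(':', '_vs_')}.csv"
        rounded = df.map(_round_sig) if not df.empty else df
        rounded.to_csv(path, index=False)
        written.append(path)
        summary[label] = json.loads(df.to_json(orient="records"))
    summary_path = out_dir / "results_summary.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    written.append(summary_path)
    return written


def read_result_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read back a written result table as a DataFrame (round-trip check)."""
    df = pd.read_csv(Path(path))
    cols = _RESULT_COLUMNS.get(kind)
    if cols:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"result table {path}: missing columns {missing}")
    return df


# -- minimal mwTab reader --------------------------------------------------

def read_mwtab_peak_table(path: str | Path) -> PeakTable:
    """Map the ``MS_METABOLITE_DATA`` block of an mwTab file to a PeakTable.

    Treats any samples x named-metabolites numeric block as raw areas; the
    ``Samples`` line names the columns and the optional ``Factors`` line
    supplies group labels (the token after the last ``:`` of each factor
    cell).  Samples whose group is not one of the four study groups are kept
    as pooled QCs.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip() == "MS_METABOLITE_DATA_START")
        end = next(i for i, l in enumerate(lines)
                   if l.strip() == "MS_METABOLITE_DATA_END")
    except StopIteration as exc:
        raise SchemaError(f"{path}: no MS_METABOLITE_DATA block") from exc
    block = [l for l in lines[start + 1:end] if l.strip()]
    header = block[0].split("\t")
    sample_ids = [s.strip() for s in header[1:]]
    groups = [""] * len(sample_ids)
    data_rows = block[1:]
    if data_rows and data_rows[0].split("\t")[0].strip().lower() == "factors":
        groups = [c.split(":")[-1].strip().replace(" + ", "").replace("+", "")
                  for c in data_rows[0].split("\t")[1:]]
        data_rows = data_rows[1:]
    names, areas = [], []
    for row in data_rows:
        cells = row.split("\t")
        names.append(cells[0].strip())
        try:
            areas.append([float(c) if c.strip() else 0.0
                          for c in cells[1:len(sample_ids) + 1]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in metabolite "
                             f"{cells[0]!r}") from exc
    from .peaktable import GROUPS
    norm = {g.lower(): g for g in GROUPS}
    norm.update({"control+flx": "ControlFlx", "controlflx": "ControlFlx",
                 "csis+flx": "CSISFlx", "csisflx": "CSISFlx"})
    samples = []
    for i, sid in enumerate(sample_ids):
        g = norm.get(groups[i].lower().replace(" ", ""))
        if g is None:
            samples.append(SampleMeta(sid, "QC", role="qc_pooled",
                                      injection_order=i + 1))
        else:
            samples.append(SampleMeta(sid, g, injection_order=i + 1))
    matrix = np.asarray(areas, dtype=float).T  # block is metabolites x samples
    return PeakTable(samples, [Metabolite(n) for n in names], matrix, "raw")
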
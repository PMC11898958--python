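"""Readers and writers: retention tables, descriptor matrices,
validation reports and analysis configuration.

All delimited files are comma-separated UTF-8 with a header row and
decimal points.  Unicode minus signs (U+2212), as often produced by
copy-pasting from typeset tables, are normalised to ASCII on ingest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    CompoundRecord,
    DescriptorMatrix,
    GAConfig,
    RetentionTable,
)
from .datasets import organophosphate_table
from .validation import ValidationReport

__all__ = [
    "load_retention_table",
    "load_descriptor_matrix",
    "save_report",
    "load_report",
    "save_config",
    "load_config",
]

_REQUIRED_COLUMNS = ("name", "chi_c18", "chi_iam", "logk_hsa", "pct_hsa")


def _normalise_minus(df: pd.DataFrame) -> pd.DataFrame:
    return df.apply(
        lambda col: col.str.replace("−", "-", regex=False)
        if col.dtype == object else col
    )


def load_retention_table(source: str | Path) -> RetentionTable:
    """Load a chromatographic-index table.

    ``source`` is either the string ``"builtin:table1"`` (the packaged
    18-organophosphate table) or a path to a CSV file with columns
    ``name, chi_c18, chi_iam, logk_hsa, pct_hsa`` (``id`` and ``smiles``
    optional).
    """
    if str(source) == "builtin:table1":
        return organophosphate_table()
    path = Path(source)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, no header row") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = _normalise_minus(df)
    records = []
    for i, row in df.iterrows():
        numeric = {}
        for col in ("chi_c18", "chi_iam", "logk_hsa", "pct_hsa"):
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: non-numeric value {row[col]!r} at row {i + 1}, column {col!r}"
                ) from exc
        records.append(
            CompoundRecord(
                id=int(row["id"]) if "id" in df.columns else i + 1,
                name=str(row["name"]),
                smiles=str(row["smiles"]) if "smiles" in df.columns and pd.notna(row["smiles"]) else None,
                **numeric,
            )
        )
    return RetentionTable(records)


def load_descriptor_matrix(path: str | Path, provenance: dict | None = None) -> DescriptorMatrix:
    """Load a compound x descriptor CSV (first column = compound name).

    Rejects duplicate compound names and missing values: impute or drop
    upstream, explicitly.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no descriptor columns found")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate compound name(s) {dupes}")
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"{path}: missing value at compound {df.index[r]!r}, descriptor {df.columns[c]!r}"
        )
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric descriptor column(s) {bad}")
    return DescriptorMatrix(df, provenance=provenance)


def save_report(report: ValidationReport, path: str | Path) -> None:
    """Write a validation report as JSON plus a human-readable summary.

    The summary goes to ``<path>.txt`` next to the JSON file.
    """
    path = Path(path)
    payload = {
        "endpoint_name": report.endpoint_name,
        "metrics": report.metrics,
        "n_tr": report.n_tr,
        "n_ext": report.n_ext,
        "train_ids": list(report.train_ids),
        "ext_ids": list(report.ext_ids),
        "acceptable": report.acceptable,
        "vectors": {
            k: None if getattr(report, k) is None else [float(v) for v in getattr(report, k)]
            for k in ("y_obs_tr", "y_fit_tr", "y_cv", "y_obs_ext", "y_pred_ext")
        },
    }
    try:
        path.write_text(json.dumps(payload, indent=2))
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    lines = [
        f"QSRR validation report — endpoint {report.endpoint_name}",
        f"training n = {report.n_tr}, external n = {report.n_ext}",
        "",
    ]
    lines += [f"  {k:10s} = {v:.4f}" for k, v in report.metrics.items()]
    flags = report.acceptable
    lines += ["", f"acceptable (R2 > 0.6 and R2_EXT > 0.5): {flags['overall']}"]
    path.with_suffix(path.suffix + ".txt").write_text("\n".join(lines) + "\n")


def load_report(path: str | Path) -> ValidationReport:
    """Load a report written by :func:`save_report`."""
    payload = json.loads(Path(path).read_text())
    vec = {
        k: None if v is None else np.array(v, dtype=float)
        for k, v in payload["vectors"].items()
    }
    return ValidationReport(
        endpoint_name=payload["endpoint_name"],
        n_tr=payload["n_tr"],
        n_ext=payload["n_ext"],
        train_ids=payload["train_ids"],
        ext_ids=payload["ext_ids"],
        **payload["metrics"],
        **vec,
    )


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Serialise an AnalysisConfig to YAML (namespaced under ``ga``)."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig; unknown keys are an error (catches typos)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    ga_raw = raw.pop("ga", {})
    ga_known = {f.name for f in dataclasses.fields(GAConfig)}
    ga_unknown = set(ga_raw) - ga_known
    if ga_unknown:
        raise ValueError(f"{path}: unknown ga key(s) {sorted(ga_unknown)}")
    return AnalysisConfig(ga=GAConfig(**ga_raw), **raw)
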
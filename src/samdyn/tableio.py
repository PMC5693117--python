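"""Readers and writers for the delimited-table and BED dialects used here.

Tables are tab- or comma-delimited with a header (auto-detected on read;
writers always emit tab-delimited).  Units are encoded in column names
(``time_h`` is hours, ``time_d`` days).  Interval files follow BED
conventions: 0-based half-open, BED3/BED6 or narrowPeak-like with the summit
offset in the 10th column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ModelParameters

__all__ = [
    "TableSchema", "SCHEMAS", "read_table", "write_table",
    "read_bed", "write_bed", "read_genes_bed",
    "read_params_file", "write_params_file", "write_manifest",
]


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    monotone: tuple[str, ...] = ()           # strictly increasing columns
    non_negative: tuple[str, ...] = ()
    non_decreasing: tuple[str, ...] = ()


SCHEMAS = {
    "trajectory": TableSchema(
        "trajectory",
        required=("time_h", "cz_cells", "total_cells", "cz_ratio",
                  "n_unseparated", "organs_cum"),
        monotone=("time_h",),
        non_negative=("cz_cells", "total_cells", "n_unseparated"),
        non_decreasing=("organs_cum",),
    ),
    "observed": TableSchema(
        "observed",
        required=("time_d",),
        monotone=("time_d",),
    ),
    "nuclei": TableSchema(
        "nuclei",
        required=("id", "x", "y", "z", "layer"),
    ),
    "emergence": TableSchema(
        "emergence",
        required=("time_d", "organs_cum"),
        monotone=("time_d",),
        non_decreasing=("organs_cum",),
    ),
    "profile": TableSchema(
        "profile",
        required=("position_um", "intensity"),
        monotone=("position_um",),
    ),
}


class SchemaError(ValueError):
    pass


def read_table(path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a delimited table (separator auto-detected)."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for "
                          f"{schema.name} table")
    for col in schema.monotone:
        vals = df[col].to_numpy(float)
        bad = np.flatnonzero(np.diff(vals) <= 0)
        if len(bad):
            raise SchemaError(f"{path}: column {col!r} not strictly "
                              f"increasing at row {int(bad[0]) + 1}")
    for col in schema.non_decreasing:
        vals = df[col].to_numpy(float)
        bad = np.flatnonzero(np.diff(vals) < 0)
        if len(bad):
            raise SchemaError(f"{path}: column {col!r} decreases at row "
                              f"{int(bad[0]) + 1}")
    for col in schema.non_negative:
        vals = df[col].to_numpy(float)
        bad = np.flatnonzero(vals < 0)
        if len(bad):
            raise SchemaError(f"{path}: negative value in column {col!r} "
                              f"at row {int(bad[0])}")
    if schema.name == "nuclei":
        if df["id"].duplicated().any():
            raise SchemaError(f"{path}: duplicated nucleus ids")
        for col in df.columns:
            if col in ("id", "layer") or df[col].dtype == object:
                continue
            vals = df[col].to_numpy(float)
            if col not in ("x", "y", "z") and np.any(vals < 0):
                raise SchemaError(f"{path}: negative intensity in "
                                  f"column {col!r}")
            if not np.all(np.isfinite(vals)):
                raise SchemaError(f"{path}: non-finite value in {col!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table tab-delimited with header, stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


# ---------------------------------------------------------------- BED I/O
def read_bed(path, dialect: str = "auto") -> pd.DataFrame:
    """Read BED3/BED6/narrowPeak intervals into a DataFrame.

    narrowPeak files (10 columns) yield a ``summit`` column with the
    absolute summit position (start + offset; offset -1 means missing).
    A 4th column holding an integer is also accepted as a summit offset
    ("bed4-summit" dialect); otherwise it is kept as ``name``.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: need 0 <= start < end, "
                                 f"got [{start}, {end})")
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 10:                     # narrowPeak
                rec["name"] = parts[3]
                try:
                    rec["score"] = float(parts[4])
                except ValueError:
                    rec["score"] = np.nan
                rec["strand"] = parts[5] if parts[5] in "+-" else None
                offset = int(parts[9])
                rec["summit"] = start + offset if offset >= 0 else np.nan
            elif len(parts) >= 6:                    # BED6
                rec["name"] = parts[3]
                try:
                    rec["score"] = float(parts[4])
                except ValueError:
                    rec["score"] = np.nan
                rec["strand"] = parts[5]
            elif len(parts) == 4:
                if dialect == "bed4-summit":
                    try:
                        rec["summit"] = start + int(parts[3])
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{ln}: summit offset not an integer"
                        ) from exc
                else:
                    rec["name"] = parts[3]
            rows.append(rec)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    if "summit" in df.columns:
        off = df.index[(df["summit"].notna())
                       & ((df["summit"] < df["start"])
                          | (df["summit"] >= df["end"]))]
        if len(off):
            raise ValueError(f"{path}: summit outside interval at "
                             f"record(s) {list(off[:5])}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write intervals as BED; emits narrowPeak-style rows when a summit
    column is present."""
    has_summit = "summit" in df.columns
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if has_summit and not pd.isna(row["summit"]):
                name = row.get("name", ".") or "."
                fh.write(f"{row['chrom']}\t{start}\t{end}\t{name}\t0\t.\t"
                         f"0\t-1\t-1\t{int(row['summit']) - start}\n")
            elif "strand" in df.columns and not pd.isna(row.get("strand")):
                name = row.get("name", ".") or "."
                score = row.get("score", 0)
                score = 0 if pd.isna(score) else score
                fh.write(f"{row['chrom']}\t{start}\t{end}\t{name}\t"
                         f"{score:g}\t{row['strand']}\n")
            elif "name" in df.columns and not pd.isna(row.get("name")):
                fh.write(f"{row['chrom']}\t{start}\t{end}\t{row['name']}\n")
            else:
                fh.write(f"{row['chrom']}\t{start}\t{end}\n")


def read_genes_bed(path) -> pd.DataFrame:
    """Read gene models from BED6; the TSS is the strand-aware 5' end."""
    df = read_bed(path)
    if "strand" not in df.columns or df["strand"].isna().any():
        raise ValueError(f"{path}: gene models require a strand (BED6)")
    if not set(df["strand"]) <= {"+", "-"}:
        raise ValueError(f"{path}: strand must be '+' or '-'")
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = pd.DataFrame({"chrom": df["chrom"], "tss": tss,
                        "strand": df["strand"]})
    if "name" in df.columns:
        out["name"] = df["name"]
    return out


# ------------------------------------------------------- config & manifest
def read_params_file(path) -> ModelParameters:
    """Read model parameters from a flat key = value file."""
    overrides = {}
    valid = set(ModelParameters().to_dict())
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'name = value'")
            key, value = (tok.strip() for tok in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{ln}: unknown parameter {key!r}")
            if key == "initiation_mode":
                overrides[key] = value
            elif value.lower() in ("none", ""):
                overrides[key] = None
            else:
                overrides[key] = float(value)
    return ModelParameters(**overrides)


def write_params_file(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        for key, value in params.to_dict().items():
            fh.write(f"{key} = {value}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_prefix, config: dict, inputs=(), outputs=()) -> Path:
    """Write a JSON run manifest (config, seed, input/output checksums)."""
    manifest = {
        "config": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                       else str(v)) for k, v in config.items()},
        "inputs": {str(p): _sha256(Path(p)) for p in inputs
                   if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs
                    if Path(p).exists()},
    }
    path = Path(f"{out_prefix}.manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
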
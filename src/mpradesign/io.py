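"""Readers and writers for the pipeline's text formats.

Variant tables, cohorts and score matrices are tab-separated text with a
header; tracks are bedGraph-like 4-column text (chrom, 0-based start, end,
value); evaluation reports are JSON.  Missing required columns raise
:class:`~mpradesign.errors.SchemaError` naming the column; all round-trips
are lossless up to float formatting (full precision is written).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MatchedCohort
from .errors import SchemaError

VARIANT_COLUMNS = ("CHROM", "POS", "REF", "ALT", "AF", "TSS_SCORE")
COHORT_COLUMNS = VARIANT_COLUMNS + ("GROUP", "ROLE", "RELAXED")


def _require(df: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}", column=col)


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="VARIANT_ID", float_format="%.17g")


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="VARIANT_ID", float_precision="round_trip")
    _require(df, VARIANT_COLUMNS, f"variant table {path}")
    return df


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="VARIANT_ID", float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="VARIANT_ID", float_precision="round_trip")


def write_cohort(cohort: MatchedCohort, path) -> None:
    meta = {"ratio": cohort.ratio, "n_af_bins": cohort.n_af_bins}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        cohort.records.to_csv(fh, sep="\t", index=True, index_label="VARIANT_ID", float_format="%.17g")


def read_cohort(path) -> MatchedCohort:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        df = pd.read_csv(fh, sep="\t", index_col="VARIANT_ID", float_precision="round_trip")
    _require(df, COHORT_COLUMNS, f"cohort table {path}")
    relaxed = list(df.loc[df["RELAXED"] & (df["ROLE"] == "positive")].index.unique())
    return MatchedCohort(
        records=df,
        ratio=int(meta.get("ratio", 10)),
        n_af_bins=int(meta.get("n_af_bins", 100)),
        relaxed_groups=relaxed,
    )


def write_track(values, path, chrom: str = "chr1", start: int = 0, step: int = 1) -> None:
    """bedGraph-like 4-column text; intervals are 0-based half-open."""
    values = np.asarray(values, dtype=float)
    starts = start + step * np.arange(values.size)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + step, "value": values})
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.17g")


def read_track(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Returns (intervals frame, dense value array) for a constant-step track."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"track file {path} is empty")
    return df, df["value"].to_numpy()


def write_neighborhoods(arr: np.ndarray, variant_ids, path) -> None:
    """Flatten (n, markers, bins) to TSV columns M{m}_B{b} with a variant index."""
    n, m, b = arr.shape
    cols = [f"M{i}_B{j}" for i in range(m) for j in range(b)]
    df = pd.DataFrame(arr.reshape(n, m * b), index=variant_ids, columns=cols)
    df.attrs["shape"] = (m, b)
    df.to_csv(path, sep="\t", index=True, index_label="VARIANT_ID", float_format="%.17g")


def read_neighborhoods(path) -> tuple[np.ndarray, pd.Index]:
    df = pd.read_csv(path, sep="\t", index_col="VARIANT_ID", float_precision="round_trip")
    markers = len({c.split("_")[0] for c in df.columns})
    bins = df.shape[1] // markers
    return df.to_numpy().reshape(len(df), markers, bins), df.index


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")
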
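"""Read/write AIRR rearrangement TSVs, sample sheets and clone tables.

The rearrangement reader targets the AIRR community rearrangement schema
(``v_call``, ``j_call``, ``junction_aa``, ``productive``,
``duplicate_count``) but accepts a column-name *dialect* mapping so that
tool-flavoured exports load without preprocessing.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tcrtissue.types import (
    CLONE_COLUMNS,
    CLONE_KEY,
    CloneTable,
    SampleMeta,
    SampleSheetError,
    check_unique_coordinates,
)

logger = logging.getLogger(__name__)

#: canonical field -> acceptable source column names, in priority order
DEFAULT_DIALECT: Mapping[str, Sequence[str]] = {
    "sequence_id": ("sequence_id",),
    "v_call": ("v_call",),
    "j_call": ("j_call",),
    "cdr3_aa": ("junction_aa", "cdr3_aa"),
    "productive": ("productive",),
    "duplicate_count": ("duplicate_count",),
}

_ALLELE_SUFFIX = re.compile(r"\*\d+$")
_TRUE_TOKENS = {"t", "true", "1", "yes", "y"}
_FALSE_TOKENS = {"f", "false", "0", "no", "n"}


def normalize_gene_call(call: str, gene_level: bool = True) -> str:
    """Normalize a V/J gene call.

    Ambiguous comma-separated calls keep the first listed gene; at
    gene-level granularity the IMGT allele suffix (``*NN``) is stripped.
    """
    first = str(call).split(",")[0].strip()
    if gene_level:
        first = _ALLELE_SUFFIX.sub("", first)
    return first


def _parse_productive(value) -> bool | None:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    return None


def read_rearrangements(
    path: str | Path,
    dialect: Mapping[str, Sequence[str] | str] | None = None,
    gene_level: bool = True,
) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV into a normalized DataFrame.

    Returns a frame with columns ``sequence_id, v_call, j_call, cdr3_aa,
    productive, duplicate_count``. Gene calls are normalized (first gene of
    an ambiguous call; allele suffix stripped when ``gene_level``). Rows
    whose ``duplicate_count`` or ``productive`` cannot be parsed are
    skipped with a warning; the counts are recorded in
    ``df.attrs["n_skipped"]`` and ``df.attrs["n_ambiguous_calls"]`` so that
    rows_in == rows_out + skipped.

    Raises
    ------
    ValueError
        If a mandatory column cannot be resolved through the dialect.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    df = normalize_rearrangements(raw, dialect=dialect, gene_level=gene_level)
    if df.attrs["n_skipped"]:
        logger.warning("%s: skipped %d unparseable rows", path, df.attrs["n_skipped"])
    if df.empty:
        logger.warning("%s: no usable rearrangement rows", path)
    return df


def normalize_rearrangements(
    raw: pd.DataFrame,
    dialect: Mapping[str, Sequence[str] | str] | None = None,
    gene_level: bool = True,
) -> pd.DataFrame:
    """Normalize an in-memory AIRR rearrangement frame (same contract as
    :func:`read_rearrangements`, minus the file read)."""
    resolved_dialect = dict(DEFAULT_DIALECT)
    if dialect:
        for key, cols in dialect.items():
            resolved_dialect[key] = (cols,) if isinstance(cols, str) else tuple(cols)

    n_in = len(raw)

    columns: dict[str, str] = {}
    for field, candidates in resolved_dialect.items():
        found = next((c for c in candidates if c in raw.columns), None)
        if found is None:
            if field == "sequence_id":
                continue  # optional; synthesized below
            raise ValueError(
                f"mandatory column for {field!r} not found; tried {list(candidates)}"
            )
        columns[field] = found

    df = pd.DataFrame(index=raw.index)
    if "sequence_id" in columns:
        df["sequence_id"] = raw[columns["sequence_id"]]
    else:
        df["sequence_id"] = [f"row{i}" for i in range(n_in)]

    n_ambiguous = int(raw[columns["v_call"]].fillna("").str.contains(",").sum())
    n_ambiguous += int(raw[columns["j_call"]].fillna("").str.contains(",").sum())
    df["v_call"] = raw[columns["v_call"]].map(
        lambda c: normalize_gene_call(c, gene_level)
    )
    df["j_call"] = raw[columns["j_call"]].map(
        lambda c: normalize_gene_call(c, gene_level)
    )
    df["cdr3_aa"] = raw[columns["cdr3_aa"]].fillna("").str.strip().str.upper()
    df["productive"] = raw[columns["productive"]].map(_parse_productive)
    df["duplicate_count"] = pd.to_numeric(
        raw[columns["duplicate_count"]], errors="coerce"
    )

    bad = (
        df["productive"].isna()
        | df["duplicate_count"].isna()
        | (df["duplicate_count"] < 1)
    )
    n_skipped = int(bad.sum())
    df = df.loc[~bad].copy()
    df["productive"] = df["productive"].astype(bool)
    df["duplicate_count"] = df["duplicate_count"].astype(int)
    df = df.reset_index(drop=True)

    df.attrs["n_input_rows"] = n_in
    df.attrs["n_skipped"] = n_skipped
    df.attrs["n_ambiguous_calls"] = n_ambiguous
    return df


_SHEET_COLUMNS = ["sample_id", "donor_id", "age", "lineage", "subset", "tissue", "replicate"]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a TSV/CSV sample sheet into validated :class:`SampleMeta` records.

    Hard errors: missing columns, duplicated (donor, lineage, subset,
    tissue, replicate) coordinates, unknown lineage/subset tokens,
    replicate < 1.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in raw.columns]
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {missing}")
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            donor_id=row.donor_id,
            age=int(row.age),
            lineage=row.lineage,
            subset=row.subset,
            tissue=row.tissue,
            replicate=int(row.replicate),
        )
        for row in raw.itertuples()
    ]
    check_unique_coordinates(samples)
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "donor_id": s.donor_id,
                "age": s.age,
                "lineage": s.lineage,
                "subset": s.subset,
                "tissue": s.tissue,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def write_clone_tables(tables: Iterable[CloneTable] | CloneTable, path: str | Path) -> None:
    """Write clone tables as one TSV with columns
    ``sample_id, v_call, j_call, cdr3_aa, copies, frequency``."""
    if isinstance(tables, CloneTable):
        tables = [tables]
    frames = []
    for t in tables:
        df = t.df.loc[:, CLONE_COLUMNS].copy()
        df.insert(0, "sample_id", t.sample.sample_id)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["sample_id"] + CLONE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_clone_tables(
    path: str | Path, samples: Mapping[str, SampleMeta]
) -> list[CloneTable]:
    """Read a clone-table TSV back into per-sample :class:`CloneTable`s.

    ``samples`` maps sample_id -> metadata (e.g. from the sample sheet).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"copies": int, "frequency": float}, keep_default_na=False
    )
    tables = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        if sample_id not in samples:
            raise KeyError(f"sample {sample_id!r} absent from sample metadata")
        tables.append(
            CloneTable(
                sample=samples[sample_id],
                df=group.loc[:, CLONE_KEY + ["copies", "frequency"]].reset_index(
                    drop=True
                ),
            )
        )
    return tables
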
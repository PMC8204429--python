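"""Clone assembly and abundance filters.

A clone is the set of rearrangements sharing identical TRBV and TRBJ gene
calls and CDR3 amino-acid sequence. A unique sequence must be detected at
least twice (``min_copies=2``) to be called a clone, which suppresses
spurious singletons created by sequencing error.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from tcrtissue.types import CLONE_KEY, CloneTable, SampleMeta

logger = logging.getLogger(__name__)


def remove_nonproductive(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose rearrangement is not productive.

    Expects a ``productive`` boolean column; the number removed is logged.
    """
    keep = records["productive"].astype(bool)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d non-productive records", n_removed)
    out = records.loc[keep].reset_index(drop=True)
    if out.empty and n_removed:
        logger.warning("all records were non-productive")
    return out


def assemble_clones(
    records: pd.DataFrame,
    sample: SampleMeta,
    min_copies: int = 2,
    productive_only: bool = True,
) -> CloneTable:
    """Collapse one sample's annotated rearrangements into clones.

    Records are grouped by (v_call, j_call, cdr3_aa); a group's copy number
    is the sum of its records' ``duplicate_count``. Groups with fewer than
    ``min_copies`` copies are discarded and frequencies are computed over
    the retained copies.
    """
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    if productive_only and not records.empty:
        records = remove_nonproductive(records)
    if records.empty:
        return CloneTable(sample=sample)

    grouped = (
        records.groupby(CLONE_KEY, sort=False)["duplicate_count"]
        .sum()
        .reset_index()
        .rename(columns={"duplicate_count": "copies"})
    )
    kept = grouped.loc[grouped["copies"] >= min_copies]
    if kept.empty:
        logger.warning(
            "%s: all %d candidate clones fell below min_copies=%d",
            sample.sample_id,
            len(grouped),
            min_copies,
        )
        return CloneTable(sample=sample)
    return CloneTable.from_counts(sample, kept)


def copy_cutoff_filter(table: CloneTable, fraction: float = 0.5) -> CloneTable:
    """Remove clones below ``fraction`` of the sample's mean copy number.

    The threshold is ``fraction * total_copies / n_clones``, computed once
    on the input table (single pass, not iterated); clones strictly below
    it are removed and frequencies re-normalized over the survivors. Ties
    at exactly the threshold survive.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if table.n_clones == 0:
        return table
    threshold = fraction * table.total_copies / table.n_clones
    kept = table.df.loc[table.df["copies"] >= threshold, CLONE_KEY + ["copies"]]
    return CloneTable.from_counts(table.sample, kept)


def donor_min_copies_filter(
    tables: Sequence[CloneTable], min_copies: int = 2
) -> list[CloneTable]:
    """Alternative evidence scope: require ``min_copies`` copies of a clone
    summed across all of a donor's samples rather than within each library.

    Each table should first be assembled with ``min_copies=1``; clone keys
    whose donor-wide copy total falls below ``min_copies`` are removed from
    every table of that donor and frequencies re-normalized.
    """
    by_donor: dict[str, list[CloneTable]] = {}
    for t in tables:
        by_donor.setdefault(t.sample.donor_id, []).append(t)
    out: list[CloneTable] = []
    for donor_tables in by_donor.values():
        totals = (
            pd.concat([t.df[CLONE_KEY + ["copies"]] for t in donor_tables])
            .groupby(CLONE_KEY)["copies"]
            .sum()
        )
        keep_keys = set(totals.index[totals >= min_copies])
        for t in donor_tables:
            mask = [
                tuple(row) in keep_keys
                for row in t.df[CLONE_KEY].itertuples(index=False)
            ]
            out.append(
                CloneTable.from_counts(t.sample, t.df.loc[mask, CLONE_KEY + ["copies"]])
                if any(mask)
                else CloneTable(sample=t.sample)
            )
    return out


def assemble_sample_tables(
    records_by_sample: dict[str, pd.DataFrame],
    samples: Iterable[SampleMeta],
    min_copies: int = 2,
    productive_only: bool = True,
) -> list[CloneTable]:
    """Assemble a clone table for every sample in a cohort."""
    sample_map = {s.sample_id: s for s in samples}
    return [
        assemble_clones(
            records_by_sample[sid], sample_map[sid], min_copies, productive_only
        )
        for sid in sample_map
        if sid in records_by_sample
    ]
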
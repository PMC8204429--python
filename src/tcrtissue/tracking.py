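"""Clone tracking across tissue sites: per-clone copies per site and the
subset composition of each site's copies (the data behind line-circle
plots)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from tcrtissue.types import CLONE_KEY, CloneTable

logger = logging.getLogger(__name__)


def _donor_frame(
    tables: Sequence[CloneTable], lineage: str | None, replicate_1_only: bool
) -> pd.DataFrame:
    frames = []
    for t in tables:
        s = t.sample
        if lineage is not None and s.lineage != lineage:
            continue
        if replicate_1_only and s.replicate != 1:
            continue
        df = t.df[CLONE_KEY + ["copies"]].copy()
        df["donor_id"] = s.donor_id
        df["tissue"] = s.tissue
        df["subset"] = s.subset
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=CLONE_KEY + ["copies", "donor_id", "tissue", "subset"])
    out = pd.concat(frames, ignore_index=True)
    donors = out["donor_id"].unique()
    if len(donors) > 1:
        raise ValueError(f"expected one donor, got {list(donors)}")
    return out


def top_clones(
    tables: Sequence[CloneTable],
    n: int = 500,
    lineage: str | None = None,
    replicate_1_only: bool = False,
) -> pd.DataFrame:
    """Rank one donor(+lineage)'s clones by total copies over all samples.

    Replicates are summed within a sample by default (restrict with
    ``replicate_1_only``). Ties are broken by clone key lexicographically,
    so the ranking is invariant to input order. Returns the top ``n``
    (or all, if fewer) as a frame with columns v_call, j_call, cdr3_aa,
    total_copies.
    """
    df = _donor_frame(tables, lineage, replicate_1_only)
    if df.empty:
        return pd.DataFrame(columns=CLONE_KEY + ["total_copies"])
    totals = (
        df.groupby(CLONE_KEY, as_index=False)["copies"]
        .sum()
        .rename(columns={"copies": "total_copies"})
        .sort_values(
            ["total_copies"] + CLONE_KEY, ascending=[False, True, True, True]
        )
        .reset_index(drop=True)
    )
    return totals.head(n)


@dataclass
class CloneTrack:
    """One clone's distribution across sites for one donor.

    ``site_copies`` maps tissue -> total copies; ``subset_fractions`` is a
    long frame (tissue, subset, copies, fraction) where fractions sum to 1
    within each site with non-zero copies. ``site_repertoire_fraction``
    maps tissue -> this clone's share of the site's total copies.
    """

    clone: tuple[str, str, str]
    donor_id: str | None
    site_copies: dict = field(default_factory=dict)
    subset_fractions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tissue", "subset", "copies", "fraction"]
        )
    )
    site_repertoire_fraction: dict = field(default_factory=dict)

    @property
    def total_copies(self) -> int:
        return int(sum(self.site_copies.values()))

    @property
    def present_sites(self) -> list[str]:
        return sorted(self.site_copies)


def track_clone(
    clone: tuple[str, str, str],
    tables: Sequence[CloneTable],
    lineage: str | None = None,
    replicate_1_only: bool = False,
) -> CloneTrack:
    """Aggregate one clone's copies per site and subset for one donor.

    Copies are summed per site across subsets and replicates; subset
    fractions are subset copies / site copies. A clone absent from the
    donor yields an empty track.
    """
    df = _donor_frame(tables, lineage, replicate_1_only)
    site_totals = df.groupby("tissue")["copies"].sum()
    mask = (
        (df["v_call"] == clone[0])
        & (df["j_call"] == clone[1])
        & (df["cdr3_aa"] == clone[2])
    )
    hits = df.loc[mask]
    donor = df["donor_id"].iloc[0] if not df.empty else None
    if hits.empty:
        logger.info("clone %s absent from donor", clone)
        return CloneTrack(clone=clone, donor_id=donor)
    site_copies = hits.groupby("tissue")["copies"].sum()
    by_subset = hits.groupby(["tissue", "subset"], as_index=False)["copies"].sum()
    by_subset["fraction"] = by_subset["copies"] / by_subset["tissue"].map(site_copies)
    return CloneTrack(
        clone=clone,
        donor_id=donor,
        site_copies=site_copies.to_dict(),
        subset_fractions=by_subset,
        site_repertoire_fraction=(site_copies / site_totals.loc[site_copies.index]).to_dict(),
    )


def clone_tracking_table(
    tables: Sequence[CloneTable],
    n: int = 500,
    lineage: str | None = None,
    replicate_1_only: bool = False,
) -> pd.DataFrame:
    """Long tracking table for the top ``n`` clones of one donor(+lineage):
    one row per (clone, site, subset) with copies and the subset's fraction
    of the site's copies for that clone."""
    ranked = top_clones(tables, n=n, lineage=lineage, replicate_1_only=replicate_1_only)
    rows = []
    for rank, key in enumerate(ranked[CLONE_KEY].itertuples(index=False), start=1):
        track = track_clone(tuple(key), tables, lineage, replicate_1_only)
        for rec in track.subset_fractions.itertuples(index=False):
            rows.append(
                {
                    "rank": rank,
                    "v_call": key.v_call,
                    "j_call": key.j_call,
                    "cdr3_aa": key.cdr3_aa,
                    "tissue": rec.tissue,
                    "subset": rec.subset,
                    "copies": rec.copies,
                    "fraction_of_site_copies": rec.fraction,
                    "site_repertoire_fraction": track.site_repertoire_fraction[rec.tissue],
                }
            )
    return pd.DataFrame(rows)
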
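"""Core containers: sample metadata and per-sample clone tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

LINEAGES = ("CD4", "CD8")
SUBSETS = ("TCM", "TEM", "TRM", "TEMRA")
#: default anatomic sites; extensible via the sample sheet
TISSUES = ("Bld", "BM", "Spl", "LN", "Lung")

#: columns that define a clone within a sample
CLONE_KEY = ["v_call", "j_call", "cdr3_aa"]
CLONE_COLUMNS = CLONE_KEY + ["copies", "frequency"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# subset x lineage combinations that are not sorted (low-frequency
# populations); their appearance is a validation warning, not an error
UNSORTED_COMBINATIONS = {("CD4", "TEMRA"), ("CD8", "TCM")}


class SampleSheetError(ValueError):
    """Raised when a sample sheet violates a hard constraint."""


@dataclass(frozen=True)
class SampleMeta:
    """Coordinates of one sorted-cell sequencing library.

    Parameters
    ----------
    sample_id
        Unique library identifier.
    donor_id
        Donor the cells came from.
    age
        Donor age in years.
    lineage
        ``"CD4"`` or ``"CD8"``.
    subset
        Memory subset: ``"TCM"``, ``"TEM"``, ``"TRM"`` or ``"TEMRA"``.
    tissue
        Anatomic site (``"Bld"``, ``"BM"``, ``"Spl"``, ``"LN"``, ``"Lung"``
        by default; other site labels are accepted).
    replicate
        Biological replicate number (>= 1); replicates are separate DNA
        aliquots of the same sorted-cell pool.
    """

    sample_id: str
    donor_id: str
    age: int
    lineage: str
    subset: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise SampleSheetError(
                f"unknown lineage {self.lineage!r}; accepted: {', '.join(LINEAGES)}"
            )
        if self.subset not in SUBSETS:
            raise SampleSheetError(
                f"unknown subset {self.subset!r}; accepted: {', '.join(SUBSETS)}"
            )
        if self.replicate < 1:
            raise SampleSheetError(
                f"replicate must be >= 1, got {self.replicate} for {self.sample_id!r}"
            )
        if (self.lineage, self.subset) in UNSORTED_COMBINATIONS:
            warnings.warn(
                f"{self.sample_id!r}: {self.lineage} {self.subset} is not a "
                "sorted subset x lineage combination",
                stacklevel=2,
            )

    @property
    def coordinates(self) -> tuple[str, str, str, str, int]:
        return (self.donor_id, self.lineage, self.subset, self.tissue, self.replicate)


@dataclass
class CloneTable:
    """Clones of one sample: unique (v_call, j_call, cdr3_aa) keys with
    copy counts and within-sample frequencies.

    ``df`` has columns ``v_call, j_call, cdr3_aa, copies, frequency``;
    frequencies sum to 1 over a non-empty table.
    """

    sample: SampleMeta
    df: pd.DataFrame = field(default_factory=lambda: _empty_clone_frame())

    def __post_init__(self) -> None:
        missing = [c for c in CLONE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"clone table missing columns: {missing}")
        if self.df.duplicated(CLONE_KEY).any():
            raise ValueError("duplicate clone keys within a sample")

    @property
    def n_clones(self) -> int:
        return len(self.df)

    @property
    def total_copies(self) -> int:
        return int(self.df["copies"].sum())

    @classmethod
    def from_counts(cls, sample: SampleMeta, df: pd.DataFrame) -> "CloneTable":
        """Build a table from clone keys + copies, computing frequencies."""
        df = df.loc[:, CLONE_KEY + ["copies"]].copy()
        total = df["copies"].sum()
        df["frequency"] = df["copies"] / total if total > 0 else np.nan
        df = df.sort_values(
            ["copies"] + CLONE_KEY, ascending=[False, True, True, True]
        ).reset_index(drop=True)
        return cls(sample=sample, df=df)

    def with_df(self, df: pd.DataFrame) -> "CloneTable":
        return replace(self, df=df.reset_index(drop=True))

    def frequency_vector(self) -> pd.Series:
        """Clone frequencies indexed by the (v_call, j_call, cdr3_aa) key."""
        return pd.Series(
            self.df["frequency"].to_numpy(),
            index=pd.MultiIndex.from_frame(self.df[CLONE_KEY]),
        )


def _empty_clone_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "v_call": pd.Series(dtype=str),
            "j_call": pd.Series(dtype=str),
            "cdr3_aa": pd.Series(dtype=str),
            "copies": pd.Series(dtype=int),
            "frequency": pd.Series(dtype=float),
        }
    )


def check_unique_coordinates(samples: Iterable[SampleMeta]) -> None:
    seen: dict[tuple, str] = {}
    for s in samples:
        if s.coordinates in seen:
            raise SampleSheetError(
                f"duplicate sample coordinates {s.coordinates} "
                f"({seen[s.coordinates]!r} and {s.sample_id!r})"
            )
        seen[s.coordinates] = s.sample_id
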
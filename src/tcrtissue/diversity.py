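"""Clonal diversity: normalized-entropy clonality, top-N clone
proportions, and clonality-versus-age regression.

Clonality of a sample with clone frequencies ``p(x)`` over ``L`` unique
clones is ``1 - H(p) / log2(L)`` where ``H`` is the Shannon entropy in
bits: 0 for a maximally diverse (uniform) repertoire, 1 for a monoclonal
one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tcrtissue.types import CloneTable, SampleMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClonalityResult:
    sample: SampleMeta | None
    clonality: float
    entropy_bits: float
    n_clones: int


def clonality(
    counts: Sequence[float] | np.ndarray, sample: SampleMeta | None = None
) -> ClonalityResult:
    """Normalized-entropy clonality of a sample's clone copy counts.

    ``clonality = 1 - H / log2(L)`` with ``H = -sum p log2 p``. For a
    single clone (L = 1) the ratio is 0/0; a monoclonal sample is defined
    as maximally clonal (clonality 1).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no clones")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    entropy_bits = float(stats.entropy(counts, base=2))
    if counts.size == 1:
        logger.info("monoclonal sample: clonality defined as 1")
        value = 1.0
    else:
        value = 1.0 - entropy_bits / np.log2(counts.size)
    return ClonalityResult(
        sample=sample,
        clonality=float(value),
        entropy_bits=entropy_bits,
        n_clones=int(counts.size),
    )


def clonality_of_table(table: CloneTable) -> ClonalityResult:
    return clonality(table.df["copies"].to_numpy(), sample=table.sample)


def _band_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"top {edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


def top_n_fraction(
    table: CloneTable | Sequence[float],
    edges: Sequence[int] = (10, 100, 1000),
) -> pd.Series:
    """Fraction of a sample's copies held by rank bands of its clones.

    Clones are ranked by copies descending; rank ties are broken by CDR3
    (then V/J) lexicographic order for reproducibility. With the default
    edges the bands are ``top 10``, ``11-100``, ``101-1000``, ``>1000``.
    Bands beyond the clone count carry fraction 0; fractions sum to 1.
    """
    if isinstance(table, CloneTable):
        df = table.df.sort_values(
            ["copies", "cdr3_aa", "v_call", "j_call"],
            ascending=[False, True, True, True],
        )
        counts = df["copies"].to_numpy(dtype=float)
    else:
        counts = np.sort(np.asarray(table, dtype=float))[::-1]
    if counts.size == 0:
        raise ValueError("no clones")
    total = counts.sum()
    cuts = [0] + [min(int(e), counts.size) for e in edges] + [counts.size]
    fractions = [counts[lo:hi].sum() / total for lo, hi in zip(cuts[:-1], cuts[1:])]
    return pd.Series(fractions, index=_band_labels(list(edges)), name="fraction")


def clonality_frame(results: Sequence[ClonalityResult]) -> pd.DataFrame:
    """Tidy one-row-per-sample frame of clonality results with metadata."""
    rows = []
    for r in results:
        s = r.sample
        rows.append(
            {
                "sample_id": s.sample_id if s else None,
                "donor_id": s.donor_id if s else None,
                "age": s.age if s else None,
                "lineage": s.lineage if s else None,
                "subset": s.subset if s else None,
                "tissue": s.tissue if s else None,
                "replicate": s.replicate if s else None,
                "clonality": r.clonality,
                "entropy_bits": r.entropy_bits,
                "n_clones": r.n_clones,
            }
        )
    return pd.DataFrame(rows)


def clonality_vs_age(
    results: pd.DataFrame, group_by: Sequence[str] = ("lineage", "subset")
) -> pd.DataFrame:
    """Ordinary least-squares regression of clonality on donor age.

    One fit per ``group_by`` cell (default lineage x subset, pooling all
    tissue sites); every sample is one point. Returns slope (clonality
    units per year), intercept, two-sided p-value for slope = 0, the
    slope's standard error, R^2 and n. Groups with fewer than 3 samples or
    no age variation are skipped with a warning.
    """
    rows = []
    for keys, group in results.groupby(list(group_by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        if len(group) < 3:
            logger.warning("group %s skipped: fewer than 3 samples", keys)
            continue
        if group["age"].nunique() < 2:
            logger.warning("group %s skipped: constant age", keys)
            continue
        if group["clonality"].nunique() == 1:
            # constant response: flat fit, no evidence against slope = 0
            fit_row = {
                "slope": 0.0,
                "intercept": float(group["clonality"].iloc[0]),
                "p_value": 1.0,
                "stderr": 0.0,
                "r_squared": 0.0,
            }
        else:
            fit = stats.linregress(group["age"], group["clonality"])
            fit_row = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "p_value": fit.pvalue,
                "stderr": fit.stderr,
                "r_squared": fit.rvalue**2,
            }
        rows.append(dict(zip(group_by, keys)) | fit_row | {"n": len(group)})
    return pd.DataFrame(rows)
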
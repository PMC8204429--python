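"""TRBV gene usage: per-sample percentages of unique clones, gene x sample
matrices with per-gene standardization for heatmaps/PCA, and CD4-vs-CD8
usage comparison."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tcrtissue.clones import copy_cutoff_filter
from tcrtissue.types import CloneTable

logger = logging.getLogger(__name__)


def trbv_usage(table: CloneTable, apply_cutoff: bool = True) -> pd.Series:
    """Percent of a sample's unique clones using each TRBV gene.

    Each unique clone counts once regardless of copy number. When
    ``apply_cutoff`` the 50%-of-mean copy-number filter
    (:func:`tcrtissue.clones.copy_cutoff_filter`) is applied first.
    Percentages sum to 100 over the genes present.
    """
    if apply_cutoff:
        table = copy_cutoff_filter(table)
    if table.n_clones == 0:
        logger.warning("empty clone table: no TRBV usage")
        return pd.Series(dtype=float, name=table.sample.sample_id)
    counts = table.df["v_call"].value_counts()
    usage = 100.0 * counts / counts.sum()
    usage.name = table.sample.sample_id
    return usage.sort_index()


def usage_matrix(
    tables: Sequence[CloneTable],
    scale: bool = False,
    apply_cutoff: bool = True,
    ddof: int = 1,
) -> pd.DataFrame:
    """TRBV usage matrix: genes as rows, samples as columns.

    Raw values are per-sample percentages (columns sum to 100); genes
    absent from a sample are 0. With ``scale`` each gene (row) is centered
    and scaled to a z-score across samples using the sample-SD (``ddof=1``)
    convention; zero-variance genes map to 0 rather than NaN.
    """
    if len(tables) < 2:
        raise ValueError("usage_matrix requires at least 2 samples")
    cols = [trbv_usage(t, apply_cutoff=apply_cutoff) for t in tables]
    mat = pd.concat(cols, axis=1).fillna(0.0).sort_index()
    if not scale:
        return mat
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=ddof)
    z = mat.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def lineage_usage_comparison(
    usage: pd.DataFrame,
    lineages: Mapping[str, str],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-gene CD4-vs-CD8 usage comparison across samples.

    ``usage`` is a raw (unscaled) gene x sample percentage matrix;
    ``lineages`` maps sample_id -> "CD4"/"CD8". Returns per gene the mean
    and standard error of usage in each lineage and a two-sided two-sample
    t-test p-value; genes with fewer than 2 samples in either lineage are
    skipped. ``adjust`` optionally applies a statsmodels multiple-testing
    correction (e.g. ``"holm"``, ``"fdr_bh"``) in a ``p_adjusted`` column.
    """
    cd4 = [s for s in usage.columns if lineages[s] == "CD4"]
    cd8 = [s for s in usage.columns if lineages[s] == "CD8"]
    rows = []
    for gene, row in usage.iterrows():
        a, b = row[cd4].to_numpy(float), row[cd8].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.info("gene %s skipped: <2 samples in a lineage", gene)
            continue
        t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "gene": gene,
                "cd4_mean": a.mean(),
                "cd4_se": stats.sem(a),
                "cd4_n": len(a),
                "cd8_mean": b.mean(),
                "cd8_se": stats.sem(b),
                "cd8_n": len(b),
                "t_statistic": t,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    return out
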
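"""Repertoire overlap as cosine similarity between clone-frequency
vectors, with replicate averaging, per-donor matrices and compiled
cross-donor group summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import squareform

from tcrtissue.clones import copy_cutoff_filter
from tcrtissue.types import CloneTable, SampleMeta

logger = logging.getLogger(__name__)


def cosine(freq_a: Mapping | pd.Series, freq_b: Mapping | pd.Series) -> float:
    """Cosine similarity of two clone-frequency vectors over the union of
    clone keys: sum(a_i * b_i) / (||a|| * ||b||)."""
    a = pd.Series(freq_a, dtype=float)
    b = pd.Series(freq_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("frequencies must be non-negative")
    union = a.index.union(b.index)
    av = a.reindex(union, fill_value=0.0).to_numpy()
    bv = b.reindex(union, fill_value=0.0).to_numpy()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(av @ bv / (na * nb))


@dataclass(frozen=True)
class PairCosine:
    cosine_mean: float
    n_replicate_pairs: int


def sample_pair_cosine(
    replicates_a: Sequence[CloneTable],
    replicates_b: Sequence[CloneTable],
    apply_cutoff: bool = True,
) -> PairCosine:
    """Replicate-averaged cosine similarity between two samples.

    With two replicates per sample this is the mean of the four pairwise
    replicate comparisons cos(A1,B1), cos(A1,B2), cos(A2,B1), cos(A2,B2).
    The 50%-of-mean copy cutoff is applied to each replicate table
    separately before computing frequencies. A missing replicate degrades
    gracefully to the available pairs (recorded in ``n_replicate_pairs``).
    """
    if not replicates_a or not replicates_b:
        raise ValueError("each sample needs at least one replicate table")
    if len(replicates_a) < 2 or len(replicates_b) < 2:
        logger.warning("missing replicate: averaging over available pairs only")
    if apply_cutoff:
        replicates_a = [copy_cutoff_filter(t) for t in replicates_a]
        replicates_b = [copy_cutoff_filter(t) for t in replicates_b]
    vecs_a = [t.frequency_vector() for t in replicates_a]
    vecs_b = [t.frequency_vector() for t in replicates_b]
    values = [cosine(a, b) for a in vecs_a for b in vecs_b]
    return PairCosine(
        cosine_mean=float(np.mean(values)), n_replicate_pairs=len(values)
    )


def _population_label(meta: SampleMeta) -> str:
    return f"{meta.subset}_{meta.tissue}"


def overlap_matrix(
    tables: Sequence[CloneTable], apply_cutoff: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Cosine-similarity matrix over one donor+lineage's subset x tissue
    populations, replicate-averaged per cell.

    Returns the symmetric unit-diagonal matrix (rows/columns labelled
    ``subset_tissue``, sorted) and a complete-linkage leaf ordering of the
    labels for heatmap rendering.
    """
    donors = {t.sample.donor_id for t in tables}
    lineages = {t.sample.lineage for t in tables}
    if len(donors) != 1 or len(lineages) != 1:
        raise ValueError("overlap_matrix expects one donor and one lineage")
    groups: dict[str, list[CloneTable]] = {}
    for t in tables:
        groups.setdefault(_population_label(t.sample), []).append(t)
    if len(groups) < 2:
        raise ValueError("need at least 2 subset x tissue populations")
    labels = sorted(groups)
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            value = sample_pair_cosine(groups[la], groups[lb], apply_cutoff).cosine_mean
            mat.loc[la, lb] = mat.loc[lb, la] = value
    distance = 1.0 - mat.to_numpy()
    np.fill_diagonal(distance, 0.0)
    order = leaves_list(complete(squareform(distance, checks=False)))
    return mat, [labels[i] for i in order]


#: Fig.-3B-style pair designs
SAME_SUBSET_BETWEEN_SITES = "same_subset_between_sites"
CROSS_SUBSET_WITHIN_SITE = "cross_subset_within_site"
CROSS_SUBSET_BETWEEN_SITES = "cross_subset_between_sites"


def classify_pair(a: SampleMeta, b: SampleMeta) -> str | None:
    """Classify a within-donor, within-lineage sample pair by design cell.

    Same-subset same-site pairs (replicate self-pairs) return None.
    """
    if a.donor_id != b.donor_id or a.lineage != b.lineage:
        raise ValueError("pairs are classified within donor and lineage")
    same_subset = a.subset == b.subset
    same_site = a.tissue == b.tissue
    if same_subset and same_site:
        return None
    if same_subset:
        return SAME_SUBSET_BETWEEN_SITES
    if same_site:
        return CROSS_SUBSET_WITHIN_SITE
    return CROSS_SUBSET_BETWEEN_SITES


def pairwise_cosine_frame(
    tables: Sequence[CloneTable], apply_cutoff: bool = True
) -> pd.DataFrame:
    """All within-donor, within-lineage population pairs with their
    replicate-averaged cosine, pair design class and group label.

    The group label identifies the compiled-figure cell: the shared subset
    for same-subset pairs, otherwise the (sorted) subset pair, suffixed
    with the site relation.
    """
    groups: dict[tuple, list[CloneTable]] = {}
    for t in tables:
        key = (t.sample.donor_id, t.sample.lineage, t.sample.subset, t.sample.tissue)
        groups.setdefault(key, []).append(t)
    keys = sorted(groups)
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            if ka[0] != kb[0] or ka[1] != kb[1]:
                continue
            meta_a = groups[ka][0].sample
            meta_b = groups[kb][0].sample
            design = classify_pair(meta_a, meta_b)
            if design is None:
                continue
            pc = sample_pair_cosine(groups[ka], groups[kb], apply_cutoff)
            if meta_a.subset == meta_b.subset:
                group = meta_a.subset
            else:
                group = "-".join(sorted((meta_a.subset, meta_b.subset)))
            rows.append(
                {
                    "donor_id": ka[0],
                    "lineage": ka[1],
                    "subset_a": ka[2],
                    "tissue_a": ka[3],
                    "subset_b": kb[2],
                    "tissue_b": kb[3],
                    "design": design,
                    "group": group,
                    "cosine_mean": pc.cosine_mean,
                    "n_replicate_pairs": pc.n_replicate_pairs,
                }
            )
    return pd.DataFrame(rows)


def compile_group_overlap(
    pairs: pd.DataFrame,
    normalize_between_subjects: bool = False,
    pool_level: str = "pair",
) -> pd.DataFrame:
    """Compile pairwise cosines into per-(lineage, design, group) means
    with SEM, pooling pairs across donors.

    ``normalize_between_subjects`` applies a within-donor centering with
    grand-mean restoration (value - donor mean + grand mean) before the
    SEM, removing between-subject level differences; raw means are always
    reported alongside. ``pool_level="donor"`` averages within donor first
    and treats donors as the units.
    """
    if pairs.empty:
        return pd.DataFrame()
    pairs = pairs.copy()
    if normalize_between_subjects:
        grand = pairs["cosine_mean"].mean()
        donor_means = pairs.groupby("donor_id")["cosine_mean"].transform("mean")
        pairs["cosine_norm"] = pairs["cosine_mean"] - donor_means + grand
    value_col = "cosine_norm" if normalize_between_subjects else "cosine_mean"
    if pool_level == "donor":
        pairs = (
            pairs.groupby(["lineage", "design", "group", "donor_id"], as_index=False)
            .agg(raw_mean=("cosine_mean", "mean"), value=(value_col, "mean"))
        )
    else:
        pairs["value"] = pairs[value_col]
        pairs["raw_mean"] = pairs["cosine_mean"]
    rows = []
    for (lineage, design, group), g in pairs.groupby(["lineage", "design", "group"]):
        values = g["value"].to_numpy(float)
        rows.append(
            {
                "lineage": lineage,
                "design": design,
                "group": group,
                "mean": values.mean(),
                "raw_mean": g["raw_mean"].mean(),
                "sem": float(stats.sem(values)) if len(values) > 1 else 0.0,
                "n": len(values),
                "sem_defined": len(values) > 1,
            }
        )
    return pd.DataFrame(rows)
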
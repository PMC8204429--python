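"""CDR3 sequence-similarity analyses.

Distances between clones are computed on CDR3 amino-acid sequences
(unit-cost Levenshtein, or Hamming for equal lengths), and between samples
on TRBV usage (symmetrized Kullback-Leibler divergence with a pseudocount
of 1 per gene, natural log). Sample pairs are classified into a stratum
hierarchy by the finest metadata level at which the two samples differ —
replicate, subset, tissue, lineage, donor — and per-stratum mean distances
are compared between neighboring strata with two-sided unpaired t tests.

Clones overlapping between samples and non-productive rearrangements are
removed before sampling, so each analyzed clone is private to one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from tcrtissue.types import CLONE_KEY, CloneTable, SampleMeta

logger = logging.getLogger(__name__)

#: stratum labels, finest to coarsest
STRATA = ("replicate", "subset", "tissue", "lineage", "donor")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance: minimum number of insertions, deletions
    and substitutions converting ``a`` into ``b``."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def hamming(a: str, b: str) -> int | None:
    """Number of mismatching positions between equal-length strings.

    Hamming distance is undefined for unequal lengths; such pairs return
    None under the default skip-pair policy and are excluded from means.
    """
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def kl_divergence_sym(
    counts_i: Mapping[str, float] | pd.Series,
    counts_j: Mapping[str, float] | pd.Series,
    support: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> float:
    """Symmetrized KL divergence between two TRBV usage count vectors.

    A pseudocount is added to each gene's count in each sample over the
    common support (the union of observed genes, or an explicit cohort-wide
    gene list), counts are normalized to frequencies p_i and p_j, and
    ``sum_v p_i(v) ln(p_i(v)/p_j(v)) + p_j(v) ln(p_j(v)/p_i(v))`` is
    returned (natural log; >= 0; 0 iff the smoothed frequencies coincide).
    """
    ci = pd.Series(counts_i, dtype=float)
    cj = pd.Series(counts_j, dtype=float)
    if support is None:
        support = ci.index.union(cj.index)
    ci = ci.reindex(support, fill_value=0.0).to_numpy() + pseudocount
    cj = cj.reindex(support, fill_value=0.0).to_numpy() + pseudocount
    pi = ci / ci.sum()
    pj = cj / cj.sum()
    return float(np.sum(pi * np.log(pi / pj) + pj * np.log(pj / pi)))


def remove_overlapping_clones(tables: Sequence[CloneTable]) -> list[CloneTable]:
    """Remove every clone key that appears in more than one sample, from
    all samples it appears in."""
    if len(tables) < 2:
        raise ValueError("need at least 2 samples")
    keys = pd.concat([t.df[CLONE_KEY] for t in tables], ignore_index=True)
    counts = keys.value_counts(subset=CLONE_KEY)
    shared = set(counts.index[counts > 1])
    out = []
    n_removed = 0
    for t in tables:
        mask = np.array(
            [tuple(r) not in shared for r in t.df[CLONE_KEY].itertuples(index=False)],
            dtype=bool,
        )
        n_removed += int((~mask).sum())
        kept = t.df.loc[mask]
        if kept.empty and len(t.df):
            logger.warning("%s: all clones overlapped", t.sample.sample_id)
        out.append(t.with_df(kept))
    logger.info(
        "removed %d clone occurrences shared between samples (%d distinct keys)",
        n_removed,
        len(shared),
    )
    return out


@dataclass
class DistanceSample:
    """A seeded random draw of clones from one sample for distance work."""

    sample: SampleMeta
    clones: pd.DataFrame
    seed: int
    undersampled: bool


def draw_distance_sample(
    table: CloneTable, n: int = 500, seed: int = 0
) -> DistanceSample:
    """Uniformly sample ``n`` clones without replacement, seeded.

    The table is canonically sorted by clone key before drawing, so the
    draw is invariant to input row order. With fewer than ``n`` clones all
    are taken and the sample is flagged as undersampled.
    """
    df = table.df.sort_values(CLONE_KEY, kind="mergesort").reset_index(drop=True)
    undersampled = len(df) < n
    if undersampled:
        logger.info(
            "%s: only %d clones available (requested %d)",
            table.sample.sample_id,
            len(df),
            n,
        )
        chosen = df
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(df), size=n, replace=False)
        chosen = df.iloc[np.sort(idx)]
    return DistanceSample(
        sample=table.sample,
        clones=chosen.reset_index(drop=True),
        seed=seed,
        undersampled=undersampled,
    )


def pooled_distance_matrix(
    samples: Sequence[DistanceSample], metric: str = "levenshtein"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Distance matrix over all sampled clones pooled across samples.

    Returns a symmetric zero-diagonal matrix (float; NaN for skipped
    Hamming pairs of unequal length) and a label frame aligned 1:1 with
    its rows (sample_id, donor, lineage, tissue, subset, replicate,
    cdr3_aa).
    """
    labels = pd.concat(
        [
            pd.DataFrame(
                {
                    "sample_id": s.sample.sample_id,
                    "donor_id": s.sample.donor_id,
                    "lineage": s.sample.lineage,
                    "tissue": s.sample.tissue,
                    "subset": s.sample.subset,
                    "replicate": s.sample.replicate,
                    "cdr3_aa": s.clones["cdr3_aa"],
                }
            )
            for s in samples
        ],
        ignore_index=True,
    )
    seqs = labels["cdr3_aa"].tolist()
    m = len(seqs)
    mat = np.zeros((m, m), dtype=np.float32)
    if metric == "levenshtein":
        align = edlib.align
        for i in range(m):
            a = seqs[i]
            row = mat[i]
            for j in range(i + 1, m):
                row[j] = align(a, seqs[j], task="distance")["editDistance"]
    elif metric == "hamming":
        lengths = np.array([len(s) for s in seqs])
        for i in range(m):
            a = seqs[i]
            for j in range(i + 1, m):
                mat[i, j] = hamming(a, seqs[j]) if lengths[i] == lengths[j] else np.nan
    else:
        raise ValueError(f"unknown metric {metric!r}")
    mat = mat + mat.T
    return mat, labels


def pairwise_distance_matrix(
    samples: Sequence[DistanceSample], metric: str = "levenshtein"
) -> pd.DataFrame:
    """All inter-clone distances in long form with sample labels.

    For each ordered sample pair (including a sample with itself, which
    feeds the replicate stratum) every cross clone-pair distance appears
    as one row (sample_a, sample_b, distance).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    mat, labels = pooled_distance_matrix(samples, metric=metric)
    ids = labels["sample_id"].to_numpy()
    rows = []
    boundaries = {}
    for sid in pd.unique(ids):
        idx = np.flatnonzero(ids == sid)
        boundaries[sid] = idx
    sample_ids = list(boundaries)
    for i, sa in enumerate(sample_ids):
        for sb in sample_ids[i + 1 :]:
            block = mat[np.ix_(boundaries[sa], boundaries[sb])]
            flat = block.ravel()
            rows.append(
                pd.DataFrame(
                    {"sample_a": sa, "sample_b": sb, "distance": flat}
                )
            )
    return pd.concat(rows, ignore_index=True)


def classify_stratum(a: SampleMeta, b: SampleMeta) -> str:
    """Finest stratum at which two samples differ."""
    if a.donor_id != b.donor_id:
        return "donor"
    if a.lineage != b.lineage:
        return "lineage"
    if a.tissue != b.tissue:
        return "tissue"
    if a.subset != b.subset:
        return "subset"
    return "replicate"


def _pair_mean_distances(
    samples: Sequence[DistanceSample], metric: str
) -> pd.DataFrame:
    """Mean cross-clone distance for every sample pair, with stratum."""
    mat, labels = pooled_distance_matrix(samples, metric=metric)
    ids = labels["sample_id"].to_numpy()
    index = {s.sample.sample_id: np.flatnonzero(ids == s.sample.sample_id) for s in samples}
    metas = {s.sample.sample_id: s.sample for s in samples}
    rows = []
    sample_ids = [s.sample.sample_id for s in samples]
    for i, sa in enumerate(sample_ids):
        for sb in sample_ids[i + 1 :]:
            block = mat[np.ix_(index[sa], index[sb])]
            finite = block[np.isfinite(block)]
            mean = float(finite.mean()) if finite.size else np.nan
            rows.append(
                {
                    "sample_a": sa,
                    "sample_b": sb,
                    "stratum": classify_stratum(metas[sa], metas[sb]),
                    "mean_distance": mean,
                    "n_clone_pairs": int(np.isfinite(block).sum()),
                }
            )
    return pd.DataFrame(rows)


def _pair_kl_divergences(
    samples: Sequence[DistanceSample], pseudocount: float = 1.0
) -> pd.DataFrame:
    """Symmetrized KL divergence of TRBV usage for every sample pair,
    over the cohort-union gene support."""
    counts = {
        s.sample.sample_id: s.clones["v_call"].value_counts() for s in samples
    }
    support = sorted(set().union(*[set(c.index) for c in counts.values()]))
    metas = {s.sample.sample_id: s.sample for s in samples}
    sample_ids = [s.sample.sample_id for s in samples]
    rows = []
    for i, sa in enumerate(sample_ids):
        for sb in sample_ids[i + 1 :]:
            rows.append(
                {
                    "sample_a": sa,
                    "sample_b": sb,
                    "stratum": classify_stratum(metas[sa], metas[sb]),
                    "mean_distance": kl_divergence_sym(
                        counts[sa], counts[sb], support=support, pseudocount=pseudocount
                    ),
                    "n_clone_pairs": len(counts[sa]) * len(counts[sb]),
                }
            )
    return pd.DataFrame(rows)


def distance_hierarchy(
    samples: Sequence[DistanceSample],
    metric: str = "levenshtein",
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum mean distances with SE and neighboring-stratum t tests.

    Every sample pair is assigned to the finest stratum at which the two
    samples differ; for edit/Hamming metrics the unit of analysis is the
    per-pair mean cross-clone distance (so unequal sampling depth cannot
    dominate), for ``metric="kl"`` the per-pair TRBV divergence. Returns
    (strata summary, per-pair long frame). The summary has one row per
    stratum present, ordered finest to coarsest, with mean, SE, n_pairs
    and the two-sided unpaired t-test p-value against the next-coarser
    stratum (Student's pooled-variance by default; Welch via
    ``equal_var=False``).
    """
    if metric == "kl":
        pairs = _pair_kl_divergences(samples)
    else:
        pairs = _pair_mean_distances(samples, metric)
    present = [s for s in STRATA if (pairs["stratum"] == s).any()]
    summary_rows = []
    for stratum in present:
        values = pairs.loc[pairs["stratum"] == stratum, "mean_distance"].dropna()
        summary_rows.append(
            {
                "stratum": stratum,
                "mean": values.mean(),
                "se": float(stats.sem(values)) if len(values) > 1 else 0.0,
                "n_pairs": len(values),
            }
        )
    summary = pd.DataFrame(summary_rows)
    pvals = [np.nan] * len(summary)
    for k in range(len(summary) - 1):
        a = pairs.loc[pairs["stratum"] == summary.loc[k, "stratum"], "mean_distance"].dropna()
        b = pairs.loc[pairs["stratum"] == summary.loc[k + 1, "stratum"], "mean_distance"].dropna()
        if len(a) > 1 and len(b) > 1:
            pvals[k] = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    summary["p_vs_next"] = pvals
    return summary, pairs


def embedding_input(
    tables: Sequence[CloneTable], n: int = 250, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Square Levenshtein matrix + labels for an external 2-D embedding.

    Draws ``n`` clones per sample (seeded) from overlap-free tables and
    returns the symmetric zero-diagonal clone x clone distance matrix with
    per-clone tissue and subset labels, ready to hand to e.g. a tSNE
    implementation. The embedding itself is out of scope.
    """
    clean = remove_overlapping_clones(tables)
    samples = [
        draw_distance_sample(t, n=n, seed=seed + i) for i, t in enumerate(clean)
    ]
    return pooled_distance_matrix(samples, metric="levenshtein")
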
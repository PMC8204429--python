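"""Synthetic multi-donor, multi-tissue, multi-subset TCR-beta cohorts.

The generator emits AIRR-format rearrangement tables plus a sample sheet
and a machine-readable ground-truth bundle, so every analysis stage can be
validated end to end against known parameters. It emulates the phenomena
the analyses target:

* per-subset geometric clone-size distributions whose pool clonality is
  ordered TEMRA >> TEM ~ TRM >> TCM,
* cross-tissue clone sharing whose breadth differs by subset
  (TEMRA > TEM > TRM > TCM),
* lineage- and donor-biased TRBV gene usage,
* nested CDR3 positional imprints (donor strongest, then lineage, then
  tissue; none for subsets by default) so the distance-hierarchy strata
  are separable,
* one shared CDR3 length distribution across all groups, so edit-distance
  effects cannot be length artifacts,
* two replicate libraries per sample drawn (multinomially) from the same
  cell pool,
* a per-read error process that injects one-substitution singleton
  records, and a small non-productive background,
* optional age-dependent clonal expansion of circulating subsets
  (clone-size decay grows exponentially with donor age for TEM/TEMRA,
  flat for TRM/TCM).

All randomness flows from a single integer seed through one
``numpy.random.Generator`` in a deterministic loop order, so the same seed
reproduces the cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tcrtissue.airr_io import write_sample_sheet
from tcrtissue.types import AA_ALPHABET, SampleMeta

TRBV_GENES = (
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV5-4", "TRBV6-1", "TRBV6-4", "TRBV7-2",
    "TRBV7-9", "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV14",
    "TRBV15", "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV29-1", "TRBV30",
)
TRBJ_GENES = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6", "TRBJ2-7",
)

#: interior CDR3 positions reserved for each imprint level (0-based within
#: the region between the leading C and trailing F)
IMPRINT_POSITIONS = {
    "donor": (0, 1),
    "lineage": (2, 3),
    "tissue": (4, 5),
    "subset": (6,),
}


@dataclass(frozen=True)
class SubsetProfile:
    """Clone-pool parameters of one memory subset.

    ``n_clones`` pool size per donor x lineage x subset; ``decay`` the
    geometric rank-frequency decay (larger = more clonal); ``sharing`` the
    probability that a clone is also present in each non-home tissue;
    ``age_decay_slope`` the per-year log-scale growth of ``decay`` with
    donor age (clonal expansion with age; 0 = age-stable), centered at the
    reference age.
    """

    n_clones: int
    decay: float
    sharing: float
    age_decay_slope: float = 0.0


# pool clonality at the reference age: TEMRA 0.34 >> TEM 0.18 ~ TRM 0.15
# >> TCM 0.02, mirroring the observed subset hierarchy; sharing breadth
# TEMRA > TEM > TRM > TCM mirrors the observed overlap hierarchy
DEFAULT_SUBSET_PROFILES: Mapping[str, SubsetProfile] = {
    "TEMRA": SubsetProfile(400, 0.05, 0.80, 0.010),
    "TEM": SubsetProfile(1200, 0.008, 0.50, 0.020),
    "TRM": SubsetProfile(1200, 0.0065, 0.20, 0.0),
    "TCM": SubsetProfile(2500, 0.0008, 0.05, 0.0),
}

DEFAULT_SUBSETS_BY_LINEAGE: Mapping[str, tuple[str, ...]] = {
    "CD4": ("TCM", "TEM", "TRM"),
    "CD8": ("TEM", "TRM", "TEMRA"),
}


@dataclass
class GeneratorConfig:
    """Study design and generative parameters of a synthetic cohort."""

    donors: tuple[tuple[str, int], ...] = (("D383", 39), ("D324", 56), ("D466", 59))
    lineages: tuple[str, ...] = ("CD4", "CD8")
    tissues: tuple[str, ...] = ("Bld", "BM", "Spl", "LN", "Lung")
    subsets_by_lineage: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSETS_BY_LINEAGE)
    )
    subset_profiles: Mapping[str, SubsetProfile] = field(
        default_factory=lambda: dict(DEFAULT_SUBSET_PROFILES)
    )
    #: cells sequenced per replicate library
    depth: int = 20_000
    n_replicates: int = 2
    #: per-read probability of emitting a one-substitution singleton
    error_rate: float = 0.005
    #: per-read probability of a non-productive background record
    nonproductive_rate: float = 0.01
    #: CDR3 imprint strengths (probability a reserved interior position
    #: carries the entity's preferred residue)
    donor_imprint: float = 0.9
    lineage_imprint: float = 0.6
    tissue_imprint: float = 0.4
    subset_imprint: float = 0.0
    #: log-normal sd of donor-level jitter on lineage TRBV usage weights
    #: (chosen so the between-donor usage divergence exceeds half the
    #: between-lineage divergence, keeping donor the top stratum)
    donor_usage_sd: float = 0.8
    #: reference age at which subset decay parameters apply exactly
    reference_age: int = 45
    trbv_genes: tuple[str, ...] = TRBV_GENES
    trbj_genes: tuple[str, ...] = TRBJ_GENES

    def validate(self) -> None:
        for name, p in self.subset_profiles.items():
            if p.n_clones < 1:
                raise ValueError(f"{name}: pool must contain at least one clone")
            if not 0 < p.decay < 1:
                raise ValueError(f"{name}: decay must be in (0, 1)")
            if not 0 <= p.sharing <= 1:
                raise ValueError(f"{name}: sharing must be a probability")
        for v in (
            self.error_rate,
            self.nonproductive_rate,
            self.donor_imprint,
            self.lineage_imprint,
            self.tissue_imprint,
            self.subset_imprint,
        ):
            if not 0 <= v <= 1:
                raise ValueError("rates and imprint strengths must be in [0, 1]")
        if not self.donors or not self.tissues:
            raise ValueError("need at least one donor and one tissue")


@dataclass
class SyntheticCohort:
    """Generated cohort: sample sheet, per-sample AIRR records, truth."""

    config: GeneratorConfig
    seed: int
    samples: list[SampleMeta]
    records: dict[str, pd.DataFrame]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write AIRR TSVs (one per sample), the sample sheet and the
        ground-truth bundle (JSON) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sample_sheet(self.samples, outdir / "sample_sheet.tsv")
        for sid, df in self.records.items():
            df.to_csv(outdir / f"{sid}.tsv", sep="\t", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _preferred_letters(rng: np.random.Generator, entities: Sequence[str], k: int) -> dict:
    """Assign each entity ``k`` preferred residues, distinct across
    entities position-wise so imprints of different entities never
    coincide."""
    prefs = {}
    for pos in range(k):
        letters = rng.permutation(list(AA_ALPHABET))[: len(entities)]
        for e, letter in zip(entities, letters):
            prefs.setdefault(e, []).append(letter)
    return {e: "".join(v) for e, v in prefs.items()}


def _sample_id(donor: str, lineage: str, subset: str, tissue: str, rep: int) -> str:
    return f"{donor}_{lineage}_{subset}_{tissue}_r{rep}"


def _true_clonality(p: np.ndarray) -> float:
    if p.size == 1:
        return 1.0
    h = -(p * np.log2(p)).sum()
    return float(1.0 - h / np.log2(p.size))


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    For each donor x lineage x subset a clone universe is drawn: TRBV
    calls from donor-jittered lineage usage weights, TRBJ uniform, CDR3s
    from one shared length distribution with nested positional imprints,
    geometric rank frequencies, a home tissue per clone plus Bernoulli
    presence in the other tissues. Each sample (subset x tissue) yields
    ``n_replicates`` multinomial libraries of ``depth`` cells from the
    tissue-restricted pool, plus error singletons and a non-productive
    background.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    genes = list(config.trbv_genes)
    aa = np.array(list(AA_ALPHABET))

    donor_ids = [d for d, _ in config.donors]
    subsets_all = sorted({s for ss in config.subsets_by_lineage.values() for s in ss})
    prefs = {
        "donor": _preferred_letters(rng, donor_ids, len(IMPRINT_POSITIONS["donor"])),
        "lineage": _preferred_letters(rng, list(config.lineages), len(IMPRINT_POSITIONS["lineage"])),
        "tissue": _preferred_letters(rng, list(config.tissues), len(IMPRINT_POSITIONS["tissue"])),
        "subset": _preferred_letters(rng, subsets_all, len(IMPRINT_POSITIONS["subset"])),
    }
    strengths = {
        "donor": config.donor_imprint,
        "lineage": config.lineage_imprint,
        "tissue": config.tissue_imprint,
        "subset": config.subset_imprint,
    }

    # lineage-level usage weights, then a per-donor log-normal jitter
    # shared by both lineages of the donor (a donor-level usage signature)
    lineage_usage = {
        lin: rng.dirichlet(np.full(len(genes), 2.0)) for lin in config.lineages
    }
    donor_usage = {}
    for donor in donor_ids:
        jitter = np.exp(rng.normal(0.0, config.donor_usage_sd, len(genes)))
        for lin in config.lineages:
            w = lineage_usage[lin] * jitter
            donor_usage[(donor, lin)] = w / w.sum()

    samples: list[SampleMeta] = []
    records: dict[str, pd.DataFrame] = {}
    truth_samples: dict[str, dict] = {}
    truth_sharing: list[dict] = []

    for donor, age in config.donors:
        for lineage in config.lineages:
            for subset in config.subsets_by_lineage[lineage]:
                profile = config.subset_profiles[subset]
                n = profile.n_clones
                decay = profile.decay * float(
                    np.exp(profile.age_decay_slope * (age - config.reference_age))
                )
                decay = min(decay, 0.999)

                v_calls = np.array(genes)[
                    rng.choice(len(genes), size=n, p=donor_usage[(donor, lineage)])
                ]
                j_calls = np.array(config.trbj_genes)[
                    rng.choice(len(config.trbj_genes), size=n)
                ]
                home = np.array(config.tissues)[
                    rng.choice(len(config.tissues), size=n)
                ]
                cdr3 = _generate_cdr3s(
                    rng, n, aa,
                    [("donor", donor), ("lineage", lineage), ("subset", subset)],
                    home, prefs, strengths,
                )
                weights = (1.0 - decay) ** np.arange(n)

                # dedupe clone keys (collisions are rare but would break
                # the clone<->truth correspondence)
                keys = pd.DataFrame({"v_call": v_calls, "j_call": j_calls, "cdr3_aa": cdr3})
                unique = ~keys.duplicated()
                v_calls, j_calls = v_calls[unique], j_calls[unique]
                cdr3, home = [c for c, u in zip(cdr3, unique) if u], home[unique]
                weights = weights[unique]
                n = len(weights)

                presence = np.zeros((n, len(config.tissues)), dtype=bool)
                for t_idx, tissue in enumerate(config.tissues):
                    presence[:, t_idx] = (home == tissue) | (
                        rng.random(n) < profile.sharing
                    )

                for ta in range(len(config.tissues)):
                    for tb in range(ta + 1, len(config.tissues)):
                        inter = int((presence[:, ta] & presence[:, tb]).sum())
                        union = int((presence[:, ta] | presence[:, tb]).sum())
                        truth_sharing.append(
                            {
                                "donor_id": donor,
                                "lineage": lineage,
                                "subset": subset,
                                "tissue_a": config.tissues[ta],
                                "tissue_b": config.tissues[tb],
                                "configured_sharing": profile.sharing,
                                "jaccard": inter / union if union else 0.0,
                            }
                        )

                for t_idx, tissue in enumerate(config.tissues):
                    mask = presence[:, t_idx]
                    if not mask.any():
                        continue
                    p = weights[mask] / weights[mask].sum()
                    order = np.argsort(p)[::-1]
                    top10 = float(p[order[:10]].sum())
                    pool_idx = np.flatnonzero(mask)
                    for rep in range(1, config.n_replicates + 1):
                        sid = _sample_id(donor, lineage, subset, tissue, rep)
                        meta = SampleMeta(
                            sample_id=sid, donor_id=donor, age=age,
                            lineage=lineage, subset=subset, tissue=tissue,
                            replicate=rep,
                        )
                        df, n_err, err_keys = _emit_library(
                            rng, config, sid, p, pool_idx, v_calls, j_calls, cdr3, aa
                        )
                        samples.append(meta)
                        records[sid] = df
                        truth_samples[sid] = {
                            "true_clonality": _true_clonality(p),
                            "true_top10_fraction": top10,
                            "n_pool_clones": int(mask.sum()),
                            "n_error_records": n_err,
                            "error_keys": err_keys,
                        }

    truth = {
        "seed": seed,
        "samples": truth_samples,
        "sharing": truth_sharing,
        "imprints": {
            "preferred_letters": prefs,
            "strengths": strengths,
            "positions": {k: list(v) for k, v in IMPRINT_POSITIONS.items()},
        },
        "subset_profiles": {
            name: {
                "n_clones": p.n_clones,
                "decay": p.decay,
                "sharing": p.sharing,
                "age_decay_slope": p.age_decay_slope,
            }
            for name, p in config.subset_profiles.items()
        },
    }
    return SyntheticCohort(
        config=config, seed=seed, samples=samples, records=records, truth=truth
    )


def _generate_cdr3s(rng, n, aa, entity_levels, home, prefs, strengths):
    """CDR3s: leading C, trailing F, interior from one shared length
    distribution (7-17 residues) with per-level positional imprints."""
    interior_len = 7 + rng.binomial(10, 0.5, size=n)
    seqs = []
    for i in range(n):
        interior = list(aa[rng.integers(0, len(aa), interior_len[i])])
        levels = entity_levels + [("tissue", home[i])]
        for level, entity in levels:
            strength = strengths[level]
            if strength == 0:
                continue
            letters = prefs[level][entity]
            for slot, pos in enumerate(IMPRINT_POSITIONS[level]):
                if pos < interior_len[i] and rng.random() < strength:
                    interior[pos] = letters[slot]
        seqs.append("C" + "".join(interior) + "F")
    return seqs


def _emit_library(rng, config, sid, p, pool_idx, v_calls, j_calls, cdr3, aa):
    """One replicate library: multinomial cell draw + error singletons +
    non-productive background, as an AIRR rearrangement frame."""
    counts = rng.multinomial(config.depth, p)
    drawn = np.flatnonzero(counts)
    rows = {
        "sequence_id": [f"{sid}_c{k}" for k in drawn],
        "v_call": [v_calls[pool_idx[k]] for k in drawn],
        "j_call": [j_calls[pool_idx[k]] for k in drawn],
        "junction_aa": [cdr3[pool_idx[k]] for k in drawn],
        "productive": ["T"] * len(drawn),
        "duplicate_count": counts[drawn].tolist(),
    }

    n_err = int(rng.binomial(config.depth, config.error_rate))
    err_keys = []
    for e in range(n_err):
        k = rng.choice(len(p), p=p)
        src = cdr3[pool_idx[k]]
        pos = int(rng.integers(0, len(src)))
        letter = str(aa[rng.integers(0, len(aa))])
        while letter == src[pos]:
            letter = str(aa[rng.integers(0, len(aa))])
        mutated = src[:pos] + letter + src[pos + 1 :]
        rows["sequence_id"].append(f"{sid}_e{e}")
        rows["v_call"].append(v_calls[pool_idx[k]])
        rows["j_call"].append(j_calls[pool_idx[k]])
        rows["junction_aa"].append(mutated)
        rows["productive"].append("T")
        rows["duplicate_count"].append(1)
        err_keys.append([v_calls[pool_idx[k]], j_calls[pool_idx[k]], mutated])

    n_np_reads = int(rng.binomial(config.depth, config.nonproductive_rate))
    n_np = max(n_np_reads // 5, 1 if n_np_reads else 0)
    for b in range(n_np):
        length = 7 + int(rng.binomial(10, 0.5))
        junk = "C" + "".join(aa[rng.integers(0, len(aa), length)]) + "F"
        rows["sequence_id"].append(f"{sid}_np{b}")
        rows["v_call"].append(str(np.array(config.trbv_genes)[rng.integers(0, len(config.trbv_genes))]))
        rows["j_call"].append(str(np.array(config.trbj_genes)[rng.integers(0, len(config.trbj_genes))]))
        rows["junction_aa"].append(junk)
        rows["productive"].append("F")
        rows["duplicate_count"].append(int(1 + rng.poisson(3.0)))

    return pd.DataFrame(rows), n_err, err_keys


def clonality_study_config() -> GeneratorConfig:
    """Study preset for subset-clonality recovery: two donors, one tissue
    triple, default subset pools (the configured clonality hierarchy
    TEMRA >> TEM ~ TRM >> TCM)."""
    return GeneratorConfig(
        donors=(("D1", 40), ("D2", 60)),
        tissues=("Bld", "Spl", "Lung"),
    )


def sharing_study_config(sharing: float) -> GeneratorConfig:
    """Study preset for overlap-vs-sharing calibration: one donor, one
    CD8 TEM pool across two tissues with the given sharing probability."""
    return GeneratorConfig(
        donors=(("D1", 45),),
        lineages=("CD8",),
        tissues=("Bld", "Spl"),
        subsets_by_lineage={"CD8": ("TEM",)},
        subset_profiles={"TEM": SubsetProfile(600, 0.01, float(sharing))},
        depth=8_000,
        error_rate=0.0,
    )


def aging_study_config() -> GeneratorConfig:
    """Study preset for clonality-vs-age recovery: six donors spanning
    four decades; TEM pools expand with age (positive decay slope), TRM
    pools are age-stable. Pools are sized so the rarest clone is well
    covered at the library depth, keeping the clonality estimate unbiased
    along the age axis."""
    return GeneratorConfig(
        donors=tuple((f"D{i}", age) for i, age in enumerate((28, 35, 42, 49, 56, 63))),
        lineages=("CD8",),
        tissues=("Bld", "Spl"),
        subsets_by_lineage={"CD8": ("TEM", "TRM")},
        subset_profiles={
            "TEM": SubsetProfile(500, 0.003, 0.3, age_decay_slope=0.02),
            "TRM": SubsetProfile(500, 0.003, 0.3, age_decay_slope=0.0),
        },
        depth=30_000,
    )


def hierarchy_study_config(tissue_imprint: float = 0.4) -> GeneratorConfig:
    """Study preset for the distance-stratum hierarchy: three donors, two
    lineages, three tissues, two subsets, two replicates. Pools are large
    relative to the library depth so clone detection is incomplete and
    each replicate retains private clones after overlapping-clone removal
    (as in real repertoires, where sampling misses low-copy clones)."""
    return GeneratorConfig(
        donors=(("D1", 40), ("D2", 55), ("D3", 62)),
        lineages=("CD4", "CD8"),
        tissues=("Bld", "Spl", "Lung"),
        subsets_by_lineage={"CD4": ("TEM", "TRM"), "CD8": ("TEM", "TRM")},
        subset_profiles={
            "TEM": SubsetProfile(4000, 0.002, 0.3),
            "TRM": SubsetProfile(4000, 0.002, 0.15),
        },
        depth=4_000,
        tissue_imprint=tissue_imprint,
    )


def cohort_clone_tables(
    cohort: SyntheticCohort,
    min_copies: int = 2,
    replicate_1_only: bool = False,
    productive_only: bool = True,
):
    """Assemble clone tables for every sample of a synthetic cohort (the
    same path real data takes: AIRR normalization then clone assembly)."""
    from tcrtissue.airr_io import normalize_rearrangements
    from tcrtissue.clones import assemble_clones

    tables = []
    for s in cohort.samples:
        if replicate_1_only and s.replicate != 1:
            continue
        records = normalize_rearrangements(cohort.records[s.sample_id])
        tables.append(
            assemble_clones(
                records, s, min_copies=min_copies, productive_only=productive_only
            )
        )
    return tables


def ground_truth_report(cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    """Tidy frames of the cohort's ground truth for parameter-recovery
    checks: per-sample truth (clonality, top-10 mass, pool size, injected
    errors), per-tissue-pair sharing, and imprint assignments."""
    meta = {s.sample_id: s for s in cohort.samples}
    sample_rows = []
    for sid, t in cohort.truth["samples"].items():
        m = meta[sid]
        sample_rows.append(
            {
                "sample_id": sid,
                "donor_id": m.donor_id,
                "age": m.age,
                "lineage": m.lineage,
                "subset": m.subset,
                "tissue": m.tissue,
                "replicate": m.replicate,
                "true_clonality": t["true_clonality"],
                "true_top10_fraction": t["true_top10_fraction"],
                "n_pool_clones": t["n_pool_clones"],
                "n_error_records": t["n_error_records"],
            }
        )
    imprint_rows = [
        {"level": level, "entity": entity, "letters": letters}
        for level, assignment in cohort.truth["imprints"]["preferred_letters"].items()
        for entity, letters in assignment.items()
    ]
    return {
        "samples": pd.DataFrame(sample_rows),
        "sharing": pd.DataFrame(cohort.truth["sharing"]),
        "imprints": pd.DataFrame(imprint_rows),
    }
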
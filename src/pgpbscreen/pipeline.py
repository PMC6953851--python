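"""End-to-end orchestration: from a collection to a ranked bonitur table.

Runs the full screening chain on a typed collection: trait summarization,
per-(species, response) ANOVA + Scott-Knott, bonitur scoring of every
strain, dense ranking, and optional MPN/fingerprint summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .fingerprint import count_profiles, cut_clusters, similarity_matrix, upgma
from .model import Collection, CONTROL, Species, TRAITS
from .mpn import estimate_mpn
from .screening import (
    BoniturResult,
    biometric_score,
    bonitur_table,
    genus_distribution,
    rank_strains,
    trait_score,
    trait_summary,
)
from .stats import MeansGrouping, one_way_anova, scott_knott


@dataclass
class ScreenResult:
    """Everything the `report` stage emits."""

    bonitur: pd.DataFrame
    trait_summary: object
    groupings: dict  # (species, response) -> MeansGrouping
    genus_table: pd.DataFrame
    mpn_estimates: list = field(default_factory=list)
    fingerprint_groups: Optional[list] = None
    n_profiles_95: Optional[int] = None


def score_collection(collection: Collection, alpha: float = 0.05,
                     mode: str = "band") -> tuple[pd.DataFrame, dict]:
    """Bonitur-score and rank every strain of a collection.

    Trait bins are derived from the collection's own positive-strain means
    (``mode`` chooses band vs literal cutoffs); biometric scores come from
    Scott-Knott groupings of each (species, response) relative to CONTROL.
    Returns the ranked table and the groupings used.
    """
    summary = trait_summary(collection.traits, collection.strains)
    trait_means = {t: summary.per_trait.loc[t, "mean"] for t in TRAITS}
    traits_by_id = {t.strain_id: t for t in collection.traits}

    groupings: dict[tuple[str, str], MeansGrouping] = {}
    for species in (Species.TOMATO, Species.LULO):
        for response in ("rdw", "sdw"):
            if not any(o.species == species for o in collection.biomass):
                continue
            anova = one_way_anova(collection.biomass, species, response)
            groupings[(species.value, response)] = scott_knott(anova, alpha)

    results: list[BoniturResult] = []
    for strain in collection.strains:
        sid = strain.strain_id
        scores = []
        tm = traits_by_id.get(sid)
        for trait in TRAITS:
            value = tm.value(trait) if tm is not None else None
            mean = trait_means[trait]
            scores.append(0 if (value is None or pd.isna(mean))
                          else trait_score(value, mean, mode))
        for key in (("tomato", "rdw"), ("tomato", "sdw"),
                    ("lulo", "rdw"), ("lulo", "sdw")):
            grouping = groupings.get(key)
            if grouping is None or sid not in grouping.means:
                scores.append(1)  # no trial data: indistinguishable from control
            else:
                scores.append(biometric_score(sid, grouping, CONTROL))
        results.append(BoniturResult(sid, tuple(scores)))

    ranked = rank_strains(results)
    return bonitur_table(ranked), groupings


def run_screen(collection: Collection, alpha: float = 0.05, mode: str = "band",
               band_tol: float = 0.02, cutoff: float = 0.70,
               clone_threshold: float = 0.95) -> ScreenResult:
    """Full report: scoring plus MPN, fingerprint and genus summaries."""
    bonitur, groupings = score_collection(collection, alpha=alpha, mode=mode)
    summary = trait_summary(collection.traits, collection.strains)
    genus_table = genus_distribution(collection.strains)

    estimates = [estimate_mpn(series) for series in collection.dilutions]

    fingerprint_groups = None
    n_profiles = None
    if collection.bands:
        ids, sim = similarity_matrix(collection.bands, tol=band_tol)
        dend = upgma(ids, sim)
        fingerprint_groups = cut_clusters(dend, cutoff)
        n_profiles, _ = count_profiles(ids, sim, clone_threshold)

    return ScreenResult(
        bonitur=bonitur,
        trait_summary=summary,
        groupings=groupings,
        genus_table=genus_table,
        mpn_estimates=estimates,
        fingerprint_groups=fingerprint_groups,
        n_profiles_95=n_profiles,
    )
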
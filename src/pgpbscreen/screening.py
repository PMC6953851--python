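"""Trait summarization and bonitur multi-trait scoring/ranking.

Each strain is scored on four in-vitro traits (0-3 points each, binned
against the mean value over trait-positive strains) and four greenhouse
biometric responses (0-2 points each, relative to the uninoculated
control's Scott-Knott group), for a maximum bonitur total of
4*3 + 4*2 = 20.  Strains totalling >= 10 are flagged as having
biotechnological potential; ranking is dense on descending total.

Trait bins (default "band" mode): with m the positive-strain mean, score 1
below 0.65*m, 2 between 0.65*m and 1.35*m, and 3 above 1.35*m; a value on
a bin boundary takes the higher bin.  A "literal" mode with cutoffs at
0.35*m and 0.70*m is kept for comparison (see docs/methods.md for why
band mode is the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import StrainRecord, TraitMeasurement, TRAITS
from .stats import MeansGrouping

#: the eight bonitur components in display order
BONITUR_COMPONENTS = (
    "iaa", "fepo4", "alpo4", "siderophore_index",
    "tomato_rdw", "tomato_sdw", "lulo_rdw", "lulo_sdw",
)
TRAIT_MAX = 3
BIOMETRIC_MAX = 2
MAX_TOTAL = 4 * TRAIT_MAX + 4 * BIOMETRIC_MAX  # 20
BIOTECH_THRESHOLD = 10


@dataclass
class TraitSummary:
    """Descriptive summary of the in-vitro trait table."""

    n_strains: int
    per_trait: pd.DataFrame  # index: trait; columns: n_positive, mean, min, max
    co_occurrence: dict[frozenset, int]  # exact trait-subset -> strain count
    at_least_one: int
    multi_trait: int
    by_source: pd.DataFrame  # trait x source positive counts
    by_genus: pd.DataFrame  # trait x genus positive counts


def trait_summary(traits: Iterable[TraitMeasurement],
                  strains: Iterable[StrainRecord]) -> TraitSummary:
    """Positive counts, positive-strain means/ranges and trait co-occurrence."""
    traits = list(traits)
    strains = list(strains)
    meta = {s.strain_id: s for s in strains}

    rows = []
    for trait in TRAITS:
        vals = [t.value(trait) for t in traits if t.detected(trait)]
        rows.append({
            "trait": trait,
            "n_positive": len(vals),
            "mean": float(np.mean(vals)) if vals else np.nan,
            "min": float(np.min(vals)) if vals else np.nan,
            "max": float(np.max(vals)) if vals else np.nan,
        })
    per_trait = pd.DataFrame(rows).set_index("trait")

    co: dict[frozenset, int] = {frozenset(sub): 0
                                for n in range(len(TRAITS) + 1)
                                for sub in combinations(TRAITS, n)}
    n_any = n_multi = 0
    src_counts: dict[str, dict[str, int]] = {t: {} for t in TRAITS}
    gen_counts: dict[str, dict[str, int]] = {t: {} for t in TRAITS}
    for t in traits:
        positive = frozenset(tr for tr in TRAITS if t.detected(tr))
        co[positive] += 1
        if positive:
            n_any += 1
        if len(positive) >= 2:
            n_multi += 1
        rec = meta.get(t.strain_id)
        for tr in positive:
            if rec is not None:
                src_counts[tr][rec.source.value] = src_counts[tr].get(rec.source.value, 0) + 1
                gen_counts[tr][rec.genus] = gen_counts[tr].get(rec.genus, 0) + 1

    return TraitSummary(
        n_strains=len(traits),
        per_trait=per_trait,
        co_occurrence=co,
        at_least_one=n_any,
        multi_trait=n_multi,
        by_source=pd.DataFrame(src_counts).T.fillna(0).astype(int),
        by_genus=pd.DataFrame(gen_counts).T.fillna(0).astype(int),
    )


def trait_bin_bounds(mean_trait: float, mode: str = "band") -> tuple[float, float]:
    """(lower, upper) cutoffs separating scores 1|2 and 2|3 for a trait."""
    if mean_trait <= 0:
        raise ValueError("mean trait value must be positive")
    if mode == "band":
        return 0.65 * mean_trait, 1.35 * mean_trait
    if mode == "literal":
        return 0.35 * mean_trait, 0.70 * mean_trait
    raise ValueError(f"unknown scoring mode {mode!r}")


def trait_score(value: Optional[float], mean_trait: float, mode: str = "band") -> int:
    """Bonitur score 0-3 for one trait value; ``None`` means not detected."""
    if value is None:
        return 0
    if value < 0:
        raise ValueError("trait value must be >= 0")
    lower, upper = trait_bin_bounds(mean_trait, mode)
    if value >= upper:  # boundary resolves to the higher bin
        return 3
    if value >= lower:
        return 2
    return 1


def biometric_score(strain_id: str, grouping: MeansGrouping,
                    control_id: str = "CONTROL") -> int:
    """Score 0-2 from the strain's Scott-Knott group relative to control.

    2 when the strain's group mean ranks above the control's group, 1 when
    they share a group, 0 when below.
    """
    control_rank = grouping.cluster_index(control_id)
    try:
        strain_rank = grouping.cluster_index(strain_id)
    except KeyError:
        raise KeyError(f"strain {strain_id!r} absent from the means grouping")
    if strain_rank < control_rank:
        return 2
    if strain_rank == control_rank:
        return 1
    return 0


def biometric_score_fixed(value: float, lower: float, upper: float) -> int:
    """Score 0-2 from fixed cutoffs (replays published per-response bounds).

    0 below ``lower``, 1 between the bounds, 2 at/above ``upper``; boundary
    values take the higher bin.
    """
    if lower >= upper:
        raise ValueError("lower cutoff must be below upper cutoff")
    if value >= upper:
        return 2
    if value >= lower:
        return 1
    return 0


@dataclass(frozen=True)
class BoniturResult:
    """Per-component bonitur scores, total and (once ranked) dense rank."""

    strain_id: str
    scores: tuple[int, ...]  # eight components in BONITUR_COMPONENTS order
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.scores) != len(BONITUR_COMPONENTS):
            raise ValueError(f"expected {len(BONITUR_COMPONENTS)} component scores")
        for name, s, cap in zip(
            BONITUR_COMPONENTS, self.scores, (TRAIT_MAX,) * 4 + (BIOMETRIC_MAX,) * 4
        ):
            if not 0 <= s <= cap:
                raise ValueError(f"component {name} score {s} outside [0, {cap}]")

    @property
    def total(self) -> int:
        return sum(self.scores)

    @property
    def biotech_potential(self) -> bool:
        return self.total >= BIOTECH_THRESHOLD


def bonitur_total(strain_id: str, scores) -> BoniturResult:
    """Assemble and validate a strain's eight-component bonitur result."""
    return BoniturResult(strain_id, tuple(int(s) for s in scores))


def rank_strains(results: Iterable[BoniturResult]) -> list[BoniturResult]:
    """Dense-rank strains on descending total; ties share a rank.

    Equal totals get the same rank and the next distinct total gets the
    next integer; display order breaks ties by strain_id.
    """
    results = list(results)
    if not results:
        raise ValueError("no bonitur results to rank")
    ordered = sorted(results, key=lambda r: (-r.total, r.strain_id))
    ranked = []
    rank = 0
    prev_total: Optional[int] = None
    for r in ordered:
        if r.total != prev_total:
            rank += 1
            prev_total = r.total
        ranked.append(BoniturResult(r.strain_id, r.scores, rank=rank))
    return ranked


def bonitur_table(ranked: list[BoniturResult]) -> pd.DataFrame:
    """Ranked results as a tidy table (one row per strain)."""
    return pd.DataFrame([
        {"strain_id": r.strain_id,
         **dict(zip(BONITUR_COMPONENTS, r.scores)),
         "total": r.total, "rank": r.rank,
         "biotech_potential": r.biotech_potential}
        for r in ranked
    ])


def genus_distribution(strains: Iterable[StrainRecord]) -> pd.DataFrame:
    """Per-genus strain counts and percentages (1-decimal display)."""
    strains = list(strains)
    counts: dict[str, int] = {}
    for s in strains:
        counts[s.genus] = counts.get(s.genus, 0) + 1
    total = len(strains)
    df = pd.DataFrame(
        [{"genus": g, "count": c, "percent": round(100.0 * c / total, 1)}
         for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    )
    return df
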
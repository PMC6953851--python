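"""Synthetic strain collections with known ground truth.

The generator emulates the statistical structure of the study's 101-strain
collection so every downstream stage can be tested against a planted
truth: provenance proportions and genus frequencies with one dominant
genus; right-skewed (log-normal) trait values with the observed detection
probabilities; band profiles organized into latent clusters plus
near-identical clone pairs; replicated biomass responses with tiered
group effects; and dilution-series outcomes from the Poisson presence
model at a known density lambda.

Each component draws from its own RNG stream spawned from the master seed,
so enabling or resizing one component does not perturb the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    BandProfile,
    BiomassObservation,
    Collection,
    CONTROL,
    DilutionSeries,
    Medium,
    Soil,
    Source,
    Species,
    StrainRecord,
    TraitMeasurement,
    TRAITS,
)

#: provenance proportions of the emulated collection (isolate counts /101)
DEFAULT_SOURCE_PROPS = {"TR": 42 / 101, "LR": 33 / 101, "BS": 26 / 101}
DEFAULT_SOIL_PROPS = {"ORG": 40 / 101, "SF": 34 / 101, "CH": 27 / 101}
DEFAULT_MEDIUM_PROPS = {"JMV": 49 / 101, "JNFb": 31 / 101, "LGI": 13 / 101,
                        "NFb": 6 / 101, "LGI-P": 2 / 101}
DEFAULT_GENUS_FREQS = {
    "Rhizobium": 0.58, "Pseudomonas": 0.12, "Burkholderia": 0.11,
    "Enterobacter": 0.05, "Variovorax": 0.04, "Cupriavidus": 0.03,
    "Stenotrophomonas": 0.02, "Caulobacter": 0.01, "Novosphingobium": 0.01,
    "Xanthomonas": 0.01, "Pelomonas": 0.01, "unclassified": 0.01,
}
#: per-trait detection probability (fraction of positive strains)
DEFAULT_DETECTION_PROBS = {"iaa": 0.485, "fepo4": 0.713, "alpo4": 0.435,
                           "siderophore_index": 0.435}
#: per-trait (target mean, (min, max)) of the positive-value distribution;
#: siderophore values are 1 + lognormal (index >= 1 by definition)
DEFAULT_TRAIT_VALUE_PARAMS = {
    "iaa": (33.0, (2.96, 193.97)),
    "fepo4": (6.36, (0.40, 56.00)),
    "alpo4": (3.85, (0.62, 17.05)),
    "siderophore_index": (0.7, (0.06, 2.23)),  # offset above 1
}
#: control dry-weight means in g/plant (species -> (rdw, sdw))
DEFAULT_CONTROL_MEANS = {"tomato": (0.25, 0.83), "lulo": (0.12, 0.315)}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic collection."""

    n_strains: int = 101
    source_props: dict = field(default_factory=lambda: dict(DEFAULT_SOURCE_PROPS))
    soil_props: dict = field(default_factory=lambda: dict(DEFAULT_SOIL_PROPS))
    medium_props: dict = field(default_factory=lambda: dict(DEFAULT_MEDIUM_PROPS))
    genus_freqs: dict = field(default_factory=lambda: dict(DEFAULT_GENUS_FREQS))
    detection_probs: dict = field(default_factory=lambda: dict(DEFAULT_DETECTION_PROBS))
    trait_value_params: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_VALUE_PARAMS))
    # fingerprint structure
    n_band_clusters: int = 12
    bands_per_profile: int = 10
    band_jitter_fraction: float = 0.002  # well below the 2% matching tolerance
    n_clone_pairs: int = 5
    # biomass design
    r_replicates: int = 5
    control_means: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_MEANS))
    effect_tier_probs: tuple = (0.3, 0.4, 0.3)  # P(decrease), P(null), P(increase)
    effect_magnitude_range: tuple = (0.08, 0.25)  # fraction of control mean
    residual_cv: float = 0.06
    # dilution design
    dilution_amounts: tuple = (1e-4, 1e-5, 1e-6)  # g of original material
    n_vials: int = 3
    lambda_range: tuple = (5e3, 5e5)  # true densities, log-uniform (cells/g)
    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("source_props", "soil_props", "medium_props", "genus_freqs",
                     "detection_probs"):
            for k, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k!r}] = {v} outside [0, 1]")
        if self.n_strains < 0:
            raise ValueError("n_strains must be >= 0")
        if self.r_replicates < 2:
            raise ValueError("need r >= 2 replicates for ANOVA")
        if self.n_clone_pairs * 2 > max(self.n_strains, 1):
            raise ValueError("clone pairs cannot exceed half the strains")
        if any(l <= 0 for l in self.lambda_range):
            raise ValueError("lambda range must be positive")
        if self.band_jitter_fraction < 0:
            raise ValueError("band jitter must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters of a generated collection."""

    trait_values: dict = field(default_factory=dict)  # strain -> {trait: value|None}
    band_cluster: dict = field(default_factory=dict)  # strain -> cluster label
    clone_pairs: list = field(default_factory=list)  # [(strain_a, strain_b), ...]
    biomass_effect: dict = field(default_factory=dict)  # (species, strain) -> fraction
    lambda_true: dict = field(default_factory=dict)  # sample_id -> cells/g

    def to_json(self, path) -> None:
        payload = {
            "trait_values": self.trait_values,
            "band_cluster": self.band_cluster,
            "clone_pairs": self.clone_pairs,
            "biomass_effect": {f"{sp}:{sid}": e for (sp, sid), e in self.biomass_effect.items()},
            "lambda_true": self.lambda_true,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _lognormal_params(target_mean: float, value_range: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean whose ~99% span matches the range."""
    lo, hi = value_range
    sigma = math.log(hi / lo) / (2 * 2.575829)
    mu = math.log(target_mean) - sigma ** 2 / 2.0
    return mu, sigma


def _allocate(n: int, props: dict) -> list[str]:
    """Deterministic largest-remainder allocation of n items to categories."""
    keys = list(props)
    raw = np.array([props[k] for k in keys], dtype=float)
    raw = raw / raw.sum() * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    out: list[str] = []
    for k, c in zip(keys, base):
        out.extend([k] * int(c))
    return out


def generate_dilution_series(lam: float, amounts, n_vials: int,
                             rng: np.random.Generator,
                             sample_id: str = "sample") -> DilutionSeries:
    """Dilution outcomes under the Poisson presence model.

    Each vial at amount ``m`` is positive independently with probability
    ``1 - exp(-lam * m)``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if any(m <= 0 for m in amounts):
        raise ValueError("amounts must be positive")
    positives = tuple(
        int(rng.binomial(n_vials, 1.0 - math.exp(-lam * m))) for m in amounts
    )
    return DilutionSeries(sample_id, tuple(amounts), (n_vials,) * len(amounts), positives)


def generate_collection(config: SimulationConfig) -> tuple[Collection, GroundTruth]:
    """Generate a full synthetic collection and its ground truth.

    Deterministic given ``config.seed``.  Strain ids are "S001"...;
    component RNG streams (strains, traits, bands, biomass, dilutions) are
    spawned independently from the master seed.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rng_strains, rng_traits, rng_bands, rng_biomass, rng_dil = (
        np.random.default_rng(s) for s in master.spawn(5)
    )

    n = config.n_strains
    truth = GroundTruth()
    collection = Collection()
    if n == 0:
        return collection, truth

    ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- strain records -----------------------------------------------------
    sources = _allocate(n, config.source_props)
    soils = _allocate(n, config.soil_props)
    media = _allocate(n, config.medium_props)
    genera = _allocate(n, config.genus_freqs)
    for perm_target in (sources, soils, media, genera):
        rng_strains.shuffle(perm_target)
    collection.strains = [
        StrainRecord(sid, Source(src), Soil(so), Medium(me), ge)
        for sid, src, so, me, ge in zip(ids, sources, soils, media, genera)
    ]

    # --- traits -------------------------------------------------------------
    for sid in ids:
        values: dict[str, Optional[float]] = {}
        for trait in TRAITS:
            if rng_traits.random() < config.detection_probs[trait]:
                mean, rng_range = config.trait_value_params[trait]
                mu, sigma = _lognormal_params(mean, rng_range)
                v = float(rng_traits.lognormal(mu, sigma))
                if trait == "siderophore_index":
                    v += 1.0  # halo at least as wide as the colony
                values[trait] = round(v, 4)
            else:
                values[trait] = None
        truth.trait_values[sid] = values
        collection.traits.append(TraitMeasurement(sid, **values))

    # --- band profiles ------------------------------------------------------
    # Cluster members share the prototype's bands and each carries one
    # unique private band, placing within-cluster Jaccard around 0.86:
    # above the 70% group cutoff, below the 95% clone threshold.  Clone
    # pairs copy a partner's full profile up to tiny jitter.
    n_clusters = max(1, min(config.n_band_clusters, n))

    def sample_band(existing: list[float], min_gap: float = 0.05) -> float:
        while True:
            b = float(np.exp(rng_bands.uniform(np.log(100.0), np.log(3000.0))))
            if all(abs(b - e) > min_gap * (b + e) / 2.0 for e in existing):
                return b

    prototypes: list[np.ndarray] = []
    for _ in range(n_clusters):
        bands: list[float] = []
        for _ in range(config.bands_per_profile):
            bands.append(sample_band(bands))
        prototypes.append(np.sort(bands))
    cluster_of = [int(c) for c in rng_bands.integers(0, n_clusters, size=n)]

    def jittered(sizes: np.ndarray, scale: float) -> tuple[float, ...]:
        jit = sizes * (1.0 + rng_bands.normal(0, scale, size=sizes.size))
        return tuple(np.sort(np.round(jit, 1)))

    taken_private: dict[int, list[float]] = {c: list(prototypes[c]) for c in range(n_clusters)}
    profiles: dict[str, BandProfile] = {}
    for sid, c in zip(ids, cluster_of):
        truth.band_cluster[sid] = c
        private = sample_band(taken_private[c])
        taken_private[c].append(private)
        member = np.sort(np.append(prototypes[c], private))
        profiles[sid] = BandProfile(sid, jittered(member, config.band_jitter_fraction))

    pair_ids = rng_bands.choice(n, size=2 * config.n_clone_pairs, replace=False)
    for a, b in zip(pair_ids[::2], pair_ids[1::2]):
        sa, sb = ids[int(a)], ids[int(b)]
        base = np.array(profiles[sa].bands)
        profiles[sb] = BandProfile(sb, jittered(base, config.band_jitter_fraction / 4))
        truth.band_cluster[sb] = truth.band_cluster[sa]
        truth.clone_pairs.append((sa, sb))
    collection.bands = [profiles[sid] for sid in ids]

    # --- biomass ------------------------------------------------------------
    tiers = (-1, 0, 1)
    for species in (Species.TOMATO, Species.LULO):
        rdw0, sdw0 = config.control_means[species.value]
        for treatment in [CONTROL] + ids:
            if treatment == CONTROL:
                effect = 0.0
            else:
                tier = tiers[int(rng_biomass.choice(3, p=config.effect_tier_probs))]
                magnitude = float(rng_biomass.uniform(*config.effect_magnitude_range))
                effect = tier * magnitude
            truth.biomass_effect[(species.value, treatment)] = effect
            for rep in range(1, config.r_replicates + 1):
                rdw_mean = rdw0 * (1.0 + effect)
                sdw_mean = sdw0 * (1.0 + effect)
                rdw = max(0.0, rng_biomass.normal(rdw_mean, config.residual_cv * rdw0))
                sdw = max(0.0, rng_biomass.normal(sdw_mean, config.residual_cv * sdw0))
                collection.biomass.append(
                    BiomassObservation(species, treatment, rep, round(rdw, 5), round(sdw, 5))
                )

    # --- dilution series: one per (source, soil) sample ----------------------
    lo, hi = config.lambda_range
    for source in Source:
        for soil in Soil:
            sample_id = f"{source.value}-{soil.value}"
            lam = float(np.exp(rng_dil.uniform(np.log(lo), np.log(hi))))
            truth.lambda_true[sample_id] = lam
            collection.dilutions.append(
                generate_dilution_series(lam, config.dilution_amounts,
                                         config.n_vials, rng_dil, sample_id)
            )

    return collection, truth
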
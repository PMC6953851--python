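"""Domain types shared by every stage of the screening pipeline.

The pipeline describes a culturable-microbiome strain screen: bacteria
isolated from bulk soil (BS) or from unwashed tomato/lulo roots (TR/LR),
grown from three soil managements (secondary forest SF, conventional
horticulture CH, organic ORG) on five semisolid N-free media.  Each strain
carries in-vitro trait measurements (IAA, phosphate solubilization,
siderophore index), a BOX-PCR band profile, and greenhouse biomass
responses; each sample carries a serial-dilution outcome used for
most-probable-number population estimates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Source(str, Enum):
    """Isolation source: bulk soil, tomato roots, or lulo roots."""

    BS = "BS"
    TR = "TR"
    LR = "LR"


class Soil(str, Enum):
    """Soil management: secondary forest, conventional or organic horticulture."""

    SF = "SF"
    CH = "CH"
    ORG = "ORG"


class Medium(str, Enum):
    """Semisolid N-free isolation media."""

    JMV = "JMV"
    NFB = "NFb"
    JNFB = "JNFb"
    LGI = "LGI"
    LGI_P = "LGI-P"


class Species(str, Enum):
    """Trap/greenhouse plant species."""

    TOMATO = "tomato"
    LULO = "lulo"


CONTROL = "CONTROL"

#: Trait column names in canonical order.
TRAITS = ("iaa", "fepo4", "alpo4", "siderophore_index")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def normalize_strain_id(strain_id: str) -> str:
    """Canonical form of a strain label for identity comparison.

    Leading zeros in the numeric prefix are not significant ("04T" and
    "4T" name the same strain); the text form is preserved elsewhere.
    """
    return re.sub(r"^0+(?=\d)", "", strain_id.strip())


def parse_source_soil(token: str) -> tuple[Source, Soil]:
    """Parse a combined provenance token such as ``"BS-ORG"`` or ``"TR-CH"``."""
    parts = token.strip().split("-")
    if len(parts) != 2:
        raise ValidationError(f"cannot parse source-soil token {token!r}")
    return Source(parts[0]), Soil(parts[1])


@dataclass(frozen=True)
class StrainRecord:
    """Identity and provenance of one isolated strain."""

    strain_id: str
    source: Source
    soil: Soil
    medium: Medium
    genus: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValidationError("strain_id must be non-empty")


@dataclass(frozen=True)
class TraitMeasurement:
    """In-vitro trait values for one strain.

    ``None`` encodes "below the detection limit", which is distinct from a
    measured zero in storage although both receive bonitur bin score 0.
    Units: iaa in ug IAA per mg protein; fepo4/alpo4 solubilized P on the
    study's mg-per-unit scale; siderophore_index is the unitless halo/colony
    diameter ratio (>= 1 when a halo is present).
    """

    strain_id: str
    iaa: Optional[float] = None
    fepo4: Optional[float] = None
    alpo4: Optional[float] = None
    siderophore_index: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("iaa", "fepo4", "alpo4"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v} for {self.strain_id}")
        si = self.siderophore_index
        if si is not None and si < 1:
            raise ValidationError(
                f"siderophore_index must be >= 1 when detected (halo >= colony), got {si}"
            )

    def value(self, trait: str) -> Optional[float]:
        if trait not in TRAITS:
            raise KeyError(trait)
        return getattr(self, trait)

    def detected(self, trait: str) -> bool:
        return self.value(trait) is not None


@dataclass(frozen=True)
class BiomassObservation:
    """One replicate's dry-weight response in the greenhouse trial."""

    species: Species
    treatment: str  # strain_id or CONTROL
    replicate: int
    rdw: float
    sdw: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate index starts at 1")
        if self.rdw < 0 or self.sdw < 0:
            raise ValidationError("dry weights must be >= 0")


@dataclass(frozen=True)
class DilutionSeries:
    """Presence/absence outcomes across a serial dilution for one sample.

    ``amounts`` is the mass of original material per inoculated vial in
    grams (dilution factor x inoculated volume), strictly decreasing.
    """

    sample_id: str
    amounts: tuple[float, ...]
    n_vials: tuple[int, ...]
    n_positive: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.amounts) == len(self.n_vials) == len(self.n_positive)):
            raise ValidationError("dilution series arrays must have equal length")
        if len(self.amounts) == 0:
            raise ValidationError("dilution series must have at least one level")
        if any(a <= 0 for a in self.amounts):
            raise ValidationError("amounts must be positive")
        if any(b >= a for a, b in zip(self.amounts, self.amounts[1:])):
            raise ValidationError("amounts must be strictly decreasing")
        for n, g in zip(self.n_vials, self.n_positive):
            if n < 1:
                raise ValidationError("each dilution level needs >= 1 vial")
            if not 0 <= g <= n:
                raise ValidationError("n_positive must lie in [0, n_vials]")


@dataclass(frozen=True)
class BandProfile:
    """Ordered fragment sizes (bp) of one strain's rep-PCR fingerprint."""

    strain_id: str
    bands: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bands):
            raise ValidationError("band sizes must be positive")
        if list(self.bands) != sorted(self.bands):
            raise ValidationError("bands must be sorted ascending")
        rounded = [round(b) for b in self.bands]
        if len(set(rounded)) != len(rounded):
            raise ValidationError("duplicate band sizes after rounding to 1 bp")


_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class Alignment:
    """Aligned nucleotide sequences keyed by strain id, all equal length."""

    sequences: tuple[tuple[str, str], ...]  # (strain_id, sequence) in input order

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError("aligned sequences must have equal length")
        for sid, seq in self.sequences:
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValidationError(f"sequence {sid} has characters outside A,C,G,T,N,-: {bad}")

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, strain_id: str) -> str:
        for sid, seq in self.sequences:
            if sid == strain_id:
                return seq
        raise KeyError(strain_id)


@dataclass
class Collection:
    """A full strain collection: the unit every pipeline stage consumes."""

    strains: list[StrainRecord] = field(default_factory=list)
    traits: list[TraitMeasurement] = field(default_factory=list)
    biomass: list[BiomassObservation] = field(default_factory=list)
    dilutions: list[DilutionSeries] = field(default_factory=list)
    bands: list[BandProfile] = field(default_factory=list)
    alignment: Optional[Alignment] = None

    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains]


def validate_collection(collection: Collection) -> list[str]:
    """Cross-reference checks; returns warnings, raises on hard violations.

    Hard violations: duplicate strain ids (after normalization); a biomass
    table lacking a CONTROL treatment for a species present in the data.
    Soft: trait/band/biomass rows whose strain_id is absent from the
    strain list are reported as warnings.
    """
    warnings: list[str] = []
    norm_ids = [normalize_strain_id(s.strain_id) for s in collection.strains]
    seen: set[str] = set()
    for sid in norm_ids:
        if sid in seen:
            raise ValidationError(f"duplicate strain_id (after normalization): {sid}")
        seen.add(sid)

    known = set(norm_ids)

    def check(label: str, sid: str) -> None:
        if normalize_strain_id(sid) not in known:
            warnings.append(f"{label} references unknown strain_id {sid!r}")

    for t in collection.traits:
        check("trait row", t.strain_id)
    for b in collection.bands:
        check("band profile", b.strain_id)

    species_with_control: dict[Species, bool] = {}
    for obs in collection.biomass:
        species_with_control.setdefault(obs.species, False)
        if obs.treatment == CONTROL:
            species_with_control[obs.species] = True
        else:
            check("biomass row", obs.treatment)
    for sp, has_ctrl in species_with_control.items():
        if not has_ctrl:
            raise ValidationError(f"biomass table for {sp.value} lacks a CONTROL treatment")

    # balanced-design check: unbalance is allowed but flagged
    counts: dict[tuple[Species, str], int] = {}
    for obs in collection.biomass:
        counts[(obs.species, obs.treatment)] = counts.get((obs.species, obs.treatment), 0) + 1
    by_species: dict[Species, set[int]] = {}
    for (sp, _), c in counts.items():
        by_species.setdefault(sp, set()).add(c)
    for sp, cs in by_species.items():
        if len(cs) > 1:
            warnings.append(f"unbalanced biomass design for {sp.value}: replicate counts {sorted(cs)}")
    return warnings
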
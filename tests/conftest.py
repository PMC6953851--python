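import pytest

from pgpbscreen.model import (
    Alignment,
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
)
from pgpbscreen.simulate import SimulationConfig, generate_collection


@pytest.fixture
def small_collection() -> Collection:
    """Two strains with every data type populated, controls included."""
    strains = [
        StrainRecord("01T", Source.TR, Soil.SF, Medium.JMV, "Rhizobium"),
        StrainRecord("02S", Source.BS, Soil.ORG, Medium.JNFB, "Pseudomonas"),
    ]
    traits = [
        TraitMeasurement("01T", iaa=12.5, fepo4=3.2, alpo4=None, siderophore_index=1.5),
        TraitMeasurement("02S", iaa=None, fepo4=8.123456, alpo4=0.9, siderophore_index=None),
    ]
    biomass = []
    for sp, base in ((Species.TOMATO, 0.25), (Species.LULO, 0.12)):
        for trt, shift in ((CONTROL, 0.0), ("01T", 0.03), ("02S", -0.02)):
            for rep in range(1, 4):
                v = base + shift + 0.001 * rep
                biomass.append(BiomassObservation(sp, trt, rep, v, 3 * v))
    dilutions = [DilutionSeries("BS-SF", (1e-4, 1e-5, 1e-6), (3, 3, 3), (3, 1, 0))]
    bands = [
        BandProfile("01T", (100.0, 200.0, 300.0)),
        BandProfile("02S", (101.0, 200.0, 400.0)),
    ]
    alignment = Alignment((("01T", "ACGTACGT"), ("02S", "ACGAACGT")))
    return Collection(strains, traits, biomass, dilutions, bands, alignment)


@pytest.fixture(scope="session")
def synthetic():
    """One 101-strain synthetic collection with ground truth (fixed seed)."""
    return generate_collection(SimulationConfig(seed=42))
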
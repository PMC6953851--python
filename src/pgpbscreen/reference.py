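"""Reference dataset shipped with the package.

Small tables from the published survey of 101 diazotrophic/N-scavenging
strains isolated from *Solanum* soils and rhizospheres: the per-medium MPN
summary grid, the component bonitur scores of the 24 strains flagged with
biotechnological potential, and the genus census.  They serve as worked
inputs for the summary arithmetic and the scoring/ranking engine.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: positive-strain mean trait values reported by the survey (display units)
REPORTED_TRAIT_MEANS = {"fepo4": 6.36, "alpo4": 3.85}

#: reported detection counts out of 101 strains
REPORTED_TRAIT_POSITIVES = {"iaa": 49, "fepo4": 72, "alpo4": 44, "siderophore_index": 44}

#: published score-bin cutoffs per trait (lower, upper)
REPORTED_TRAIT_CUTOFFS = {
    "iaa": (21.5, 44.7),
    "fepo4": (4.1, 8.4),
    "alpo4": (2.5, 5.2),
    "siderophore_index": (1.1, 2.4),
}

#: published biometric score cutoffs (lower, upper) in g/plant
REPORTED_BIOMETRIC_CUTOFFS = {
    ("tomato", "rdw"): (0.23, 0.27),
    ("tomato", "sdw"): (0.79, 0.87),
    ("lulo", "rdw"): (0.11, 0.13),
    ("lulo", "sdw"): (0.30, 0.33),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("pgpbscreen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_mpn_table() -> pd.DataFrame:
    """Survey MPN grid: source, soil, medium, isolate count n, display MPN."""
    return _read("reference_mpn_table.tsv")


def load_bonitur_scores() -> pd.DataFrame:
    """Component bonitur scores of the 24 flagged strains plus printed totals/ranks."""
    return _read("reference_bonitur.tsv")


def load_genus_counts() -> pd.DataFrame:
    """Genus census of the 101-strain collection (genus, class, count)."""
    return _read("reference_genus_counts.tsv")
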
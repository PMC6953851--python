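# pgpbscreen

A tested, reusable implementation of the computational chain used to
screen culturable plant growth-promoting bacteria (PGPB): strains isolated
from soils and *Solanum* rhizospheres on N-free semisolid media are
quantified by most-probable-number (MPN) estimation, genotyped by rep-PCR
(BOX-PCR) fingerprint clustering, placed in a 16S distance phylogeny,
compared in greenhouse trials by ANOVA with Scott-Knott means grouping,
and finally prioritized by an additive multi-trait **bonitur** score.

It is aimed at microbiologists and bioinformaticians running culturable-
microbiome strain screens who want each analysis step reproducible from
plain tab-separated tables rather than locked inside spreadsheet or
commercial gel-analysis workflows.

## The methods in brief

- **MPN estimation.** A vial inoculated with `m` grams of sample at cell
  density λ turns positive with probability `1 − exp(−λm)`. With `g_i`
  positives of `n_i` vials at amounts `m_i`, the maximum-likelihood λ
  solves `Σ g_i m_i e^{−λm_i}/(1−e^{−λm_i}) = Σ (n_i−g_i) m_i`, found by
  bracketed root finding; a 95% interval comes from the observed
  information of ln λ. Survey arithmetic (per-sample totals, per-medium
  and per-soil means of the ×10⁴ display values) is included.
- **Fingerprint clustering.** Bands match under a proportional size
  tolerance (default 2% of the mean size); profile similarity is the
  Jaccard coefficient `m/(|a|+|b|−m)`; UPGMA on `d = 1 − s` with group
  calling at a 70% similarity cutoff and near-clonal counting at 95%.
- **Phylogeny.** Kimura 2-parameter distances
  `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)` with pairwise deletion, Saitou–Nei
  neighbor joining, and bootstrap support from column resampling.
- **Group statistics.** One-way ANOVA per (species, response); Scott-Knott
  recursive partitioning of sorted means using the λ statistic with a
  χ² approximation at `ν₀ = k/(π−2)` degrees of freedom; Pearson
  correlation.
- **Bonitur scoring.** Four in-vitro traits (IAA, FePO₄ and AlPO₄
  solubilization, siderophore index) scored 0–3 against the positive-
  strain mean; four biometric responses (root/shoot dry weight in tomato
  and lulo) scored 0–2 against the control's Scott-Knott group; total out
  of 20, dense-ranked, with totals ≥ 10 flagged as biotech candidates.

A synthetic-data module generates full collections with known ground
truth (planted trait detections, band clusters and clone pairs, biomass
effect tiers, true densities) so every stage is testable end to end.

## Worked example

```sh
pgpbscreen --seed 7 simulate --n-strains 101 --out demo
pgpbscreen score --collection demo --out demo/bonitur.tsv
# -> scored 101 strains; 30 with total >= 10 -> demo/bonitur.tsv
head -3 demo/bonitur.tsv
```

```text
strain_id  iaa  fepo4  alpo4  siderophore_index  tomato_rdw  tomato_sdw  lulo_rdw  lulo_sdw  total  rank  biotech_potential
S067       3    1      3      2                  2           2           2         2         17     1     True
S090       2    3      2      2                  2           2           2         2         17     1     True
```

Each row gives a strain's eight component scores, their sum (max 20) and
its dense rank; `biotech_potential` marks totals ≥ 10. The fingerprint and
dilution stages on the same collection:

```sh
pgpbscreen fingerprint --bands demo/bands.tsv --out demo/groups.tsv --newick demo/dend.nwk
# -> 12 groups at 70%; 96 distinct profiles at 95% (5 near-clonal sets)
pgpbscreen mpn --dilutions demo/dilutions.tsv --out demo/mpn.tsv
# -> estimated MPN for 9 samples -> demo/mpn.tsv
```

The 12 groups and 5 near-clonal sets are exactly the planted band
clusters and clone pairs of the simulated collection (101 − 5 = 96
distinct profiles); `demo/mpn.tsv` lists λ̂ with its 95% interval and the
×10⁴ display value per sample. Library use mirrors the CLI: see
`pgpbscreen.pipeline.run_screen` for the one-call version and
`docs/methods.md` for models, defaults and caveats.

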
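# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer should know.

## MPN estimation (`pgpbscreen.mpn`)

**Model.** Vials inoculated with `m` grams of original material from a
sample of density λ (cells g⁻¹) turn positive independently with
probability `1 − exp(−λm)` (single-hit Poisson model). The
maximum-likelihood estimate solves the score equation

    Σ_i g_i m_i e^{−λm_i} / (1 − e^{−λm_i}) = Σ_i (n_i − g_i) m_i

by Brent root finding on an initial bracket of [10⁻³, 10¹²] cells g⁻¹,
expanded geometrically when needed, to relative tolerance better than
10⁻⁸. The 95% interval is `exp(ln λ̂ ± 1.96·SE)` with
`SE² = 1/(λ̂² J(λ̂))` from the observed information
`J(λ) = Σ g_i m_i² e^{−λm_i}/(1−e^{−λm_i})²`.

**Degenerate series.** All-negative: λ̂ = 0 with the exact upper bound
`ln 20 / Σ n_i m_i` (the largest λ whose all-negative probability is
≥ 0.05). All-positive: the likelihood is increasing in λ, so the estimate
is flagged unbounded and only the analogous lower bound is reported.

**Survey arithmetic.** Display values are λ̂/10⁴ rounded to two decimals.
Sample totals sum per-medium display values, including media with growth
but no retrieved isolates. Per-medium means divide by the number of
samples (nine), counting absent media as zero; per-soil means average the
three sample totals per soil. Computation is done at full precision and
rounded only for display; comparisons of displayed values use a 0.015
tolerance to absorb per-cell rounding. With three vials per level the
estimator is coarse (median relative error ≈ 25% in the shipped
synthetic runs); it tightens as vials per dilution grow, and interval
coverage is close to nominal at 50 vials. The dilution design (three
levels of 10⁻⁴–10⁻⁶ g, three vials each) is a convention: the number of
vials per dilution in the original survey design is not recorded.

## Fingerprint analysis (`pgpbscreen.fingerprint`)

Band sizes x, y are matchable when `|x − y| ≤ tol·(x+y)/2` with tol
defaulting to 0.02; the tolerance is taken relative to the mean of the
two sizes so the relation is symmetric, matching gel-analysis convention.
Matching is a greedy pass over matchable pairs ordered by size difference
(deterministic, identical to the optimal assignment when bands are well
separated); an exact maximum-cardinality assignment is available via
`exact=True` for ambiguous profiles. Similarity is Jaccard on the matched
count; two empty profiles are defined as identical (similarity 1).

UPGMA agglomerates on `d = 1 − s` with the size-weighted average-linkage
recurrence; ties on the minimal distance are broken by the
lexicographically earliest pair of cluster labels (a cluster's label is
the input position of its first member), so dendrograms are reproducible.
Group calling cuts the dendrogram into maximal subtrees whose merges all
sit at or above the cutoff (0.70 for diversity groups); profile counting
cuts at 0.95 and reports groups of size ≥ 2 as near-clonal sets. Raising
the cutoff always refines the partition. Newick export writes ultrametric
branch lengths as height increments.

## Phylogeny (`pgpbscreen.phylo`)

K2P distances use pairwise deletion: sites with a gap or N in either
sequence of a pair are excluded (this maximizes usable sites per pair;
complete deletion is a stricter alternative not implemented). Saturation
(either log argument non-positive) raises an error rather than returning
a truncated distance. Neighbor joining follows the Saitou–Nei Q-criterion
with deterministic tie-breaking by taxon index; negative branch lengths
are clamped to zero for display, with the raw value kept on each node as
`raw_length` and the total deficit logged. Bootstrap resamples alignment
columns with replacement, skips replicates that saturate (an error is
raised if more than 10% do), and reports for every internal edge the
fraction of replicates containing the same unrooted bipartition in
leaf-label canonical form.

## Group statistics (`pgpbscreen.stats`)

One-way ANOVA is computed per (species, response) with the textbook
decomposition. Scott-Knott recursively splits the sorted means: the
maximal between-group sum of squares B₀ over the k−1 contiguous splits is
tested with `λ = π/(2(π−2)) · B₀/σ̂₀²`,
`σ̂₀² = (Σ(ȳᵢ−ȳ)² + ν·MSE/r)/(k+ν)`, against the χ² quantile at
`ν₀ = k/(π−2)` (non-integer, evaluated with the continuous quantile
function); accepted halves are re-tested recursively. Unbalanced designs
replace r by the harmonic mean of group sizes and are flagged. Group
labels run a, b, c, … from the highest mean down, so "above the
control's group" is well defined for scoring.

Two behavioural notes. First, clusters are always contiguous intervals in
mean order by construction. Second, because each accepted half is
re-tested at level α, even perfectly separated effect tiers are split
further at roughly rate α per tier; on planted two-tier data the
procedure separates the tiers essentially always but returns exactly two
groups only ~86–90% of the time at α = 0.05. This is a property of the
procedure, not noise in the implementation.

## Screening and bonitur (`pgpbscreen.screening`)

Trait summaries count positives (detected values; a not-detected cell is
distinct from a measured zero in storage, though both score 0) and
compute means over positive strains only, plus co-occurrence counts over
all subsets of the four traits and per-source/per-genus cross-tabs.

Trait scores use bins derived from the positive-strain mean m. The
default **band** mode places the 1|2 and 2|3 cutoffs at `0.65·m` and
`1.35·m` (a ±35% band around the mean); the **literal** mode places them
at `0.35·m` and `0.70·m`. Band mode is the default because only it
reproduces the published per-trait cutoffs from the published means
(e.g. AlPO₄ mean 3.85 → bounds 2.5/5.2; FePO₄ mean 6.36 → 4.1/8.6 vs
printed 4.1/8.4, within the rounding of a mean reported to two decimals),
whereas the literal reading gives 1.35/2.70 for AlPO₄, which matches no
published bound. Boundary values always take the higher bin.

Biometric scores default to the Scott-Knott-relative rule (2/1/0 for a
group above/with/below the control's); a fixed-cutoff variant replays
published per-response bounds. The bonitur total sums four 0–3 trait
scores and four 0–2 biometric scores (max 20); totals ≥ 10 flag
biotechnological potential. Ranking is dense on descending total — tied
totals share a rank and the next distinct total takes the next integer —
with ties ordered by strain id for display only.

Strains without greenhouse data receive the neutral biometric score 1
(indistinguishable from control) rather than being dropped, so partially
characterized collections still rank.

## Synthetic data (`pgpbscreen.simulate`)

The generator emulates the survey's statistical shape with 101 strains by
default: provenance proportions from the survey's isolate counts, one
dominant genus (*Rhizobium*, 58%), per-trait detection probabilities
(IAA 0.485, FePO₄ 0.713, AlPO₄ 0.435, siderophore 0.435), and positive
trait values drawn log-normal with the published positive-strain mean and
a σ set so the ~99% span matches the published range (printed ranges are
strongly right-skewed, e.g. IAA 2.96–193.97 around a mean near 33).
Siderophore indices are 1 + log-normal, respecting the halo ≥ colony
floor.

Band profiles: each of 12 latent clusters has a 10-band prototype
(log-uniform 100–3000 bp, minimum 5% relative separation so matching is
unambiguous at the 2% tolerance); members carry the prototype plus one
unique private band, putting within-cluster Jaccard near 10/12 ≈ 0.86 —
above the 0.70 group cutoff, below the 0.95 clone threshold — and all
bands are jittered by 0.2% (≪ tolerance). Five clone pairs duplicate a
partner's full profile with quarter-strength jitter, so the expected
distinct-profile count at 95% is exactly n − 5.

Biomass: five replicates per (species, treatment); control means sit at
the midpoints of the published score bins (tomato RDW 0.25, SDW 0.83 g;
lulo RDW 0.12, SDW 0.315 g); each strain×species draws an effect tier
(decrease/null/increase with probabilities 0.3/0.4/0.3) and a magnitude
of 8–25% of the control mean, with normal residuals at 6% CV — the
survey reports only qualitative per-strain outcomes, so these tiers are a
stylized stand-in. Dilution series use the Poisson presence model at a
log-uniform true density of 5×10³–5×10⁵ cells g⁻¹ per (source, soil)
sample.

Each component (strains, traits, bands, biomass, dilutions) uses its own
RNG stream spawned from the master seed, so changing one component's
parameters does not perturb the draws of another.

**What passing on synthetic data does not show.** The generator plants
exactly the structure each stage assumes: clean band clusters, normal
homoscedastic residuals, independent trait detections, single-hit MPN
vials. Real gels smear and drop bands, real trait assays are correlated
within phylogenetic groups, and real biomass variances differ between
treatments — recovery on synthetic data validates the algorithms, not
robustness to those violations. 16S alignments are likewise not simulated
realistically; phylogeny tests use star/additive fixture trees and
planted-clade alignments from `pgpbscreen.phylo`.

## Known limitations

- The MPN stage offers only the log-normal observed-information interval;
  no bias-corrected (Cornish-Fisher) variants.
- Band calling from gel images, taxonomic classification against external
  databases, and maximum-likelihood trees are out of scope.
- The survey's per-medium JMV and LGI means (9.98 and 2.85 ×10⁴) are not
  recoverable from its printed per-sample grid under any divisor; the
  shipped arithmetic reproduces the JNFb mean and the per-soil means and
  leaves those two uncorroborated.
- Scott-Knott inherits the liberal small-k behaviour of its χ²
  approximation; null split rates track α only approximately.
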
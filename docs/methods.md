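# Methods

This note documents the statistical procedures implemented in `pathtriad`,
the defaults and why they were chosen, the numerical decisions, what the
synthetic-data generator does and does not emulate, and known limitations.

## Profile integration

A *ratio profile* maps gene symbols to log2 expression ratios for one
comparison of two cell types.  Profiles are keyed by uppercase gene symbol
(the namespace gene-set collections use); the mass-spectrometry accession is
carried as metadata.  Reading a file with duplicate symbols keeps the record
with the largest |log2 ratio| — the strongest signal — and logs a warning.
Keying by accession instead is available (`read_profile(key_on="accession")`)
for workflows that resolve symbols later.

Two merge operations:

* **Technical merge** (two MS runs of one sample).  Only proteins quantified
  in both runs are retained (strict intersection; `union=True` relaxes
  this).  A shared protein is *removed* when its two log2 ratios point in
  strictly opposite directions **and** its linear fold changes differ by
  more than `conflict_threshold` (default 5): such a protein is
  irreconcilable between runs.  The threshold is applied on the linear
  fold-change scale, `|2^r1 − 2^r2| > 5`, because a "difference of fold
  changes" is a linear-scale quantity; direction is judged on the log2 scale
  with 0 counting as neither direction (a zero ratio can never form a
  conflict).  Every retained shared protein gets the arithmetic mean of its
  two log2 ratios — the geometric mean of the ratios, the natural average
  for multiplicative quantities.
* **Biological merge** (two cell lines, same kind of comparison).
  Intersection plus log2-ratio mean; no conflict removal, because
  between-line disagreement is biology, not measurement error.

`build_three_profiles` fixes the merging tree: the two iPS-vs-precursor
profiles merge into hiPSCs/HFF; the two ES-vs-precursor profiles into
hESCs/HFF; the four cross profiles merge in two stages (iPS lines within
each ES line first, then across ES lines) into hiPSCs/hESCs.  Every merge
emits an `IntegrationReport` (input sizes, intersection, removals) so
profile-size accounting is auditable.

## Similarity

Spearman rank correlation over the proteins shared by two profiles
(at least 3 required).  Ties get average ranks (rank-Pearson definition,
via `scipy.stats.spearmanr`), which reduces to the classical
`1 − 6·Σd²/(n(n²−1))` when ranks are distinct; the test suite checks
agreement with an independently coded rank-Pearson oracle to 1e-12 and
invariance under strictly monotone transforms.  Rank correlation is used
because log2-ratio distributions of label-free proteomics are not well
described by a parametric family.  Ratio histograms centre a bin on zero so
the spike of unchanged proteins is not split at a bin edge.

## Enrichment engine

Proteins are ranked by descending log2 ratio; every quantified protein
participates (no fold-change filter).  Rank ties are broken
lexicographically by symbol so the ranking is a pure function of the data.

For a pathway with `Nh` members mapped into the ranked list of `N`
proteins, the running sum increments by `|r_i|^p / Σ|r_j|^p` (sum over
members) at member positions and decrements by `1/(N − Nh)` elsewhere.
The enrichment score ES is the extremum of largest magnitude; the *leading
edge* comprises the members at or before the extremum (at or after it for
negative ES).  Defaults: weight exponent `p = 1` (the weighted statistic;
`p = 0` gives the classical Kolmogorov–Smirnov form), pathway size window
20–200 mapped proteins, 1000 permutations, significance at FDR < 25%.
Pathway members absent from the profile are ignored entirely; `mapped_n`
counts only present members, which is what makes near-window cases (a
19-member pathway against a 20 minimum) reproducible.  Pathways outside the
window are reported with `tested=False` and their mapped count — the
downstream three-way step must distinguish "not tested" from "tested but
not significant".

**Null model.**  Because a ratio profile has no per-sample replicates,
phenotype labels cannot be permuted; the null is *gene_set* permutation:
ES of uniformly random same-size subsets of the ranked universe, sampled
without replacement.  Each pathway's null sample comes from an RNG stream
derived from the master seed and a CRC of the pathway name, so results are
independent of evaluation order and reproducible in isolation.
`exhaustive=True` enumerates all `C(N, k)` subsets when there are at most
`max_exhaustive` (default 100 000) of them — the exact permutation
distribution on small universes — and otherwise falls back to a seeded
sample of that many subsets (capped enumeration).

**NES, p, FDR** follow the sign-stratified scheme standard for this
statistic:

* `NES = ES / mean(|null ES| of the same sign)`;
* nominal p = fraction of same-sign null ES at least as extreme
  (inclusive); a p below the permutation resolution is reported as 0.0 with
  a `p_below_resolution` flag (a printed "0.000" means `< 1/n_perm`);
* per-pathway null ES are normalized the same way and pooled; the q-value
  for an observed NES\* is the ratio of the pooled-null tail fraction to
  the observed tail fraction on the same side, capped at 1.

**Numerical choices.**  The member-weight normalizer uses correctly-rounded
summation (`math.fsum`), making the running sum independent of summation
order and hence bit-reproducible against a position-by-position oracle.
The positive extremum is preferred when the two extrema tie in magnitude;
the tie test uses a 1e-9 tolerance because exact magnitude ties are
*structural* (e.g. a member block centred in the list yields extrema of
exactly ±x) while the two magnitudes are computed along different
floating-point paths.  The same tolerance is applied to inclusive tail
counting.  A ratio of 1e-9 is orders of magnitude below any meaningful ES
difference at realistic list sizes.  If every mapped member has a zero
metric the weighted increments are undefined and fall back to the uniform
`1/Nh` form.  A profile whose ranking metric is *constant* carries no
ordering information at all: scores are still computed (the running-sum
contract holds) but all p-values and q-values are forced to 1 with a
warning, since any apparent enrichment would be an artifact of
lexicographic tie-breaking.

## Three-way classification

Each pathway receives a direction per profile: UP/DOWN (tested,
significant), NS (tested, not significant), NT (not tested — size outside
the window; the mapped count is reported alongside so a reader can judge
near-threshold cases, e.g. 18–19 mapped proteins; the classifier never
auto-promotes such pathways).  The category is a total, deterministic
function of the triple (delta = hiPSCs/hESCs first):

| triple | category |
|---|---|
| (UP, DOWN, DOWN) | incomplete_repression |
| (DOWN, UP, UP) | incomplete_activation |
| (NS/NT, UP, UP) | common_up |
| (NS/NT, DOWN, DOWN) | common_down |
| exactly one vs-precursor significant, delta significant in the same direction | delta_only |
| exactly one vs-precursor significant, otherwise | ips_specific / es_specific |
| only delta significant | delta_only |
| anything else | uninformative |

The `delta_only` rule for same-sign single-sided patterns attributes the
signal to the pluripotent-vs-pluripotent difference rather than to one cell
line: a pathway up in hiPSCs/hESCs and up in hiPSCs/HFF but silent in
hESCs/HFF is most parsimoniously an hiPSC-elevated pathway, which the delta
profile already expresses.  Both vs-precursor directions significant but
discordant, or concordant with a delta signal that does not form an
incomplete pattern, are left uninformative rather than guessed.

**Discriminating proteins** of an incomplete call are the members of the
union of the pathway's leading edges (across the three enrichment runs)
that are quantified in all three profiles and whose three log2 ratios carry
the category's strict sign pattern — positive delta and negative
vs-precursor ratios for incomplete repression, the mirror for incomplete
activation.  Zero ratios never qualify (strict signs).

## Interaction modules

Given a protein set and an undirected scored edge list (confidence in
[0, 1]; self-loops dropped, duplicate edges keep the maximum), the induced
subgraph retains edges with confidence strictly above `min_score` (default
0.4) and returns connected components largest-first, singletons omitted.
Raising the threshold can only shrink components (monotone filtration,
property-tested).  Only local edge lists are read; no interaction database
is contacted.

## Synthetic data generator

The generator emulates the *statistical* structure of a comparative
membrane-proteomics study:

* universe of `n_proteins` (default 1100, the scale of a membrane
  proteomics experiment); a core fraction (0.5) of proteins detected in
  every sample, the rest with per-protein detectability uniform on
  [0.2, 0.9], detected independently per sample — so samples have
  overlapping-but-unequal protein sets;
* latent truth per protein: the vs-precursor log2 ratio drawn from a
  zero-centred two-component Gaussian mixture (85% sd 0.35, 15% sd 1.3 —
  a spike with heavy shoulders), the delta ratio from a tighter mixture
  (85% sd 0.15, 15% sd 0.6 — the two pluripotent cell types are nearly
  identical), the second vs-precursor ratio their sum so the three
  comparisons are internally consistent on the log2 scale;
* planted sets (defaults: one 30-member set per category) whose members
  carry the exact pattern triple: effect 2.0 log2 units vs the precursor
  and 0.4 in the delta profile — magnitudes typical of incompletely
  regulated membrane pathways.  Members share the exact triple (no
  within-set variation) so ground-truth recovery is well defined, members
  are always detectable so planted set sizes are exact, and conflicts are
  never injected into planted members;
* technical replicate pairs per sample: both runs share the sample's
  detected set plus disjoint per-run extras sized so the expected pairwise
  overlap is `replicate_overlap` (default 0.8); independent Gaussian noise
  (default sd 0.2) on every value; a `conflict_rate` fraction (default 1%)
  of shared non-planted proteins is forced into the conflict regime
  (opposite signs, the positive value pushed above log2(threshold+1), which
  guarantees the removal predicate fires);
* random null gene sets and a scored edge list in which each planted set
  forms a high-confidence ring-plus-chords module over background noise
  edges.

What it does **not** emulate: peptide-level quantitation, abundance-
dependent noise, correlated detectability between samples (real MS runs
co-detect much more strongly than independence predicts — integrated
profile sizes therefore come out ~550–760 rather than the ~750–810 of a
real experiment of this design), shared-member correlation between
pathways, and identification error.  Passing tests on this generator
demonstrate correctness of the algorithms and calibration of the
permutation test under the stated model, not robustness to those real-data
features.

With `noise_sd=0` and `conflict_rate=0` the full pipeline recovers every
planted category exactly (tested); with replicate noise 0.5 the planted
incomplete patterns are recovered in ≥ 90% of seeded runs, and on null
data the nominal permutation p is calibrated at the 5% level within three
binomial standard errors (both tested; the calibration and power checks use
a reduced universe — 400–600 proteins, 15–40 null sets — chosen to keep the
default suite quick while leaving the binomial error bands meaningful).

## Known limitations

* Enrichment p/FDR values depend on the gene-set release and permutation
  scheme; analyses of the same profiles with different pathway collections
  will agree in direction and classification, not in exact q-values.
* The gene_set permutation null ignores inter-protein correlation, which
  can make it anti-conservative on strongly co-regulated sets; this is
  inherent to the null, not to the implementation.
* FDR q-values are the ratio-of-tails estimator and are not monotone in
  NES by construction; they are capped at 1 and should be read as
  GSEA-style q-values, not Benjamini–Hochberg ones.
* The three-way truth table treats significance as binary at the
  configured FDR threshold; pathways hovering at the threshold can change
  category between seeds.  The report keeps the full triple and mapped
  counts so such calls can be audited.
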
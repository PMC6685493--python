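# Methods

`sweepscape` re-implements, as a tested reusable pipeline, an outlier-based
scan for positive selection on gene-regulatory-factor (GRF) genes across
three diverged human-like populations, together with the cluster-level
follow-up used for KRAB-ZNF gene clusters and a protein-level
interpretation of nonsynonymous variants in C2H2 zinc-finger genes.  All
inputs can be produced by the package's own forward simulator, so every
stage is testable without external downloads.

## Statistics

**Weir–Cockerham F_ST (haploid form).**  Inputs are phased haplotypes, so
the estimator is the haploid analysis-of-variance variant: with `r`
populations, haplotype counts `n_i` and allele frequencies `p_i`,

    MSP = Σ n_i (p_i − p̄)² / (r−1)
    MSG = Σ n_i p_i (1−p_i) / Σ (n_i − 1)
    n_c = (Σ n_i − Σ n_i²/Σ n_i) / (r−1)
    θ   = (MSP − MSG) / (MSP + (n_c − 1)·MSG)

The genotype-heterozygosity term of the diploid 1984 estimator is absent —
a deliberate, documented divergence justified by the phased input.  Sites
monomorphic in the pooled pair are undefined (NaN), never 0; negative
estimates are returned raw.  `global_fst_wc` sums the variance components
over sites before dividing (ratio of sums), the standard genome-scale
form.

**EHH and iHH.**  EHH(x) is the probability that two random carrier
haplotypes are identical at every site from the core out to distance x
(the core itself does not partition carriers, so EHH(0) = 1 by
construction).  iHH is the trapezoidal integral of EHH over physical
distance on both sides, truncated after the first point below 0.05 (the
conventional cutoff; configurable).  Genetic-map-based integration is not
implemented because the underlying scan integrates physically.  The EHH
span is the total width over which EHH stays at or above 0.5.

**XP-EHH.**  Per site, `ln(iHH_A / iHH_B)` using all-haplotype EHH per
population, integrated bidirectionally; sites where either iHH vanishes
are undefined and dropped.  Scores are standardized (centred/scaled) over
the analysed site set, mimicking genome-wide standardization; both
standardized and raw paths are available because browsers distribute
either.

**H statistics.**  Haplotype frequencies p₁ ≥ p₂ ≥ … over a window give
H1 = Σ p_i², H12 = (p₁+p₂)² + Σ_{i≥3} p_i², H2 = H1 − p₁², and the
softness ratio H2/H1, which rises as a sweep becomes softer.  Windows are
SNP-count windows (default 200 SNPs sliding by 25 in `AnalysisConfig`;
the desk-scale runs in this repository use 40 SNPs sliding by 10, matched
between observed data and null simulations — the window used on real
genome-scale data is a free parameter).

**Rank scores.**  A raw score v maps to −log10(r/N) where r is the number
of genome-wide values ≥ v (ties share the larger r).  A rank score above
1.3 therefore marks empirical P < 0.05; the maximum is log10(N); the
minimum (the smallest value, r = N) is exactly 0.  Gene scores are the
maximum rank score over track points overlapping the gene body (±flank,
default 0); genes without coverage are undefined and excluded downstream
with a logged count, mirroring the incomplete coverage of real score
browsers.  Candidates are genes in the top 5% of each method's gene-score
distribution (boundary ties included), intersected across CLR, XP-CLR and
XP-EHH.

**Enrichment.**  GRF-vs-non-GRF 2×2 tables are tested with the exact
two-sided Fisher test (sum of tables no more probable than observed), the
raw p floored at 2.2e-16 — the smallest value such tests are customarily
reported at — then Bonferroni-multiplied by the family size (default: the
number of method × population tests in the run; 18 in the original
3 CLR + 6 XP-CLR + 6 XP-EHH + 3 F_ST layout, which is why the floor prints
as 3.96e-15).  The verdict threshold on the adjusted p defaults to 0.001
rather than 0.05: published verdict patterns label adjusted p ≈ 1.7e-3
"No difference" while 4e-4 is "Enrichment", implying the stricter cutoff;
it is overridable.  Confounder checks: two-sample Kolmogorov–Smirnov on
per-gene recombination rates between GRF and non-GRF genes, and Spearman
rank correlation (average-rank ties) of gene length against rank score.

**Cluster-level evidence.**  Four lines per cluster: (1) maximal runs of
consecutive SNPs with XP-EHH rank score above 1.3 ("uninterrupted" is read
literally — tolerance 0, configurable), tested by sampling same-length
regions from the mappable universe and counting how often their best run
reaches the observed one; (2) a recombination-deficit test sampling
same-length regions of the genetic map and comparing length-weighted mean
rates; (3) a neutral-simulation comparison: matched-length replicates from
the package's simulator, singleton-thinned, summarized by the same
statistics (windowed H12, XP-EHH run length, maximum score) and compared
one-sided upper-tail; (4) H12 region delimitation: windows with H12 ≥ 0.1
merged when closer than 10 kb, kept when the EHH span at the peak window
reaches the minimum span (50 kb on genome-scale data; 20 kb in the
desk-scale runs here, because a 50-kb simulated region cannot contain a
50-kb span).  All empirical p-values use the (1+k)/(1+N) convention —
never zero, floor 1/(N+1), printing as 0.001 at N = 1000.

**ZNF annotation.**  C2H2 fingers are detected with the canonical pattern
C-x(2,4)-C-x(12)-H-x(3,5)-H (lazy spacers, leftmost non-overlapping);
zinc-coordinating residues are the two Cys and two His; recognition-helix
DNA-contact residues (helix −1, 2, 3, 6) are anchored on the first
coordinating His at index h as (h−7, h−5, h−4, h−1), which assumes the
canonical twelve-residue C–H core; for non-canonical spacing the same
His-anchored offsets are applied (the helix is His-proximal) — a
documented approximation.  Linkers are any maximal inter-finger gap (the
canonical TGEKP is not required).  KRAB domains come from supplied
annotation, not prediction.  Variant classification translates codons with
the standard nuclear code; synonymous changes carry no impact class;
nonsynonymous variants are reported when their maximum pairwise F_ST
strictly exceeds 0.15 (0.25 marking the high tier).

## The synthetic-data generator

A discrete-generation forward Wright–Fisher diploid simulator with
recombination and infinite-sites mutation, chosen over re-implementing a
coalescent because it is simpler to verify end to end and adequate at desk
scale.  Default study conditions (all config-overridable):

| parameter | default | why |
| --- | --- | --- |
| ancestral size N_anc | 2000 diploids | a large, diverse pre-bottleneck pool; suppresses spurious high-homozygosity neutral outliers and mirrors the African/out-of-Africa size contrast |
| branch sizes | 500 diploids each | rescaled desk-scale populations |
| splits | 350 / 200 generations before present | measured genome-scale F_ST on defaults: derived pair 0.17 ± 0.04 (the 0.1–0.2 working range), AFR–derived ≈ 0.25 |
| μ, r | 1e-7, 0.5e-7 per bp per generation | enough variation per 50-kb region (~150–200 pooled SNPs); ρ/θ = 0.5 keeps desk-scale sweeps from being shredded by recombination during their (rescaled-long) rise |
| burn-in | 2000 generations from an equilibrium-SFS-seeded start | the seed supplies standing diversity, the burn-in builds linkage; far cheaper than a cold start at 8–10 N_anc generations |
| singleton thinning | 48% of global singletons removed | mimics low-coverage ascertainment's deficit of rare alleles; whole singleton sites are removed (per-genotype thinning is not modelled) |
| sweeps | s = 0.05, hard (1/2N start), onset 225 generations, conditioned on completion | at desk scale a hard sweep needs ~250 generations; conditioning on fixation just before sampling gives the "recent completed sweep" archetype; soft/incomplete variants via initial frequency and target frequency |

Seeds are mandatory everywhere; an unseeded run raises.  Selection is
genic ((1+s) per copy); sweeps lost before sampling are retried from a
snapshot at onset up to a cap.  The allele-frequency trajectory, retry
count and realized selected position travel with the output matrix as
provenance metadata.

What the generator emulates: three diverged populations with a bottleneck
size history, neutral background variation with a 1/i frequency spectrum
(validated by the Watterson and SFS tests), physical-distance LD, hard /
soft / incomplete / complete sweeps, and low-coverage singleton deficit.
What it does not: gene conversion, mutation-rate and recombination-rate
heterogeneity along the sequence, background selection, migration
(supported but default-off), overlapping generations, genotype error.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under an idealized neutral-plus-sweep model, not performance on real
population data.

The fixture bundle lays simulated 50-kb blocks (3 "clusters", one with a
planted sweep, plus 8 neutral background blocks that give the permutation
tests a genome-like sampling universe) along one synthetic chromosome,
tiles genes inside and beyond them, writes CLR/XP-CLR tracks as
exponential noise elevated inside planted sweep intervals, a genetic map,
a GRF catalog, a synthetic KRAB-ZNF protein (canonical fingers joined by
TGEKP linkers, KRAB box at the N-terminus) with its CDS and a coding-
variant table whose per-population frequencies echo strongly
differentiated real variants.  A JSON manifest records every piece of
ground truth.

## Desk-scale calibration of the H12 recovery conditions

At the rescaled parameters (s = 0.05, branch N = 500) a hard sweep takes
roughly 250 generations — a substantial fraction of 2N — during which new
mutation and recombination genuinely erode the swept haplotype, while a
small, cold-started ancestral population occasionally produces neutral
replicates whose deepest genealogies mimic sweeps.  Two design choices
resolve this honestly rather than by weakening thresholds: the
large seeded ancestral population (which removes most spurious neutral
H12 outliers and is also the more human-realistic shape), and low
per-generation recombination (which preserves sweep haplotype integrity;
its flip side, longer-range neutral LD, is absorbed by the matched null).
Under the frozen defaults, completed sweeps exceed every member of a
100+-replicate neutral H12 ensemble in ≈ 95% of replicates, comfortably
above the 80% target at empirical p < 0.01.

## Problem sizes used in the shipped tests and acceptance script

Neutral null ensemble of 120 (tests) or 200 (acceptance script) replicates
and 25 sweep replicates at the
study conditions; 200 single-population equilibrium replicates (θ = 6,
ρ = 12, samples of 30) for the Watterson and SFS checks; 400 (tests) or
200 (acceptance script) permutation-calibration trials at 99 permutations;
the pipeline run uses 1,000 permutations for region tests and shares one
null ensemble across populations and clusters (keyed by region length —
one simulated replicate yields statistics for all three populations).
H12 windows in these runs are 40 SNPs sliding by 10, and the minimum EHH
span for region calling is 20 kb, both matched between observed and null
data.

## Numerical and design notes

- Coordinates: 0-based half-open internally; VCF positions 1-based; BED
  preserved as-is; every conversion covered by a round-trip test.
- Multi-allelic and indel VCF records are skipped (counted), not split;
  missing or unphased genotypes are hard errors — every statistic assumes
  complete phased haplotypes and the simulator never emits missingness.
- Windowed score tracks are normalized to points at window midpoints on
  read; whether real browser tracks are SNP-centred or fixed-window varies,
  so both layouts parse.
- The EHH walk refines haplotype classes with a bincount relabelling and
  stops early once EHH cannot recover (exact for every consumer that
  truncates at or above the stopping bound).
- Haplotype-frequency ties in the H statistics are broken by first
  occurrence; H1, H12 and H2/H1 are tie-invariant (asserted by test).
- `select_candidates` includes all genes tied with the top-fraction
  boundary value (a conservative superset); the top fraction applies to
  per-gene scores over all scored genes, so GRF enrichment against the
  same universe is well-defined.
- Permutation sampling excludes the focal region from the universe and can
  be restricted to covered intervals (used with the fixture's block
  layout); "same size" sampling is genome-wide within the chromosome.
- Regions found in two populations are kept as separate records.
- The bundled class vocabulary is data (TSV), not code; identifier
  normalization uses a caller-supplied synonym table, no network lookups.

## Known limitations

- The demography is a desk-scale stand-in, flagged as such in every
  manifest; it is not a fitted human model, and headline counts from
  genome-scale studies (thousands of catalog genes, hundreds of candidate
  genes, 42 high-F_ST variants) are out of reach by construction.
- CLR and XP-CLR are consumed as precomputed tracks, never computed; the
  fixture's tracks are calibrated noise, so CLR/XP-CLR behaviour on real
  data is untested here.
- iHH integrates physical distance only; XP-EHH standardization is over
  the analysed site set, which at desk scale is far smaller than a genome.
- The contact-residue offsets assume the canonical C2H2 core; unusual
  fingers (e.g. C-x(4)-C variants with shifted helices) may be annotated
  one or two residues off.
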
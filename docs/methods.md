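# Methods

This note records the models, conventions and numerical choices behind
`admixscan`, and what the bundled simulator does and does not emulate.

## Coordinates, data model, missingness

Genotypes are phased biallelic SNPs held as an `(2N, L)` int8 haplotype
matrix (0 / 1 / −1 = missing) with strictly increasing physical positions;
coordinates are 0-based half-open internally and 1-based only in VCF.
Unphased or half-missing VCF genotypes are recorded as missing in both
haplotypes of the sample: a single unphased call breaks the haplotype
identity that every statistic here relies on. Missing alleles are excluded
pairwise from frequencies and LD; in EHH walks a haplotype is dropped at its
first missing call in the extension and stays dropped.

One chromosome per dataset; multi-chromosome analyses are concatenations of
per-chromosome runs (the LAD scan has an explicit pooled, multi-chromosome
mode, see below).

## Quality control

Site filters run in a fixed order — missingness > 10%, per-population exact
Hardy–Weinberg p < 1e-8, MAF < 0.05 — and a site is counted against the
first filter it fails. A site fails HWE if *any* population fails, matching
per-population testing practice; MAF is computed on the sample subset under
analysis, not on any larger file it came from. The HWE test is the exact
conditional test: given the allele counts, `P(h) ∝ 2^h · n! / (n_AA! h!
n_aa!)` over heterozygote counts `h` of the right parity, and the two-sided
p-value sums all outcomes no more probable than the observed one (a 1+1e-12
relative guard absorbs floating-point ties). QC and LD pruning are
idempotent.

LD pruning uses diploid genotype-dosage correlation (the convention of the
standard pruning tool) with a greedy left-to-right scan: the later site of
any pair with r² > 0.5 within a 50 kb span is dropped. The scan evaluates
every in-window pair, which subsumes any step-size stride; the kept set
therefore has no remaining pair above the threshold within a window.
Pruning is exposed for population-structure workflows; the selection scans
themselves run on unpruned data. By contrast, the two-locus LD report
(`D`, `D'`, `r²`) is computed from phased haplotype frequencies — the two
conventions are deliberately separate.

Polarization flips allele codes so 1 = derived wherever the ancestral
allele matches REF or ALT, and drops sites with unknown or mismatching
ancestral state.

## Selection statistics

**F_ST.** Per-SNP Weir–Cockerham (1984) two-population variance components
`a` (among populations), `b` (among individuals within populations), `c`
(within individuals) from sample sizes, allele frequencies and observed
heterozygosity; `FST = a/(a+b+c)` with the components retained. Sites
monomorphic across both groups, or with fewer than two complete diploids in
a group, are flagged undefined and excluded from ranking. The implementation
is vectorized; the test suite holds an independent scalar transcription of
the same printed formulas and requires agreement to 1e-12.

**EHH / iHH.** `EHH(d)` is the probability that two random carriers of the
core allele are identical over the interval to distance `d`:
`Σ C(n_i,2)/C(n_c,2)` over the partition of carriers into identical extended
haplotypes. The denominator is fixed at the core carrier count, so dropping
haplotypes at missing data can only decrease EHH and the curve is monotone
non-increasing from EHH(0)=1. iHH is the trapezoidal integral over the
maximal prefix with EHH ≥ 0.05, in bp·EHH units — distances are physical bp
under a uniform map (no genetic map is assumed), which cancels in the
log-ratios. Curves are truncated at inter-site gaps > 200 kb; cutoff and
max-gap are the established scanning tool's defaults. A curve that never
falls below the cutoff before the chromosome edge (or a gap) is *censored*
and its site is excluded rather than edge-truncated, avoiding downward-
biased iHH near chromosome ends. The inner partition-refinement walk is
numba-compiled.

**iHS.** `ln(iHH_A/iHH_D)` with both directions summed per allele, computed
on polarized data, standardized to mean 0 / SD 1 within 20 equal-width
derived-allele-frequency bins over [0.05, 0.95]; bins with fewer than two
scored sites merge into a neighbor (logged). Twenty bins keep ≳50 sites per
bin at the bundled simulation scale and the count is configurable.

**XP-EHH.** Pooled-allele iHH in each panel per direction, integrated over a
*joint* truncation extent — the further of the two panels' first drops below
the EHH cutoff — then `ln(iHH_A/iHH_B)`, standardized genome-wide (whether
per-chromosome or genome-wide normalization is used in the field varies;
genome-wide is chosen here and matters only when concatenating
chromosomes). Positive values mean longer homozygosity in panel A; swapping
panels negates the raw score exactly.

**Outlier combination.** Rank-based p-values `p_i = rank_i/(N+1)` (average
ranks on ties; the `N+1` denominator keeps p > 0 and Fisher's score finite)
are computed over all scored sites per statistic. The top-1% sets of F_ST
(signed ranking: high = differentiated) and |XP-EHH| are intersected and
scored with `F_CS = −2(ln p_FST + ln p_XPEHH)`; the combined p-value is the
χ²(4) upper tail. The F_CS ranking is identical to ranking by the product
`p₁·p₂` — only the induced order is used downstream, so the score's scale is
immaterial. iHS outliers are taken at the top 0.1% of |standardized| values.

**Regions and classification.** Outlier SNPs within 200 kb merge by single
linkage; region bounds are padded by half the gap (matching the ±150–300 kb
windows used when displaying candidate loci; configurable). A target region
is labelled `post_admixture` if it overlaps (≥1 bp) a significant LAD
region, `shared_with_<source>` if it overlaps a source-group region from any
test, else `private_target`; multiple labels are reported in that fixed
order. Overlap is positional, not gene-name based, to avoid annotation-
dialect dependence. Source-group regions come from each source's own iHS
scan *and* from the F_ST+XP-EHH combination between sources — a sweep that
happened in a source is visible in the source-vs-source comparison even
when it is near fixation there (where iHS loses power). A two-way
source-vs-source signal cannot by itself say which source was selected, so
its regions are attributed to both sources; whether a shared signal is
adaptive admixture or a residual source signal is likewise left
undetermined, as that distinction needs evidence beyond the overlap graph.
An external ancestry-component scan (site, log-likelihood ratio) can be
ingested with the conventional LLRT > 15 cutoff and contributes target
regions.

## Local-ancestry deviation

Per-haplotype ancestry tracts (half-open intervals tiling the chromosome;
adjacent same-label tracts are legal and all consumers are invariant to such
splits) are converted to per-SNP dosage fractions `α_k(s)`. The LAD
statistic is `(α_k(s) − ᾱ_k)/σ_k` with `ᾱ_k`, `σ_k` the empirical mean and
SD across scanned sites — the simplest standardization consistent with
using 4.42 as a z-like threshold; the threshold's genome-wide calibration
is inherited from the literature, not re-derived, and is configurable.
Dosage is a haplotype fraction (phased tracts are available), evaluated at
SNPs rather than uniform windows. Ancestries with zero dosage variance are
skipped; fewer than 100 sites triggers an instability warning. Nearby sites
are strongly autocorrelated (tract-length scale), which makes the empirical
SD conservative for threshold exceedance on neutral data.

The 4.42 threshold presumes a *genome-wide* background. On a single short
chromosome carrying a selected tract, the chromosome's own moments are
contaminated by the signal (a post-admixture selected tract spans
megabases), so `lad_scan_genome` pools dosage moments across several
chromosomes and standardizes each against the pooled background — the
faithful analogue of how the statistic is used on real genomes. The
validation suite evaluates the post-admixture scenario this way, adding
eleven neutral companion chromosomes simulated under the same demography.

## The simulator

The generator emulates the study system the scans target: a cohort with
four ancestry components — autochthonous Maghrebi-like (MAG) plus
European-like (EUR), West/East-African-like (WEA) and Middle-Eastern-like
(MEA) sources — formed by a pulse of admixture. Defaults: proportions
q = (0.60, 0.153, 0.15, 0.097) (the European-like fraction matches the
genome-wide average reported for western North Africa; the others are
round numbers in the reported ranges), pulse g = 10 generations ago,
uniform recombination r = 1e-8/bp, one 50 Mb chromosome with 4,000 SNPs
(80 SNPs/Mb, comparable to genotyping-array density), 100 diploid target
samples and 100-haplotype source pools. All outputs are a pure function of
the configuration including its seed.

**Founder pools.** Per-site ancestral frequencies are shared across pools
and per-pool frequencies follow Balding–Nichols draws; each pool's
haplotypes are mosaics of 48 founder haplotypes with switch rate 5e-6/bp
(200 kb founder segments, a human-like LD decay scale). Finite founder
sampling adds ≈1/K of between-pool variance, so the Balding–Nichols F is
set to `fst_target − 1/K`; the realized mean pairwise F_ST, measured with
the package's own estimator, lands within a few percent of the 0.10 target
(documented band 0.05–0.15).

**Sweeps before admixture.** The favored-allele frequency follows the
deterministic haploid-selection recursion `p' = p(1+s)/(1+ps)`; carrier
counts each generation are the rounded quota of that trajectory. Haplotypes
are constructed in the large-population limit of per-generation carrier
resampling against a stationary background: a founder-label genealogy at
pool scale captures the establishment-phase skew toward early-expanding
carrier lineages, and each final carrier copies its founder haplotype
around the locus, escaping at an exponentially distributed distance per
side (rate r × generations — one recombination opportunity per generation)
onto fresh pre-sweep background haplotypes. Sampled carrier lineages in a
large population share no recent ancestor, so the construction yields
hitchhiking on the 1/(r·G) physical scale while the chromosome-wide
background keeps the pool's stationary diversity — a closed pool of 100
haplotypes simulated literally for 400 generations would instead lose most
of its background diversity to drift. The swept site is chosen to
segregate near p₀ in the swept pool and to be rare (< 0.15) in all other
pools, as expected of a recently arisen variant; scenario defaults are a
single-copy (p₀ = 0.01) hard sweep with s = 0.05 for 400 generations
(private, fixing in the pool) or 140 generations (shared, reaching ≈ 0.90
in the source).

**Admixture.** Each target haplotype draws ancestry breakpoints as a
Poisson process of rate g·r per bp, labels tracts independently with the
admixture proportions, and copies alleles from a random haplotype of the
labelled pool. Drawn tracts are returned unmerged as ground truth; interior
tract lengths are exponential with mean 1/(g·r) (boundary-truncated on a
finite chromosome, so the distributional checks use chromosomes much longer
than the mean).

**Post-admixture selection.** After the pulse, the cohort is evolved as a
Wright–Fisher population for the configured number of generations with
fitness 1+s for haplotypes carrying the designated ancestry at the locus;
recombination splices both alleles and tracts, so the returned tracts
remain the ground truth. Selection runs in a 1,000-haplotype population and
the 200-haplotype cohort is sampled afterwards — the cohort is a sample
from a larger population, so sampling noise rather than closed-population
drift sets the genome-wide dosage variance. The timeline is pulse →
(g generations, shorthand) → selective pressure appears → (generations,
explicit); defaults s = 0.1 over 15 generations drive the favored
ancestry's local dosage from 0.153 to ≈ 0.40–0.55.

**What the simulator does not emulate.** No coalescent genealogy, mutation
during sweeps, demographic size changes, non-uniform recombination or
gene conversion, genotyping error, phasing or local-ancestry inference
error (tracts are exact), array ascertainment bias, or X-chromosome
inheritance. Passing validation therefore shows the statistics and their
wiring behave correctly under a controlled admixture-with-sweep model —
not that real-data complications (switch errors in inferred tracts,
reference-panel misspecification, ascertainment) are handled; on real data
those enter through the quality of the inputs.

## Validation scales and numerical conventions

The validation suite uses 20 replicate seeds per scenario; neutral
calibration and normalization contracts run at 2,000 SNPs, the sweep
scenarios at the 4,000-SNP default. Standardizations use population SD
(ddof = 0) and are exact by construction (checked to 1e-9). Ranking ties
break by site order for determinism; all RNG flows from a single
`numpy.random.default_rng` seed per simulation, and pipeline outputs are
byte-stable across reruns (fixed float formatting, sorted JSON keys, no
timestamps). Known limitations: the exact HWE tie rule uses a 1e-12
relative probability guard; region padding makes region bounds extend
beyond outer outlier SNPs by half the merge gap; iHS/XP-EHH exclude
censored sites, so scans lose power within roughly one truncation length of
chromosome ends.
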
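# Methods

This note records the models, conventions and numerical choices behind
`defcom`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what each procedure assumes, which parameters
matter, and what the synthetic data do and do not establish.

## Synthetic communities

The generator (`defcom.synthetic`) emulates a defined 12-member gut
community installed in germ-free mice and fed two diets in oscillating
phases. Its purpose is statistical, not biological realism: it produces
data with exactly the structure the downstream analyses assume, with known
ground truth.

- **Genomes.** Uniform random ACGT sequences per species. Inter-species
  homology is modeled as blocks copied between designated pairs with point
  substitutions at `100 − percent_identity` percent of positions (always
  to a different base), packed from the genome start; a species whose
  blocks exceed its genome length is rejected. This is deliberately
  simpler than an evolutionary model — it is sufficient to create the
  ambiguous reads and shared peptides the analyses must cope with.
  Sequences use uppercase unambiguous alphabets (no N/X handling).
- **Genes** are laid out on a regular grid (length ≈ 80% of the spacing,
  rounded to a codon multiple), with EC numbers, CAZy families, KEGG
  categories and susC/susD pairs (each carrying a PUL id) assigned at
  configurable proportions. Proteomes are strand-aware translations of the
  gene sequences with internal stops recoded to serine, so protein
  homology tracks DNA homology; auxiliary proteomes (host, three
  distractor species, contaminants) are random amino-acid strings.
- **Shotgun reads**: multinomial species origins with weights
  proportion × genome length, uniform start, random strand, optional
  per-base substitution errors; every read carries its true origin label.
  No quality-score, GC-bias or fragment-size modeling.
- **Count matrices**: per-gene negative binomial with
  mean = depth × species_load(diet) × baseline × 2^(diet effect) and a
  shared dispersion α (variance = μ + αμ²; α = 0 degenerates to Poisson).
  Gene baselines are lognormal(0, 1) normalized to sum 1. The diet effect
  applies to a designated (or randomly drawn, default 10%) subset of genes
  on the second diet; the species-load multiplier scales all of a species'
  means on the second diet — the minimal mechanism that produces
  community-level masking. The `spectral` assay splits each sample into
  two technical runs by binomial thinning (p = 0.5), mirroring duplicate
  MS runs.
- **Insertion libraries**: uniform insertion positions over the target
  genome; input counts multinomial with mild lognormal(0, 0.25) abundance
  jitter; output counts multinomial with weights input × fitness of the
  disrupted gene (intergenic insertions are neutral).
- **Growth curves**: the Zwietering reparameterized logistic
  od(t) = A₀ + A / (1 + exp(4μ(λ − t)/A + 2)) with A = K − A₀, so lag λ
  (h), maximum rate μ (OD/h) and carrying capacity K (OD) are direct
  inputs; additive Gaussian noise, floored at 0. Defaults follow the
  screening design the package targets: 6 replicates per substrate, 72 h
  duration.

All randomness flows from a single integer seed through numpy's
`default_rng`; identical designs and seeds reproduce outputs exactly.

Because the generator's genomes are i.i.d. random sequences, k-mer
uniqueness is higher and peptide sharing lower than in real communities of
related *Bacteroides*; homology blocks restore those phenomena locally but
not genome-wide. Passing tests therefore establish the correctness of the
accounting and the statistical procedures, not field performance on real
strains.

## Community profiling (COPRO-Seq)

A read is assigned to a species iff its sequence matches exactly (either
strand) a location in exactly one species' genome; matches in two or more
species are ambiguous, no match is unassigned, and the three tallies
always sum to the input count. Matching is exact on canonical k-mers
(k = read length, default 25 bp) rather than via an external aligner:
deterministic, oracle-checkable, and adequate for the error-free synthetic
reads; an aligner-backed assigner can be substituted behind the same
contract.

The **informative genome size** of a species is the number of its genome
positions whose canonical k-mer occurs exactly once in the union of all
community genomes. Dividing unique-read counts by informative size removes
the bias against species with less distinctive genomes: with a fully
shared block between two species, reads from the block are discarded as
ambiguous, but both informative sizes shrink in proportion, leaving the
quotient unbiased (verified by simulation recovery to <1% absolute at 10⁵
reads).

The presence threshold (default 0.003% of the community, the level at
which reads begin to assign spuriously to distractor genomes) is applied
inclusively (≥); below-threshold rows are flagged absent but retained.
PoMA divides each proportion by the per-(animal, species) maximum, so it
is invariant to rescaling a species' whole trajectory; all-zero
trajectories yield missing values with a warning.

Ordination uses the Hellinger distance
d(p, q) = √Σ(√pᵢ − √qᵢ)² on proportions rescaled to sum 1, followed by
classical metric scaling (double-centered −½D², symmetric
eigendecomposition). Negative eigenvalues — possible because Hellinger
distances need not be exactly Euclidean after finite-precision centering —
are reported but excluded from the percent-variance denominator, and axes
are truncated to positive eigenvalues.

## Metatranscriptomics

**Size factors** are median-of-ratios: for features with nonzero counts in
every sample, the median of count / geometric-mean ratios per sample; when
no feature qualifies the code falls back to library-size ratios with a
warning. *Community-level* normalization computes one factor set from all
genes and measures each function's share of the whole metatranscriptome;
*species-level* normalization computes factors independently within each
species' gene subset and measures regulation within that member. The two
agree exactly on single-species matrices.

**EC binning** sums raw gene counts per EC; genes without an EC contribute
nowhere, and a gene with several ECs contributes its full count to each
(no fractional splitting — collapsing is by annotation, not apportionment).

The **NB exact test** models the two group totals as negative binomial
with matching size-factor sums and a common mean estimated from the grand
total, and sums the probabilities of all splits no more likely than the
observed one. Dispersion is estimated by method of moments on normalized
counts, floored at 10⁻⁸. With 3–4 replicates per group the per-feature
estimate is very unstable and makes the test conservative, so the default
shares one dispersion across features (the median of per-feature
estimates) — consistent with the generator, which draws all genes at a
common dispersion; per-feature mode and a fixed dispersion override are
available. At dispersion 0 the test reduces exactly to the conditional
binomial (Poisson) exact test.

The **Mann–Whitney U test** is exact by full enumeration of all
C(n_a+n_b, n_a) labelings of the pooled midranks (used up to 184,756
labelings); the two-sided p-value is the fraction of labelings with
|U − n_a n_b / 2| at least the observed. With ties this extremeness
measure reduces to the classical two-sided exact test when ties are
absent. Larger inputs fall back to scipy. Note the granularity: a 4-vs-4
comparison can reach p = 2/70 ≈ 0.0286 at best.

**Kinetics classification** works on one trajectory with a diet switch at
day s and phase end at day e: net change Δ = v(e) − v(s); below the
response floor (default 25% of the trajectory's dynamic range) the label is
`none`; `rapid` if at least ⅔ of Δ is reached within 2 days of the switch;
`delayed` if at most ⅓ is reached early and at least ⅔ of Δ accrues in the
final inter-sample interval; `gradual` otherwise. The ⅓/⅔ thresholds are
symmetric, deliberate conventions — the verbal definitions they encode
("dramatically within 1–2 d", "not until the end of a phase") admit other
readings.

**Masking detection** flags features whose community- and species-level
tests are both significant at α with opposite fold-change directions. The
species-level test for each EC runs within its *dominant contributor* (the
species providing the largest share of the bin's counts), since that is
the species whose regulation a community-share shift can hide; a fixed
species can be forced. The canonical `masking_scenario` (3 species ×
100 genes, 4 animals/diet, depth 3×10⁵, dispersion 0.01, load multiplier
0.2, +1 log2 within-species effect) makes the community trend
0.2 × 2 = 0.4× (down) while the species trend is 2× (up); note that a load
multiplier m and effect e only mask when m·2^e < 1.

**Bootstrap clustering** is average linkage on correlation distance
(1 − Pearson r between samples); support for each internal cluster is the
plain proportion of feature-resampled bootstrap trees containing the same
leaf set — an ordinary bootstrap, not the multiscale-bootstrap AU value of
pvclust, so supports here are somewhat conservative for small feature
counts.

**Array-style calls**: present ⇔ detected in ≥⌈5/7·n⌉ animals in at least
one group; DE ⇔ p < 0.01 and |FC| ≥ 2, with FC the ratio of group means
with a pseudocount of 1. The p-value comes from a regularized t-statistic
whose variance is shrunk toward the mean variance of genes with similar
overall expression (rank window of 101, 10 pseudo-observations) — a
moderated test in the Cyber-T/limma family; a posterior
probability-of-differential-expression term is not computed, so the DE
rule uses p and FC only.

## Theoretical peptidomes

Digestion follows the classical trypsin rule — cleave C-terminal to K or
R, suppressed before P (configurable) — producing all fragments with 0 to
`max_missed` internal cleavage sites; the zero-missed fragments partition
the protein. Masses are monoisotopic, unmodified, residues + water, via
pyteomics. The default index keeps fragments of 600–4890 Da (inclusive)
with ≤1 missed cleavage; note these *index* filters are distinct from
typical search-engine settings (up to 4 missed cleavages), and both are
plain parameters. Initial methionine is kept; no semi-tryptic peptides.

A peptide is **unique** iff it occurs at exactly one locus of one protein
in the composite database (community + host + distractors + contaminants);
a peptide repeated within a single protein is nonunique under this
per-occurrence reading. The alternative — collapsing within-protein
repeats so uniqueness means "one protein" — is available via
`collapse_within_protein=True`. Per-species summaries report the percent
of the species' peptides that are unique and the species' percent
contribution to the unique metaproteome (contributions sum to 100%);
widening the mass window or raising the missed-cleavage cap never removes
peptides, and adding a species never raises another species' uniqueness.

## Spectral-count proteomics

NBC divides a protein's count by the total spectra in its (sample, run);
NBS divides by the total spectra of the protein's species in that run (a
species absent from a run yields a missing value, not zero). The two
coincide for single-species data. Presence: ≥4 raw counts summed over a
sample's two runs. Eligibility for testing: ≥3 valid runs, valid meaning
strictly more than 5 counts. Runs are the unit for eligibility only;
samples (animals) are the statistical unit for testing — per-sample values
are the mean of the run-level normalized values, and runs are never pooled
as replicates. With 2 animals per diet an exact rank test cannot reach
p < 0.05 (minimum 1/3); calls require the 4-animal layout or larger, and
the package documents rather than papers over this power limit.

Calls: UP ⇔ p < 0.05 ∧ q < 0.05 ∧ median count difference > +5 (group
medians of per-sample summed raw counts); DOWN symmetric; NULL otherwise;
no call for ineligible proteins. The test runs on normalized values while
the >5 rule uses raw-count medians; both scales are emitted. q-values are
Storey's procedure: π₀ estimated on the λ grid 0.05…0.95 and extrapolated
with a cubic smoothing spline, clipped to (0, 1]; with fewer than 20
p-values π₀ is fixed at 1, which reduces q exactly to Benjamini–Hochberg.
Under NBC, q-values are computed over all tested proteins; under NBS,
within each species' tested set.

## PUL activation

susC/susD pairs are formed left-to-right within each species from a susC
followed by a susD with at most one intervening gene (configurable) and a
matching PUL id when both are annotated; unpaired homologs are listed, not
errors. Fold-change versus the reference condition (MM-Glc) is
(value + 1) / (mean reference + 1) on normalized counts — the pseudocount
of one normalized unit defines 0/0 as 1 and keeps the >100-fold criterion
meaningful at zero counts. A pair is *reported* when either gene exceeds
100-fold in any replicate; *activated* when, for **both** genes, at least
two replicates exceed 100-fold and the mean across all replicates exceeds
100-fold. All comparisons are strict (exactly 100 fails). The mean is
arithmetic by default (geometric available) — the "average up-regulation"
convention is genuinely ambiguous. With n = 2 replicates the ≥2-replicate
clause requires both. Activation implies reported, and raising the
threshold shrinks the activated set monotonically.

## Tn-seq fitness

Per-mutant fitness is output proportion / input proportion, each
proportion over the respective population total. Mutants absent from the
*input* cannot be normalized and are excluded (counted, not floored);
mutants absent from the *output*, and any computed ratio below 0.01, are
reported at the 0.01 floor with a flag — matching the "<0.01" plotting
convention — while the raw ratio is also emitted. Gene-level fitness is
the arithmetic mean over insertions in the first 80% of the gene
(3'-proximal insertions often leave function intact); genes without a
qualifying insertion are omitted. Library statistics (percent of ORFs
covered, mean distinct insertions per covered ORF) use the same first-80%
rule.

## Growth phenotyping

Summaries are extrema-based by design: A_tot = A_max − A_min and
rate = A_tot / (t_max − t_min), with each extremum taken at the earliest
time attaining it (tie rule) and rate set to 0 with a flag when the two
times coincide. No blank subtraction, lag estimation or exponential-phase
model fitting — plate-reader screens of anaerobes on 40+ carbohydrates
produce many irregular curves for which raw extrema are the robust choice.
Optional moving-average smoothing is off by default and recorded in
output. The growth call is A_tot ≥ 0.1 OD (configurable; a screening
convention, not a biological constant). Replicate aggregation reports
mean ± sample SD (n−1); ranking takes the arg-max of mean rate per
substrate among growers, reporting exact ties jointly.

## Problem sizes and runtime

Tests and the acceptance script run at desk scale, chosen to exercise
every code path with tight statistical tolerances: 1–3 kb genomes with
8–10 genes for profiling oracles (10⁵ reads for recovery), 3 species ×
100 genes × 8 samples for the masking scenario (100 seeds), 1000 random
proteins ≤200 aa for digestion/uniqueness oracles, 1000 features for
null-calibration of the NB test, 2500-mutant insertion libraries, and
72 h growth curves at 0.5 h resolution. The full suite completes in well
under a minute of compute.

## Known limitations

- Exact matching in read assignment ignores sequencing error; errored
  reads become "unassigned" rather than mismapped, which is conservative.
- The NB exact test conditions on group totals with a plug-in dispersion;
  it does not model per-sample outliers.
- Ordinary bootstrap supports are biased low relative to multiscale AU
  values for small feature sets.
- The moderated-t presence/DE path assumes roughly comparable variance
  among similarly expressed genes; heavy-tailed arrays would need a
  heavier-tailed prior.
- The generator does not emulate rRNA carryover, barcode/demultiplexing
  artifacts, batch effects, or realistic phylogenetic genome structure.
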
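# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `pedscreen`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pedigree sharing statistics

**Model.** Each non-founder receives one paternal and one maternal gamete;
conditional on the pedigree, the genotype-ancestry of everyone is fully
determined by one Bernoulli(1/2) indicator per meiosis saying which
parental homolog was transmitted. For a group query, only the meioses of
the group members and their ancestors matter ("relevant meioses", m).

`expected_all_share_fraction` enumerates all 2^m transmission patterns and
counts those in which a single founder allele copy is present in every
group member (*single-allele consensus*: pairs sharing different copies do
not count — this is what makes the grandmother-plus-two-cousins value
exactly 1/8 and the four-affecteds value exactly 1/64).
`relationship_coefficients` counts, per pattern, how many of a pair's
allele copies coincide, giving (k0, k1, k2) exactly. Both run in chunks of
2^20 patterns; beyond `max_exact_meioses` (default 25) the all-share
computation switches to seeded Monte Carlo over `mc_draws` random patterns
(default 10^6) and reports the binomial standard error.

`n_meioses` is the minimum, over common ancestors, of the summed
generational distances — an up-then-down path, so mates never connect
through a shared child. Pairs without a common ancestor raise an error
(there is no defensible HMM prior for them), and inbred members are
rejected (the 9-state identity machinery is out of scope).

`min_observation_probability` is the exact binomial tail
P(X ≥ k), X ~ Bin(2N, maf), via `scipy.stats.binom.sf` — no normal
approximation, since the interesting regime is maf ≈ 10⁻³, N ≈ 21.

## Gene-drop simulator

**Recombination.** Haldane model: per meiosis and chromosome, crossover
count ~ Poisson(genetic length in Morgans), positions uniform, no
interference, on a linear map (default 1 cM/Mb, so a 130 Mb chromosome is
1.3 Morgans). Ancestry is carried as piecewise-constant founder-copy
labels; genotypes are derived by sampling one Bernoulli(frequency) allele
per founder copy per marker, i.e. founders are in linkage equilibrium.

**Ascertainment.** When a causal CNV is configured, the meioses on the
descent paths from the planted founder homolog to the designated carriers
(default: the pedigree's affected members) are re-drawn until the gamete
carries the CNV haplotype at the interval midpoint (expected two draws per
meiosis). This mirrors how such a family is found in practice — ascertained
*because* the variant segregates — and is why simulated sharing around the
CNV exceeds the unconditional expectation, as it does in a real ascertained
family. Unconditioned drops (no causal CNV) average exactly the theoretical
sharing fractions, which is how the tests validate them.

**Phenotype.** Affection = carrier of the causal homolog AND
Bernoulli(penetrance); non-carriers are never affected (no phenocopies).
Default penetrance 0.8: the source family shows five affected relatives
and one unaffected obligate carrier among the six known carriers; no
numeric penetrance is reported for it, so 5/6 rounded to 0.8 is this package's
choice, made once.

**Emitters and their defaults.**

- *Variant tables* (default n = 2000): each variant's derived allele is
  planted on one random founder copy so genotypes segregate; true MAF is a
  mixture — with weight `rare_tail_weight` (default 0.1) uniform on
  (0, 0.05%), else uniform on (1%, 50%); per-panel MAFs jitter ±50% around
  the truth; cohort counts ~ Bin(42, MAF). The synonymous fraction defaults
  to 0.5. The causal variant is missense, panel- and cohort-absent, and
  rides the CNV carrier homolog.
- *Array intensities*: intensity = 0.5·(CN − 2)·gain + N(0, sd), gain 2.0,
  noise sd 0.5, probe spacing 2 kb. The control panel defaults to 16
  diploid samples: the study design this emulates calls CNVs against
  hundreds of population controls, and a 4-sample reference panel leaves
  enough shared reference-mean noise to create correlated false calls
  across cases.
- *qPCR*: target Ct = baseline − log2(CN/2) + N(0, sd), 4 replicates,
  reference assay and diploid calibrator wells at their baselines; Ct noise
  sd 0.05 (typical replicate scatter), zero for exactness tests.
- *Expression*: one designated gene elevated fold-2 in affected-tissue
  conditions, 3 subjects per condition, two probes for a subset of genes so
  probe-collapsing is exercised.

## Pair HMM and consensus segments

States are shared-allele counts {0, 1, 2}, with state 2 removed when
k2 = 0. The stationary distribution is the Cotterman vector. The
transition kernel over map distance d Morgans is the matrix exponential of
Q = a(1π′ − I):

    P(d) = e^(−ad) I + (1 − e^(−ad)) 1π′,

which preserves π exactly and has rows summing to 1 for any a. The rate is
a = m / k0 (m = n_meioses), chosen so the leave rate out of the
one-allele-shared state, a·(1 − π₁), equals m per Morgan — equivalently,
IBD segments on a path of m meioses have mean length 100/m cM, the
first-order Markov approximation to the true (non-Markov) switching
process. Degenerate priors (k0 = 0 or 1) never switch.

Emissions are joint ordered-genotype probabilities under Hardy–Weinberg
founder haplotypes: IBD0 draws four independent alleles, IBD1 draws
(x,y),(x,z), IBD2 draws (x,y),(x,y). Genotype error is an ε-probability
uniform replacement applied per individual (default ε = 0.01); a missing
genotype contributes the marginal of the observed one, or 1 when both are
missing — so fully missing data returns the prior, a property the tests
assert. Forward–backward uses per-step scaling; chromosomes are
independent chains.

A marker is in the group consensus when P(IBD ≥ 1) > 0.5 (strict — ties
excluded) for *every* case pair. Runs of consensus markers become 0-based
half-open segments spanning first to last shared marker; a run touching a
chromosome's first (last) marker is extended to the chromosome start (end)
taken from the genetic map, not from the observed marker span.

**Known limitation.** Thresholding per-marker posteriors is resolution
limited: at the desk-scale default of 10⁴ markers per ~3 Gb (1 marker per
0.29 cM) roughly a fifth of true pair segments span too few informative
markers to push the posterior over 0.5, so the genome-wide consensus
fraction underestimates the theoretical expectation by about one
percentage point. The effect shrinks with marker density (the real
workflow this emulates used a 123k-SNP pruned grid). Consequently the
replicate-mean bracket test for the 12.5% expectation is run on the
consensus machinery fed exact pair-sharing indicators, while inference
fidelity is held to a segment-level Jaccard ≥ 0.8 criterion against
gene-drop truth.

LD pruning follows the windowed greedy convention (window 50 markers, step
5, r² > 0.35 removes the later marker, MAF ≤ 0.1 dropped first); r² is the
squared Pearson correlation of dosage vectors over samples non-missing at
both markers, defined 0 (with a warning) for monomorphic markers. Note
that pruning on family genotypes alone removes more markers than pruning
on population controls would, because IBD sharing within a family is
itself a source of inter-marker correlation.

## Exome filter cascade

Filter order: exclude synonymous; keep variants with every panel MAF
strictly below 0.1% *and* control-cohort count below 2 ("seen at least
twice" removes — counts are allele observations among 42 chromosomes);
keep variants inside any group IBD segment (half-open interval test by
binary search); keep variants with ≥ 1 alternate allele in every case,
missing genotypes counting as absent (conservative). Per-step,
per-individual counts tally surviving variants carried by that individual.
The four predicates are per-record and independent, so the final shared
set is invariant to filter order — a property the tests check by running
all 24 permutations. Database membership per se is never a filter; only
frequency is.

## CNV screen

Standardization is (x − reference mean)/reference SD per probe, sample-SD
convention (ddof = 1), requiring ≥ 2 reference samples; zero reference SD
yields z = 0 with a warning. Smoothing is a centered moving average
(default 20 probes) whose window shrinks symmetrically at chromosome
edges; even windows use one extra probe on the right in the interior.
Calls are maximal runs of smoothed z beyond ±0.3 spanning > 10 kb and
≥ 10 probes. With unit-variance standardized noise, a window-20 mean has
SD ≈ 0.22, so ±0.3 sits at ≈ 1.34 smoothed-null SDs: sensitive enough
that a CN = 3 duplication (raw shift +1 at gain 2.0) is essentially always
called, at the cost of short false calls that the segregation screen must
remove. Segregation requires a same-state call with reciprocal overlap
≥ 0.5 in every case, no ≥ 0.5-overlap call in any control, and no ≥ 0.5
overlap with a known-CNV catalog interval (state ignored for the last two
— conservative). At the default noise level the implanted 1.3 Mb
duplication is recovered in every seeded run and is the unique surviving
call larger than 100 kb; occasionally a ~20-probe coincidental shared call
also survives, mirroring the extra shared CNVs that real studies screen
out against population catalogs.

qPCR copy number is CN = 2·2^(−ΔΔCt) with ΔCt = mean target Ct − mean
reference Ct, ΔΔCt relative to the mean calibrator ΔCt, calibrators
assumed diploid, assay efficiency fixed at 2 (no standard-curve
correction). Integer states are rounded and clipped to [0, 4], a plausible
germline autosomal range.

## Gene prioritization

Per-subject expression is normalized to span [0, 1] exactly (constant
profiles are an error); condition values are subject-averaged per probe
*then* probe-averaged per gene — the order matters when probes are missing
in some subjects and is fixed by design. Affected/control ratios are
ranked descending per comparison (ties → average ranks); control values
are floored at 10⁻⁶ and flagged, since the source method does not define
division by zero. A caveat the examples demonstrate: two near-zero
normalized values can produce an explosive ratio, letting a weakly
expressed gene win a single comparison; averaging ranks across
comparisons and sources damps this. External prioritization tools are
represented only as ingested score/rank tables. Aggregation is mean rank
over the union universe with worst-rank imputation (flagged) for genes
missing from a source, re-ranked ascending.

Ranking in the per-tissue comparisons is within-comparison (each
comparison yields its own rank table) rather than averaging ratios across
control tissues first; a gene "ranked first in all comparisons" can be
read off the per-source tables.

## Reproducibility

Every stochastic component takes a seed; identical seed + config give
byte-identical outputs (the end-to-end report hash is tested). Monte
Carlo fallbacks record their seed in the result object. All interval
outputs are 0-based half-open and say so in a header comment; VCF
positions are 1-based. Floats are rounded to 6 decimals on write.
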
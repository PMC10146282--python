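# Methods

## The system being modeled

A tetrazyg cross: two tetraploid parents, each a doubled diploid of an
interspecific F1 hybrid, produce diploid gametes that unite into
tetraploid progeny. The ovule parent is heterozygous *C. reticulata* /
*C. medica* along the whole genome; the pollen parent carries one
*P. trifoliata* homolog against a mosaic homolog alternating
*C. reticulata* and *C. maxima*. Because each tracked ancestor
(*C. medica*, *P. trifoliata*) is carried by exactly one parent, a
hybrid's windowed dose of that ancestor (0–2) *is* the corresponding
gamete's dose, which makes the gamete's phylogenomic structure directly
observable from hybrid genotypes.

## Meiosis model

Bivalent-only meiosis with per-chromosome preferential pairing and no
double reduction. The tetrasomic parameter τ = 1 − PP enters through the
pairing configuration: identical homologs pair (homologous configuration)
with probability 1 − 2τ/3, and each of the two heterologous
configurations occurs with probability τ/3. This mapping is chosen
because it reproduces the centromeric gamete-class probabilities
(τ/6, τ/6, 1 − τ/3) exactly: a heterologous meiosis delivers one random
chromatid from each of two mixed bivalents, giving the homozygous classes
with probability 1/4 each. Double reduction is structurally impossible in
this model (a gamete receives one chromatid from each bivalent, never two
sisters); the parameter flag exists only to reject misuse.

Crossovers per bivalent are Poisson with mean twice the chromosome's map
length in Morgans, positions uniform, each crossover tail-swapping one
randomly chosen chromatid of each pairing partner (no chromatid
interference). The factor two makes the *transmitted* chromatid carry the
configured map length on average. A useful consequence, used throughout
the tests: the marginal gamete-class distribution at *every* locus — not
only the centromere — is (τ/6, τ/6, 1 − τ/3), because crossovers preserve
the per-chromatid 1/2–1/2 ancestry marginal within a heterologous
bivalent. Recombination affects linkage between loci, not the one-locus
margins.

## Default study conditions

The generator's defaults are fixed once and treated as the study
conditions: 9 chromosomes of 20 Mb with the centromere at 0.45 L and
1.0 Morgan genetic length each; per-chromosome preferential pairing
profiles matching the published estimates for the two rootstock parents
(ovule side mean ≈ 0.50, pollen side mean ≈ 0.76); 95 hybrids; 240
diagnostic SNPs per taxon per chromosome (a desk-scale stand-in for the
~72k real DSNPs, giving 12 twenty-SNP windows per chromosome per
ancestor); read depth Poisson(20) with symmetric error ε = 0.01 and 2%
site dropout. The citrumelo mosaic's alternation breakpoint is not
reported for the real accession; the default is a single mid-chromosome
switch with the starting taxon alternating by chromosome parity, and it
is configurable.

What the generator does *not* emulate: double reduction and multivalents,
crossover interference, locus-dependent marker density and coverage
biases, allele-specific mapping error, population structure among
reference accessions, and chromosomal instability. Passing tests
therefore validate the estimators under the stated meiotic model, not
robustness to these real-data features.

## Estimators and numerical choices

**GST mining.** Per taxon, one-vs-rest with the rest pool's allele
frequency the unweighted mean of the other taxa (equal population sizes);
total-population frequency the unweighted mean of the two subpopulations.
Heterozygous reference accessions contribute half an allele. Sites with
more than 20% missing calls, or any all-missing taxon, are excluded.
GST = 1 is tested with tolerance 1e−9; monomorphic sites (HeTot = 0) are
undefined and skipped.

**Windowed dosing.** Reads are pooled across each window's 20 member
DSNPs and compared with f_d = clamp(d/4, ε, 1 − ε) for d = 0..4 under a
binomial likelihood. Calls require pooled coverage ≥ 10 reads and a
log₁₀ likelihood ratio ≥ 1 over the runner-up dose; otherwise the cell is
missing. The ε floor matters even for error-free simulations: at ε = 0,
dose 0 assigns probability zero to any diagnostic read, so one
minority-dose site inside a window would veto the majority dose. The
terminal window of a chromosome keeps a remainder of ≥ 10 sites or is
merged into the previous window. A window split by a genuine within-window
crossover has no single true dose at any depth; the pooled call and the
majority-site dose both flip at the 50/50 split point, and the
likelihood-ratio gate blanks most cells near it.

**Cleaning.** Singletons — interior calls differing from both nearest
non-missing neighbours on the same chromosome while those neighbours
agree — become missing; chromosome ends are untouched. Filters drop
windows with > 15% missing calls, then individuals with > 20%.
Individuals whose apparent-recombination load (Σ|Δdose| over adjacent
non-missing windows) exceeds median + 3·IQR are removed; the rule is a
robust automatic stand-in for inspecting the global recombination
distribution, and the multiplier is configurable.

**PP estimation.** The window nearest the centromere midpoint plus its
two flanking windows; per marker, grid search of the log-likelihood
(x1+x2)·log(τ/6) + x3·log(1 − τ/3) over τ ∈ {0, 0.005, …, 1} (the
combinatory constant is irrelevant to the argmax; the log form avoids
underflow). At τ = 0 the homozygous term is −∞ whenever x1+x2 > 0. Ties
break toward smaller τ. Chromosome PP is the mean over the three markers.
Near the PP = 0 boundary the clipped closed form induces a small upward
bias (≈ +0.02 at N = 1000), which the recovery tests absorb within their
±0.05 band.

**Segregation scan.** Per-window chi-square against (N/6, N/6, 4N/6),
df = 2; windows with N < 20 are flagged but still tested.
Benjamini–Hochberg q-values by default; a single-λ Storey estimate is
available behind a flag (the exact q-value procedure used on the real
data is ambiguous between the two cited approaches, and BH is the more
conservative, reproducible default).

**Recombination fractions and maps.** r̂ = min(0.5, Σ|Δdose|/(2N)) over
jointly non-missing gametes (≥ 20 required). The estimator is exact for
single-crossover intervals and undercounts double crossovers — acceptable
at 20-DSNP window resolution — and it *saturates below 0.5 for unlinked
pairs*: opposite-direction chromatid switches cancel in the dose
difference, giving E[r̂] = 5/18 ≈ 0.278 for independent duplex doses at
τ = 1 and less at lower τ. The linkage-grouping threshold default is
therefore 0.15 (single linkage, connected components), below the
saturation value but above apparent adjacent-window fractions under the
study conditions. Under strong preferential pairing dose columns are
nearly constant and apparent linkage is degenerate — grouping is only
meaningful on informative (high-τ) cohorts. Marker order is fixed to the
physical assembly; adjacent fractions accumulate through the Kosambi
function, with missing or saturated intervals assigned zero length (with
a warning) unless a cap is configured.

**Marey profile.** Local linear regression of cM on bp at each marker
over a span of 0.15 of the chromosome's markers (minimum 4 points) with
tricube weights; the local slope, clipped at 0, is the rate in cM/Mb.
Requires ≥ 10 markers per linkage group.

**Ordination.** Manhattan dissimilarity (mean |Δdose| over shared loci)
and classical principal coordinates via scikit-bio, axis variance
relative to the positive eigenvalues.

**Association.** Per window and trait, phenotype ~ intercept + dose with
additive 0/1/2 coding; for the single regressor the F statistic is t² and
the F-test p equals the two-sided t p. Windows with fewer than two dose
classes are skipped. Significance is annotated at p < 0.01 (the printed
source threshold direction is ambiguous; less-than is the only reading
consistent with calling signals "significant"). Candidate-gene
inheritance maps each gene interval to overlapping windows, takes the
per-hybrid majority dose (missing or tied → undetermined), and tabulates
class percentages plus the fraction of hybrids carrying ≥ 1 donor dose at
every interval.

## Problem sizes

Test and acceptance runs are desk-scale by design: cohorts of 40–1000
gametes, 3–9 chromosomes, 12–56 windows per chromosome; the full default
pipeline (95 hybrids, 8640 DSNPs) runs in a few seconds, and the complete
test suite in well under a minute of compute for the unit tests plus
~15 s for the end-to-end checks. The heterozygosity-floor simulation uses
60,000 meioses so that the binomial standard error (0.19 percentage
points) is small against the 0.67-point gap between the 66% floor and its
expectation 2/3.

## Known limitations

Dose calling assumes equal coverage of the four haplotypes and no
reference bias; no HMM smoothing is applied along chromosomes (singleton
cleaning plays that role); the rf estimator's unlinked saturation makes
absolute distances near saturation unreliable (only short-range fractions
feed the maps); PP estimates inherit an upward boundary bias at PP ≈ 0;
and the association scan fits no kinship or multi-QTL corrections.
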
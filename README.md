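# tetrameio

Analysis of meiotic behavior in allotetraploid (doubled-diploid) citrus
rootstock parents, from diagnostic-SNP mining and windowed ancestral
dosing of tetraploid hybrids through gamete-structure inference to
preferential-pairing estimation, recombination landscapes, and
dose–phenotype association — together with a synthetic
allotetraploid-meiosis generator that carries full ground truth.

## Who it is for

Breeders and geneticists working with "tetrazyg" populations: progenies of
crosses between two tetraploid parents that each arose by chromosome
doubling of an interspecific diploid hybrid. In such parents every
chromosome exists as two *identical* pairs of divergent homologs, so the
whole analysis hinges on how often identical homologs pair at meiosis
(preferential pairing) versus pairing at random (tetrasomy).

## The model

For a duplex locus A₁A₁A₂A₂ of a doubled diploid, without double
reduction, the diploid gametes fall into three classes whose probabilities
are governed by the tetrasomic parameter τ = 1 − PP:

    P(A₁A₁) = τ/6        P(A₂A₂) = τ/6        P(A₁A₂) = 1 − τ/3

so heterozygosity restitution ranges from 100% under strict disomy
(PP = 1) down to 66.7% under full tetrasomy (PP = 0). τ is estimated per
centromeric marker by maximizing the multinomial likelihood

    L(τ) = C · (τ/6)^(x1+x2) · (1 − τ/3)^x3

over a grid from 0 to 1 in steps of 0.005 (the closed form is
τ̂ = min(1, 3(x1+x2)/N), used as an independent oracle in the tests).
Upstream, ancestor-diagnostic SNPs are sites with inter-population
differentiation GST = (HeTot − (He_Ti + He_T−i)/2)/HeTot equal to 1;
ancestral doses are called per 20-DSNP window by a pooled binomial read
likelihood; downstream, recombination fractions r̂ = Σ|Δdose|/(2N) feed
Kosambi maps (cM = 25·ln((1+2r)/(1−2r))) on fixed physical order, Marey
profiles (local-linear tricube smoother, span 0.15), chi-square tests of
the (1/6, 1/6, 4/6) tetrasomic expectation with Benjamini–Hochberg
q-values, principal coordinates of Manhattan dissimilarities, and a
per-window GLM phenotype scan.

## Worked example

`examples/02_meiotic_behavior.py` simulates 500 diploid ovules of an
interspecific doubled diploid with a different preferential-pairing value
per chromosome and re-estimates the meiotic parameters:

```
chrom  PP_true  PP_hat  PHR_hat  PHR_expected  %distorted(q<0.05)
   C1     0.90   0.933    0.978         0.967       100.0
   C2     0.50   0.565    0.853         0.833       100.0
   C3     0.00   0.000    0.649         0.667         0.0
```

PP_hat is the mean grid-search MLE over the three centromeric windows;
PHR_hat is the observed fraction of heterozygous gametes, tracking its
expectation 1 − (1 − PP)/3; the last column is the share of windows whose
segregation deviates significantly from the fully tetrasomic expectation
(q < 0.05) — all of them wherever pairing is preferential, none on the
truly tetrasomic chromosome. The other example scripts cover dosing
accuracy, the negative map-length/PP relation with a Marey profile, the
association scan, and the full pipeline.

The end-to-end pipeline is also available from the shell:

```sh
tetrameio all --outdir runs/demo --seed 1      # or: python examples/05_full_pipeline.py
```

which writes plain-text tables for every stage (mined panel, dose and
gamete matrices, PHR/PP/segregation reports, maps, Marey profiles, PCoA
coordinates, association results, candidate-gene inheritance) plus a
`summary.json`.

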
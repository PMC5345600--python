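# Methods

## Study design being modelled

Two diverged lineages (I, II) of a haplodiploid arthropod are crossed
reciprocally. F1 hybrid females are kept unmated, so every son is a haploid
recombinant F2 male carrying a single maternal gamete; his cytoplasm
(cytotype) comes from the grandmaternal lineage of the cross. F2 males are
collected as viable adults or inviable eggs, giving four hybrid groups by
phenotype × cytotype. All individuals are genotyped at a panel of
microsatellite loci fixed for different fragment sizes in the two parental
populations, so every call maps to a lineage of origin.

Because the analysis only ever *compares* hybrid groups drawn from the same
cross, linkage and segregation distortion — which shift haplotype and allele
frequencies in every group identically — cancel out of the group contrasts.
The suite verifies this for the per-locus exact tests under tight linkage
(r = 0.05).

## Genotype scoring and filtering

* **Peak scoring.** Haploids carry one allele, but stutter and PCR artefacts
  produce extra peaks. A call is the size of the largest-area peak iff its
  area is ≥ 2× every other peak's area and ≥ 400 fluorescence units;
  otherwise no-call. Ties for the largest peak are no-calls, since the
  dominance rule cannot hold for two equal maxima.
* **Diagnostic markers.** A marker is kept when each parental population
  shows exactly one allele, the two alleles differ, and call rate ≥ 0.8 in
  both (the amplification-reliability threshold is a package choice; the
  underlying criterion is qualitative). Non-parental alleles in hybrids are
  recoded as missing with a warning rather than as errors.
* **Sample filter.** Hybrids missing calls at more than 2 of the 8 panel
  markers are excluded. Under the generator's default completely-at-random
  9% missingness this removes only ~3% of samples (quotas 92/94/134/134 →
  roughly 91/92/129/128); real data, where failed amplification concentrates
  in particular individuals (especially inviable eggs), loses far more to
  the same rule — the optional phenotype-dependent missing rate exists to
  mimic that regime.

## The inference chain

For a viable-vs-inviable comparison within a cytotype:

1. Each of the 28 marker pairs gives a 2×4 group × haplotype count table
   over pairwise-complete individuals (column order I.I, I.II, II.I, II.II,
   first symbol = alphabetically first marker).
2. **Generalized CMH** (general-association statistic, 2 groups × 4
   categories, df 3) pools observed-minus-expected haplotype counts over the
   28 strata against the multivariate-hypergeometric covariance.
3. **Adjusted residuals** (standardized Pearson residuals,
   d = (n−E)/√(E(1−row/N)(1−col/N))) reduce each table to four viable-row
   z-scores; cells with E = 0 are inestimable and dropped. The same
   construction on the per-locus 2×2 allele tables yields the **allele
   indicator** of haplotype x.y at pair (A,B): d_A(x) + d_B(y).
4. **Linear model.** OLS of haplotype residual on indicator plus a
   pair × class cell-mean structure (this parameterization — one dummy per
   observed (pair, class) cell, no intercept — is numerically identical to
   intercept + pair + class + pair:class; both use 57 parameters on a
   complete design, leaving 112 − 57 = 55 residual df, or 54 with one
   inestimable cell). The interaction is tested by the extra-sum-of-squares
   F (27 numerator df) and equivalently as a Gaussian likelihood-ratio
   chi-square.
5. **Contrasts and labels.** Per pair, parental-minus-recombinant fitted
   mean at indicator 0 (the indicator enters additively, so the common value
   cancels), t-tested on the model's residual variance, Holm-corrected
   across 28 pairs by default. Positive and significant → BDM; negative and
   significant → heterosis; otherwise none. Labels are exactly antisymmetric
   under negation of the viable-row residuals.
6. **Cytonuclear scan** (viable I vs viable II): per-locus 2×2 Fisher exact
   tests, Holm across the panel, with the direction of the frequency
   difference attached.

## Null behaviour of the residual model — an important caveat

The suite's null simulations (500 replicates, study-scale groups, no
genetic effects) show that the omnibus interaction F and the per-pair
contrast t-tests are **strongly anticonservative**: the null mean of
F(27, 55) is ≈ 10 rather than ≈ 1, the omnibus p is < 0.05 in essentially
every null replicate, and with Holm correction nearly every null replicate
still yields at least one BDM or heterosis label. Two structural facts cause
this:

* the four viable-row residuals of a pair obey a near-exact sum-to-zero
  constraint (their unweighted numerators sum to zero exactly, and with
  haplotype frequencies near ¼ the standardizing denominators are nearly
  equal), so the per-pair class contrast carries full multinomial sampling
  noise (variance ≈ 1) while being treated as signal;
* the indicator is computed from the same counts as the response, so after
  the indicator fit the within-(pair × class)-cell error — what the OLS
  residual variance estimates — is far smaller (σ² ≈ 0.1).

The F and t reference distributions therefore do not hold, and the
corresponding calibration tests in the suite fail by design rather than by
accident. The pooled CMH shares a related problem: its variance assumes
independent strata, but all 28 pair strata are built from the same
individuals (null rejection ≈ 0.39 at α = 0.05, worse under linkage).
Single-stratum CMH, the adjusted-residual formula itself, and the per-locus
Fisher tests (including the whole cytonuclear scan) are exactly calibrated.

Practical consequence: treat omnibus significance and weak labels with
caution; strong injected effects are still recovered reliably (a
recombinant-penalized pair with s = 0.9 was labelled BDM at the correct pair
in every replicate of the suite's 200-replicate recovery runs, and the
mirrored heterosis injection symmetrically),
and the magnitude ranking of contrasts is informative — in simulations the
injected pair's contrast dominates all bystanders.

## The simulator

`simulate.generate_dataset` draws each F2 male as one recombinant gamete:
the first marker follows its transmission-bias probability of carrying the
lineage-I allele (default 0.5); each subsequent marker either switches
lineage from its predecessor with the configured recombination fraction
(r < 0.5) or, when unlinked (r = 0.5, the default), is drawn independently
from its own bias. Viability is multiplicative —
v = v₀ · Π(1 − s) over matching epistatic penalties · Π(1 − c) over matching
allele × cytotype penalties — with phenotype drawn as a Bernoulli(v).
Penalizing the recombinant class at a pair models a BDM incompatibility;
penalizing the parental class models heterosis.

Defaults emulate the study conditions: 8 unlinked markers A–H, per-group
sampling quotas 92 (viable I), 94 (viable II), 134, 134 (inviable), and 9%
missing calls injected completely at random (an optional phenotype-dependent
missing rate exists but defaults off). Baseline viability 0.5 is a sampling
throughput choice only: with quota sampling the group compositions, not the
absolute survival rate, determine the statistics. Features of real data the
generator does not emulate: PCR-bias-driven (genotype-correlated)
missingness, null alleles, and linkage maps beyond adjacent-marker
fractions; calibration and recovery results therefore speak to sampling
noise under the stated model, not to genotyping artefacts.

## Numerical choices

* Fisher two-sided p uses the probability-mass convention (sum of
  fixed-margin tables no more probable than observed), checked against full
  enumeration for all 2×2 tables with N ≤ 40.
* Holm step-down is used wherever "sequential Bonferroni" correction is
  required; adjusted p-values are monotone in rank and capped at 1.
* CMH drops categories empty in every stratum before computing df; a
  singular pooled covariance falls back to a generalized inverse with df =
  rank, with a warning. Strata with N ≤ 1 are skipped.
* OLS uses `numpy.linalg.lstsq`; an exact fit's residual sum of squares is
  snapped to zero below 1e−12 relative tolerance, and zero-variance
  contrasts report p = 1 when the estimate is numerically zero, p = 0
  otherwise.
* Adjusted residuals with zero expected count (or saturated columns,
  n_+j = N) are NaN and excluded downstream; a record is also dropped when
  either of its locus allele residuals is undefined.
* Problem sizes in the suite and acceptance script (500 null replicates,
  200 recovery replicates, 100-replicate scans) were chosen to give
  binomial/KS resolution well below the thresholds being tested.

## Known limitations

* The method identifies marker *pairs* whose haplotype classes deviate from
  the allele-frequency relation; with 8 loci it cannot localize causal genes
  or count incompatibility loci, and three-way interactions are out of scope.
* The residual-model significance machinery is anticonservative (see above);
  p-values from `pairwise_contrasts` should be read as ranking scores unless
  recalibrated against the package's own null simulations.
* Transmission bias and differential amplification are confounded in real
  data; the simulator exposes them as separate knobs but the analysis cannot
  distinguish them.
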
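# Methods

This note documents the statistical models, the simulator, the numerical
choices, and the limits of what the synthetic experiments can show.

## Genotype representation

Genotypes are population-of-origin classes (0 = homozygous population 1,
1 = heterozygous, 2 = homozygous population 2, −1 missing), not nucleotide
alleles.  The population labels are dataset-level constants; phase and
allele identity are out of scope because every statistic in the package
depends only on class counts.  I/O modules never drop individuals;
complete-case filtering happens inside each statistic (joint tables use
individuals scored at *all* loci of the tuple, marginals use everyone
scored at that locus), so a single individual can legitimately contribute
to a marginal scan but not to a pair test.

## Single-locus statistics

**Goodness of fit.** Pearson χ² against the design expectation (1:2:1 for
intercrosses, 1:1 for backcrosses).  Classes with expected proportion zero
are *structural*: an observed count there is a data error (an impossible
genotype under the design), and the class is excluded with df = k−1 over the
k possible classes.  This deliberately differs from treating the class as
observed-zero, which would inflate df.

**Exact multinomial test.** For small broods (N capped at 200 by default)
the p-value is the total probability of all outcome vectors no more probable
than the observed one, by full enumeration over the (N+2 choose 2)
compositions.  Floating-point ties are resolved with a 1e−9 relative
tolerance on the "no more probable" comparison, so the modal outcome always
yields p = 1.  The statistic field carries −2·log p(obs); df is a sentinel 0
(no χ² reference exists).

**Relative viability.** w = 2·n_hom/n_het, the homozygote class's survival
relative to heterozygotes given the Mendelian 1:2 expectation, with
delta-method SE w·√(1/n_hom + 1/n_het) from the variance of a ratio of
Poisson-like counts.  w is zero exactly when the class is absent (SE then
undefined), and is scale-free (homogeneous of degree zero in the counts).
The formulation is kept behind a single function so an alternative estimator
can be swapped in.

**Heterogeneity between strata.** The textbook r×c contingency χ² on
groups × classes, with classes empty in every group collapsed first and
df = (r−1)(c−1) after collapse.  A `df` override is exposed because printed
reference values in this literature sometimes imply non-textbook df; the
default never second-guesses the standard rule.

## Interaction statistics

**Two loci.** Expected cells rᵢcⱼ/n from the observed marginals.  This *is*
the mechanism that "accounts for single-locus deviations": any fitness
surface of the form w(g₁)·w(g₂) changes the marginals but leaves the
survivors' joint distribution an exact product of those marginals, so the
statistic stays calibrated (verified by simulation in the acceptance
checks).  Empty classes are collapsed per axis; an axis reduced to one class
is degenerate and reported as a flagged row in scans.

**Three loci.** The no-three-way-interaction null is fitted by iterative
proportional fitting to the three observed two-way margins — the unique
maximum-entropy table with the observed pairwise structure, equivalently the
log-linear model with all pairwise terms.  IPF cycles the three margin
scalings until the worst margin discrepancy is below `tol` (default 1e−10,
checked to 1e−8 in tests); zero margins propagate zeros safely.
Convergence failure raises, carrying the discrepancy.

Degrees of freedom for the three-locus χ² default to 12 for a full 3×3×3
table, matching the printed-threshold convention of the field this package
serves; the log-linear count is 8 = (3−1)³, available as `loglinear_8`, and
a null simulation in the test suite shows the statistic's mean tracks 8 —
i.e. the 12-df convention is conservative.  The method label of every result
records which policy produced the p-value, and a within-stratum permutation
p (shuffling one locus's column, preserving all marginals) is provided to
sidestep the choice entirely.  Expected cells below 1e−12 are treated as
structural zeros: excluded from the sum with one df removed each.

**Enumeration and multiple testing.** Only tuples with pairwise distinct
chromosomes are tested by default: linkage makes intra-chromosomal
non-independence expected, not epistatic.  For the default panel (25 markers
distributed 1,3,5,3,2,2,1,4,1,1,1,1 over 12 chromosomes) this gives 276
pairs and 1780 triples — the elementary symmetric polynomials e₂ and e₃ of
the per-chromosome counts.  Bonferroni only, matching the field's practice;
scan outputs also carry the relaxed p < 0.001 reporting flag.  Ranking ties
break by (χ² descending, tuple lexicographic).

## The simulator

**What it emulates.** F1×F1 intercrosses, all eight backcross types
({F1 from either reciprocal} × {F1 parent female or male} × {either
recurrent population}), and two-generation backcross programs with
genotype-selected parents; tens to hundreds of progeny per cross; viability
selection at single loci and over epistatic tuples; optional sex-ratio
distortion.

**Transmission.** Gametes are sampled at marker resolution: the strand at
the first marker of a chromosome is uniform, and switches between adjacent
markers occur independently with probability r = (1 − e^(−2d/100))/2
(Haldane) for their map separation d cM.  Under a no-interference crossover
process, recombination events in disjoint intervals are independent, so this
Markov sampling is the exact marginal law of Poisson-breakpoint meiosis
observed at the markers — and it vectorizes over whole broods.  Female map
distances are scaled by `female_recombination` (default 0): at 0, every
female gamete chromosome is an exact copy of one parental haplotype, which
makes chromosome-wide cosegregation through females *exact*, not
approximate.

**Selection.** Fitness components (per-locus triples, epistatic tables) are
normalized by their maximum on construction; a candidate's survival
probability is the product of applicable components and candidates are
accepted by rejection sampling.  A cap of 1000 candidates per requested
survivor bounds runtime under near-lethal models; exceeding it raises a
data error rather than looping forever.

**Sex.** A fair coin by default.  The polygenic option sets
P(female) = logistic(Σ eᵢ·(dosageᵢ − 1)) with dosage the P2-allele count, so
synthetic data can exhibit sex-genotype associations for pipeline testing;
it is an emulation device, not a model of sex determination.

**Default panel.** The 25-marker fixture reproduces the motivating
chromosome distribution and letter-suffixed marker names; map positions are
arbitrary (20 cM spacing within chromosomes) and documented as such —
no analysis result here depends on true positions.

**What it does not emulate.** Genotyping error and missingness mechanisms
(a misclassification layer is a clean extension but defaults to absent),
crossover interference, temperature-dependent fitness (temperature is
carried as metadata only), mechanistic mtDNA–nuclear interactions (only
representable as fitness differing by maternal background), and
developmental timing.  Calibration results on synthetic data therefore
speak to the statistics' behavior under the modeled sampling process, not
to assay-specific artifacts of real genotype data.

## Study-condition experiments

`dmscan.experiments` fixes the conditions used for calibration:

* **Type-I error**: null F2, n = 400, 2000 replicates, α = 0.05, for both
  the single-locus GOF and the two-locus test; compared against the exact
  central 99% binomial envelope of α.
* **Calibration under marginal selection**: w = (1, 1, 0.4) independently at
  both loci, n = 500.  The selection strength is chosen so the distortion is
  pronounced while every expected joint cell stays above ~5 (Cochran's
  guidance for the χ² approximation); with smaller homozygote viabilities
  the smallest cell's expectation drops below 1 and the χ² approximation
  itself, not the design property, dominates the rejection rate.
* **Viability recovery**: w = (1, 1, 0.2) at one locus, n = 1000, 200
  seeds; the delta-method 3-SE interval should cover the truth in ≥ 95% of
  seeds (nominally ~99.7%).
* **Backcross asymmetry**: an assay marker at 0 cM and a jointly-lethal
  pair at 150/170 cM on the same chromosome, n = 200 per cross, tested at
  the 8-cross Bonferroni level.  The geometry matters: *at* a causal locus a
  male-F1 backcross still segregates het : hom = 1 : r, which is detectably
  distorted for any r ≤ 0.5 at this sample size.  The observable contrast —
  female-F1 crosses fully distorted, male-F1 crosses near 1:1 — arises when
  the assay marker is far from the causal factors, exactly the situation of
  a sparse marker panel on a long chromosome carrying distal incompatibility
  factors.  The survivor heterozygote frequency at the assay marker in the
  male cross is ~0.517 under this geometry (closed form from the Markov
  strand process), giving the test essentially no power there, while the
  female cross leaves *only* heterozygotes.

Problem sizes throughout (replicate counts, brood sizes) are chosen to make
Monte-Carlo error small relative to the envelopes being checked while
keeping the full suite fast enough to run routinely.

## Pipeline

Strata are declarative column filters analyzed independently; pooling across
reciprocal crosses is an explicit configuration choice, never implicit.
Scan outputs are TSV; the run summary JSON carries test counts, thresholds,
significant counts, per-stratum sizes, and provenance (config hash, seed,
version).  Reports re-render scan TSVs without re-thresholding, so flags can
never disagree between machine and human outputs.  Exit codes separate
configuration (2), data (3), and statistical-degeneracy (4) failures.
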
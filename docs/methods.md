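# Methods

## Model and units

`phylodem` works throughout in mutation-scaled coalescent units, the
parameterisation used by multilocus IM samplers such as G-PhoCS:

- θ = 4·N<sub>e</sub>·μ per branch (dimensionless, per site). Under
  neutrality θ equals the expected pairwise nucleotide diversity, which is
  what the simulator-calibration tests exploit.
- τ per internal node: expected substitutions per site per lineage. A
  population exists on the half-open interval [birth τ, parent τ); tips are
  born at 0, ancestral populations at their own τ, and the root extends to
  infinity.
- m per directed band: the per-generation migration probability divided by
  μ. A "bidirectional" band is stored as two directed bands sharing a
  `pair_id`, because posterior screening can legitimately keep one
  direction and drop the other, and fitted rates are direction-specific.

Absolute units exist only after calibration (below); keeping the core in
mutation scale avoids committing to uncertain values of μ and generation
time anywhere upstream of the final conversion.

### Band activity

A band is active only on the intersection of its endpoints' existence
intervals. We assume a band dies as soon as either endpoint population is
absorbed into its parent — lineages that have relabelled to an ancestor no
longer migrate through bands attached to the daughter. This matches the
natural reading of "continuous gene flow since divergence" but is a
convention; samplers differ in whether ancestral lineages inherit bands,
and the choice only matters for bands whose endpoints end at different
times.

## Simulator

`simulate_genealogy` is an event-driven structured coalescent. Between
consecutive τ breakpoints (the internal-node times), three exponential
clocks race: per-population coalescence at rate k(k−1)/θ, and per-band
backward migration at rate m × (number of lineages in the band's
forward-time recipient). A forward band donor→recipient therefore moves
lineages recipient→donor backward in time. At a breakpoint, daughter
lineages relabel instantaneously and all rates are rebuilt. Exact ties
between event times have probability zero with continuous clocks; if a
seeded RNG ever produced one, the event list is ordered coalescence before
migration, which fixes the outcome deterministically.

Mutations are infinite-sites: a branch of length b on a locus of ℓ bp
receives Poisson(b·ℓ) mutations, each creating a new biallelic site whose
carriers are the leaves below the branch. Site positions are distinct
uniform draws from the locus; in the (negligible at realistic θℓ) corner
where mutations outnumber positions, positions extend past ℓ rather than
recurring, preserving the infinite-sites contract. Loci are independent and
non-recombining, the standard approximation for short RAD loci.

Default dataset shape emulates the targeted study design: loci of 649 bp
(the study's mean RAD-locus length; thousands of loci), two diploid
individuals per population for coalescent-model work, and whole-locus
dropout missingness (an individual × locus Bernoulli mask) — the dominant
missingness mode of RAD data, where a restriction-site polymorphism or low
coverage removes the whole locus for an individual. Per-site missingness
and sequencing error are deliberately not modelled; the simulator feeds
method validation, not read-level benchmarking.

What passing tests on these synthetic data do *not* show: robustness to
genotyping error, allele dropout biased by divergence, linked selection, or
recombination within loci — none of which the generator emulates.

## Summary statistics

- **Joint SFS**: per population pair, complete-case per site (with
  whole-locus dropout this drops loci missing any pair member). Folding
  orients each site by the pooled two-population minor allele; exact 50/50
  ties keep the derived orientation. Invariant positions of included loci
  are tallied in cell (0, 0) so totals equal sites surveyed.
- **Weighted F_ST** is a ratio of sums across sites (never a mean of
  ratios; a regression test guards this by checking invariance under site
  duplication). The default per-site algebra is Hudson's:
  num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
  den = p₁(1−p₂) + p₂(1−p₁). The `reynolds` option implements the
  coancestry estimator of the Reynolds–Weir–Cockerham family for haploid
  allele counts (the between/within components a and a+b without
  heterozygosity terms). For n₁ = n₂ the two are algebraically identical
  (both numerator and denominator agree up to a common factor of 2), which
  the test suite verifies; they differ only under unbalanced sampling,
  where Hudson's is the more robust default. Sites monomorphic in the
  pooled pair are skipped.
- **Diversity**: π, Watterson's θ̂ (per-locus harmonic normaliser, so
  varying per-locus sample sizes under missingness are handled), d_xy; all
  per site, averaged over loci weighted by length.
- **Moment estimators**: θ̂ per population via Watterson; τ̂ as half the net
  divergence [d_xy − (π₁+π₂)/2]/2. Unbiased under isolation with equal θ;
  downwardly biased by migration and distorted by strong θ asymmetry —
  documented, since it serves as a light-weight recovery check, not an
  inference engine.
- **Distances**: allele-sharing distance (mean |dosage difference|/2 over
  pairwise-complete sites; default) and Euclidean dosage distance scaled by
  √sites. Both are exposed because genotype-based distance tools differ and
  the study's choice is not recoverable; the metric is recorded in output
  metadata. Population-level matrices average cross-population individual
  pairs, mirroring how mean geographic distances are built.
- **Mantel test**: Pearson r on off-diagonal triangles, null by jointly
  permuting rows and columns of the second matrix, one-tailed "greater"
  p with the +1 rule, 9999 permutations by default — the convention of the
  vegan ecology package. Type-I calibration is property-tested.

## Trace post-processing

- **Burn-in** defaults to 10% and is applied per chain before
  concatenation; chain ids are preserved so summaries can report both the
  pooled posterior and the mean of per-chain means (the replicate
  convention used for reporting multi-chain point estimates).
- **HPD**: shortest window containing ⌈mass·n⌉ consecutive sorted samples;
  ties break to the lowest-start window (deterministic). A property test
  checks every output against a brute-force scan.
- **ESS**: n/(1 + 2Σρ̂ₖ) with the autocorrelation sum truncated at the
  first non-positive estimate (initial positive sequence), computed by FFT;
  deterministic, capped at n; constant series report n with a warning.
- **Calibration**: g ~ Lognormal(meanlog ln 3.5, sdlog ln 1.16) years;
  μ ~ Gamma with mean 1.236×10⁻⁸ and standard deviation 0.107×10⁻⁸ per
  site per generation (shape ≈ 133.4). The μ spread is interpreted as a
  standard deviation: read literally as a variance it would exceed the
  squared mean by nine orders of magnitude and collapse the distribution
  onto zero, which cannot be the intended calibration.
- **Conversion**: N<sub>e</sub> = θ/(4μ); T = (τ/μ)·g; 2Nm = m·θ_target/2,
  derived from N_t·m_pergen = (θ_t/4μ)·(m·μ) = m·θ_t/4 and the factor 2 for
  gene copies. One independent (g, μ) pair is drawn per retained posterior
  sample, so calibration uncertainty propagates into every HPD; whether the
  original workflow drew per sample or per summary is not documented, and
  per-sample is the conservative (wider-interval) choice. 2Nm uses the
  *receiving* population's θ from the same posterior sample; using the
  donor's θ instead is a one-line change and the convention is recorded in
  output column names.
- **Band screening**: retain iff the 95% HPD lower bound of m is strictly
  positive at the precision carried by the trace file (no epsilon): any
  atom of posterior mass at zero larger than 1 − mass forces the lower
  bound to zero and drops the band.

## gdi

gdi = 1 − e^(−2τ/θ) is computed row-wise on posterior samples;
`-expm1` keeps precision near zero. Two estimates exist per node because θ
may refer to either daughter; both are always computable. Partition
aggregates (e.g. "all pairs separated by the river") average per-sample gdi
over all cross-partition pairs and both tip-θ choices *before*
summarising, so the reported HPD is the HPD of the mean and respects the
posterior correlation between τ and θ. Pair τ is the MRCA's τ and θ comes
from the tips; using ancestral θs instead is possible via
`gdi_posterior` per node. The thresholds 0.2/0.7 are strict
inequalities on both sides, so boundary values classify as ambiguous. gdi
is conventionally computed from a no-migration model's posterior; passing a
trace with migration columns triggers a warning rather than an error.

## Packaged example demography

The seven-tip fixture mirrors the published mouse-lemur IM model. Where the
source analysis prints converted values (N<sub>e</sub> 3,600 for Andobo and
14,900 for VohiposaSahafina; divergence times 453/272/254/43/41 ka in the
migration model and 3.1 ka for the Sahamamy–Andobo split without migration;
2Nm 1.15, 0.30, 0.11 for three bands), the fixture back-converts them with
the central calibrations g = 3.5 and μ = 1.236×10⁻⁸. Parameters not
printed anywhere — θ for the other tips and all ancestral branches, the
southern clade's internal split time (120 ka), the remaining nine band
rates — are synthetic round values chosen once to be plausible for the
system and are labelled as such in `phylodem/fixtures.py`. The synthetic
trace generator wraps each parameter in stationary AR(1) lognormal noise
(default 3% relative sd, lag-1 correlation 0.6) purely so that HPD and ESS
machinery sees realistic autocorrelated input; it emulates the *shape* of
an MCMC posterior, not the study's actual chains, and quantities derived
from it (e.g. the aggregate gdi of 0.978 across the river) are properties
of the fixture, not reproductions of the published estimates.

## Numerical and design choices

- All randomness flows through integer seeds; compound operations split
  seeds with `numpy.random.SeedSequence.spawn`, so partial re-runs are
  reproducible and sub-streams independent.
- Problem sizes in tests (2,000 loci, 5,000 oracle replicates, 20,000
  pairwise genealogies) were chosen so that 3-standard-error and 99%-CI
  bands are tight enough to catch unit errors while the whole suite runs in
  about a minute on one CPU.
- VCF interchange is a minimal 4.2 dialect: one pseudo-contig per locus,
  REF/ALT = A/T for ancestral/derived, unphased genotypes, `./.` for
  masked individual × locus entries. Genotype (dosage) matrices round-trip
  exactly; haplotype phase intentionally does not, since unphased VCF
  cannot carry it and no downstream statistic uses phase.
- The demography document is canonical JSON (sorted keys, fixed
  indentation), so save→load→save is byte-identical and content hashes are
  stable for provenance manifests. Newick export carries topology and
  branch lengths (parent τ − child birth τ) for interchange with tree
  tools.

## Known limitations

- No recombination, selection, or genotype-likelihood layer; no SFS
  estimation from likelihoods (ANGSD-style workflows are upstream of this
  package's inputs).
- The moment τ̂ estimator assumes isolation with equal θ; it is a sanity
  check, not a substitute for the MCMC sampler (which this package
  post-processes but does not implement).
- Band screening inherits the HPD's sensitivity to posterior atoms at
  exactly zero; traces written with few significant digits can round small
  rates to zero and thereby drop marginal bands.
- The ambiguous-zone classification of gdi boundary values and the
  θ-of-recipient 2Nm convention are documented conventions, not field-wide
  standards.
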
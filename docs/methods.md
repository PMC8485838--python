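# Methods

`cpphylo` analyses a single non-recombining organelle locus (chloroplast
DNA) sampled from structured populations: it reconstructs haplotype
relationships, quantifies diversity and differentiation, tests for
demographic expansion, and compares explicit demographic scenarios by
approximate Bayesian computation.  This note records the models, the
defaults and why, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Data model and filtering

All statistics operate on a *complete* matrix: any alignment column
containing a gap (`-`), missing data (`N`, `?`) or an IUPAC ambiguity
code in **any** sequence is removed before analysis (complete deletion).
This makes haplotype identity, site counts and Hamming distances well
defined at the cost of discarding columns that are usable pairwise.
Per-pair deletion is deliberately not used anywhere downstream.  Columns
are 1-based inclusive in every report; input is case-insensitive and `U`
is read as `T`.

Site classes follow the standard definitions: a complete column is
*polymorphic* when it shows at least two bases, and *parsimony
informative* when at least two bases are each carried by at least two
sequences; polymorphic non-informative columns are singletons.

## Haplotype network

Sequences collapse to haplotypes by exact identity on the filtered
matrix; labels (H01, H02, ...) follow first occurrence in the input.
The network is Bandelt, Forster & Röhl's (1999) median joining:

1. build the ε-relaxed minimum-spanning network over the current node
   set — an edge belongs to the MSN iff its weight is within ε of the
   minimax path cost between its endpoints (computed from one MST);
2. for every connected triple, form the column-wise majority-consensus
   median; add every novel median whose connection cost is within ε of
   the minimum over all candidates;
3. remove median vectors of degree ≤ 2 and iterate to a fixed point.

Defaults are ε = 0 and equal character weights (the common defaults of
network software).  Determinism: candidate medians are processed in
lexicographic order, and a three-way column tie takes the base of the
lexicographically smallest node label of the triple; medians identical
to an existing node are merged; a median removed as obsolete is never
re-proposed (this guarantees termination).  With ε = 0 and no medians
added the network equals the minimum-spanning network exactly.

## Diversity and differentiation

* **Hd** — Nei's unbiased gene diversity n/(n−1)(1−Σp²) with the Nei
  (1987) sampling variance.  Reports round Hd to 2 decimals and π to 5,
  the conventions of the field's survey tables.
* **π** — mean pairwise per-site p-distance, no multiple-hit correction.
* **Tamura–Nei (1993) distances** feed the AMOVA; base frequencies come
  from the whole matrix; a pair whose logarithm argument is non-positive
  (saturation) falls back to the p-distance with a logged warning.
* **AMOVA** — Excoffier–Smouse–Quattro sums of squared distances with
  1-, 2- and 3-level designs.  The distance entries are treated as
  squared Euclidean distances (the molecular-AMOVA convention); variance
  components are reported signed, never truncated at zero, and percent
  variance is computed on the signed components.  Permutation schemes:
  samples among populations for F_ST, whole populations among groups for
  F_CT, samples among populations within groups for F_SC; p-values use
  (b+1)/(B+1).  With every sample in one population the decomposition
  degenerates to within-population variance and F_ST = 0.  The set of
  populations included is configurable (`min_pop_size`), because
  published AMOVA tables sometimes drop singleton populations without
  saying so; the package does not guess.
* **G_ST / N_ST** — Pons & Petit (1996) unbiased estimators on haplotype
  frequencies, with N_ST weighting by inter-haplotype distances (Hamming
  by default; a model-corrected matrix can be supplied).  Populations
  with n < 2 are excluded and logged.  The permutation test permutes
  haplotype identities on the distance matrix and recomputes N_ST;
  N_ST significantly above the permuted values indicates phylogeographic
  structure.  When all inter-haplotype distances are equal, N_ST = G_ST
  identically.
* **Mantel IBD** — Pearson correlation of lower triangles with joint
  row/column permutations.  Geographic distance defaults to great-circle
  kilometres from decimal coordinates (a planar-degree alternative is
  provided); the genetic matrix in the pipeline is pairwise G_ST.

## Neutrality tests and their p-values

Tajima's D uses the standard constants; Fu's Fs is
ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling formula at
θ̂ = mean pairwise differences, computed with unsigned Stirling numbers
of the first kind in log space (stable to n well beyond 100); R2 is the
Ramos-Onsins & Rozas statistic on per-sequence singleton loads.
Conventions: D and R2 are undefined at S = 0 and raise rather than
return 0; k_obs = 1 makes Fs +∞ and raises.  The R2 singleton when
count-1 bases tie for the majority (n = 2) is assigned to the carrier of
the lexicographically smallest base.

p-values come from seeded neutral coalescent simulation conditioned on
(n, S): a Kingman genealogy receives exactly S mutations placed on
branches proportionally to length, and all three statistics are computed
from the same replicates.  D is two-tailed (doubled smaller tail); Fs
and R2 are lower-tailed, small values indicating expansion.  Under
constant size the realized type-I rates at the 5% level sit inside the
binomial band around the nominal rate (checked at 500 replicates).

## Mismatch distributions

Observed distributions are relative frequencies of pairwise difference
counts.  The expected distribution under a sudden expansion uses the
finite-size form of the Rogers–Harpending model,

    F_i = F̂_i(θ1) · P[Γ(i+1) ≤ τ(1+θ1)/θ1]
        + e^{−τ(1+θ1)/θ1} Σ_{j≤i} τ^{i−j}/(i−j)! · F̂_j(θ0),

where F̂ is the geometric equilibrium θ^i/(1+θ)^{i+1}; it reduces to the
θ0 equilibrium as τ → 0 and to the θ1 equilibrium as τ → ∞.  The vector
is renormalised over the observed support so both distributions sum
to 1.  (τ, θ0, θ1) minimise the plain sum of squared deviations via
bounded multistart L-BFGS-B — generalized least squares is deliberately
not used, keeping the fitted objective identical to the reported SSD
statistic.  θ1 is bounded at 10⁴ and a fit at the bound is flagged
(near-infinite post-expansion size).  Harpending's raggedness sums
squared differences of consecutive class frequencies with zero classes
imagined on both flanks, so the first and last classes contribute
boundary terms.  p-values are a parametric bootstrap: coalescent samples
of size n under the fitted expansion (time in mutational units; haploid
size θ, locus rate 1/2), each refit, p = P(statistic ≥ observed).
Lineages with n < 8 are refused by default — a handful of sequences
cannot constrain three parameters.

## Coalescent engine

A single-locus structured Kingman coalescent with divergence (merge),
admixture and size-change events.  **Sizes are haploid copy numbers**:
the within-population pair coalescence rate is 1/N per generation, so a
pair coalesces on average N generations ago.  This is the natural
convention for maternally inherited cpDNA and means every prior size and
time is read directly in (haploid) individuals and generations.

Mutation is finite-sites HKY at per-site, per-generation rate
μ = 1.59×10⁻⁹ /site/year × 10 years/generation, the chloroplast-wide
synonymous rate typical of angiosperms combined with a 10-year
generation time.  Defaults: κ = 2 and equal base frequencies
(configurable; the pipeline can pass empirical frequencies).  The
overlay generates candidate events at the maximal per-base rate and
thins by the current base's actual rate — an exact simulation of the
process without matrix exponentials, verified in the tests against
`expm(Qt)` on a fixed tree and against msprime and Watterson/TMRCA
expectations.

## ABC over five demographic scenarios

Three terminal lineages (north, central, south; sample sizes 17/74/5;
locus 2,858 bp) under five scenarios: (1) simultaneous three-way
divergence at t2; (2–4) one pair diverging at t1 inside an ancestor
that splits at t2, the three rotations; (5) the north lineage formed by
admixture between central and south at t1 (rate r), the latter two
diverging at t2.  The most recent merge retains the parent lineage's
terminal size; the oldest event joins everything into an ancestor of
size Na.  Priors: sizes uniform on [10, 10⁵]; times uniform on
[10², 10⁵] generations with t2 ≥ t1 enforced by rejection; r uniform on
[0.1, 0.9] (the admixture prior is this package's assumption — no
published value exists).  The mutation rate is fixed at its mean by
default, with a log-uniform option spanning a factor of 10 either way.

Summary statistics (15): per lineage, segregating sites, mean pairwise
differences, and the mean relative frequency of the rarest base across
that lineage's segregating sites; per lineage pair, pooled segregating
sites and a Hudson-type F_ST = 1 − (mean within)/(mean between), clamped
to [−1, 1] and 0 by convention when there is no between-group variation.

Model choice: statistics are standardised by table-wide median absolute
deviation; the nearest 1% of simulations by Euclidean distance are
retained; a multinomial logistic regression of the scenario label on the
standardised statistics, weighted by an Epanechnikov kernel in the
distance, is evaluated at the observed point.  95% CIs come from a
seeded nonparametric bootstrap over the accepted set (the regression's
analytic covariance is not exposed by the solver used and the bootstrap
is exact for this purpose); the plain rejection estimate is always
reported alongside.  Error rates classify pseudo-observed datasets
(PODs) drawn per scenario: type I for scenario k is the fraction of k's
PODs not assigned to k, type II the fraction of other scenarios' PODs
assigned to k.  Parameter posteriors use Beaumont local-linear
adjustment (log scale for sizes and times, Epanechnikov weights,
weighted quantiles), truncated to the prior support; a singular
regression falls back to the unadjusted rejection posterior with a
warning.  Times are reported in generations and years (×10).

Reproducibility: every simulation derives its generator from a
counter-based substream (seed, scenario, index), so serial, resumed and
re-ordered runs agree; per-scenario table chunks are written as they
complete and re-used on rerun.

Problem sizes: the package default reference table is 2×10⁴ simulations
per scenario with 100 PODs per scenario — the scale at which the test
suite exercises scenario recovery; production analyses can raise
`n_sims` arbitrarily (the table streams to disk).  "Prior midpoints"
for recovery checks are the means of the constrained prior (t1 at 1/3,
t2 at 2/3 of the time interval), because the unconstrained midpoints
t1 = t2 collapse several scenarios onto one another.

## Synthetic data

`generate_study_like` wraps the simulator to emit a survey-shaped
dataset — 96 sequences × 2,858 bp in 20 populations of sizes 3–9 across
three lineages (17/74/5) — as FASTA + metadata TSV + a JSON manifest of
the generating parameters.  Default parameters encode the demographic
growth the study system shows: terminal sizes 80,000 descending from an
ancestor of 5,000, with event times at the constrained-prior means.
That choice is a calibration, not an estimate: it is the parameter
region where the generator reproduces the observed survey's diversity
ranges (per-lineage Hd in [0.6, 1] and π in [2×10⁻⁴, 3×10⁻³] in
essentially all seeded draws; constant equal sizes at the plain prior
midpoints manage only ~80% because high haplotype diversity and low
nucleotide diversity jointly require star-like genealogies).

What the generator does **not** emulate: within-lineage spatial
structure (samples are assigned to populations in contiguous blocks, so
population-level differentiation within a lineage is pure drift noise),
realistic geographic coordinates (population centroids are jittered
lineage centroids), indels/missing data, and mutation-rate variation
across sites.  Tests passing on these fixtures therefore validate the
estimators and the inference machinery, not the spatial fine structure
of any real dataset.

`reference_haplotype_table` bundles the exact per-population haplotype
*counts* of the published 20-population survey (96 individuals, 49
haplotypes) for regression-testing the frequency-based statistics; its
sequences are synthetic placeholders on a unit-step Hamming chain and
carry no sequence-level information.

## Known limitations

* The real study's supplementary alignment is not redistributable here,
  so the sequence-level published values (polymorphic-site counts,
  lineage Tajima's D, F_ST between lineages, G_ST/N_ST, AMOVA
  percentages) are reproduced in *form* on synthetic data; the test that
  re-analyses the real matrix activates only when the user supplies it
  under `data/supplementary/`.
* SSD p-values use plain SSD refitting, not Arlequin's generalized
  least-squares τ estimator; published SSD/Hri values should be treated
  as order-of-magnitude references.
* Scenario 5's admixture rate prior, and the HKY nuisance defaults, are
  package assumptions (flagged above).
* The logistic posterior's bootstrap CIs quantify accepted-set sampling
  noise only, not table Monte-Carlo error; at small table sizes the
  rejection estimate is often the more stable of the two.
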
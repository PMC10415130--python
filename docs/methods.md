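# Methods

## Model and assumptions

The package treats genome composition as a deterministic, mean-field linear
kinetic system.  The state is the vector of fractional base contents
C = (C_A, C_C, C_G, C_T) (order fixed everywhere as A, C, G, T); the dynamics
are dC/dt = M C with the generator M built so that its off-diagonal entry in
row u, column s is k_{s→u} and each column sums to zero.  Column-sum zero is
the conservation law: total content stays exactly 1 analytically, and within
solver tolerance numerically.  There is no selection, no indel process, no
finite-population sampling noise, and no context dependence at the single-base
level; context enters only through the dyad network.  Rates are expressed in
per-site per-byr (billion years) units everywhere; user-facing inputs in
mutation-frequency units are converted at the boundary by the linear map
k = 2.831 f (the packaged calibration constant, overridable, since the
underlying regression is not reproduced here).

All 12 rates are free parameters.  The no-strand-bias (NSB) reduction imposes
the six equalities that complementarity implies when mutation rates are
strand-invariant; the package keeps both representations and checks round-trip
identity.  The strand-symmetry-averaged block of the packaged human rate
table is an independent estimate, not the arithmetic mean of the individual
block (the CA/GT pair differs in the third decimal), so both blocks are
stored verbatim and never cross-derived.

## Integration and the exact propagator

`evolve()` integrates the ODE with SciPy's LSODA (stiff-capable) at
rtol 1e-9 / atol 1e-12.  These defaults are far tighter than the physics
needs (rate spreads up to ~8/byr over a 4.28 byr horizon are mild), but batch
runs are then insensitive to occasional stiff draws.  A dedicated integrator
for the six-rate reduced system exists purely as a cross-check that the
reduced equations and the general network are the same dynamical system; the
two trajectories agree to ≤1e-9.

Because the system is linear with a constant generator, the exact solution
C(t) = V exp(Λt) V⁻¹ C(0) is available by eigendecomposition.  Ensemble
studies (10^5–10^6 replicates) use this closed form, batched over replicates,
rather than per-replicate ODE integration; the two routes are cross-checked
in the test suite.  Stationary compositions come from the generator's null
space (`scipy.linalg.null_space`), which serves as the long-time oracle; a
reducible network (multi-dimensional null space) is reported as an error
because its long-time limit depends on the initial state.

The dyad network is the analogous 16-state system: 96 directed edges, one per
single-position substitution.  The NSB pairing maps an edge (d1→d2) to
(revcomp(d1)→revcomp(d2)); the pairing is an involution with no fixed points,
giving exactly 48 classes.  Equilibrium class detection groups stationary
contents that agree within an absolute tolerance, default 1e-6: the
underlying algebra gives exact coincidences, but the numerical null space
needs a threshold.  Generic NSB rates give the ten reverse-complement
classes; generic unconstrained rates give sixteen; context-independent rates
(each edge carrying the singleton rate of its mutating position, neighbours
ignored) give the three closed-form values equal to the outer square of the
singleton equilibrium.

## Sampling protocols

Three rate-sampling modes, all driven by `numpy.random.SeedSequence` child
streams so a single master seed reproduces a run bit-for-bit regardless of
batching:

- **uniform_unconstrained** — 12 i.i.d. draws from U(0, b) with
  b = 1.109 + m·0.690 (the largest symmetry-averaged rate's mean plus m
  standard deviations); b = 1.799 at multiplier m = 1.
- **truncnorm_individual** — 12 draws from normals centred at the individual
  packaged means with sd scaled by m, truncated at zero only (no upper
  bound).  One-sided truncation inflates the sample mean above the centre;
  this skewness artefact is asserted in the tests rather than corrected,
  since it is a property of the protocol itself.
- **truncnorm_symmetric** — six draws centred at the symmetry-averaged means,
  expanded to an exactly NSB 12-rate set.

Initial compositions: the flat 0.25 genome; random constrained draws (two
bases, in a random order, uniform in a configurable per-base range defaulting
to [0.1, 0.4], the remaining two splitting 1 − remainder so the four always
sum to one exactly; draws whose remainder is negative are resampled); or the
four extreme-skew corners (±1, ±1).  A corner composition is underdetermined
— any split between its two non-zero bases gives the same skews — so the
symmetric 0.5/0.5 split is used.

## Compliance metrics and tolerance boxes

Skews are (G−C)/(G+C) and (A−T)/(A+T) on the given strand.  A zero
denominator is reported as skew 0 with an explicit degenerate flag; such
compositions cannot arise under strictly positive rates, only from
pathological inputs.  Compliance is membership in a closed per-kingdom
tolerance box (mean ± 1 sd per axis) packaged from cohort measurements of
eukaryotes, prokaryotes and DNA viruses; the boundary counts as compliant.
The prokaryote AT-axis sd is packaged as 9.401e-3 (the source also prints
9.400e-3 in one place; the tolerance-region figure is used).

The NSB pair-ratio diagnostics histogram the six ratios k_a/k_b of rates that
NSB would equate, split by compliance, with the histogram mode as the summary
statistic.  Bin edges are offset by half a width so that 1 lies strictly
inside a bin.  The default width is 0.25 for visualisation; mode *testing* on
compliant subsets uses width 1.0, because at the ensemble sizes used here the
compliant subset has only a few hundred members and narrower bins make the
modal bin a noise draw — at reference runs with ×50 more compliant systems
the modal bin contains 1 at widths 0.5 and 1.0 alike, so the wide bin
stabilises variance without displacing the mode.  For the non-compliant
subset the analytic reference is the ratio-of-uniforms law (density 1/2 on
[0, 1], 1/(2z²) beyond, independent of the bound b), checked by
Kolmogorov–Smirnov on a 10,000-point subsample: a full-sample KS at n ≈ 2×10^5
would flag the (real but irrelevant) distortion caused by removing the
compliant subset rather than the distributional shape under test.

## Crossing times

Time-to-PR-2 is the first recorded time the skew pair enters the box,
refined by bisection between the bracketing records to 1e-3 byr using the
exact propagator (ensembles) or linear interpolation (single recorded
trajectories).  First crossing is used without a persistence requirement,
although skew trajectories of linear systems can be non-monotone; the
recording grid is dense enough (1000 points) that re-exits are resolved.

Two equilibration definitions are implemented:

- **oracle_threshold** — equilibrated when max_b |C_b(t) − C_b(∞)| falls to
  a threshold (default 1e-4), with C(∞) from the null space.  This is the
  unambiguous, oracle-grounded definition.
- **fluctuation_calibrated** — the self-calibrating procedure: per replicate
  and recording interval the fluctuation is Σ_b |ΔC_b|/4 between consecutive
  records; EQtolerance is 1% of the ensemble-mean fluctuation over 25
  reference intervals spread evenly across the record; a replicate is
  equilibrated at the first interval whose range (max − min over bases) of
  per-base |ΔC_b| is ≤ EQtolerance.  The published description of this
  procedure is ambiguous in step D ("1% of 25 of the mean fluctuations");
  the reading above is one documented interpretation.  Because consecutive-
  record differences only mean anything at a constant recording step, this
  mode requires the uniform time grid (the default for timing studies); the
  log-spaced grid remains available for oracle-mode studies.

The two definitions measure different stringencies (a content threshold of
1e-4 versus a calibrated per-step change of ~1.5e-6), so their absolute times
differ; they rank replicates consistently (rank correlation > 0.8 on seeded
ensembles, median absolute difference < 0.5 byr), which is what the
cross-mode test asserts.

The timing study pairs t_pr2 with t_eq per replicate over seeded ensembles
(default: strand-symmetric truncated-normal rates, random constrained
initials, prokaryote box, horizon 4.28 byr, n = 10^4 per multiplier — sizes
chosen so distributional summaries are stable at desk scale).  Under these
conditions the mean time to PR-2 compliance is ~2.6 byr at multiplier 1,
decreasing monotonically through multipliers 2, 5, 10 (a consequence of
time-rescaling covariance of linear ODEs: scaling all rates by c scales all
crossing times by 1/c, which the tests assert directly), and compliance
precedes equilibration by ~1 byr on average under the fluctuation-calibrated
definition.  "Not reached within the horizon" is a distinct outcome (NaN),
never conflated with a large time; the horizon is extendable to separate
"slow" from "never".

## Generalized constraint system

The 12 constraint forms are stored in their printed factored shape (outer
factor × linear combination + inner constant) and expanded programmatically;
a literal transcription kept in the test fixtures guards against
transcription drift.  The lowercase symbols map positionally (k_ag ≡ k_{A→G});
the coefficients are printed to 1–2 significant figures, so every numeric
consequence derived from them carries a tolerance — no Eq-level check uses
exact equality except the linear-algebraic identities (exact linearity of the
prediction map, zero residual by construction).  Conformity on compliant
ensembles is assessed by Pearson correlation of (actual, predicted) pairs per
form and by comparing aggregate residual 2-norms between compliant and
non-compliant subsets (Mann–Whitney).  The symbolic-regression search that
produced the forms, and the gradient-boosting compliance classifier (whose
reported headline is that k_AT, k_TA, k_GC, k_CG matter most), are not
reimplemented.

## Genome content analysis

FASTA counting is strand-specific (forward strand as recorded), case-
insensitive (soft-masked bases count identically — a deliberate divergence
from mask-aware counting, which the source data shows to make negligible
difference), and ambiguity-code-aware: skipped symbols are tallied, dyads
never span them, and both the sliding (all overlapping dimers) and
segmentation (non-overlapping, frame restarting at each contiguous segment)
modes are exact.  Multi-record files are pooled whole-genome by default with
per-record output available, since per-chromosome versus whole-genome pooling
is a user-level choice.  Tolerance boxes estimated from cohorts use the
sample standard deviation and require ≥2 genomes per label with non-zero
spread.

## Synthetic data

The genome generator draws i.i.d. bases whose probabilities solve the
(gc_content, gc_skew, at_skew) system; an optional first-order Markov repeat
probability correlates neighbours without changing marginals, for
sliding-vs-segmentation comparisons.  What it deliberately does not emulate:
repeat structure, isochores, coding constraint, or any long-range
correlation — so tests passing on these genomes validate the counting and
statistical machinery, not claims about real genome architecture.  Rate
ensembles carry ground-truth labels: exactly NSB, NSB perturbed by a
controlled relative factor (pair ratio pinned near (1+ε/2)/(1−ε/2)),
constraint-conforming (the chosen subset of forms re-solved exactly — a small
linear solve with non-negative solutions enforced by resampling), and
adversarial (one pair member scaled tenfold).

## Known limitations

- The kinetic model is deterministic mean-field; finite-genome stochasticity
  and regional rate variation are out of scope.
- Dyad-level rate *values* have no packaged empirical source; only the class
  structure of the dyad equilibrium is checked against theory, using random
  or constructed rates.
- The constraint coefficients' low printed precision limits the sharpness of
  any quantitative claim built on them.
- The fluctuation-calibrated equilibration time depends on the recording
  grid and on one reading of an ambiguous published procedure; the oracle
  mode is preferred when an exact stationary target is available.
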
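# Methods

## Model of gain timing

A clonal gained segment at allele-specific copy number `nt:nb` (total :
minor, minor ≤ major by convention) is assumed to have reached its state
through `K` single-copy duplications of existing copies, with no deletions
and no further change after the last gain. Truncal evolution (germline to
the most recent common ancestor of the sampled tumor) is divided into `K+1`
stages with time fractions `t`, `sum(t) = 1`; SSNVs accrue on each copy at a
constant rate, so the chance a random truncal SSNV arises in stage `k` on a
copy destined for final multiplicity `j` is proportional to `A[j,k] * t[k]`.
The history matrix `A` is not unique: different duplication orderings give
different matrices, and several orderings can collapse to the same matrix.

- `K = (nt - nb - 1) + max(nb - 1, 0)` for `nb >= 1` (stage 0 is the
  germline-like 1:1 state with two observable copies, so stage `k` holds
  `k + 2` copies); `K = nt - 1` for LOH states (`nb = 0`, see below).
- Timeable states: `nt - nb >= 2`, plus copy-neutral LOH 2:0; the diploid
  2:1 state carries no gain. States above `nt = 7` are refused: highly
  amplified regions keep evolving and break the fixed-history assumption.

**Enumeration.** Histories are generated as split sequences on final
descendant counts: a gain splits one copy carrying `c >= 2` final
descendants into `c1 + c2 = c`. Every duplication tree induces such a
sequence and vice versa, so enumerating split sequences (interleaving major-
and minor-allele gains, deduplicating by the integer matrix) covers all
orderings. A brute-force oracle that replays every explicit duplication-tree
ordering confirms the sets agree for all states up to `nt = 6`.

**LOH convention.** For `nb = 0` only the retained allele is modeled; the
lost allele's SSNVs are unobservable. Stage 0 (one observable copy, final
multiplicity `nt`) absorbs both pre-loss and post-loss/pre-gain time — both
periods contribute only multiplicity-`nt` SSNVs from one observable copy —
and the loss is taken to precede all gains. The alternative (loss
interleaved between gains) is not modeled.

## Spectrum estimation (EM)

Reads of an SSNV at multiplicity `j` are `Binomial(d_i, f_j)` with the
purity-adjusted allele fraction `f_j = j P / (nt P + 2 (1 - P))` (normal
cells contribute two reference copies at SSNV loci). Only detected SSNVs
(`m >= 1`; configurable to `m >= r`) enter, so the likelihood conditions each
record on detection, dividing the mixture term by
`sum_j q_j Pr(m_i >= r | f_j)`. The detection probability uses `f_j`, not
the raw allele state: detection is an event on reads.

The maximizer is found by a minorize–maximize scheme: Jensen's bound on the
mixture numerator (classical E-step responsibilities) plus a tangent bound on
the convex `-log` of the detection denominator; the surrogate maximum over
the simplex is `q_j = R_j / (lambda + C_j)` with `lambda` solved by a
monotone 1-D root find. The iteration provably increases the conditioned
log-likelihood and reduces to textbook EM when detection is certain.
Defaults: uniform start, `|delta loglik| < 1e-8`, at most 2000 iterations
(non-convergence returns the best iterate with a warning), at least 10
SSNVs per segment.

## Timing bounds

Matching the spectrum exactly, `(A - q s^T) t = 0` with `1·t = 1`, is
underdetermined for states beyond single/double gains, so the initiation and
lead times are *bounded*: each is maximized by linear programming with
symmetric slack variables `u+ - u-` on every spectrum constraint, penalized
at 100 per unit. Per history the LP returns the attained stage duration and
the total slack; across histories the winner is the one with the largest
*penalized* objective (duration − 100 × slack), and its duration is the
reported bound. On a noise-free spectrum the generating history is feasible
with zero slack, so the winner's duration can never undercut the true value
— the bound guarantee, verified exhaustively over every state `nt <= 7`,
every history and a 0.25-step simplex lattice of true durations. The
penalized comparison (rather than a plain max of durations) is what keeps
the bounds informative on noisy spectra: an infeasible history that buys a
long lead time with slack loses to a feasible one, which also produces the
characteristic biases on 6:2 data (lead time overestimated when it is truly
small; initiation time underestimated when intermediate stages are brief).

For 2:0, 3:1, 3:0 and 4:1 the unique history matrix is invertible and
`t = c A^{-1} q` solves directly (tolerance for negative components 1e-9,
infeasible spectra flagged); the LP reproduces these solutions to 1e-6.

The LPs (at most 7 rows, 19 variables) are solved by a package-local
Bland's-rule tableau simplex compiled with numba. The exhaustive guarantee
sweep alone needs several hundred thousand solves, which a general-purpose
solver would not sustain; scipy's HiGHS backend remains available via
`method="highs"` and the test suite cross-validates the two on randomized
instances.

**Bootstrap.** Percentile CIs (default 95%, B = 200) resample SSNV records
with replacement and repeat EM + LP; the bound itself is bootstrapped, ties
between histories and all. Gains are labeled late/early when the
lead-/initiation-time bound falls in the last/first 20% of truncal time.
Nearby segments with identical `nt:nb` (gap ≤ 1 Mb by default) can be pooled
to borrow SSNVs.

## Benchmark simulator

For a chosen history and `t`: allele-state counts `Multinomial(M, q)`,
depths `NegBinomial(mean u_D, size u_D/10)` (variance `11 u_D`; "dispersion"
is read as the NB size parameter, overridable), mutant reads
`Binomial(D, f_j)`. Records drawn with zero mutant reads are redrawn holding
the allele state, so exactly `M` detected records return (a drop-and-report
mode exists). Early/late calls at threshold `T` are scored as a confusion
matrix (positive = predicted time < `T`); undefined ratios are NaN. Grid
runs fix the initiation time at 0.1/0.2/0.3, draw the lead time uniformly on
`(0, 1 - t0 - 0.01)` and spread the remainder evenly over intermediate
stages.

What the simulator does *not* emulate: mutational-signature composition,
mapping artifacts, subclonal copy-number mixtures, sequencing error on
reference reads, and correlated depths along the genome. Passing benchmarks
therefore demonstrate correctness of the estimator under its own generative
assumptions, not robustness to caller errors upstream.

Scaled-down study sizes used in the tests (chosen to keep the suite within
minutes while leaving Monte-Carlo noise well below the asserted margins):
150 paired replicates per `M` level for the 6:1 recovery check, 200
replicates per bias direction for 6:2, 2000/300 runs for the neutral-model
fits, 2000 sigma1 samples, 10,000 driver-order races, 1000 permutation
replicates for the null calibration.

## Genome-doubling detection

Arrival times (1 − lead-time bound) of all timed segments are smoothed by a
Gaussian KDE (Silverman bandwidth) on [0, 1]. Candidate bursts are *mode
cores*: for each density mode, the connected component of
`{density >= 0.5 * peak}` containing it (a full-width-at-half-maximum
interval). A GD is called when a core holds more than 40% of timed segments
with member standard deviation ≤ 0.15 (cluster SDs near 0.1 are typical of
real doublings; the cap rejects diffuse timing profiles, whose density never
drops below half of its shallow peaks, so their core swallows the whole
range and fails on SD ≈ 0.29). The most prominent passing core wins;
`gd_time` is its member mean, and segments arriving more than 1.3 SD before
(after) it are pre-(post-)GD events, with rates `pre/gd_time` and
`post/(1 - gd_time)`. At least 10 timed segments are required. The 40% rule
is applied to segment counts, not genome length.

## Cohort recurrence

Per patient, 1-Mbp-bin timing values (initiation or arrival) are ranked
after Uniform(±1e-6) jitter; deviations from the middle rank `(B+1)/2`
(`B` = that patient's non-missing bin count) are summed per bin across
patients and divided by the null SD `sqrt(sum_p (B_p^2 - 1)/12)`. Under
within-patient exchangeability the scores are approximately standard normal;
`|z| > 1.645` flags bins at two-sided 90% confidence, negative meaning
recurrently early, positive recurrently late.

Per-variant multiplicity is the binomial MLE over allele states (ties to the
smaller multiplicity); clonality propagates a Clopper–Pearson VAF interval
through `CCF = VAF (nt P + 2(1-P)) / (P * multiplicity)` and flags clonal
when the CI covers 1.

## Branching-process models

Both models grow from one cell that just acquired the doubling. Neutral:
birth `a0`, death `b0`, `lambda0 = a0 - b0 > 0`, passenger gains at `u0`
(infinite-sites). Conditioned on non-extinction, fixed post-GD gains are
Geometric(`lambda0/(lambda0+u0)`) with mean `u0/lambda0`, and the expected
number of gains carried by ≥ 90% of `N` cells is
`N/ceil(0.9N) * u0/lambda0 ≈ 1.11 u0/lambda0` — so without selection a
doubling must be one of the last truncal events. Selection: type-0 cells
convert at `u1` to type-1 cells (birth `a1`, death `b1`,
`lambda1 > lambda0`); with `q1 = b1/a1`,
`q0 = (a0+b0+u1 - sqrt((a0+b0+u1)^2 - 4 a0 (u1 q1 + b0)))/(2 a0)`,
`alpha = a0(1-q0)`, `beta = u1(1-q1)/(1-q0)`, `zeta = alpha + beta`, the
first type-1 cell with an infinite line of descent arrives with survival
function `(alpha+beta)/(alpha + beta e^{zeta t})`. Its expected passenger
load is `u0` times the integral of that survival function, evaluated by
adaptive quadrature and cross-checked against the analytic value
`(u0/alpha) ln((alpha+beta)/beta)`.

**Simulators.** Exact event-driven (Gillespie) dynamics, conditioned on
non-extinction by rejection (restart on extinction; cap 1e6 attempts). Two
exact sampling devices replace infinite-horizon simulation:

1. *Census survival draws.* Any cell alive at a census survives forever with
   probability `lambda/a` for its type, independently of everything else
   (branching property). A mutation is *fixed* iff every surviving cell
   carries it, so fixation and "first surviving type-1 founder" are decided
   by Bernoulli draws at a finite census — exactly, at any census size.
2. *Immediate founder decisions.* A type-1 clade has constant rates, so its
   survival is `Bernoulli(1 - b1/a1)` at its founding; the reduced sigma1
   sampler tracks only type-0 counts plus per-cell passenger counters and
   stops at the first successful founder. Doomed clades cannot found further
   type-1 lineages and never affect sigma1 or non-extinction.

The census simulator tracks per-cell clone identities in a mutation tree
(O(1) per event via uniform cell picks and swap-removal); dominance is a
subtree count at the census (`>= ceil(0.9 N)` cells, default census
N = 10,000 in tests). Runs exceeding an event cap (default 4–5 × 10^7,
reached by roughly 1% of runs in the small-`u1` regime where the type-0
population must grow to ~10^5 before the first successful founder) are
restarted; the induced censoring of the extreme late-sigma1 tail is well
below the distributional tolerances asserted. Near-critical rejected
excursions (extinction-conditioned dynamics are critical for `a0 ≈ b0`) are
likewise bounded by the cap. Time units are arbitrary; no calendar mapping
is attempted, and no inference of branching parameters from data is offered.

**Two-driver race.** Cells start driver-free (`a0`, `b0`); driver `i`
arrives at rate `u_i` and adds `delta_i` to the birth rate, additively for
double mutants. A run ends at the first doubly-mutant cell whose lineage
survives (`Bernoulli(1 - b0/a3)` at creation) and records which driver came
first; extinct runs restart. Defaults `a0 = 1, b0 = 0.9, u1 = u2 = 0.01`
keep the base population near-critical so drivers matter, at tractable race
lengths.

## Defaults and degenerate inputs

| parameter | default | meaning |
| --- | --- | --- |
| `min_ssnv` | 10 | fewest detected SSNVs to time a segment |
| `max_cn` | 7 | largest supported total copy number |
| `slack_penalty` | 100 | LP cost per unit constraint violation |
| `bootstrap` | 200 | CI resamples (0 disables) |
| `late/early threshold` | 0.2 | truncal-time fraction for labels |
| `depth dispersion` | `u_D/10` | NB size parameter of simulated depths |
| GD `min_fraction` / `max_sigma` | 0.4 / 0.15 | burst size and concentration |
| GD `level_frac` / `sigma_factor` | 0.5 / 1.3 | core level; pre/post boundary |

Degenerate inputs are refused loudly: all-zero stage durations, undetected
SSNVs (`m = 0`) at ingest, non-timeable or oversized copy-number states,
overlapping segments, empty cohort matrices, `gd_time` at 0/1 (rate flagged
NaN). Constant arrival times form a single zero-SD cluster. All randomness
flows from explicit seeds; identical seeds give byte-identical outputs.

## Known limitations

Deletions, subclonal copy-number mixtures and extrachromosomal amplification
are out of scope; multi-sample phylogenies and public/private SSNV
classification are upstream responsibilities. The reported times are upper
bounds, not point estimates: on states with many histories the bound can sit
well above the true value when the spectrum is compatible with later gains
(quantified for 6:1/6:2 in the test suite). SSNV pre-selection
(clonality, signature filtering) materially affects results and is assumed
done.
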
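# Methods

## Setting and assumptions

The package designs trials with K experimental arms and one shared
control.  Patient outcomes are independent normal with known standard
deviation σ; larger means are better, and the effect of arm k is
θ_k = μ_k − μ_0.  Arm k joins the platform once n(k) control patients have
been recruited (n(k) = 0 for arms present at the start; n(k) is
nondecreasing in k) and is analysed up to J_k times.  All worked designs
use the standard geometry: equal stage counts J, 1:1 allocation between
each open arm and the control per stage, so arm k and its concurrent
control window both hold j·n patients at the arm's j-th analysis and the
cumulative control count is n(k) + j·n.

Only concurrent controls enter an arm's test statistic.  This is what
makes staggered entry safe under time trends in the outcome, and it fully
determines the joint law of the statistics: means θ_k √I_kj with
I_kj = [σ²(1/n_kj + 1/m_kj)]⁻¹ (Fisher information of the mean
difference; m_kj concurrent controls), and covariances obtained by
counting shared patients — nested treatment samples within an arm and the
overlap of control windows across arms.  Within one arm the familiar
group-sequential correlation √(I_kj / I_kj′) results; two arms with
disjoint control windows are independent.  The correlation construction
is locked in by a patient-level Monte Carlo oracle in the test suite
(agreement within 4 Monte Carlo standard errors at 2·10⁵ replicates).

## Boundaries and error control

Decision rules: at each of its analyses an arm stops for superiority if
Z > u, for futility if Z < l, and continues otherwise; the final bounds
coincide so a decision is forced.  Boundary shapes are one-parameter
families in a scale a:

* triangular: u_j = a(1 + j/J)/√j, l_j = a(−1 + 3j/J)/√j — a linearly
  narrowing continuation region, the default in the worked designs;
* Pocock: u_j = a; O'Brien–Fleming: u_j = a√(J/j); both with interim
  futility bounds at 0.

The FWER under the global null is one minus the sum, over all ∏J_k
stop-stage vectors, of the multivariate-normal probability that every arm
exits through its futility bound — a disjoint decomposition of "no arm is
ever declared superior".  Calibration brackets and root-finds the unique
a with FWER(a) = α (FWER is monotone decreasing in a); strong control over
arbitrary null subsets then follows and is verified numerically in the
tests (subset rejection probability ≤ α + 10⁻⁴).  For nonbinding futility
bounds the interim lower limits are treated as −∞ during error
evaluation, which collapses the sum to the single rectangle "no arm ever
exceeds u"; operating-characteristic evaluations always enforce the
stored bounds.

All rectangle probabilities use SciPy's Genz-type quasi-Monte Carlo
integrator at absolute tolerance 10⁻⁸ with a fixed internal generator
seed, so every probability — and hence every calibrated boundary — is
bit-reproducible.  Calibration solves |FWER − α| to 10⁻⁶ (brentq,
xtol 10⁻⁹ on a), which pins boundaries to well beyond 3 decimals.
Degenerate rectangles (any lower ≥ upper) short-circuit to 0, and an
empty index to 1.

## Power and sizing

* Pairwise power of arm k: the within-arm sum over stopping stages of
  P(continue through earlier stages, exceed u at stage j), shifted by
  θ√I.  It involves no other arm.
* Conjunctive power: probability that *every* arm whose effect reaches
  the clinically relevant θ′ is declared superior; arms below θ′ are
  marginalised out, and with no such arm the value is 1.  Sizing at
  Θ′ = (θ′, …, θ′) is justified by the minimality of conjunctive power
  there, which the tests check on effect grids (monotone in each effect,
  decreasing in the number of relevant arms).
* Disjunctive power: complement of the all-futility sum with mean shifts —
  P(at least one arm declared superior); at the global null it equals the
  FWER.

An effect of −∞ is handled symbolically (the arm exits at its first
analysis for futility with probability one and contributes no efficacy
events), not as a large negative number.

Sample-size search: when addition times are *ratios* of n, the
correlation structure is scale-free, boundaries are calibrated once on a
ratio layout, and the smallest integer n meeting the power target is
found either by a unit-step scan or by an equivalent bisection (default;
a test asserts both agree).  When addition counts are *fixed absolute*
numbers, the allocation ratios change with n, so each candidate n gets
freshly calibrated boundaries and n increases one patient at a time from
the no-staggering size — the iterative scheme for predefined addition
counts.  Ratio-derived counts are rounded up to whole patients
(conservative for power); the printed worked designs are integer-exact so
no rounding occurs there.

## Outcomes, expected sample size, pausing

A stop profile (j, q) records each arm's stopping stage and exit
direction.  Its probability is a single rectangle (continuation bands,
then the chosen exit side at the stopping stage, all shifted by θ√I)
under the full cross-arm correlation; the profiles partition the sample
space (Σ Q = 1 within integration tolerance).  The total sample size of a
profile is Σ_k n_k,jk + max_k n_0,k,jk — the control recruits until the
last-added arm has completed — and expected sample size is Σ Q·N.
Grouping profiles by N (or by per-arm counts) gives the sample-size
distributions.

Paused recruitment is a sample-size accounting variant: if every arm
added so far has stopped before the next arm's join count is reached,
recruitment (control included) halts until that arm joins, so for each
inter-arm gap the shortfall max(0, n(k) − max over strictly-earlier arms
of their reached control count) is subtracted from N.  **This rule is a
reconstruction**: it is the simplest accounting consistent with the
behaviour it must reproduce (no effect whenever the next arm joins before
the earlier arms' first analyses; platform never worse than separate
trials when both control the family error, with equality at
n(2) = n_0,1,J), and it is isolated in one function (`outcomes.paused_N`)
for easy replacement.  Boundaries and correlations are always those of
the planned, unpaused geometry.

## Separate-trials comparison

Two error conventions for K separate two-arm group-sequential trials:
Setting 1 splits the family error (per-trial α = 1 − (1−α)^{1/K});
Setting 2 keeps the full α per trial.  For conjunctive comparisons each
trial is powered at (1−β)^{1/K}.  Combined maximum size is K times the
per-trial maximum; combined expected size sums the independent trials'
expectations (each trial runs to its own conclusion).

The crossover search finds the smallest integer addition gap g (arms
joining every g control patients) at which the platform's maximum or
expected sample size reaches the separate-trials figure, re-deriving the
platform design (recalibration + iterative sizing) at every evaluated
gap.  Both metrics are nondecreasing in g — larger gaps both extend
control recruitment and decorrelate the arms, widening the boundaries —
so the first crossing is located by bisection on the integer grid with
the bracket invariant metric(lo) < target ≤ metric(hi); this visits
O(log) grid points and returns the same gap as a unit-step scan.  Sizing
warm-starts from the smallest n seen at a smaller gap (the sizing loop
only increases n, so a start at or below the answer cannot change it).

## Simulator

The Monte Carlo oracle draws the trial patient by patient: one control
stream cut at every count the design references and one stream per arm,
statistics formed exactly as defined (arm mean minus concurrent-control
mean), stopping rules applied stagewise.  A sufficient-statistic fast
path draws stagewise increments of the sums instead of individual
patients; the two engines target identical laws and the tests compare
their stop-stage frequencies and expected sizes.  Replicate counts in the
shipped tests are 4·10⁴–10⁵, chosen so that 4-standard-error agreement
bands are a few tenths of a percentage point wide while the whole suite
stays quick on one CPU.

## What the defaults emulate — and what they do not

The default study conditions are the motivating two-arm trial:
θ′ = −log(0.69), σ = 1, one-sided FWER 2.5%, 80% power, J = 2 analyses
per arm (interim halfway), 1:1 allocation, binding triangular bounds,
second arm added halfway through arm 1's recruitment.  Passing tests
certify the multivariate-normal design arithmetic under exactly these
idealisations: normal outcomes, known σ, no time trends, no overrunning
patients at interims, addition times fixed in advance.  They say nothing
about unknown-variance small samples (t-statistics), non-normal or
time-to-event endpoints beyond the normal approximation, allocation-ratio
changes mid-trial, or data-driven addition times.

## Known limitations

* Calibration assumes the common-shape case (equal J, allocation and
  boundary shape across arms, giving equal per-arm error); `BoundarySet`
  stores per-arm boundaries, but no calibration path produces unequal
  ones.
* Outcome enumeration is ∏_k 2J_k rectangles of dimension up to ΣJ_k; a
  configurable cap (default 10⁵ profiles) guards against designs where
  high-dimensional multivariate-normal integration becomes impractical.
* The paused-recruitment rule is the reconstruction described above.
* Unequal inter-arm gaps are supported in the layout but not in the
  multi-arm sweep, which adds arms at equal gaps.
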
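# Methods

## Problem and model

The package studies a specific bias mechanism in two-group clinical
research: asymmetric handling of clinically unexpected values. A researcher
who believes one group runs higher than the other encounters a surprisingly
low value in the believed-high group (or a surprisingly high one in the
believed-low group) and — following sound clinical instinct —
remeasures the patient, excludes them, or reassigns them to the other
group. Each act is individually defensible; applied asymmetrically they
manufacture a spurious group difference.

All simulation is under the global null: both groups are i.i.d. N(0, 1).
Real clinical variables are rarely exactly normal, but skewed variables are
conventionally transformed toward normality before testing, so the
simulations describe data *after* such transformation; heavy-tailed or
discrete data are outside the model. The believed-high group is a fixed
label, not a property of the data — the belief, not the evidence, drives
the manipulation direction.

## Manipulation operators

"Clinically surprising" is operationalised by rank: the k most extreme
values in the disfavored tail (k lowest in the believed-high group, k
highest in the believed-low group). Rank selection makes "k patients
manipulated per group" exact, which is the natural x-axis for the sweeps; a
threshold rule ("values beyond c") would make the manipulated count random.

- **Remeasurement.** Repeat measurements share the patient's true value:
  first and second readings are bivariate normal with common marginal
  N(μ, σ²) and correlation equal to the intraclass correlation coefficient,
  default ICC = 0.5 (measurement-noise variance equals true-value
  variance — a realistically mediocre clinical measurement). The repeat is
  drawn from the conditional law `new = μ + ρ(old−μ) + σ√(1−ρ²)·ε` and
  *kept only if less extreme*. "Less extreme" is judged directionally —
  keep max(old, new) on the low tail of the believed-high group, min(old,
  new) on the high tail of the believed-low group — matching the narrative
  of rechecking a surprisingly low/high reading. A variant judging extremity
  by absolute distance from the population mean is available
  (`less_extreme="absolute"`) for sensitivity analysis; it behaves almost
  identically at ICC 0.5. Each selected patient is remeasured once: a
  patient whose repeat came out *more* extreme keeps the original value and
  is not retried.
- **Removal** deletes the selected patients; groups shrink by k.
- **Reclassification** swaps the selected patients between groups,
  *simultaneously* on the pre-manipulation order statistics (sequential
  swapping would make the result depend on processing order). The pooled
  multiset of values is conserved exactly.

## The Tadpole statistic

Every operator attenuates the two facing tails, so skewness rises in the
higher-mean group and falls in the lower-mean group — a configuration with
no natural generating mechanism. Per-group skewness is scored with the
D'Agostino (1970) z-transformation of √b₁ (the same transformation behind
standard `skewtest` routines): √b₁ is scaled to unit variance and mapped
through a Johnson S_U fit to an approximately standard-normal z. The
statistic is the z difference oriented by observed sample means, compared
against the constant 1.64·√2. The constant treats the two z-scores as
independent unit normals and puts 5% one-sided mass beyond the threshold;
it is applied as stated, without re-deriving its exact level (the null
calibration tests confirm the realised level stays at or below 5% for
n ∈ {50, 100, 200}).

The transformation needs moderate samples: a minimum group size of 9 is
enforced, below which inputs are rejected with an explicit error. Zero
sample skewness maps to exactly 0; zero variance is rejected. Exactly tied
group means (measure zero on continuous data) are resolved by reporting
|z_a − z_b| with a tie flag, keeping the result deterministic.

## Significance tests

The simulated researcher analyses with the pooled-variance two-sample
Student t (two-sided, df = n_a + n_b − 2, handles unequal sizes after
removal) or the two-sided Mann-Whitney U. The U test uses the normal
approximation with continuity and tie corrections at all n: simulated
groups have n ≥ 20, well inside the approximation's range, and ties are
measure-zero on continuous data. Both are delegated to scipy
(`ttest_ind`, `mannwhitneyu`); the package's own contribution is the
Tadpole statistic and the manipulation/sweep machinery. "Positive" means
two-sided p < α with α = 0.05 throughout.

## Monte-Carlo design

For each (group size, manipulation, test), the engine sweeps k = 0..k_max
and records the fraction of replicates positive by the significance test
and by the Tadpole test (Tadpole detection is computed unconditionally,
i.e. not restricted to replicates whose significance test is also
positive). The **minimal k** is the smallest k whose positive fraction
*strictly* exceeds 50% — "majority" with a well-defined crossing.

Sweeps use common random numbers: the same replicate studies, sorted once,
are re-manipulated at every k, and remeasurement noise is attached to tail
*positions* (drawn position-major, both groups per position), so the noise
a position receives is independent of k and of k_max. Consequences: the
positive-fraction curve is monotone in k by construction, the minimal-k
estimator has far lower variance than independent draws would give, and
results are bit-reproducible from (config, seed) alone. The engine draws
whole replicate matrices from a single numpy `Generator` seeded by the
config; everything runs single-process and vectorised over the replicate
axis, which is what makes 20,000-replicate sweeps take seconds. A scalar
per-study path (`run_once`, plus the per-study operators) exists alongside
and is cross-checked against the vectorised path in the tests.

Removal sweeps cap k at n − 9 so the surviving group still admits a skew
z-score; other kinds cap at k = n.

### Replicate counts and problem sizes

Default `reps` is 2,000: at a 50% boundary the binomial standard error is
√(0.25/2000) ≈ 1.1%, which locates the minimal k to about ±1 patient —
the tolerance the test suite uses. The acceptance script uses 20,000
replicates for group sizes ≤ 200 (SE ≈ 0.35%, resolving the crossing
exactly) and 5,000 at 800 per group; 100,000 is available through
`SimulationConfig(reps=...)` for full-precision replication. The group-size
grid for figure-style reproduction is {20, 50, 100, 200, 400, 800}.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions exactly: equal-sized groups,
one normal population, manipulation driven purely by group membership and
rank. It does not emulate covariates, non-normal raw scales, informative
missingness, partial or repeated remeasurement, or manipulation of only a
random subset of surprising values. Passing tests therefore demonstrate the
operating characteristics of the tests and operators under the stated
model, not the prevalence or detectability of bias in any real literature.

## Known limitations

- The Tadpole test is specific to the tails-apart signature; symmetric
  trimming, fabrication, or manipulations aligned with a natural
  tails-together pattern will not trigger it.
- The threshold's nominal 5% level leans on independence and approximate
  normality of the two skew z-scores; observed null rates run at or
  slightly below 5%, so the test is, if anything, mildly conservative.
- Aggregating Tadpole z-scores across studies (meta-forensics) is not
  implemented: no principled aggregation rule is established, so it is
  deferred rather than guessed.
- Multi-group (ANOVA-style) designs and true-effect power analysis are out
  of scope.
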
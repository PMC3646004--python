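# Methods

## The inference model

A trajectory is reduced to movement rates `r_t` (inter-fix Euclidean distance
over elapsed time) and signed turning angles `phi_t` in `(-pi, pi]`
(quadrant-aware arctangent of successive displacement vectors;
counter-clockwise positive, exact reversals mapped to `+pi`). Each step-series
entry carries a latent behavioural state `z_t`; states are assigned
independently (no transition model). Within state `j` rates are
Weibull(shape `a_j`, scale `b_j`) and angles wrapped-Cauchy(mean `mu_j`,
concentration `rho_j`); the likelihood is the product of per-entry factors.
Entries with a valid rate but no valid angle (a gap at the third fix of the
triple) contribute the Weibull factor only — the likelihood factorises, so
discarding them would only waste information.

`rho` is capped at `rho_max = 0.99`: the wrapped Cauchy degenerates to a
point mass as `rho -> 1`, and a finite cap keeps the uniform prior on
`(0, rho_max)` proper and the density bounded.

## Priors and sampler

* `a, b ~ Gamma(shape 0.3, rate 0.01)` — the moment match to a vague prior
  with mean 30 and variance 3000.
* `mu ~ U(-pi, pi]`, `rho ~ U(0, rho_max)`, `w ~ Dirichlet(1)`.

One sweep of the Metropolis-within-Gibbs sampler draws: every label from its
exact full conditional `P(z_t = j) ∝ w_j f_j(r_t, phi_t)` (vectorised,
log-space, independent across entries); weights from the conjugate
`Dirichlet(1 + counts)`; then per state four random-walk Metropolis blocks —
log-scale walks for `a` and `b` (with the log-transform Jacobian folded into
the target), a wrapped walk for `mu`, and a boundary-reflected walk for `rho`
(reflection is symmetric on the interval, so the uniform prior cancels).
Empty states automatically sample their priors.

Proposal SDs adapt by Robbins-Monro on the log scale towards 30% acceptance
during burn-in only; freezing adaptation afterwards preserves the exact
stationary distribution. The default protocol is a single chain of 100,000
iterations after a 2,000-iteration burn-in, thinned to every 10th sweep
(10,000 kept samples). Split-chain R-hat on the continuous parameters is
available (`fit.split_rhat`) and is checked in the test suite; multi-chain
comparisons are obtained by re-running with different seeds.

The choice of Metropolis-within-Gibbs (rather than a particular black-box
Gibbs implementation) is deliberate: only the posterior is specified by the
model, exact-conditional label/weight updates mirror the independent-state
assumption, and every block is unit-tested against brute-force enumeration or
dense-grid quadrature oracles.

## Label switching and summaries

The mixture posterior is invariant under state-label permutation, so chains
swap state identities. Before summarising, Stephens' batch KL relabeling is
applied: per kept sample the classification matrix
`P^(m)[t, j] ∝ w_j f_j(r_t, phi_t)` is permuted to minimise the KL divergence
from the running average `Q`, iterating assignment and average to a fixed
point, enumerating all `N! ≤ 6` permutations exactly. `Q` is seeded from the
first kept sample: seeding from the plain average of a switching chain would
be symmetric across states and tie every permutation. The global orientation
after relabeling is conventional, and is fixed by sorting states by posterior
Weibull mean — "state 1" is always the slower (area-restricted) state.

Summaries are computed per state from the relabeled chain:

* *posterior mean density*: the pointwise average over kept samples of the
  parametric pdf, with the pointwise SD across samples as a confidence band
  (the average of densities integrates to one; the band curves are not
  densities);
* *posterior Weibull mean*: mean and SD across samples of `b Γ(1 + 1/a)`;
* *posterior mean turn vector*: mean across samples of
  `(rho cos mu, rho sin mu)`; its uncertainty is reported as a single scalar,
  the planar root-mean-square deviation of the per-sample vectors around the
  mean (the radius of the circle drawn at the arrow head);
* *state probabilities*: per entry, the fraction of kept samples assigning it
  to each state — no discretisation;
* *classification accuracy* (synthetic data only): each entry is assigned its
  maximum-probability state (ties to the lower index) and scored against the
  generating regime, maximised over state-to-regime assignments since state
  identity is arbitrary. An entry's ground truth is the regime of the middle
  fix of its (k, k+1, k+2) slot triple, the fix shared by its rate and turn.

## The synthetic generator

The generator emulates a two-regime movement path: alternating `straight`
(fast-transiting) and `area_restricted` (slow foraging) segments, each
20–100 points long (uniform integers; the last segment truncated so the
trajectory holds exactly 487 points; the first regime chosen uniformly).
Within a segment, headings accumulate von Mises turn increments from a fresh
uniform initial direction, and step lengths follow a Gaussian random walk
`d_{i+1} ~ N(d_i, sigma^2)` truncated positive by rejection, seeded at the
regime's initial step length. Autocorrelated step lengths are what make the
per-regime *initial* step meaningful; truncation guards against non-physical
negative lengths. Timestamps are uniform (`dt` units per step).

Default regime parameters (packaged in `data/synthetic_default.yaml`; the
code treats them as data and refuses to run if any are missing or
non-finite):

| regime          | mu_turn | kappa_turn | step_init | step_sd |
|-----------------|---------|------------|-----------|---------|
| straight        | 0       | 10         | 2.0       | 0.1     |
| area_restricted | pi      | 1          | 0.5       | 0.1     |

These numerals are **calibrated defaults, not transcriptions**: they were
chosen once to satisfy the qualitative regime description — directional
persistence with a highly peaked turn distribution for transiting; slower
movement with a broad turn distribution centred on reversal for
area-restricted behaviour; a shared, modest step-length innovation. Anyone
with an authoritative parameter set should drop it into the YAML; everything
downstream reads the file.

The GPS-collar emulator is plumbing that makes the preprocessing stages
testable: one candidate fix per 300 s, 5% independent dropouts, isotropic
Gaussian position noise (SD 0.05 length units), 30% two-dimensional fixes and
log-normal PDOP values (`mu = 1.3`, `sigma = 0.6`) calibrated so that the
standard screening rule — drop 2D fixes with PDOP > 5 — removes roughly 10%
of records. Collar-style experiments default to an 818-point trajectory
(`collar_generator_config`), the per-animal average of a four-animal campaign
totalling ~3,272 fixes; the 487-point default is the synthetic-trajectory
study condition. Smaller collar data volumes are numerically fragile: with a
few dozen entries the vague Gamma priors put non-trivial mass at tiny Weibull
shapes, where `Γ(1 + 1/a)` makes the posterior of the Weibull mean extremely
heavy-tailed.

What the emulator does *not* reproduce: per-night trajectory batching,
activity gaps (denning), autocorrelated fix failure, heteroscedastic position
error, or geographic projection. Passing tests therefore demonstrate
correctness of the pipeline and the qualitative resolution effects on clean
planar tracks, not performance on real collar archives.

## Subsampling and missing data

Subsampling selects fixes on the grid `anchor + k * interval` (anchor = first
retained fix; exact match by default, a configurable tolerance for jittered
real timestamps; the closest fix wins a slot). Missing slots are left absent —
no interpolation — so a rate needs fixes at slots `(k, k+1)` and an angle at
`(k, k+1, k+2)`; a gap invalidates only the affected values. Consequently the
fixes used at one interval are not necessarily a subset of those used at
another. The rule is deliberately minimal: a gap invalidates exactly the
values that need the missing fix and nothing more (no whole-night or
whole-window exclusion).

## Numerical choices

* Angles are radians in `(-pi, pi]` internally; degrees appear only on plot
  axes. Wrapping maps `-pi` to `+pi`.
* Log-density formulas are hand-vectorised (they sit in the MCMC hot path);
  `scipy.stats.weibull_min` / `wrapcauchy` serve as independent oracles in
  tests. `r = 0` is handled by the Weibull log-density's exact limits.
* Weibull method-of-moments initialisation inverts the CV relation by Brent's
  method on `a ∈ [0.1, 50]`, on a randomised contiguous split of the sorted
  rates, so multimodal rate data start with distinct state means.
* Label draws underflow-protect by row-max subtraction; an entry whose
  density is zero in every state falls back to the weights.
* Non-finite Metropolis proposals are rejected; `exp` overflow in the Weibull
  likelihood yields `-inf` and certain rejection.
* All randomness flows through explicitly threaded numpy `Generator`s; fixed
  seeds make every stage byte-reproducible. Sweep stages derive per-interval
  chain seeds from a `SeedSequence` of (base seed, interval).

## Test problem sizes

The test suite exercises the full protocol shape at reduced length: pipeline
tests run 20,000 iterations after a 2,000-iteration burn-in (the package's
scaled proxy for the 100,000-iteration protocol; acceptance rates and R-hat
are checked), oracle comparisons use 30,000–40,000 iterations on ≤5-point
datasets, and Monte-Carlo law checks use 10^5–10^6 draws.
`scripts/acceptance.py` runs the full 100,000-iteration protocol.

## Known limitations

* No model selection across N = 1, 2, 3 (DIC/WAIC), no switching dynamics,
  no observation-error state-space layer — deliberate scope bounds.
* The posterior mean of `b Γ(1 + 1/a)` is heavy-tailed for states holding
  very few points (see above); the median across samples is a more robust
  location in that regime, but the reported summary keeps the mean-of-samples
  definition.
* Trend sequences across a 12-interval sweep on a single synthetic trajectory
  wobble at the few-percent level between adjacent intervals, because the
  selected fix set changes non-monotonically with the interval; monotone
  trend statements hold end-to-end (finest vs coarsest) rather than between
  every adjacent pair.
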
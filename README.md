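# statewalk

Bayesian multi-state random-walk inference for animal movement trajectories,
with tooling to study how the *temporal resolution* of a trajectory changes
the behavioural states the model infers.

## The problem

Animal-borne tracking devices (GPS collars in particular) record a
"geospatial lifeline": a time-ordered sequence of positions. Converted to
movement rates and turning angles, such trajectories can be segmented into
latent behavioural states — typically a *slow, area-restricted* mode
(foraging/resting: low speeds, large frequent turns) and a *fast-transiting*
mode (high speeds, near-straight travel). But every derived metric depends on
the interval between fixes: as sampling coarsens, apparent movement rates
drop and turning angles flatten toward uniformity, so states that are obvious
at a 5-minute grain can be undetectable at an hourly one. `statewalk`
implements the full pipeline needed to quantify this effect on synthetic data
with known ground truth:

1. **simulate** — a two-regime correlated random walk (von Mises turn
   increments, autocorrelated Gaussian step lengths) plus a GPS-collar
   observation emulator (dropouts, position noise, 2D/3D flags, PDOP values);
2. **preprocess** — quality screening, regular-grid temporal subsampling (no
   interpolation: missing slots simply drop the affected values) and
   conversion to movement rates and signed turning angles;
3. **model / fit** — an `N`-state mixture of random walks fitted by
   Metropolis-within-Gibbs MCMC;
4. **postprocess / viz** — Stephens relabeling, posterior mean densities with
   SD bands, mean turn vectors, per-point state probabilities, classification
   accuracy against the generating regime, and the corresponding figures.

## The model

For movement rates `r_t` and turning angles `phi_t`, each observation carries
a latent state `z_t ∈ {1..N}` (N = 1, 2 or 3, states assigned independently —
no switching dynamics). Within state `j`:

    r_t   ~ Weibull(a_j, b_j)            f(r) = (a/b)(r/b)^(a-1) exp(-(r/b)^a)
    phi_t ~ WrappedCauchy(mu_j, rho_j)   f(phi) = (1/2pi)(1-rho^2)/(1+rho^2-2rho cos(phi-mu))

with mixture weights `w` on the simplex. The Weibull mean is
`b Γ(1 + 1/a)`; the wrapped-Cauchy mean vector is `(rho cos mu, rho sin mu)`,
whose norm `rho` measures turn concentration (`rho = 0` uniform, `rho → 1`
point mass). Priors: `a, b ~ Gamma(0.3, 0.01)` (mean 30, variance 3000),
`mu ~ U(-pi, pi]`, `rho ~ U(0, 0.99)`, `w ~ Dirichlet(1)`. A single chain runs
100,000 iterations after a 2,000-iteration burn-in, keeping every 10th sweep;
labels and weights are drawn from their exact full conditionals, continuous
parameters by adaptive random-walk Metropolis (adaptation burn-in only).
Label switching is resolved by Stephens' KL relabeling with exhaustive
permutation enumeration; states are then presented slow-first.

Posterior summaries follow the *posterior mean density* convention: the
reported rate/angle distribution of a state is the average of the per-sample
parametric densities (it integrates to one), with pointwise SD bands for
fitting confidence.

## Worked example

Simulate the default two-regime trajectory (487 points, alternating segments
of 20–100 points), convert it at its native resolution, fit the two-state
model and summarise:

```
statewalk simulate --seed 1 --out traj.csv
statewalk preprocess --interval 1 --in traj.csv --out steps.csv
statewalk fit --states 2 --iters 20000 --burnin 2000 --seed 1 \
    --in steps.csv --out chain.npz
statewalk summarize --chain chain.npz --steps steps.csv \
    --truth traj.csv --out summary.json
```

The run prints `wrote 486 rates / 485 angles` and acceptance rates near 0.3
for all four parameter blocks, and `summary.json` contains (abridged):

```
state 1: weibull_mean 0.608 +/- 0.025, mean_vector (-0.336, 0.018) +/- 0.065
state 2: weibull_mean 1.983 +/- 0.046, mean_vector ( 0.813, -0.032) +/- 0.022
accuracy 0.961
```

State 1 is the slow, area-restricted regime: mean rate 0.61 length units per
step and a mean turn vector pointing down the negative x-axis (turns
concentrated near ±180°). State 2 is the fast-transiting regime: mean rate
1.98 and a strongly concentrated turn distribution around 0°. 96% of points
are assigned to their generating regime (best label permutation). A full
resolution sweep — refitting after subsampling at factors 1..12, or on
emulated collar data at 5..60-min intervals — is one command:

```
statewalk run --mode synthetic --sweep 1,3,6,12 --seed 1 --out sweep_out/
```

which writes per-interval summaries (`summary.json`), a tidy trend table
(`trends.csv`: posterior Weibull means, mean-vector norms and state
proportions per interval) and saved chains. As the interval grows, both
states' mean-vector norms shrink toward zero — the turning-angle
distributions become indistinguishable from uniform — and apparent movement
rates fall. `statewalk plot` renders the density panels, mean-vector diagrams
and state-coloured trajectories; `statewalk equal-n` runs the equal-sample-
size control that separates resolution effects from sample-size effects.

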
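# Methods

## The model

Each cell carries an unknown number `c` of transiently transfected reporter
plasmid copies. Per copy, transcription proceeds at a basal rate `tau0`
until the cell-specific switch time `T`, and at the active rate `tau1`
afterwards (a two-state, single-switch telegraph description of promoter
activation). mRNA `M` and protein `P` follow a chemical Langevin pair,

    dM = (c*tau(t) - dM_*M) dt + sqrt(c*tau(t) + dM_*M) dW
    dP = (alpha*M - dP_*P) dt + sqrt(alpha*M + dP_*P) dW

with diffusion equal to the square root of the summed production and
degradation propensities, so both intrinsic birth/death noise and the
copy-number-scaled production term are represented. Fluorescence is
observed every 30 min through `F = kappa*P + eps`, `eps ~ N(0, sigma2)`.

Because `c` and `tau` enter drift and diffusion only through the product
`c*tau(t)`, a single trace cannot separate them: the law of `F` is exactly
invariant under `(c, tau) -> (g*c, tau/g)`. The hierarchical population
layer resolves this ridge. Every per-cell quantity is drawn from a
population distribution; the copy-number distribution is shared by **all**
constructs while each construct has its own rate distributions. All rates
are therefore estimated relative to one common copy-number scale and are
comparable across constructs even though their absolute unit is arbitrary.
We anchor that scale by fixing the copy-number population log-median at
zero (median `c` = 1).

## Kinetic constants

`delta_M` (default ln2/180 per min, a 3 h mRNA half-life), `delta_P`
(ln2/1440, a stable ~24 h fluorescent reporter), `alpha` (1 protein per
mRNA per min) and `kappa` (1e-3 AU per protein) are fixed configuration
constants, not sampled; with rates in arbitrary units only their ratios
shape the traces. `sigma2` (default 4e4 AU^2, i.e. ~200 AU measurement
noise on signals of 1e4-1e5 AU) is sampled globally by a random-walk
Metropolis step on `log sigma2` — the Kalman-marginalized likelihood is
not conjugate in `sigma2`, so a Gibbs draw is not available.

## Likelihood

Between observations the latent moments are propagated by a
continuous-discrete Gaussian filter. The drift is linear with
piecewise-constant input, so the mean uses the exact closed-form flow
(numerically stable `expm1`-based propagators, split exactly at `T`); the
covariance accumulates the diffusion matrix evaluated along the predicted
mean with a trapezoidal rule over substeps (default 4 per 30-min interval).
Each fluorescence sample applies a standard Kalman update. With
`sigma2 = 0` and no process-noise variance at an observation the law is
degenerate: the log-likelihood is `-inf` unless the datum sits on the
deterministic path. The filter inherits the exact `(c, tau) -> (g*c,
tau/g)` invariance of the model, which the tests assert to 1e-8.

Alternatives (particle filtering, path augmentation) would fit behind the
same interface; the Gaussian filter was chosen because the linear drift
makes it fast and, at the molecule numbers these traces imply, accurate
(validated against a kernel-density estimate over 4e5 forward simulations).

## Sampler

A Metropolis-within-Gibbs sweep updates, per cell: log-scale random walks
on `c`, `tau0`, `tau1`, `M0`, `P0`; a reflected random walk on `T` over the
observed window (flat prior); and a likelihood-invariant "scale swap"
`(c, tau0, tau1) -> (g*c, tau0/g, tau1/g)` that moves along the product
ridge at zero likelihood cost, dramatically improving mixing of the
copy/rate decomposition. `tau0 <= tau1` is enforced by proposal rejection.
Per sweep, the population layer is Gibbs-updated: normal/inverse-gamma
conditionals for each construct's rate log-mean and log-variance and for
the shared copy-number log-variance (log-mean fixed at zero as the scale
anchor). `M0` and `P0` carry fixed broad log-normal priors rather than
sampled hypers; the figures of merit never involve their population
distributions.

Because the data pin the product `c*tau` very tightly, product-direction
proposals use small steps (default 0.15 log-units; the high-signal test
fixtures use 0.02) while the swap move carries the ridge direction.
Initialization is method-of-moments: the late-time fluorescence slope
estimates `c*tau1` through the quasi-steady mRNA level, the switch time
starts at the first 20%-of-range crossing, and chains after the first are
jittered. Default budget: 2 chains of 50k sweeps, 20k burn-in, thinning 10;
all tests declare their own reduced budgets (20k sweeps for the recovery
fixture), sized so the full suite runs on one CPU at desk scale.

### How the copy/rate decomposition is resolved

The likelihood identifies only the product, so the decomposition is decided
by the population layer. The hyperpriors encode the transfection biology:
the copy-number log-variance prior is loose (inverse-gamma(2, 1.0), prior
mean 1.0 — transient transfection spreads copy numbers over orders of
magnitude) while the per-construct rate log-variance priors favour tight
distributions (inverse-gamma(2, 0.1) — cells of one clonal line share
per-copy rates much more closely). Cell-to-cell expression variability is
consequently attributed mostly to copy number, per-copy rates shrink
toward their construct distribution, and estimated copy numbers decorrelate
from estimated rates. This is a modelling commitment, not something the
data can test: a generator whose true rate spread exceeded its copy-number
spread would be decomposed wrongly (while still fitting the traces and
recovering between-construct rate ratios, which depend only on products).

## Synthetic data

The generator reproduces the study design: ~19 constructs, 30-35 cells
each, imaged every 30 min for 48 h. Per-cell parameters come from
log-normal population distributions (`c` median 10, log-sd 1.0 shared by
all constructs; construct-specific `tau1`, log-sd 0.3), `tau0 = u * tau1`
with `u ~ U[0, u_max)` so basal never exceeds active, and `T` uniform on
the window. The log-normal family is a choice the source data motivate
only at the level of single-cell mean rates; the hierarchical families
were never stated and are configurable. The integrator is an exponential
Euler-Maruyama: the exact linear-drift flow over each 0.1-min substep plus
a `sqrt(Q(x) h)` Gaussian kick, reflecting at zero (the chemical Langevin
approximation can undershoot). The exact flow makes the noise-free limit
agree with the ODE oracle to machine precision, which plain Euler steps
cannot. Switch times are honoured exactly by splitting the crossing
substep.

What the generator does **not** emulate: autofluorescence background
(traces are background-free, so the 8,000 AU preselection acts on signal
alone), promoter bursting beyond the single switch, reporter maturation,
cell growth/size effects, and realistic division (an optional marker with
post-division signal halving exists only to exercise the QC path). Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to real imaging artefacts.

## Quality control

Mirrors the imaging study: keep traces with >= 10 samples strictly above
8,000 AU (strictness is a fixed convention; either convention works),
split at division markers with the boundary sample assigned to the
post-division generation, truncate at the first global fluorescence
maximum (one cell cycle; first occurrence on ties), and subsample a
uniform-random 30-35 traces per construct, seeded. Preselection runs
before synchronization, following the order of the imaging protocol.

## Downstream statistics

Per-cell summaries use the `tau1` posterior (basal-rate summaries are kept
separate); CV = SD/mean, SNR = 1/CV, switch-time spread as the central 90%
interval, switch samples centred on their median for cross-cell display.
Stack densities are Silverman-bandwidth KDEs of log-rate samples on a
log-spaced grid, renormalized to unit trapezoidal mass, cells sorted by
posterior mean. Log-normality of single-cell mean rates is tested by a KS
statistic with estimated parameters whose p-value comes from a parametric
bootstrap (estimating parameters makes the naive KS p anti-conservative;
the naive value is reported alongside). Containment ("filter" action of a
regulatory module) rank-matches cells of two groups by posterior-mean
quantile and asks whether the central 90% rate interval of one lies within
the other's — the original comparison was visual, so the interval level
and matching rule are this package's formalization. Behaviour classes:
multimodal if a 2-component Gaussian mixture beats 1 component by 10 BIC
points, else slow-wide above the cohort's upper-quartile CV, else
fast-high/fast-low about the cohort median mean — thresholds are named
heuristics, the classes having been described but never given a rule.

## Numerical notes and limitations

- Filter substeps default to 4 per observation interval; the likelihood is
  an approximation whose sampler-facing error cancels in the grid-oracle
  comparison (both routes share the filter) but not in absolute density.
- Degenerate posteriors (zero variance) are flagged rather than summarized
  (SNR undefined); degenerate population distributions ("point", zero-width
  uniform) are legal in the generator but have no density for inference.
- Inverse-gamma guards (`b0 > 0`) keep population variances away from zero;
  a degenerate construct (all rates identical) still mixes.
- Convergence diagnostics (split-Rhat, bulk ESS) are advisory; the
  reduced-budget fixtures show per-chain agreement of the headline ratio
  rather than full convergence of every nuisance parameter.
- Absolute rates and copy numbers are reported on the anchored scale
  (median copy number 1) and are meaningful only relative to each other.
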
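# Methods

## Model

`switchscape` analyses a two-state gene-expression circuit with positive
feedback. The gene switches between a closed (`alpha = 0`) and an open
(`alpha = 1`) chromatin state; the open gene transcribes mRNA (count `m`),
mRNA is translated into protein (count `n`), and both decay linearly. The
protein feeds back through the occupancy of its regulatory binding site,

    O(n) = n^h / (n^h + K^h),

which multiplies both the gene-activation gain `k_g` and the transcription
gain `k_r` (basal rates `k_g0`, `k_r0`; Hill exponent `h = 1` by default,
exposed as a parameter). The six reaction channels and propensities are

| # | reaction              | propensity                |
|---|-----------------------|---------------------------|
| 1 | gene open -> closed   | `d_g` (open only)         |
| 2 | gene closed -> open   | `k_g O(n) + k_g0` (closed)|
| 3 | transcription         | `k_r O(n) + k_r0` (open)  |
| 4 | translation           | `k_p m`                   |
| 5 | mRNA decay            | `d_r m`                   |
| 6 | protein decay         | `d_p n`                   |

All rates are per model time unit; no physical time unit is assumed, so
every reported time is in model units. Concentrations are identified with
copy numbers (volume V = 1) throughout, keeping the continuous reductions
and the discrete lattice on one scale.

The adiabaticity ratio `kappa = d_g / d_p` organises the analysis: gene
switching is *slow* for `kappa << 0.01`, *fast* for `kappa >> 1`, and
*intermediate* near the switching-time valley (`kappa ~ 0.03` at the
reference rates). Two reference parameter sets ship as presets, differing
only in the three gene-switching rates (ratios `d_g/k_g = 0.05` and
`d_g/k_g0 = 5` are common to both):

* `slow`: `k_r = 100, k_r0 = 0.1, k_p = 51.5, d_r = 0.7, d_p = 1.4,
  d_g = 0.0014, k_g = 0.028, k_g0 = 0.00028, K = 3000` (`kappa = 0.001`);
* `fast`: same but `d_g = 140, k_g = 2800, k_g0 = 28` (`kappa = 100`).

`kappa_family` moves along this one-parameter family: `d_g = kappa * d_p`
with `k_g`, `k_g0` rescaled to keep the two ratios locked. Under locked
ratios the adiabatically reduced drift (below) is independent of `kappa`,
so the deterministic saddle used to split the basins is common to the whole
family.

## Truncated master equation

The chemical master equation is solved on the lattice `alpha in {0,1}`,
`m < M`, `n < N` with *reflecting* truncation (outflowing jumps suppressed),
so probability is conserved exactly and the adequacy of the grid is
certified a posteriori: the solver raises an error when the stationary mass
on the outermost shells exceeds `mass_tol` (default 1e-8).

Default bounds come from the deterministic fixed points: `M ~ 2.5 x` the
open-layer fixed-point mRNA value and `N ~ 1.8 x` the fixed-point protein
value, with an additive floor of ten linear-noise standard deviations
(protein Fano factor `1 + k_p/(d_r + d_p)`); the floor only matters for
small-copy-number models, where a purely multiplicative margin is too thin.

Two stationary solvers sit behind one interface:

* **sparse** (small lattices, <= 60k states): replace one balance equation
  by the normalisation and solve the sparse linear system directly; this is
  the brute-force reference, double precision, residual tolerance 1e-10.
* **censoring** (large lattices, ~1e6 states at the reference parameters):
  the generator is block-tridiagonal in the protein level `n` (inner
  dimension `2M`: gene state x mRNA). Censoring (watching the chain only on
  levels `<= n`) eliminates levels from the top: `S_n = L_n + U_n
  (-S_{n+1})^{-1} D_{n+1}`, where `L/U/D` are the local, up- and
  down-coupling blocks. The recursion involves only inverses of
  irreducibly diagonally dominant M-matrices and is numerically benign; at
  level 0 a dense solve gives the censored stationary law and one backward
  sweep reconstructs the full distribution. Cost is one dense `2M x 2M`
  inversion per protein level (~40 s and < 2 GB for the reference grids);
  the back-substitution factors are stored in single precision, which caps
  the achievable residual near 1e-7 relative (default tolerance for this
  path). The two solvers agree to ~4e-10 in probability on a bistable test
  lattice, and basin occupancies -- the quantities the experiments consume
  at 1%-level thresholds -- are insensitive at this accuracy.

Energy landscapes are `U(m, n) = -ln P(m, n)` on the gene-summed marginal
with a probability floor (default 1e-16) so the potential is finite on the
truncated domain. KL divergences floor both tables at the same value and
renormalise before summing, making tables with exact zeros comparable.

Mean first-passage times between protein half-plane basins solve the linear
system `Q tau = -1` restricted to the non-target states: generically (small
lattices) by a sparse solve, and between half-planes by a block-tridiagonal
Thomas sweep in the protein level, which keeps the ~1e6-state fast-regime
systems at ~1 minute. The basin split defaults to the protein coordinate of
the reduced-drift saddle; `n = 400` is the sorting-experiment convention.

## Stochastic simulation

The direct Gillespie method is JIT-compiled (numba) and is the exactness
reference. Long switching-time sweeps may use tau-leaping: Poisson counts
for the mRNA/protein channels over a leap chosen by the standard
relative-change criterion (`eps = 0.03`), with two safeguards for the gene:

* when gene flips are slow on the leap scale, the leap is capped so at most
  a small flip probability falls inside it and a single flip time is drawn
  exactly (at most one flip per leap);
* when the gene flickers many times per leap (`flip rate x tau > 10`), its
  state is adiabatically averaged: transcription fires at the
  occupancy-weighted effective rate and the end-of-leap gene state is drawn
  from the flip equilibrium.

Leaps that would drive a count negative are halved and redrawn. Exactness
tests (stationary histograms, first-passage cross-checks) always run the
direct method; tau-leaped switching times agree with exact ones within
Monte-Carlo error on the test fixture.

Every replicate derives its seed from the master seed through a
counter-based (Philox) substream, so replicate `i` is unchanged when the
replicate count grows.

Switching times are measured from the source basin's metastable point
(rounded layer fixed point below `kappa = 1`, reduced fixed point above)
until the protein count first enters the target half-plane. The
dwell-excluded transition time `T` is recorded as the span since the last
visit to the source core (the metastable protein level). Note a
finite-noise effect: the *deterministic* transition-time surrogate (the
no-switching relaxation of the layer rate equations) matches the mean
flip-to-arrival segment duration well, but underestimates the
protein-core-based `T` by a factor ~2 at the reference slow parameters,
because the stochastic path wanders below the core before committing.

Averaged switching trajectories: reactive segments are extracted from the
gene-state flip to arrival near the destination fixed point (protein within
5% of the inter-state distance by default; segments aborted by a back-flip
are discarded), and the ensemble is averaged bin-wise after
re-parameterising each segment to [0, 1] by normalised arc length (50 bins
by default). This replaces a principal-curve fit; for ensembles
concentrated around a single monotone path the two coincide, and the checks
applied to the result (proximity to the deterministic relaxation and to the
minimum-action path) are robust to the substitution. To avoid storing the
~1e6 dwell events per switching event of the slow regime, segments are
sampled by running unrecorded dynamics until the gene flips and recording
only the relaxation (equivalent by the strong Markov property).

## Slow regime: two-layer reduction

For `kappa << 0.01` the dynamics decompose into a gene-closed and a
gene-open layer. Per layer, means follow the rate equations and
covariances the linear-noise flow `sigma' = sigma J^T + J sigma + 2D`; the
stationary covariance solves the corresponding Lyapunov equation directly
(exact and fast; the closed layer is degenerate -- a point mass at the
origin, handled as such on the lattice).

The stationary law is approximated by Gaussian mixtures with closed-layer
weight from the dwell-time balance

    w = (1/k_g0) / (1/k_g0 + 1/d_g) = d_g / (d_g + k_g0),

i.e. `w = 5/6` at the slow preset (the gene waits `1/k_g0` for basal
activation once the protein has decayed, but only `1/d_g` for
inactivation). The CME gene marginal confirms the balance to ~0.5%. The
*simple* mixture uses each layer's stationary pair; the *modified* mixture
time-averages the relaxation Gaussians started from the opposite layer's
stationary pair over the mean residence time (`T1 = 1/d_g` open, `T0 =
1/k_g0` closed), by trapezoidal quadrature on a log-spaced grid (200 nodes;
beyond a relaxation cutoff of `80 / min(d_r, d_p)` the moments are
stationary and the remaining quadrature mass is assigned to the endpoint).
Mixture densities are evaluated at the integer lattice points and
renormalised before comparison, making the continuous approximation and the
discrete CME directly comparable; KL divergences are reported per layer and
globally, in the direction KL(CME || approximation) by default (the
divergence direction is configurable; the choice is recorded in the output).

## Fast regime: quasi-potential by minimum action

For `kappa >> 1` the gene equilibrates instantly and the network reduces to
four channels in `(m, n)`: mRNA birth at the effective rate
`(k_r0 + k_r O)(k_g0 + k_g O)/(d_g + k_g0 + k_g O)`, mRNA decay, protein
birth, protein death. This channel set is the unique one whose rate-weighted
jumps reproduce the reduced mean-field drift while retaining the elementary
mRNA/protein stoichiometry. The drift has two stable fixed points and a
saddle in the bistable window, located by nullcline reduction to a scalar
root problem and classified by Jacobian eigenvalues.

Rare transitions are governed by the jump-process Hamiltonian
`H(x, p) = sum_j a_j(x) (e^{nu_j . p} - 1)` (exponent arguments capped at
500 against overflow). The local quasi-potential `S(x; x0)` is minimised in
geometric form: for each discrete segment the momentum `p*` solves `H = 0`
with `H_p` parallel to the tangent (2-D Newton from the per-coordinate
detailed-balance guess `p_i = ln(death_i / birth_i)`, warm-started along the
curve; in 1-D the non-trivial root is bracketed in closed form), and the
action `sum p* . dphi` is minimised over interior node positions by L-BFGS
with analytic gradients (envelope theorem: `dl/dx = -mu H_x`, `dl/dv = p*`),
re-parameterising to uniform arc length between rounds. Convergence is
declared when the best action stalls for three consecutive rounds, since
the re-parameterisation induces an action wobble (~1e-4 relative) below
which further "progress" is discretisation noise; the action is stable to
doubling the image count within ~1.2%. Deterministic (downhill) connections
return actions below 1e-4; the uphill paths from both attractors pass
through the saddle and do not coincide.

The global landscape sticks the two local quasi-potentials together: fans
of minimum-action curves from each attractor are scattered onto a grid
(linear interpolation, nearest-value fill outside the fan hull), the
on-surface is shifted so both surfaces agree at the saddle, the pointwise
minimum is taken, and the result is re-zeroed at its global minimum. The
deeper attractor is therefore at 0 and the shallower at the difference of
the two uphill actions. The convention `P^ss ~ exp(-V S)` (V = 1) is used;
along the uphill switching path the CME potential `-ln P^ss` is
monotonically related to the accumulated action (rank correlation > 0.9 at
the fast preset).

## Experiments

**Bistability window.** A parameter set is called bistable when both
protein half-plane basins carry stationary mass above 0.01. The boundary
values of the feedback strength `K` are found by a bracketed secant search
on the log-occupancy (smooth and monotone in `K`), with the basin split
frozen at the base-`K` saddle so the definition stays fixed across the
search (the deterministic window closes before the stochastic one at large
`K`). Default resolution +-5 in `K`. At the fast preset the recovered
boundaries are ~2751 and ~3227.

**Switching-time sweeps.** For each `(kappa, K)` with locked ratios, the
mean switching time between basins is estimated by replicated SSA
(tau-leaping by default; censored replicates are flagged and excluded) or
by the first-passage linear solve. The on-to-off curve at `K = 3000` falls
as `1/d_g` in the slow tail, attains its minimum at `kappa ~ 0.03`, and
rises to a plateau in the fast tail.

**Sorting experiment.** A cohort (default 50,000 cells; scaled-down
cohorts of 2,000-4,000 are used in the test suite) is drawn jointly over
(gene state, mRNA, protein) from the stationary CME solution, gated at a
protein threshold (default 400) into P+/P- groups, and each group is
evolved by independent SSA; the P+ fraction of each group is recorded on a
geometric time grid spanning 0.1-30 reference times. The cohort-weighted
average of the two groups is a martingale at the stationary P+ mass
(checked within binomial error). Real flow-cytometry noise (fluorescence
calibration, gating spill-over), cell division and extrinsic noise are not
modelled, so passing tests certify the sorting logic and the switching
dynamics, not instrument-level realism.

**Regime classification.** The reference time `T` is the deterministic
no-switching relaxation from the source metastable point to the threshold.
The classifier first tests memory strength: if the sorted P+ group closes
at least 10% of its gap to equilibrium within `5 T`, the verdict is
*intermediate* (at the valley the half-recovery time is roughly an order of
magnitude above `T`, so 25-35% of the gap closes on this window, against
~1-3% in the slow and fast regimes -- the two-orders-of-magnitude
separation is what the thresholds cut through). Otherwise kappa is
perturbed upward (locked ratios, default multiplier 10) and the verdict is
*slow* when the recovery progress at the window end gains more than 0.1
(recovery speeds up markedly), *fast* when it is unchanged or slower. The
progress gain is used rather than the change in half-recovery time because
the latter must be extrapolated when recovery is barely under way and is
noisy at realistic cohort sizes; both statistics are reported. The
classifier returns the correct label on the three canonical parameter sets
(`kappa = 0.001`, `0.03`, `50`) across seeds at cohort 2,000.

## Problem sizes used in the shipped checks

Test-suite and acceptance-script runs use: reference-scale CME lattices of
~1.2-1.7e6 states (full stationary solves) and ~1e5 states (off-basin
first-passage systems); 10-24 SSA replicates per switching-time point;
6-8 reactive segments per path ensemble; cohorts of 2,000-4,000 cells;
kappa sweeps over {1e-5, 1e-3, 1e-2} for the mixture comparison and eight
points spanning 1e-3..10 for the switching-time valley; 48-100 gMAM images.

## Known limitations

* The censoring solver's single-precision factors cap stationary residuals
  near 1e-7 relative; quantities consumed downstream (occupancies, KL
  divergences, first-passage times) are orders of magnitude less sensitive.
* Tau-leaping with the adiabatic gene branch is an approximation; it is
  excluded from exactness tests and validated against the direct method on
  the test fixture.
* The quasi-potential grid assembly interpolates between fan curves; its
  accuracy is limited by fan coverage (failed fan targets are counted and
  masked, typically corners of the box where no uphill momentum exists).
* `mean_first_passage` on unreachable targets reports singularity rather
  than attempting regularisation.
* The Hill exponent is exposed and propagated everywhere, but the shipped
  quantitative checks all run at `h = 1`.
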
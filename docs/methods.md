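# Methods

## Model

Observed data are peptide-level deuterium uptake values $y_i(t_m)$ for
peptides $i = 1..N$ at exposure times $t_1..t_M$, normalised by a fully
deuterated control so that one unit is complete exchange of the peptide.
Internally uptake is handled on this fractional scale and converted to
exchangeable-amide units (multiplied by the amide count $l_i$) only at the
likelihood boundary.

Each residue carries a latent uptake curve

$$\mu_r(t) = (1-\pi_r)\,(1 - e^{-b_r t^{p_r}}) + \pi_r\,(1 - e^{-d_r t}),$$

a convex mixture of a Weibull CDF (stretched-exponential kinetics) and an
exponential CDF (the single-rate, protection-factor-compatible model), so
$\mu_r$ is bounded in $[0,1]$, monotone, and $0$ at $t=0$.  The mixture
weight is learnt, letting the data choose between the two kinetic families
per segment.  The printed form of this equation is ambiguous in its
parenthesisation in some renderings; this package implements the convex
mixture, which is the only reading that keeps uptake in $[0,1]$.

A peptide's expected uptake is $\sum_{r \in \mathcal{R}_i} \mu_r(t)$ over
its exchangeable set $\mathcal{R}_i = \{r : \text{start}_i + 2 \le r <
\text{end}_i,\ r \ne \text{Pro}\}$: the first two residues of a peptide
back-exchange too fast to retain label and prolines have no amide
hydrogen.  The end-exclusive bound is the default because that is how the
set is usually written; an inclusive-end switch exists in
`exchangeable_residues` since lab conventions differ.  Peptides with an
empty exchangeable set are non-informative and dropped with a warning.

Observations get a Laplace likelihood with location $\sum \mu_r$ and scale
$l_i\sigma^2$.  Two deliberate consequences: the heavy tails make the fit
robust to outlier peptides, and the length factor lets long peptides be
more variable (the length-bias correction).  The scale is taken literally
as $l_i \sigma^2$ (not $l_i \sigma$); this only re-parameterises
$\sigma$, but it is worth knowing when comparing $\sigma$ values to
per-amide error magnitudes: the mean absolute per-amide residual equals
$\sigma^2$.

Kinetic parameters are piecewise constant along the sequence.  Change
points follow a Poisson process on $(1, R)$ with prior mean count
$\lambda$ (so $K \sim \text{Pois}(\lambda)$, positions ordered-uniform
with density $K!/(R-1)^K$, and $\lambda$ should scale with protein
length).  Segment parameters have independent priors, with a hierarchical
layer on the two rate parameters:

| parameter | prior | default | units / note |
|---|---|---|---|
| $\pi_k, p_k$ | Beta$(1,1)$ | flat | mixture weight; stretch exponent |
| $b_k$ | Gamma$(1, b_{rate})$ | — | Weibull rate, $1/\text{s}^{p}$ |
| $d_k$ | Gamma$(1, d_{rate})$ | — | exponential rate, $1/\text{s}$ |
| $b_{rate}, d_{rate}$ | Gamma$(1,1)$ | shared across segments | borrows strength |
| $\log\sigma$ | Normal$(-3, 1)$ | $\sigma \approx 0.05$ | global noise scale |
| $\lambda$ | fixed | $\max(1, R/25)$ | prior expected change points |
| $\rho$ | fixed | $0.5$ | birth-proposal probability |

These numerical defaults are this package's choices (weakly informative;
the hierarchy lets the rate scale adapt to the data) — no canonical
published values exist for them.

## Sampler

Inference is reversible-jump MCMC.  One sweep = a dimension move (birth
with probability $\rho$, else death), a change-point position move, a
random-walk Metropolis–Hastings update of every segment parameter, a
$\log\sigma$ update, and exact conjugate Gibbs updates of the shared Gamma
rates.

*Birth*: choose one of the $K+1$ intervals uniformly, place the new point
uniformly in it, draw both daughter-segment parameter sets from the prior.
*Death*: delete one of the $K$ points uniformly and draw the merged
segment's parameters from the prior.  Because parameter proposals are
prior draws, the prior densities cancel in the Metropolis–Hastings–Green
ratio and the birth acceptance collapses to
$\min\{1, (L'/L)\,\lambda(1-\rho)\Delta\tau / (\rho (R-1))\}$ with the
death ratio its exact reciprocal; a unit test asserts the collapsed form
against the fully assembled kernel ratio.  With the likelihood held
constant the stationary distribution of $K$ is exactly
$\text{Pois}(\lambda)$, which the acceptance suite verifies by
goodness-of-fit on 20,000 post-burn-in draws (on decorrelated subsamples —
$\chi^2$ and KS assume independence, and the integrated autocorrelation
time of $K$ is a few stored draws).

The position move is a symmetric Gaussian random walk on a single change
point, rejected if it breaks the ordering; the ordered-uniform prior is
flat there, so it accepts on the likelihood ratio alone.  It leaves the
target invariant and is not required for correctness, but matters in
practice: dimension moves with prior-drawn parameters almost never accept
under a concentrated likelihood, so without a position move a mis-placed
change point from initialisation can persist for the whole run.

Fixed-dimension updates operate on transformed scales (logit for the
$(0,1)$ parameters, log for rates and $\sigma$) with the log-Jacobian in
the target.  Proposal scales adapt by Robbins–Monro toward 0.30 acceptance
during burn-in only, so detailed balance holds for every retained sample.
Runs are bit-reproducible given the config seed.

### Initialisation

Random starts waste most of the chain, so the sampler starts from a
data-driven state: (1) generalised inversion of the peptide/residue
coupling per timepoint, regularised with a small total-variation penalty
and box constraints (the fused-lasso solver; the plain minimum-norm
pseudo-inverse fills the coupling matrix's null space with arbitrary
clipped values on under-determined stretches, which no later smoothing can
repair); (2) a least-squares fit of the kinetic mixture per residue on transformed
parameters, warm-started from the previous residue (the parameterisation
is partially redundant, and continuation keeps equal curves at equal
parameters); (3) order-0 L1 trend filtering (1-D total variation, exact
Condat algorithm, noise-adaptive penalty) of the four parameter tracks —
order 0 because the prior
is piecewise constant, so the penalty-to-infinity limit is a single
segment, not a line; (4) segments read off the smoothed tracks (jump
tolerance 0.2 on transformed scales, at most $\max(10, 3\lambda)$ change
points), with one parameter set refitted per segment; (5) $\sigma$ from
the mean absolute residual.  The TRF least-squares solver is used rather
than the Levenberg–Marquardt wrapper because the latter proved
non-reproducible call-to-call at machine precision in testing, and
initialisation must be deterministic for the bit-reproducibility contract.

## Post-inference statistics

Posterior-mean peptide predictions $\hat\mu_i$ give reconstruction errors
$\text{RE}_i = y_i - \hat\mu_i$.  Per residue, the length-normalised
errors of the covering peptides are combined as a mean (SignedARE), a mean
of absolute values (ARE, a local fit-quality metric), and an unaveraged
sum (TRE): summing rather than averaging means several overlapping
peptides deviating in the same direction amplify the evidence while
conflicting directions cancel — the mechanism that exploits redundancy.
Probabilities of effect compare the observed statistic against Monte-Carlo
null draws built from the posterior $\sigma$ samples (for TRE, a sum of
$n_r$ Laplace$(0, \sigma^{(m)})$ variates; one draw per posterior sample
by default, configurable inner replicates).  Note the null uses scale
$\sigma$ while the fitted per-amide residual scale is $\sigma^2$; for
$\sigma < 1$ the null is therefore wide and the probabilities
conservative, which is consistent with the conservative observed-FDR
calibration the acceptance suite measures.  Discoveries are controlled by
the expected FDR, $\text{EFDR}(t) = \sum (1-p_i)\mathbb{1}[p_i \ge t] /
\sum \mathbb{1}[p_i \ge t]$, thresholded at the smallest observed
probability keeping EFDR below the level at it and every larger observed
probability.

Differential analysis fits the model on one state and reconstructs the
reference (APO) state's peptides from it; the reported difference is
predicted-minus-observed, so protection in the fitted state is negative.
Per-timepoint and time-averaged results are both reported; for the
averaged rows the null is likewise a mean over timepoints of independent
Laplace sums.  Whether $\sigma$ should be shared across states is open;
each state's own posterior $\sigma$ draws feed its null here.

## Baselines and benchmark

The four comparators all solve, per timepoint, the linear coupling
$U_{pep} = C\,U_{res}$ with $C$ the binary peptides × residues
exchangeable-amide matrix: minimum-norm pseudo-inverse (unconstrained —
deliberately, since its $[0,1]$ violations are part of what is being
measured), box-constrained least squares (`scipy.optimize.lsq_linear`,
BVLS), fused lasso ($\tfrac12\|U_{pep} - C u\|_2^2 + \lambda\,TV(u)$ with
box constraints, solved by FISTA whose proximal step is exact 1-D TV
denoising followed by clipping — exact for an interval constraint; the
squared-loss form follows the comparator being emulated, which only
rescales $\lambda$, default grid includes $\lambda = 5$), and
length-normalised residue averaging.  Solver tolerance is $10^{-8}$ on
the objective.

The leave-digests-out benchmark trains any method on one digest and
predicts the held-out digests' peptide uptakes by summing inferred residue
values.  Held-out tables are first rescaled per timepoint by the ratio of
medians over the peptides common to both digests (held-out is scaled to
the training digest's scale; the direction is configurable since either
choice is defensible).  Accuracy is the median absolute deviation between
predicted and observed fraction-of-FD uptake, with a peptide-resampling
bootstrap (peptides are the exchangeable observational unit; default
1,000 resamples).  Physical plausibility is reported as bounds and
monotonicity violation percentages with tolerance $10^{-9}$.

## Conformational signature analysis

For many states against one reference, the per-state time-averaged TRE
profiles form a states × residues matrix, column-centred but not
unit-variance scaled (residues share units; scaling would inflate
low-signal residues).  Unsupervised analysis is PCA (SVD; per-component
sign fixed by making the largest-magnitude loading positive).  Supervised
analysis is orthogonal PLS-DA with one predictive and one orthogonal
component by default; categorical annotations are dummy-coded (two classes
as ±1), continuous ones standardised, and states with missing annotations
are excluded from fitting but projected afterwards.  Uncertainty
propagates by re-running the projection on per-posterior-sample TRE
matrices (50 replicates by default) and rigidly aligning each replicate's
scores to the reference configuration by the Procrustes transform without
scaling (rotation/reflection only — the projections share units); a
residue whose loading quantile interval (2.5/50/97.5%) crosses zero has no
confidently non-zero contribution.

## Synthetic data

The generator draws ground truths from the model's own prior
(`simulate_truth`), random peptide maps with controllable redundancy
(lengths 5–20, optional top-up peptides until every coverable residue
reaches a requested redundancy; different seeds emulate different
protease digests), and Laplace observations from the forward model.
Default scales mirror a small benchmark protein: ~60–100 residues, 50–70
peptides, exposure times {15, 150, 1500, 15000} s, three replicates.

For studies that need a *plausible* truth rather than an arbitrary prior
draw, `realistic_hyperparameters` centres the rate hyperpriors on the
reciprocal geometric-mean exposure time (Gamma(25, 25/ḡ) on the shared
rates): under the generic Gamma(1,1) hyperpriors most drawn rates exceed
1/s and simulated proteins are fully exchanged before the first timepoint,
which no experimentalist would accept as a realistic benchmark substrate.
The simulation protocols use this variant; the fit always uses the generic
defaults, so truth and fitting priors are not matched.

Two protocol-level generators are layered on top (`hdxcp.experiments`):

* **Protection protocol** — multiply the uptake of every peptide covering
  one random residue by a factor (0.80 strong / 0.90 / 0.95 weak), then
  run the differential analysis and score localisation (distance from the
  perturbed residue to the highest-probability residue, ties broken by
  |TRE|) and observed FDR (residues sharing a perturbed peptide count as
  true).  The model is fitted on the *unperturbed* table and the perturbed
  table supplies the reference observations: multiplying whole peptides by
  a constant produces a table that no residue-level state can reproduce,
  and fitting the model directly on such a table lets the robust Laplace
  likelihood absorb the perturbed minority of peptides as outliers
  (verified in testing: the fit leaves ≈ the full effect as residual on
  perturbed peptides and inflates $\sigma$ instead of moving the
  curves).  A physically protected state is residue-consistent, so the
  asymmetric design is the faithful simulation of a real differential
  experiment while keeping the simple peptide-multiplication perturbation.
* **Synthetic triple digest** — three random digests of one protein from a
  common truth (a few peptides shared across digests anchor the scale
  correction), at observation noise σ = 0.15, i.e. ≈ 2% mean absolute
  error per amide, a typical HDX-MS precision.  This stands in for a
  wet-lab triple-protease benchmark; what passing it shows is relative
  method accuracy under the model's own generative assumptions, not
  performance on real chromatography/spectral artefacts, real digestion
  bias, or EX1 behaviour.

## Problem sizes and limitations

The test suite and the acceptance script run everything at desk scale:
proteins of 40–60 residues, 35–50 peptides, chains of 2,500–8,000
iterations (burn-in 1,000–3,000, thinning 5), 3–10 simulation seeds.
These are the package's validation defaults; production analyses should
use the sampler defaults (30,000 iterations, 10,000 burn-in, thinning 10)
and ideally multiple chains.

Known limitations: no intrinsic-exchange chemistry or protection-factor
back-calculation; no EX1 bimodal modelling; dimension moves use prior
parameter draws, so trans-dimensional mixing leans on the initialisation
and the position move (posterior $K$ can stay above the truth when extra
change points cost little likelihood — uptake estimates are unaffected,
but $K$ itself should be interpreted cautiously); the $\sigma$ resolution
metric saturates at the model-misfit floor, so it tracks injected noise
only above that floor (the resolution experiment therefore adds noise on
top of a base dataset); and on residue stretches with zero redundancy the
posterior reverts to the prior — statistics there are reported as missing,
never as zero.
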
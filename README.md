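# hdxcp — residue-level HDX-MS by Bayesian change-point inference

Bottom-up hydrogen–deuterium exchange mass spectrometry (HDX-MS) reports
deuterium uptake on proteolytic **peptides**, not residues.  Overlapping
peptides carry residue-level information, but combining them is hard: the
system is under-determined, longer peptides are noisier than short ones,
and naive matrix inversion produces uptake values outside [0, 1] and
non-monotone kinetics.  `hdxcp` is for HDX-MS practitioners and method
developers who want residue-resolved uptake *with uncertainty*: it infers a
latent per-residue exchange process from peptide-level uptake tables and
reports posterior distributions, per-residue effect sizes, probabilities,
and expected-false-discovery-rate (EFDR) controlled differential calls.

## The model

Each residue *r* follows a mixture of stretched-exponential (Weibull) and
single-exponential uptake kinetics,

```
mu_r(t) = (1 - pi_r)(1 - exp(-b_r t^p_r)) + pi_r (1 - exp(-d_r t)),
```

a convex combination of two CDFs, hence bounded in [0, 1] and monotone in
exposure time.  A peptide's expected uptake is the sum of `mu_r` over its
exchangeable amides (the peptide's first two residues and prolines are
excluded), and observations follow a Laplace error model whose scale grows
with peptide length `l_i` (scale `l_i * sigma^2`), which both robustifies
the fit and removes length bias.  Kinetic parameters are piecewise constant
along the sequence under a Poisson-process change-point prior: the number
of change points *K* ~ Pois(λ), their positions uniform-ordered on (1, R).
The posterior over (K, τ, θ, σ) is sampled with reversible-jump MCMC
(birth/death moves across model dimensions plus random-walk
Metropolis–Hastings within a dimension), so model complexity is inferred
from the data.  Because every posterior draw is a valid kinetic curve, the
posterior-mean residue uptake is *guaranteed* to lie in [0, 1] and to be
monotone in time — the two physical constraints that matrix-inversion
approaches violate.

Also included, behind a common interface: four comparator methods
(pseudo-inverse, box-constrained least squares, fused-lasso smoothing, and
length-weighted residue averaging), a leave-digests-out benchmark,
differential statistics (TRE effect sizes, probabilities, EFDR control),
conformational signature analysis (PCA / OPLS-DA with Procrustes-aligned
posterior uncertainty), and a synthetic-data generator that makes every
stage testable without any external files.

## Worked example

```python
import numpy as np
from hdxcp import (HDXChangePoint, simulate_peptide_map, simulate_truth,
                   simulate_uptake_data, apply_protection_effect)
from hdxcp.synthetic import realistic_hyperparameters, DEFAULT_TIMES
from hdxcp.model import residue_uptake_matrix, coupling_matrix

R = 60
truth = simulate_truth(R, realistic_hyperparameters(R), seed=11)
peptides = simulate_peptide_map(R, 50, seed=12, min_redundancy=3)
apo = simulate_uptake_data(truth, peptides, DEFAULT_TIMES,
                           replicates=3, sigma=0.005, seed=13)

est = HDXChangePoint(n_iter=5000, burn_in=2000, thin=5, random_state=14)
est.fit(apo)
print(f"sigma = {est.sigma_:.4f}, posterior mean K = {est.n_changepoints_:.1f}")
# sigma = 0.0289, posterior mean K = 10.1

covered = coupling_matrix(peptides, R).sum(axis=0) > 0
rmse = np.sqrt(np.mean((est.residue_uptake_
                        - residue_uptake_matrix(truth, R, est.times_))[covered] ** 2))
print(f"residue-uptake RMSE vs truth (covered residues) = {rmse:.4f}")
# residue-uptake RMSE vs truth (covered residues) = 0.0064
```

`sigma_` is the fitted global noise scale, a resolution metric for the
dataset: the mean absolute residual per exchangeable amide equals
`sigma_**2` (here ≈ 8e-4 of full deuteration).  `residue_uptake_` is the
posterior-mean residue × time uptake matrix, within 0.007 RMSE of the
generating truth on covered residues.  A differential comparison against a
perturbed state then gives per-residue effect sizes and calls:

```python
protected = apply_protection_effect(apo, residue=30, factor=0.8,
                                    new_state="bound")
res = est.differential(protected)
avg = res[res["time"] == "avg"]
print(avg[avg["efdr_call"]][["residue", "tre", "prob"]].round(3).head(8).to_string(index=False))
#  residue   tre  prob
#       19 0.070 0.700
#       20 0.070 0.690
#       21 0.139 0.960
#       22 0.208 0.998
#       23 0.277 1.000
#       24 0.345 1.000
#       25 0.414 1.000
#       26 0.483 1.000
```

Residues whose covering peptides lost 20% uptake come out with large
positive TRE (the fitted state exchanges more than the protected
reference) and probability 1; the TRE profile peaks at the perturbed
residue 30 and decays with the number of shared perturbed peptides on
either side.

The same workflows are available from the shell:

```bash
hdxcp simulate --n-residues 60 --protect-residue 30 --seed 1 --out sim/
hdxcp fit sim/apo.csv --seed 2 --out fit/
hdxcp differential fit/chain.json sim/perturbed.csv --seed 3 --out diff/
```

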
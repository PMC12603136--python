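"""Scikit-learn-style front end for the change-point HDX model."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import (
    FitData,
    Hyperparameters,
    PeptideTable,
    coupling_matrix,
)
from .sampler import (
    PosteriorSamples,
    SamplerConfig,
    posterior_mean_uptake,
    run_rjmcmc,
)
from . import stats as _stats

__all__ = ["HDXChangePoint"]


class HDXChangePoint(BaseEstimator):
    """Residue-level HDX inference by reversible-jump MCMC.

    Fits the Bayesian change-point model to a single-state peptide uptake
    table and exposes the posterior through fitted attributes.  The
    posterior-mean residue uptake is guaranteed to lie in [0, 1] and to be
    monotone in exposure time, because every posterior draw is.

    Parameters
    ----------
    lam : prior expected number of change points; None scales it with
        protein length as max(1, R / 25).
    rho : probability of proposing a birth move.
    n_iter, burn_in, thin : chain length controls.
    adapt : Robbins-Monro proposal-scale adaptation during burn-in.
    random_state : seed for full reproducibility.

    Attributes (after fit)
    ----------------------
    samples_ : PosteriorSamples (thinned chain).
    residue_uptake_ : (R, n_times) posterior-mean uptake.
    sigma_ : posterior-mean noise scale (global resolution metric).
    n_changepoints_ : posterior-mean K.
    """

    def __init__(
        self,
        lam: Optional[float] = None,
        rho: float = 0.5,
        n_iter: int = 30_000,
        burn_in: int = 10_000,
        thin: int = 10,
        adapt: bool = True,
        random_state: Optional[int] = None,
    ):
        self.lam = lam
        self.rho = rho
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.adapt = adapt
        self.random_state = random_state

    # -- core API ------------------------------------------------------------
    def fit(self, table: PeptideTable, y=None, state: Optional[str] = None):
        if state is not None:
            table = table.for_state(state)
        fd = FitData(table)
        hyper = Hyperparameters.default_for(
            fd.n_residues,
            **({"lam": self.lam} if self.lam is not None else {}),
            rho=self.rho,
        )
        config = SamplerConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            rho=self.rho, adapt=self.adapt, seed=self.random_state,
        )
        self.fit_data_ = fd
        self.hyper_ = hyper
        self.samples_ = run_rjmcmc(fd, hyper, config)
        self.n_residues_ = fd.n_residues
        self.times_ = fd.times
        self.residue_uptake_ = posterior_mean_uptake(self.samples_)
        self.sigma_draws_ = self.samples_.sigma_draws
        self.sigma_ = float(self.sigma_draws_.mean())
        self.n_changepoints_ = float(self.samples_.K_draws.mean())
        return self

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise RuntimeError("estimator is not fitted")

    def predict_residue_uptake(self, times=None) -> np.ndarray:
        """Posterior-mean residue uptake on the fitted (or a new) time grid."""
        self._check_fitted()
        if times is None:
            return self.residue_uptake_
        return _stats.mean_residue_uptake_at(self.samples_, times)

    def predict(self, table: PeptideTable, times=None) -> np.ndarray:
        """Posterior-mean peptide uptake (amide units) for the peptides of
        ``table``: row i is peptide i, column m timepoint m."""
        self._check_fitted()
        table = table.informative()
        times = self.times_ if times is None else np.asarray(times, float)
        mu = self.predict_residue_uptake(times)
        C = coupling_matrix(table.peptides, self.n_residues_)
        return C @ mu

    # -- analysis shortcuts ---------------------------------------------------
    def reconstruction_errors(self, table: Optional[PeptideTable] = None
                              ) -> pd.DataFrame:
        self._check_fitted()
        return _stats.reconstruction_errors(
            self.samples_, table if table is not None else self.fit_data_.table)

    def differential(self, reference: PeptideTable,
                     efdr_level: float = 0.05,
                     rng: Optional[np.random.Generator] = None
                     ) -> pd.DataFrame:
        """Differential analysis of the fitted state against a reference
        (APO) table; see :func:`hdxcp.stats.differential_tre`."""
        self._check_fitted()
        if rng is None:
            rng = np.random.default_rng(
                None if self.random_state is None else self.random_state + 1)
        return _stats.differential_tre(self.samples_, reference,
                                       rng=rng, efdr_level=efdr_level)

    def fit_predict(self, table: PeptideTable) -> np.ndarray:
        """Fit and return the posterior-mean residue uptake matrix
        (benchmark plug-in interface shared with the baselines)."""
        return self.fit(table).residue_uptake_
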
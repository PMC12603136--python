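"""Reversible-jump MCMC inference for the change-point HDX model.

The posterior over (K, tau, theta, sigma, hyper-rates) lives on a union of
spaces of different dimension, so the sampler alternates trans-dimensional
birth/death moves with fixed-dimension random-walk Metropolis-Hastings
sweeps and conjugate Gibbs updates of the shared Gamma rates.

Birth move: pick one of the K+1 inter-change-point intervals uniformly,
place a new change point uniformly inside it, and draw fresh parameter sets
for the two daughter segments from the prior.  Because proposals are prior
draws, their densities cancel against the prior ratio and the acceptance
ratio collapses to

    alpha_birth = (L'/L) * lam * (1 - rho) * (tau_j - tau_{j-1}) / (rho * (R - 1)),

with the death move its exact reciprocal (a unit test asserts the collapsed
form equals the fully assembled kernel ratio).  The death move deletes one
of the K existing change points uniformly and draws a single fresh
parameter set for the merged segment.

Random-walk updates are performed on transformed scales (logit for the
(0,1)-valued mixture weight and stretch exponent, log for rates and sigma)
with the log-Jacobian included in the target.  Proposal scales are adapted
toward 0.30 acceptance by Robbins-Monro during burn-in only, preserving
detailed balance afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from ._tv import tv1d_denoise
from .model import (
    ChainState,
    FitData,
    Hyperparameters,
    PeptideTable,
    residue_uptake_matrix,
    sample_theta_prior,
    segment_indices,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "initialize",
    "run_rjmcmc",
    "posterior_mean_uptake",
]

_LOGIT_PARAMS = (0, 1)  # theta columns on logit scale (pi, p)
_PARAM_NAMES = ("pi", "p", "b", "d")


@dataclass
class SamplerConfig:
    """Chain-length and proposal settings.

    Defaults (30k iterations, 10k burn-in, thin 10) suit a full analysis;
    shorter chains are adequate for small simulated proteins.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    rho: float = 0.5
    prop_scale: dict = field(default_factory=lambda: {
        "pi": 0.6, "p": 0.6, "b": 0.6, "d": 0.6, "sigma": 0.15, "tau": 2.0,
    })
    adapt: bool = True
    adapt_target: float = 0.30
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0,1)")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in chain states plus derived residue trajectories."""

    states: list
    residue_uptake_draws: np.ndarray   # (n_samples, R, n_times)
    times: np.ndarray
    n_residues: int
    acceptance: dict                   # move -> (accepted, proposed)
    config: SamplerConfig
    seed: Optional[int]

    @property
    def n_samples(self) -> int:
        return len(self.states)

    @property
    def K_draws(self) -> np.ndarray:
        return np.array([s.K for s in self.states], dtype=int)

    @property
    def sigma_draws(self) -> np.ndarray:
        return np.array([s.sigma for s in self.states], dtype=float)

    @property
    def tau_draws(self) -> np.ndarray:
        """All change-point locations pooled across stored samples."""
        if not self.states:
            return np.empty(0)
        return np.concatenate([s.tau for s in self.states] or [np.empty(0)])

    def acceptance_rates(self) -> dict:
        return {
            m: (a / p if p else float("nan"))
            for m, (a, p) in self.acceptance.items()
        }


def posterior_mean_uptake(samples: PosteriorSamples) -> np.ndarray:
    """Posterior-mean residue uptake matrix (R x n_times).

    An average of monotone [0,1] curves, so the estimate inherits both
    physical guarantees exactly.
    """
    if samples.n_samples == 0:
        raise ValueError("no stored samples")
    return samples.residue_uptake_draws.mean(axis=0)


# ---------------------------------------------------------------------------
# initialisation


def _transform(theta_row):
    z = np.empty(4)
    z[0] = math.log(theta_row[0] / (1.0 - theta_row[0]))
    z[1] = math.log(theta_row[1] / (1.0 - theta_row[1]))
    z[2] = math.log(theta_row[2])
    z[3] = math.log(theta_row[3])
    return z


def _untransform(z):
    row = np.empty(4)
    row[0] = 1.0 / (1.0 + math.exp(-z[0]))
    row[1] = 1.0 / (1.0 + math.exp(-z[1]))
    row[2] = math.exp(z[2])
    row[3] = math.exp(z[3])
    eps = 1e-9
    row[0] = min(max(row[0], eps), 1 - eps)
    row[1] = min(max(row[1], eps), 1 - eps)
    row[2] = max(row[2], 1e-12)
    row[3] = max(row[3], 1e-12)
    return row


def _fit_residue_curve(times: np.ndarray, u: np.ndarray, z0: np.ndarray,
                       prev: np.ndarray | None = None) -> np.ndarray:
    """Least-squares fit of the kinetic mixture to one residue's uptake
    track, on transformed parameters; returns transformed parameters.
    ``prev`` adds a warm start (preferred on near-ties)."""

    def resid(z):
        z = np.clip(z, -45, 45)
        pi = 1.0 / (1.0 + np.exp(-z[0]))
        p = 1.0 / (1.0 + np.exp(-z[1]))
        b = np.exp(z[2])
        d = np.exp(z[3])
        mu = (1 - pi) * (-np.expm1(-b * times ** p)) + pi * (-np.expm1(-d * times))
        return mu - u

    best, best_sse = z0, float(np.sum(resid(z0) ** 2))
    rate0 = math.exp(z0[2])
    starts = [] if prev is None else [np.asarray(prev, float)]
    starts.append(z0)
    for pi0, p0, f_b, f_d in ((0.5, 0.9, 10.0, 0.1), (0.5, 0.9, 0.1, 10.0),
                              (0.5, 0.5, 1.0, 1.0)):
        starts.append(_transform([pi0, p0, rate0 * f_b, rate0 * f_d]))
    for i, s in enumerate(starts):
        try:
            sol = least_squares(resid, s, method="trf", max_nfev=60)
        except Exception:
            continue
        if not (np.all(np.isfinite(sol.x)) and np.all(np.abs(sol.x) < 40)):
            continue
        sse = float(np.sum(resid(sol.x) ** 2))
        # prefer the warm start on near-ties (earlier starts win ties)
        if sse < best_sse * (1.0 - 1e-9) - 1e-14:
            best, best_sse = np.clip(sol.x, -40, 40), sse
    return best


def initialize(
    data: PeptideTable | FitData,
    hyper: Hyperparameters,
    tv_penalty: Optional[float] = None,
    jump_tol: float = 0.2,
    inversion_penalty: float = 0.5,
    max_changepoints: Optional[int] = None,
) -> ChainState:
    """Data-driven starting state.

    Pipeline: TV-regularised generalised inversion of the peptide/residue
    coupling per timepoint (box-constrained to [0, 1]); per-residue
    least-squares fit of the kinetic mixture; total-variation smoothing of
    the fitted parameter tracks (on transformed scales) into
    piecewise-constant segments; change points and segment parameters read
    off the smoothed tracks; sigma from the residual spread.
    """
    fd = data if isinstance(data, FitData) else FitData(data)
    R, times = fd.n_residues, fd.times
    M = times.size

    # replicate-averaged peptide x time uptake in amide units
    Y = np.zeros((len(fd.peptides), M))
    cnt = np.zeros((len(fd.peptides), M))
    np.add.at(Y, (fd.pep_idx, fd.time_idx), fd.y)
    np.add.at(cnt, (fd.pep_idx, fd.time_idx), 1.0)
    Y = Y / np.maximum(cnt, 1)

    # TV-regularised generalised inversion per timepoint: the plain
    # minimum-norm pseudo-inverse fills the coupling matrix's null space
    # with arbitrary values (clipped 0/1 oscillations on under-determined
    # stretches), which no after-the-fact smoothing can repair; the fused
    # penalty resolves the under-determination toward piecewise-constant
    # profiles, matching the prior, and the box constraints replace the
    # clip-to-[0,1] projection
    from .baselines import fused_lasso_uptake

    U = np.zeros((R, M))
    for m in range(M):
        obs = cnt[:, m] > 0
        U[:, m] = fused_lasso_uptake(fd.C[obs], Y[obs, m],
                                     lam=inversion_penalty)[:, 0]

    covered = fd.C.sum(axis=0) > 0
    rate0 = 1.0 / np.median(times)
    z_default = _transform([0.5, 0.9, rate0, rate0])
    Z = np.tile(z_default, (R, 1))
    prev = None
    for r in np.flatnonzero(covered):
        u = np.clip(U[r], 1e-4, 1.0 - 1e-3)
        # crude single-exponential rate per timepoint, combined geometrically
        rates = -np.log1p(-u) / times
        rate = float(np.exp(np.mean(np.log(rates))))
        z0 = _transform([0.5, 0.9, rate, rate])
        # warm-start at the previous residue's fit so that tracks stay
        # smooth wherever the data are (the parameterisation is partially
        # redundant; without continuation equal curves can get unequal z)
        Z[r] = _fit_residue_curve(times, u, z0, prev=prev)
        prev = Z[r]

    # smooth each transformed parameter track into piecewise-constant form;
    # the default penalty scales with the track's own jitter (robust MAD of
    # first differences) and with sqrt(R), so noisy tracks are smoothed
    # harder while clean real jumps survive
    Zs = np.empty_like(Z)
    for j in range(4):
        if tv_penalty is None:
            jitter = 1.4826 * float(np.median(np.abs(np.diff(Z[:, j])))) \
                / math.sqrt(2.0)
            lam_j = max(1.0, 2.0 * jitter * math.sqrt(R))
        else:
            lam_j = tv_penalty
        Zs[:, j] = tv1d_denoise(Z[:, j], lam_j)

    jumps = np.max(np.abs(np.diff(Zs, axis=0)), axis=1)
    cut = np.flatnonzero(jumps > jump_tol)           # jump between r+1 and r+2
    kmax = max_changepoints or max(10, int(3 * hyper.lam))
    if cut.size > kmax:
        cut = np.sort(cut[np.argsort(jumps[cut])[::-1][:kmax]])
    tau = cut + 1.5                                  # between residues, in (1, R)
    tau = tau[(tau > 1.0) & (tau < R)]

    seg = segment_indices(tau, R)
    theta = np.empty((tau.size + 1, 4))
    for k in range(tau.size + 1):
        rows = (seg == k) & covered
        if not rows.any():
            rows = seg == k
        # refit one parameter set on the segment-mean uptake curve (safer
        # than averaging transformed parameters across residues)
        u_seg = np.clip(U[rows].mean(axis=0), 1e-4, 1.0 - 1e-3)
        z_seg = _fit_residue_curve(times, u_seg, Zs[rows].mean(axis=0))
        theta[k] = _untransform(z_seg)

    state = ChainState(tau=tau, theta=theta, log_sigma=hyper.sigma_m,
                       d_rate=1.0, b_rate=1.0)
    P = fd.predicted(state)
    absres = float(np.sum(np.abs(fd.y - P[fd.pep_idx, fd.time_idx]) / fd.l_obs))
    s2 = max(absres / fd.n_obs, 1e-10)               # E|Laplace(l s^2)|/l = s^2
    state.log_sigma = float(np.clip(0.5 * math.log(s2), -8.0, 2.0))
    return state


# ---------------------------------------------------------------------------
# the chain


class _Chain:
    """Mutable sampler state with cached predictions."""

    def __init__(self, fd, hyper, config, n_residues, times, rng, state):
        self.fd = fd            # FitData or None for a prior-only run
        self.hyper = hyper
        self.cfg = config
        self.R = n_residues
        self.times = np.asarray(times, dtype=float)
        self.rng = rng
        self.state = state
        self.scales = dict(config.prop_scale)
        self.acc = {m: [0, 0] for m in
                    ("birth", "death", "tau", "pi", "p", "b", "d", "sigma")}
        self._refresh_cache()

    # -- likelihood plumbing -------------------------------------------------
    def _refresh_cache(self):
        self.seg = segment_indices(self.state.tau, self.R)
        self.mu = residue_uptake_matrix(self.state, self.R, self.times)
        if self.fd is not None:
            self.P = self.fd.C @ self.mu
            self.absres = self._absres(self.P)
            self.loglik = self.fd.log_likelihood_from_absres(
                self.absres, self.state.log_sigma)
            if not np.isfinite(self.loglik):
                raise FloatingPointError("non-finite log-likelihood during sampling")
        else:
            self.P = None
            self.absres = 0.0
            self.loglik = 0.0

    def _absres(self, P):
        fd = self.fd
        res = fd.y - P[fd.pep_idx, fd.time_idx]
        return float(np.sum(np.abs(res) / fd.l_obs))

    def _loglik_absres(self, absres, log_sigma):
        return self.fd.log_likelihood_from_absres(absres, log_sigma)

    # -- dimension moves -----------------------------------------------------
    def dim_move(self):
        st = self.state
        if self.rng.uniform() < self.cfg.rho:
            self._birth()
        else:
            self._death()

    def _log_mh_dim(self, new_state, birth, interval):
        """Collapsed acceptance ratio for birth (or its reciprocal)."""
        lam, rho, R = self.hyper.lam, self.cfg.rho, self.R
        base = math.log(lam * (1.0 - rho) * interval / (rho * (R - 1.0)))
        if self.fd is None:
            dll = 0.0
        else:
            mu_new = residue_uptake_matrix(new_state, self.R, self.times)
            P_new = self.fd.C @ mu_new
            absres_new = self._absres(P_new)
            dll = (self._loglik_absres(absres_new, new_state.log_sigma)
                   - self.loglik)
            self._pending = (mu_new, P_new, absres_new)
        return (dll + base) if birth else (dll - base)

    def _birth(self):
        st = self.state
        K = st.K
        self.acc["birth"][1] += 1
        j = int(self.rng.integers(K + 1))
        lo = st.tau[j - 1] if j > 0 else 1.0
        hi = st.tau[j] if j < K else float(self.R)
        t_new = self.rng.uniform(lo, hi)
        if t_new in st.tau:       # measure-zero collision guard
            return
        fresh = sample_theta_prior(self.hyper, st.d_rate, st.b_rate, self.rng, 2)
        tau_new = np.insert(st.tau, j, t_new)
        theta_new = np.vstack([st.theta[:j], fresh, st.theta[j + 1:]])
        new = ChainState(tau_new, theta_new, st.log_sigma, st.d_rate, st.b_rate)
        la = self._log_mh_dim(new, birth=True, interval=hi - lo)
        if math.log(self.rng.uniform()) < la:
            self.acc["birth"][0] += 1
            self._commit(new)

    def _death(self):
        st = self.state
        K = st.K
        self.acc["death"][1] += 1
        if K == 0:
            return
        j = int(self.rng.integers(K))
        lo = st.tau[j - 1] if j > 0 else 1.0
        hi = st.tau[j + 1] if j + 1 < K else float(self.R)
        fresh = sample_theta_prior(self.hyper, st.d_rate, st.b_rate, self.rng, 1)
        tau_new = np.delete(st.tau, j)
        theta_new = np.vstack([st.theta[:j], fresh, st.theta[j + 2:]])
        new = ChainState(tau_new, theta_new, st.log_sigma, st.d_rate, st.b_rate)
        la = self._log_mh_dim(new, birth=False, interval=hi - lo)
        if math.log(self.rng.uniform()) < la:
            self.acc["death"][0] += 1
            self._commit(new)

    def _commit(self, new_state):
        self.state = new_state
        if self.fd is not None:
            self.mu, self.P, self.absres = self._pending
            self.loglik = self._loglik_absres(self.absres, new_state.log_sigma)
            self._pending = None
        self.seg = segment_indices(new_state.tau, self.R)
        if self.fd is None:
            self.mu = residue_uptake_matrix(new_state, self.R, self.times)

    def tau_step(self, it):
        """Within-model random-walk update of one change-point location.

        The ordered-uniform prior density is constant while the ordering
        holds, so with a symmetric Gaussian proposal the acceptance ratio
        reduces to the likelihood ratio; proposals that break the ordering
        or leave (1, R) fall outside the prior support and are rejected.
        This move is not needed for correctness of the birth/death kernel
        but repositions mis-placed change points that dimension moves
        (whose parameter proposals are prior draws) would take a long time
        to fix.
        """
        st = self.state
        if st.K == 0:
            return
        self.acc["tau"][1] += 1
        j = int(self.rng.integers(st.K))
        prop = st.tau[j] + self.scales["tau"] * self.rng.normal()
        lo = st.tau[j - 1] if j > 0 else 1.0
        hi = st.tau[j + 1] if j + 1 < st.K else float(self.R)
        accepted = False
        if lo < prop < hi:
            tau_new = st.tau.copy()
            tau_new[j] = prop
            new = ChainState(tau_new, st.theta, st.log_sigma, st.d_rate,
                             st.b_rate)
            if self.fd is not None:
                mu_new = residue_uptake_matrix(new, self.R, self.times)
                P_new = self.fd.C @ mu_new
                absres_new = self._absres(P_new)
                dll = (self._loglik_absres(absres_new, st.log_sigma)
                       - self.loglik)
            else:
                dll = 0.0
            if math.log(self.rng.uniform()) < dll:
                accepted = True
                self.acc["tau"][0] += 1
                self.state = new
                self.seg = segment_indices(new.tau, self.R)
                if self.fd is not None:
                    self.mu, self.P, self.absres = mu_new, P_new, absres_new
                    self.loglik += dll
                else:
                    self.mu = residue_uptake_matrix(new, self.R, self.times)
        self._adapt("tau", accepted, it)

    # -- fixed-dimension moves ----------------------------------------------
    def _theta_logprior_term(self, col, value):
        """Prior log-density plus log-Jacobian of the sampling transform
        for a single parameter."""
        h, st = self.hyper, self.state
        if col == 0:
            return ((h.pi_shape1 - 1) * math.log(value)
                    + (h.pi_shape2 - 1) * math.log(1 - value)
                    + math.log(value) + math.log(1 - value))
        if col == 1:
            return ((h.p_shape1 - 1) * math.log(value)
                    + (h.p_shape2 - 1) * math.log(1 - value)
                    + math.log(value) + math.log(1 - value))
        if col == 2:
            return (h.b_shape - 1) * math.log(value) - st.b_rate * value \
                + math.log(value)
        return (h.d_shape - 1) * math.log(value) - st.d_rate * value \
            + math.log(value)

    def theta_sweep(self, it):
        for k in range(self.state.K + 1):
            rows = self.seg == k
            for col, name in enumerate(_PARAM_NAMES):
                self._theta_step(k, col, name, rows, it)

    def _theta_step(self, k, col, name, rows, it):
        st = self.state
        cur = st.theta[k, col]
        s = self.scales[name]
        if col in _LOGIT_PARAMS:
            z = math.log(cur / (1 - cur)) + s * self.rng.normal()
            prop = 1.0 / (1.0 + math.exp(-z))
            prop = min(max(prop, 1e-12), 1 - 1e-12)
        else:
            prop = cur * math.exp(s * self.rng.normal())
            prop = max(prop, 1e-300)
        self.acc[name][1] += 1
        dlp = (self._theta_logprior_term(col, prop)
               - self._theta_logprior_term(col, cur))
        if self.fd is not None:
            row_new = st.theta[k].copy()
            row_new[col] = prop
            mu_rows = self._row_uptake(row_new)
            dP = self.fd.C[:, rows] @ (mu_rows - self.mu[rows])
            P_new = self.P + dP
            absres_new = self._absres(P_new)
            dll = self._loglik_absres(absres_new, st.log_sigma) - self.loglik
        else:
            dll = 0.0
        accepted = math.log(self.rng.uniform()) < dll + dlp
        if accepted:
            self.acc[name][0] += 1
            st.theta[k, col] = prop
            if self.fd is not None:
                self.mu[rows] = mu_rows
                self.P = P_new
                self.absres = absres_new
                self.loglik += dll
        self._adapt(name, accepted, it)

    def _row_uptake(self, row):
        pi, p, b, d = row
        t = self.times
        return (1 - pi) * (-np.expm1(-b * t ** p)) + pi * (-np.expm1(-d * t))

    def sigma_step(self, it):
        st = self.state
        h = self.hyper
        s = self.scales["sigma"]
        prop = st.log_sigma + s * self.rng.normal()
        self.acc["sigma"][1] += 1
        dlp = (-0.5 * ((prop - h.sigma_m) / h.sigma_v) ** 2
               + 0.5 * ((st.log_sigma - h.sigma_m) / h.sigma_v) ** 2)
        if self.fd is not None:
            dll = (self._loglik_absres(self.absres, prop)
                   - self.loglik)
        else:
            dll = 0.0
        accepted = math.log(self.rng.uniform()) < dll + dlp
        if accepted:
            self.acc["sigma"][0] += 1
            st.log_sigma = prop
            self.loglik += dll
        self._adapt("sigma", accepted, it)
        if st.log_sigma > 20:
            raise FloatingPointError("sigma diverged during sampling")

    def gibbs_hyper_rates(self):
        """Exact conjugate updates of the shared Gamma rates."""
        st, h = self.state, self.hyper
        nseg = st.K + 1
        st.d_rate = float(self.rng.gamma(
            h.d_alpha + nseg * h.d_shape,
            1.0 / (h.d_beta + float(np.sum(st.theta[:, 3])))))
        st.b_rate = float(self.rng.gamma(
            h.b_alpha + nseg * h.b_shape,
            1.0 / (h.b_beta + float(np.sum(st.theta[:, 2])))))
        st.d_rate = max(st.d_rate, 1e-12)
        st.b_rate = max(st.b_rate, 1e-12)

    def _adapt(self, name, accepted, it):
        if not self.cfg.adapt or it >= self.cfg.burn_in:
            return
        step = 1.0 / (1.0 + it) ** 0.6
        self.scales[name] = float(np.clip(
            self.scales[name]
            * math.exp(step * ((1.0 if accepted else 0.0) - self.cfg.adapt_target)),
            1e-3, 20.0))

    def sweep(self, it):
        self.dim_move()
        self.tau_step(it)
        self.theta_sweep(it)
        self.sigma_step(it)
        self.gibbs_hyper_rates()


def _default_init_state(hyper, n_residues, rng):
    theta = sample_theta_prior(hyper, 1.0, 1.0, rng, 1)
    return ChainState(tau=np.empty(0), theta=theta,
                      log_sigma=hyper.sigma_m, d_rate=1.0, b_rate=1.0)


def run_rjmcmc(
    data: PeptideTable | FitData | None,
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
    n_residues: Optional[int] = None,
    times=None,
    init: ChainState | None = None,
) -> PosteriorSamples:
    """Run the reversible-jump sampler and return thinned posterior draws.

    With ``data=None`` the likelihood is constant (a prior-only run, used to
    validate the trans-dimensional kernel: the stationary law of K is then
    exactly Pois(lam)); ``n_residues`` and ``times`` must then be given.
    Runs are bit-reproducible for a fixed config seed.
    """
    config = config or SamplerConfig()
    if data is not None:
        fd = data if isinstance(data, FitData) else FitData(data)
        n_residues = fd.n_residues
        times = fd.times
    else:
        fd = None
        if n_residues is None or times is None:
            raise ValueError("prior-only runs need n_residues and times")
        times = np.asarray(times, dtype=float)
    hyper = hyper or Hyperparameters.default_for(n_residues)
    rng = np.random.default_rng(config.seed)

    if init is None:
        init = (initialize(fd, hyper) if fd is not None
                else _default_init_state(hyper, n_residues, rng))
    chain = _Chain(fd, hyper, config, n_residues, times, rng, init.copy())

    states, draws = [], []
    for it in range(config.n_iter):
        chain.sweep(it)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            states.append(chain.state.copy())
            draws.append(
                residue_uptake_matrix(chain.state, n_residues, times))
    return PosteriorSamples(
        states=states,
        residue_uptake_draws=np.array(draws),
        times=times,
        n_residues=n_residues,
        acceptance={m: tuple(v) for m, v in chain.acc.items()},
        config=config,
        seed=config.seed,
    )
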
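"""Domain types and the deterministic forward model for residue-level HDX.

The observable in bottom-up HDX-MS is deuterium uptake of peptic peptides.
We posit a latent per-residue exchange process: each residue r follows a
mixture of a stretched-exponential (Weibull-type) uptake curve and a single
exponential,

    mu_r(t) = (1 - pi_r) * (1 - exp(-b_r * t**p_r)) + pi_r * (1 - exp(-d_r * t)),

which is a convex combination of two CDFs and hence bounded in [0, 1] and
monotone in exposure time t.  A peptide's expected uptake is the sum of
mu_r over its exchangeable amides (the first two residues of a peptide and
prolines carry no observable amide deuterium).  Observed uptake is the sum
plus Laplace noise whose scale grows with peptide length, down-weighting
long peptides.

Kinetic parameters are piecewise constant along the sequence: a change-point
vector tau partitions residues 1..R into K+1 segments sharing one parameter
set each.  K is Poisson a priori and tau are order statistics of uniforms on
(1, R) (a Poisson-process construction), giving p(tau | K) = K!/(R-1)**K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

__all__ = [
    "KineticParams",
    "ChainState",
    "Peptide",
    "PeptideTable",
    "Hyperparameters",
    "exchangeable_residues",
    "residue_uptake",
    "segment_indices",
    "segment_lookup",
    "residue_uptake_matrix",
    "coupling_matrix",
    "predict_peptide_uptake",
    "log_likelihood",
    "log_prior",
    "FitData",
]

# column order used wherever segment parameters are stored as an array
THETA_COLS = ("pi", "p", "b", "d")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of one residue segment.

    pi : mixture weight of the single-exponential branch, in (0, 1)
    p  : Weibull stretch exponent, in (0, 1)
    b  : Weibull rate, > 0, units 1/time**p
    d  : exponential rate, > 0, units 1/time
    """

    pi: float
    p: float
    b: float
    d: float

    def __post_init__(self) -> None:
        for name in THETA_COLS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not (0.0 < self.pi < 1.0):
            raise ValueError(f"pi must lie strictly in (0,1), got {self.pi}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie strictly in (0,1), got {self.p}")
        if self.b <= 0 or self.d <= 0:
            raise ValueError("rates b and d must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi, self.p, self.b, self.d], dtype=float)


@dataclass
class ChainState:
    """One state of the change-point model.

    theta rows are (pi, p, b, d) per segment; row k applies to residues r
    with tau[k-1] <= r < tau[k] (tau_0 = 1, tau_{K+1} = R + eps).  sigma is
    the global noise scale; hyper_rates = (d_rate, b_rate) are the current
    Gamma-prior rate parameters shared across segments.
    """

    tau: np.ndarray          # shape (K,), strictly increasing, in (1, R)
    theta: np.ndarray        # shape (K+1, 4)
    log_sigma: float
    d_rate: float = 1.0
    b_rate: float = 1.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.theta.shape != (self.K + 1, 4):
            raise ValueError(
                f"theta must have shape (K+1, 4) = {(self.K + 1, 4)}, "
                f"got {self.theta.shape}"
            )
        if self.K > 1 and not np.all(np.diff(self.tau) > 0):
            raise ValueError("tau must be strictly increasing")

    @property
    def K(self) -> int:
        return int(self.tau.size)

    @property
    def sigma(self) -> float:
        return math.exp(self.log_sigma)

    def copy(self) -> "ChainState":
        return ChainState(
            tau=self.tau.copy(),
            theta=self.theta.copy(),
            log_sigma=self.log_sigma,
            d_rate=self.d_rate,
            b_rate=self.b_rate,
        )


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide in 1-based inclusive protein coordinates."""

    id: str
    sequence: str
    start: int
    end: int
    exch: tuple = field(default=None)  # exchangeable residue indices
    l: int = field(default=None)       # number of exchangeable amides

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peptide {self.id}: start ({self.start}) must be < end ({self.end})"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.id}: sequence length {len(self.sequence)} "
                f"does not match coordinates {self.start}-{self.end}"
            )
        if self.exch is None:
            object.__setattr__(
                self, "exch",
                tuple(sorted(exchangeable_residues(self.start, self.end, self.sequence))),
            )
        if self.l is None:
            object.__setattr__(self, "l", len(self.exch))

    @property
    def informative(self) -> bool:
        return self.l >= 1


def exchangeable_residues(
    start: int, end: int, sequence: str, inclusive_end: bool = False
) -> set:
    """Exchangeable backbone amides of a peptide.

    The peptide's first two residues are excluded (rapid back-exchange of
    the N-terminal amides) as are prolines (no amide hydrogen).  The default
    bound is end-exclusive (residues r with start+2 <= r < end); set
    ``inclusive_end`` to retain the C-terminal residue, a convention switch
    because usage differs between laboratories.
    """
    if start >= end:
        raise ValueError("start must be < end")
    if len(sequence) != end - start + 1:
        raise ValueError("sequence length must equal end - start + 1")
    stop = end + 1 if inclusive_end else end
    return {
        r for r in range(start + 2, stop)
        if sequence[r - start].upper() != "P"
    }


class PeptideTable:
    """Peptide-level uptake observations for one or more protein states.

    ``data`` is a tidy frame with columns (peptide, state, time, replicate,
    uptake); uptake is stored on the fraction-of-fully-deuterated scale
    (peptide uptake divided by the fully deuterated control), so one unit
    corresponds to complete exchange of the peptide.  The forward model
    converts to exchangeable-amide units at the likelihood boundary.
    """

    REQUIRED = ("peptide", "state", "time", "replicate", "uptake")

    def __init__(
        self,
        peptides: Sequence[Peptide],
        data: pd.DataFrame,
        n_residues: int | None = None,
    ):
        self.peptides = list(peptides)
        self._by_id = {p.id: p for p in self.peptides}
        if len(self._by_id) != len(self.peptides):
            raise ValueError("duplicate peptide ids")
        data = data.copy().reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing observation columns: {missing}")
        unknown = set(data["peptide"]) - set(self._by_id)
        if unknown:
            raise ValueError(f"observations reference unknown peptides: {sorted(unknown)[:5]}")
        if not np.isfinite(data["uptake"].to_numpy(dtype=float)).all():
            raise ValueError("uptake values must be finite")
        if (data["time"].to_numpy(dtype=float) <= 0).any():
            raise ValueError("exposure times must be strictly positive")
        dup = data.duplicated(subset=["peptide", "state", "time", "replicate"])
        if dup.any():
            raise ValueError(
                f"duplicate observations at rows {list(data.index[dup][:5])}"
            )
        self.data = data
        self.n_residues = int(n_residues or max(p.end for p in self.peptides))

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def states(self) -> list:
        return sorted(self.data["state"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self.data["time"].unique()), dtype=float)

    def peptide(self, pid: str) -> Peptide:
        return self._by_id[pid]

    def for_state(self, state: str) -> "PeptideTable":
        sub = self.data[self.data["state"] == state]
        if sub.empty:
            raise ValueError(f"no observations for state {state!r}")
        keep = [p for p in self.peptides if p.id in set(sub["peptide"])]
        return PeptideTable(keep, sub, n_residues=self.n_residues)

    def informative(self) -> "PeptideTable":
        """Drop peptides with no exchangeable amide (non-informative)."""
        keep = [p for p in self.peptides if p.informative]
        if len(keep) < len(self.peptides):
            ids = {p.id for p in keep}
            sub = self.data[self.data["peptide"].isin(ids)]
            return PeptideTable(keep, sub, n_residues=self.n_residues)
        return self

    def redundancy(self) -> np.ndarray:
        """Per-residue redundancy: number of peptides whose exchangeable
        amides cover the residue (index 0 is residue 1)."""
        n = np.zeros(self.n_residues, dtype=int)
        for p in self.peptides:
            for r in p.exch:
                n[r - 1] += 1
        return n


@dataclass(frozen=True)
class Hyperparameters:
    """Prior and hyperprior settings.

    lam is the prior expected number of change points; for longer proteins
    it should grow proportionally with sequence length.  d and b have Gamma
    priors whose rate parameters carry Gamma hyperpriors (borrowing strength
    across segments); pi and p have Beta priors; log sigma is Gaussian.
    rho is the probability of proposing a birth (dimension-increasing) move.
    """

    lam: float = 2.0
    d_shape: float = 1.0
    b_shape: float = 1.0
    pi_shape1: float = 1.0
    pi_shape2: float = 1.0
    p_shape1: float = 1.0
    p_shape2: float = 1.0
    sigma_m: float = -3.0
    sigma_v: float = 1.0
    d_alpha: float = 1.0
    d_beta: float = 1.0
    b_alpha: float = 1.0
    b_beta: float = 1.0
    rho: float = 0.5

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if name == "sigma_m":
                continue
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0,1)")

    @classmethod
    def default_for(cls, n_residues: int, **overrides) -> "Hyperparameters":
        """Defaults scaled to protein length: lam = max(1, R/25)."""
        overrides.setdefault("lam", max(1.0, n_residues / 25.0))
        return cls(**overrides)


# ---------------------------------------------------------------------------
# forward model


def residue_uptake(params, t):
    """Fractional deuterium uptake of one residue at exposure time(s) t.

    Convex mixture of a Weibull CDF (stretched exponential) and an
    exponential CDF; 0 at t = 0, monotone, asymptoting to 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("exposure time must be non-negative")
    if isinstance(params, KineticParams):
        pi, p, b, d = params.pi, params.p, params.b, params.d
    else:
        pi, p, b, d = params
    return (1.0 - pi) * (-np.expm1(-b * t ** p)) + pi * (-np.expm1(-d * t))


def segment_indices(tau: np.ndarray, n_residues: int) -> np.ndarray:
    """0-based segment index of each residue 1..R under change points tau."""
    r = np.arange(1, n_residues + 1, dtype=float)
    return np.searchsorted(np.asarray(tau, dtype=float), r, side="right")


def segment_lookup(state: ChainState, r: int) -> KineticParams:
    """Kinetic parameters governing residue r (tau_{k-1} <= r < tau_k)."""
    k = int(np.searchsorted(state.tau, float(r), side="right"))
    return KineticParams(*state.theta[k])


def residue_uptake_matrix(state: ChainState, n_residues: int, times) -> np.ndarray:
    """Latent uptake for all residues: shape (R, n_times)."""
    times = np.asarray(times, dtype=float)
    seg = segment_indices(state.tau, n_residues)
    pi, p, b, d = (state.theta[:, j][:, None] for j in range(4))
    t = times[None, :]
    per_seg = (1.0 - pi) * (-np.expm1(-b * t ** p)) + pi * (-np.expm1(-d * t))
    return per_seg[seg]


def coupling_matrix(peptides: Sequence[Peptide], n_residues: int) -> np.ndarray:
    """Binary peptides x residues matrix; entry (i, j) is 1 iff residue j+1
    is an exchangeable amide of peptide i.  Row sums equal l_i."""
    C = np.zeros((len(peptides), n_residues), dtype=float)
    for i, pep in enumerate(peptides):
        for r in pep.exch:
            C[i, r - 1] = 1.0
    return C


def predict_peptide_uptake(state: ChainState, peptide: Peptide, times) -> np.ndarray:
    """Expected peptide uptake in exchangeable-amide units: sum of the
    residue curves over the peptide's exchangeable set.  Bounded in [0, l]."""
    if not peptide.informative:
        raise ValueError(f"peptide {peptide.id} has no exchangeable amides")
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for r in peptide.exch:
        out = out + residue_uptake(segment_lookup(state, r), times)
    return out


# ---------------------------------------------------------------------------
# likelihood and prior


class FitData:
    """Flat observation arrays extracted from a PeptideTable, for fast
    repeated likelihood evaluation.  Uptake is converted to amide units
    (fraction-of-FD times exchangeable-amide count)."""

    def __init__(self, table: PeptideTable, n_residues: int | None = None):
        table = table.informative()
        if len(table.data) == 0:
            raise ValueError("no observations after filtering")
        if len(table.states) > 1:
            raise ValueError(
                f"FitData expects a single state; got {table.states}; "
                "use PeptideTable.for_state first"
            )
        self.table = table
        self.n_residues = int(n_residues or table.n_residues)
        self.peptides = table.peptides
        self.times = table.times
        self.C = coupling_matrix(self.peptides, self.n_residues)
        self.l = self.C.sum(axis=1)
        pid_index = {p.id: i for i, p in enumerate(self.peptides)}
        t_index = {t: i for i, t in enumerate(self.times)}
        df = table.data
        self.pep_idx = df["peptide"].map(pid_index).to_numpy(dtype=int)
        self.time_idx = df["time"].map(t_index).to_numpy(dtype=int)
        frac = df["uptake"].to_numpy(dtype=float)
        self.y = frac * self.l[self.pep_idx]  # amide units
        self.l_obs = self.l[self.pep_idx]
        self.n_obs = self.y.size
        self._log_l_sum = float(np.sum(np.log(self.l_obs)))

    def predicted(self, state: ChainState) -> np.ndarray:
        """Peptide x time expected uptake matrix (amide units)."""
        mu = residue_uptake_matrix(state, self.n_residues, self.times)
        return self.C @ mu

    def log_likelihood_from_pred(self, P: np.ndarray, log_sigma: float) -> float:
        res = self.y - P[self.pep_idx, self.time_idx]
        return self.log_likelihood_from_absres(
            float(np.sum(np.abs(res) / self.l_obs)), log_sigma
        )

    def log_likelihood_from_absres(self, absres_over_l: float, log_sigma: float) -> float:
        # Laplace(y; mu, scale = l * sigma^2) summed over observations
        s2 = math.exp(2.0 * log_sigma)
        return (
            -absres_over_l / s2
            - self.n_obs * (math.log(2.0 * s2))
            - self._log_l_sum
        )


def log_likelihood(state: ChainState, data: PeptideTable | FitData) -> float:
    """Laplace log-likelihood of the observations under a chain state.

    Each observation contributes log Laplace(y_i; sum_{R_i} mu_r, l_i sigma^2);
    the length factor lets longer peptides be more variable.
    """
    fd = data if isinstance(data, FitData) else FitData(data)
    ll = fd.log_likelihood_from_pred(fd.predicted(state), state.log_sigma)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood: invalid state")
    return ll


def _gamma_lpdf(x, shape, rate):
    if x <= 0:
        return -np.inf
    return shape * math.log(rate) - gammaln(shape) + (shape - 1.0) * math.log(x) - rate * x


def _beta_lpdf(x, a, b):
    if not (0.0 < x < 1.0):
        return -np.inf
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x) - betaln(a, b)


def _norm_lpdf(x, m, sd):
    z = (x - m) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def log_theta_prior(row, hyper: Hyperparameters, d_rate: float, b_rate: float) -> float:
    """Log prior density of one segment's (pi, p, b, d)."""
    pi, p, b, d = row
    return (
        _beta_lpdf(pi, hyper.pi_shape1, hyper.pi_shape2)
        + _beta_lpdf(p, hyper.p_shape1, hyper.p_shape2)
        + _gamma_lpdf(b, hyper.b_shape, b_rate)
        + _gamma_lpdf(d, hyper.d_shape, d_rate)
    )


def log_prior(state: ChainState, hyper: Hyperparameters, n_residues: int) -> float:
    """Joint log prior of (K, tau, theta, sigma, hyper-rates).

    Poisson on K, ordered-uniform density K!/(R-1)^K on tau, independent
    segment priors on theta, Gaussian on log sigma and Gamma hyperpriors on
    the shared rates.  Out-of-support states return -inf (auto-reject).
    """
    K = state.K
    R = n_residues
    if K > 0 and (state.tau[0] <= 1.0 or state.tau[-1] >= R or
                  np.any(np.diff(state.tau) <= 0)):
        return -np.inf
    lp = -hyper.lam + K * math.log(hyper.lam) - gammaln(K + 1)  # Pois(K; lam)
    lp += gammaln(K + 1) - K * math.log(R - 1.0)                # K!/(R-1)^K
    for row in state.theta:
        lp += log_theta_prior(row, hyper, state.d_rate, state.b_rate)
    lp += _norm_lpdf(state.log_sigma, hyper.sigma_m, hyper.sigma_v)
    lp += _gamma_lpdf(state.d_rate, hyper.d_alpha, hyper.d_beta)
    lp += _gamma_lpdf(state.b_rate, hyper.b_alpha, hyper.b_beta)
    return float(lp)


def sample_theta_prior(hyper: Hyperparameters, d_rate: float, b_rate: float,
                       rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw segment parameter rows (pi, p, b, d) from the prior."""
    out = np.empty((size, 4), dtype=float)
    out[:, 0] = rng.beta(hyper.pi_shape1, hyper.pi_shape2, size)
    out[:, 1] = rng.beta(hyper.p_shape1, hyper.p_shape2, size)
    out[:, 2] = rng.gamma(hyper.b_shape, 1.0 / b_rate, size)
    out[:, 3] = rng.gamma(hyper.d_shape, 1.0 / d_rate, size)
    # keep strictly inside the open supports
    eps = 1e-12
    out[:, :2] = np.clip(out[:, :2], eps, 1.0 - eps)
    out[:, 2:] = np.maximum(out[:, 2:], eps)
    return out
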
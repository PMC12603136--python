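"""Comparator methods that map peptide-level uptake to residue-level uptake.

All four operate per timepoint on the linear coupling U_peptide = C U_residue,
where C is the binary peptides x residues matrix of exchangeable amides and
peptide uptake is in exchangeable-amide units (so residue values are
fractions).  None of them uses the temporal structure, so their residue
trajectories carry no monotonicity guarantee; the plain generalised inverse
is additionally unconstrained and can produce values outside [0, 1].

* pseudo-inverse (P-Inv): minimum-norm solution C^+ U_pep;
* constrained least squares (LeastSq): box constraints [0, 1];
* fused lasso (the PyHDX-style estimator): box constraints plus a total
  variation penalty coupling neighbouring residues;
* residue averaging (RFU-WA): mean of length-normalized uptakes of the
  covering peptides.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator

from ._tv import tv1d_denoise
from .model import PeptideTable, coupling_matrix

__all__ = [
    "table_to_matrices",
    "pinv_uptake",
    "leastsq_uptake",
    "fused_lasso_uptake",
    "residue_average_uptake",
    "PseudoInverseUptake",
    "ConstrainedLeastSquaresUptake",
    "FusedLassoUptake",
    "ResidueAverageUptake",
]


def table_to_matrices(table: PeptideTable):
    """Replicate-averaged peptide x time uptake in amide units, with the
    coupling matrix.  Returns (C, Y, l, times)."""
    table = table.informative()
    if len(table.states) > 1:
        raise ValueError("expected a single-state table")
    R = table.n_residues
    C = coupling_matrix(table.peptides, R)
    l = C.sum(axis=1)
    times = table.times
    pid = {p.id: i for i, p in enumerate(table.peptides)}
    tid = {t: m for m, t in enumerate(times)}
    Y = np.zeros((len(table.peptides), times.size))
    cnt = np.zeros_like(Y)
    for row in table.data.itertuples(index=False):
        i, m = pid[row.peptide], tid[row.time]
        Y[i, m] += row.uptake * l[i]
        cnt[i, m] += 1.0
    Y = Y / np.maximum(cnt, 1.0)
    return C, Y, l, times


def pinv_uptake(C: np.ndarray, u_pep: np.ndarray) -> np.ndarray:
    """Minimum-norm generalised-inverse residue uptake, one column per
    timepoint.  Deliberately unconstrained: may leave [0, 1]."""
    u_pep = np.atleast_2d(np.asarray(u_pep, dtype=float).T).T \
        if np.ndim(u_pep) == 1 else np.asarray(u_pep, dtype=float)
    return np.linalg.pinv(C) @ u_pep


def leastsq_uptake(C: np.ndarray, u_pep: np.ndarray, tol: float = 1e-12,
                   ) -> np.ndarray:
    """Box-constrained least squares per timepoint: residue values in [0,1]."""
    U = np.atleast_2d(np.asarray(u_pep, dtype=float).T).T \
        if np.ndim(u_pep) == 1 else np.asarray(u_pep, dtype=float)
    out = np.empty((C.shape[1], U.shape[1]))
    for m in range(U.shape[1]):
        res = lsq_linear(C, U[:, m], bounds=(0.0, 1.0), method="bvls", tol=tol)
        if not res.success:
            raise RuntimeError(
                f"constrained least squares failed at column {m}: {res.message}")
        out[:, m] = res.x
    return out


def fused_lasso_uptake(
    C: np.ndarray,
    u_pep: np.ndarray,
    lam: float = 5.0,
    tol: float = 1e-8,
    max_iter: int = 20_000,
) -> np.ndarray:
    """Fused-lasso residue uptake per timepoint.

    Minimizes 0.5 ||u_pep - C u||_2^2 + lam * sum_j |u_{j+1} - u_j| over
    u in [0, 1]^R by accelerated proximal gradient; the proximal step is
    exact 1-D total-variation denoising followed by clipping (for an
    interval constraint the two compose exactly).  lam = 0 reduces to the
    box-constrained least-squares baseline.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    U = np.atleast_2d(np.asarray(u_pep, dtype=float).T).T \
        if np.ndim(u_pep) == 1 else np.asarray(u_pep, dtype=float)
    R = C.shape[1]
    L = np.linalg.norm(C, 2) ** 2 + 1e-12
    out = np.empty((R, U.shape[1]))
    for m in range(U.shape[1]):
        y = U[:, m]
        x = np.clip(np.linalg.pinv(C) @ y, 0.0, 1.0)
        z, t_acc = x.copy(), 1.0
        obj_prev = np.inf
        for it in range(max_iter):
            grad = C.T @ (C @ z - y)
            x_new = np.clip(tv1d_denoise(z - grad / L, lam / L), 0.0, 1.0)
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc))
            z = x_new + ((t_acc - 1.0) / t_new) * (x_new - x)
            x, t_acc = x_new, t_new
            if it % 10 == 0:
                r = y - C @ x
                obj = 0.5 * float(r @ r) + lam * float(np.sum(np.abs(np.diff(x))))
                if abs(obj_prev - obj) < tol * max(1.0, abs(obj)):
                    break
                obj_prev = obj
        else:
            raise RuntimeError(
                f"fused lasso did not converge in {max_iter} iterations "
                f"(last objective {obj_prev:.3e})")
        out[:, m] = x
    return out


def residue_average_uptake(table: PeptideTable) -> np.ndarray:
    """Length-normalized residue averaging (the RFU-WA comparator).

    Each residue's value is the mean fractional uptake of the peptides
    whose exchangeable sets cover it; uncovered residues are NaN.
    """
    C, Y, l, _ = table_to_matrices(table)
    frac = Y / l[:, None]
    num = C.T @ frac
    den = C.sum(axis=0)
    out = np.full_like(num, np.nan)
    cov = den > 0
    out[cov] = num[cov] / den[cov, None]
    return out


class _MatrixBaseline(BaseEstimator):
    """Shared fit plumbing: estimators expose residue_uptake_ (R x T)."""

    def fit(self, table: PeptideTable, y=None):
        C, Y, l, times = table_to_matrices(table)
        self.coupling_ = C
        self.times_ = times
        self.coverage_ = C.sum(axis=0)
        self.residue_uptake_ = self._solve(C, Y, table)
        return self

    def fit_predict(self, table: PeptideTable) -> np.ndarray:
        return self.fit(table).residue_uptake_


class PseudoInverseUptake(_MatrixBaseline):
    """Generalised-inverse baseline (P-Inv); unconstrained output."""

    def _solve(self, C, Y, table):
        return pinv_uptake(C, Y)


class ConstrainedLeastSquaresUptake(_MatrixBaseline):
    """Box-constrained least-squares baseline (LeastSq)."""

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    def _solve(self, C, Y, table):
        return leastsq_uptake(C, Y, tol=self.tol)


class FusedLassoUptake(_MatrixBaseline):
    """Fused-lasso baseline; lam = 5 is the strongest comparator setting."""

    def __init__(self, lam: float = 5.0, tol: float = 1e-8,
                 max_iter: int = 20_000):
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def _solve(self, C, Y, table):
        return fused_lasso_uptake(C, Y, lam=self.lam, tol=self.tol,
                                  max_iter=self.max_iter)


class ResidueAverageUptake(_MatrixBaseline):
    """Length-normalized residue averaging (RFU-WA)."""

    def _solve(self, C, Y, table):
        return residue_average_uptake(table)
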
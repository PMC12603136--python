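"""Conformational signature analysis (CSA).

When many protein states (e.g. a ligand panel) are profiled against a
common reference, pairwise comparison stops scaling; instead the per-state
residue-level differential effect sizes (TRE) are assembled into a states x
residues matrix and analysed multivariately: PCA for the unsupervised
conformational landscape, OPLS-DA when states carry a functional
annotation, and Procrustes-aligned projections of posterior samples for
uncertainty in both scores and loadings.

The matrix is column-centered but not variance-scaled by default: residues
share units, and unit scaling would inflate low-signal residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .model import PeptideTable
from .sampler import PosteriorSamples
from .stats import reconstruction_errors, residue_errors

__all__ = [
    "SignatureMatrix",
    "build_signature_matrix",
    "pca_signatures",
    "PCAResult",
    "oplsda_signatures",
    "OPLSDAResult",
    "projection_uncertainty",
    "ProjectionUncertainty",
    "SignaturePCA",
    "SignatureOPLSDA",
]


@dataclass
class SignatureMatrix:
    """States x residues matrix of differential effect sizes (TRE).

    ``replicates`` optionally stacks per-posterior-sample versions of X for
    uncertainty quantification; ``y`` is an optional annotation per state
    (categorical or continuous, NaN/None allowed)."""

    X: np.ndarray
    state_labels: list
    y: Optional[np.ndarray] = None
    replicates: Optional[np.ndarray] = None   # (n_rep, C, R)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (states x residues)")
        if len(self.state_labels) != self.X.shape[0]:
            raise ValueError("one label per state required")
        if self.replicates is not None and \
                self.replicates.shape[1:] != self.X.shape:
            raise ValueError("replicate matrices must share X's shape")


def _tre_row(samples: PosteriorSamples, reference: PeptideTable,
             sample_index: Optional[int] = None) -> np.ndarray:
    """Time-averaged differential TRE profile of one state vs reference.

    With ``sample_index`` the prediction comes from that single posterior
    draw instead of the posterior mean (used for replicate matrices)."""
    if sample_index is None:
        re = reconstruction_errors(samples, reference)
    else:
        one = PosteriorSamples(
            states=[samples.states[sample_index]],
            residue_uptake_draws=samples.residue_uptake_draws[
                sample_index:sample_index + 1],
            times=samples.times, n_residues=samples.n_residues,
            acceptance=samples.acceptance, config=samples.config,
            seed=samples.seed)
        re = reconstruction_errors(one, reference)
    re["re_norm"] = -re["re_norm"]        # predicted - observed
    per = residue_errors(re, reference.peptides, samples.n_residues)
    wide = per.pivot(index="residue", columns="time", values="tre")
    return wide.mean(axis=1).to_numpy()


def build_signature_matrix(
    state_samples: Mapping[str, PosteriorSamples],
    reference: PeptideTable,
    y: Optional[Mapping[str, object]] = None,
    n_replicates: int = 0,
    seed: Optional[int] = None,
) -> SignatureMatrix:
    """Assemble the CSA matrix: row c is the time-averaged TRE profile of
    state c against the common reference table.  ``n_replicates`` > 0 adds
    per-posterior-sample replicate matrices (50 is a reasonable default for
    uncertainty work)."""
    reference = reference.informative()
    labels = list(state_samples)
    n_res = {s.n_residues for s in state_samples.values()}
    if len(n_res) != 1:
        raise ValueError(f"states disagree on protein length: {n_res}")
    rows = [_tre_row(state_samples[c], reference) for c in labels]
    X = np.vstack(rows)
    X = np.nan_to_num(X)                  # uncovered residues: no signal

    reps = None
    if n_replicates > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_replicates, X.shape[0], X.shape[1]))
        for j in range(n_replicates):
            for c, label in enumerate(labels):
                s = state_samples[label]
                idx = int(rng.integers(s.n_samples))
                reps[j, c] = np.nan_to_num(
                    _tre_row(s, reference, sample_index=idx))
    yv = None
    if y is not None:
        yv = np.array([y.get(c) for c in labels], dtype=object)
    return SignatureMatrix(X=X, state_labels=labels, y=yv, replicates=reps)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: np.ndarray          # C x k
    loadings: np.ndarray        # R x k, orthonormal columns
    explained_variance_ratio: np.ndarray
    mean: np.ndarray            # column means used for centering


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Resolve the per-component sign ambiguity: the coordinate with the
    largest |loading| is made positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return loadings, scores


def pca_signatures(X: np.ndarray, n_components: Optional[int] = None
                   ) -> PCAResult:
    """PCA of the signature matrix: scores S = X_centered L with orthonormal
    loadings ordered by decreasing explained variance."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two states")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(Xc.shape)
    loadings = Vt[:k].T.copy()
    scores = (U[:, :k] * s[:k]).copy()
    total = float(np.sum(s ** 2))
    ratio = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    loadings, scores = _fix_signs(loadings, scores)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=ratio, mean=mean)


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OPLSDAResult:
    scores_pred: np.ndarray       # C (fitted rows projected)
    loadings_pred: np.ndarray     # R
    scores_ortho: np.ndarray      # C x n_ortho
    loadings_ortho: np.ndarray    # R x n_ortho
    explained_variance_pred: float
    y_encoded: np.ndarray
    fitted_mask: np.ndarray       # states used in fitting (observed y)


def _encode_y(y: np.ndarray) -> tuple:
    """Dummy-code a categorical annotation (two classes become +/-1) or
    standardize a continuous one; returns (Y matrix, observed mask)."""
    vals = np.asarray(y, dtype=object)
    observed = np.array([v is not None and v == v for v in vals])
    obs_vals = vals[observed]
    if all(isinstance(v, (int, float, np.floating, np.integer))
           and not isinstance(v, bool) for v in obs_vals):
        z = np.asarray(list(obs_vals), dtype=float)
        sd = z.std()
        if sd == 0:
            raise ValueError("continuous annotation has zero variance")
        Y = ((z - z.mean()) / sd)[:, None]
    else:
        classes = sorted({str(v) for v in obs_vals})
        if len(classes) < 2:
            raise ValueError("need at least two observed classes")
        if len(classes) == 2:
            Y = np.where(np.array([str(v) for v in obs_vals]) == classes[1],
                         1.0, -1.0)[:, None]
        else:
            Y = np.array([[1.0 if str(v) == c else 0.0 for c in classes]
                          for v in obs_vals])
            Y = Y - Y.mean(axis=0)
    return Y, observed


def oplsda_signatures(X: np.ndarray, y, n_ortho: int = 1) -> OPLSDAResult:
    """Orthogonal PLS discriminant analysis of the signature matrix.

    One predictive component maximally covarying with the annotation plus
    ``n_ortho`` components capturing systematic variation orthogonal to it.
    States with missing annotation are excluded from fitting and projected
    afterwards.
    """
    X = np.asarray(X, dtype=float)
    Y, observed = _encode_y(np.asarray(y, dtype=object))
    Xf = X[observed]
    mean = Xf.mean(axis=0)
    E = Xf - mean

    def pls_direction(E):
        Z = E.T @ Y
        if Z.shape[1] == 1:
            w = Z[:, 0]
        else:
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            w = U[:, 0]
        n = np.linalg.norm(w)
        if n < 1e-12:
            raise ValueError("singular cross-covariance between X and y")
        return w / n

    W_o, P_o = [], []
    for _ in range(n_ortho):
        w = pls_direction(E)
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break                       # no orthogonal variation left
        w_o /= norm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)

    w = pls_direction(E)
    t = E @ w
    p = E.T @ t / (t @ t)
    tot = float(np.sum((Xf - mean) ** 2))
    evp = float(np.outer(t, p).ravel() @ np.outer(t, p).ravel()) / tot \
        if tot > 0 else 0.0

    # project all states (including unannotated) through the same filter
    Eall = X - mean
    t_o_all = np.zeros((X.shape[0], len(W_o)))
    for j, (w_oj, p_oj) in enumerate(zip(W_o, P_o)):
        t_o_all[:, j] = Eall @ w_oj
        Eall = Eall - np.outer(t_o_all[:, j], p_oj)
    t_all = Eall @ w

    y_enc = np.full(X.shape[0], np.nan)
    y_enc[observed] = Y[:, 0] if Y.shape[1] == 1 else np.argmax(Y, axis=1)
    return OPLSDAResult(
        scores_pred=t_all,
        loadings_pred=w,
        scores_ortho=t_o_all,
        loadings_ortho=(np.column_stack(W_o) if W_o
                        else np.zeros((X.shape[1], 0))),
        explained_variance_pred=evp,
        y_encoded=y_enc,
        fitted_mask=observed,
    )


# ---------------------------------------------------------------------------
# uncertainty by Procrustes alignment


@dataclass
class ProjectionUncertainty:
    aligned_scores: np.ndarray      # (n_rep, C, k)
    loading_quantiles: np.ndarray   # (R, k, 3) at 2.5 / 50 / 97.5 %
    uncertain_zero: np.ndarray      # (R, k) bool: interval crosses zero
    reference: PCAResult


def projection_uncertainty(
    replicates: np.ndarray,
    reference: PCAResult,
    quantiles: Sequence[float] = (0.025, 0.5, 0.975),
) -> ProjectionUncertainty:
    """Propagate posterior uncertainty into the CSA projection.

    Each replicate matrix gets its own PCA; its scores are rigidly aligned
    (rotation/reflection, no scaling) to the reference score configuration
    with the Procrustes transform, and its loadings are rotated with the
    same matrix.  A residue whose loading quantile interval crosses zero
    has no confidently non-zero contribution to that component.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim != 3 or replicates.shape[0] < 2:
        raise ValueError("need a stack of at least two replicate matrices")
    k = reference.scores.shape[1]
    C = reference.scores.shape[0]
    if C <= k:
        raise ValueError(
            f"alignment is degenerate with {C} states in {k} dimensions; "
            "reduce n_components")
    ref_c = reference.scores - reference.scores.mean(axis=0)
    n_rep = replicates.shape[0]
    scores = np.empty((n_rep, C, k))
    loads = np.empty((n_rep, reference.loadings.shape[0], k))
    for j in range(n_rep):
        res = pca_signatures(replicates[j], n_components=k)
        S = res.scores - res.scores.mean(axis=0)
        Q, _ = orthogonal_procrustes(S, ref_c)
        scores[j] = S @ Q + reference.scores.mean(axis=0)
        loads[j] = res.loadings @ Q
    lq = np.quantile(loads, quantiles, axis=0)      # (3, R, k)
    lq = np.moveaxis(lq, 0, -1)
    uncertain = (lq[..., 0] < 0) & (lq[..., -1] > 0)
    return ProjectionUncertainty(
        aligned_scores=scores, loading_quantiles=lq,
        uncertain_zero=uncertain, reference=reference)


# ---------------------------------------------------------------------------
# estimator-style wrappers


class SignaturePCA:
    """PCA of a SignatureMatrix with optional posterior uncertainty."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, sig: SignatureMatrix):
        self.result_ = pca_signatures(sig.X, self.n_components)
        self.scores_ = self.result_.scores
        self.loadings_ = self.result_.loadings
        self.explained_variance_ratio_ = self.result_.explained_variance_ratio
        if sig.replicates is not None:
            self.uncertainty_ = projection_uncertainty(
                sig.replicates, self.result_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.result_.mean) @ self.result_.loadings


class SignatureOPLSDA:
    """Supervised CSA: one predictive + n_ortho orthogonal components."""

    def __init__(self, n_ortho: int = 1):
        self.n_ortho = n_ortho

    def fit(self, sig: SignatureMatrix, y=None):
        labels = sig.y if y is None else y
        if labels is None:
            raise ValueError("OPLS-DA needs an annotation vector")
        self.result_ = oplsda_signatures(sig.X, labels, n_ortho=self.n_ortho)
        self.scores_pred_ = self.result_.scores_pred
        self.loadings_pred_ = self.result_.loadings_pred
        return self
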
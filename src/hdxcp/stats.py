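"""Post-inference statistics: reconstruction errors, per-residue effect
sizes, posterior probabilities of effect, and expected-FDR control.

The reconstructive error of a peptide is the observed uptake minus the
posterior-mean model prediction.  Per residue, the length-normalized errors
of the covering peptides are combined three ways:

* SignedARE_r : their mean (signed);
* ARE_r      : the mean of their absolute values (a local fit-quality /
               resolution metric);
* TRE_r      : their *sum* -- deliberately unaveraged, so that several
               overlapping peptides deviating in the same direction
               amplify the evidence while opposite-signed deviations
               cancel.  This is the effect size used for differential
               calls, exploiting peptide redundancy.

Probabilities of effect compare the observed statistic with a Monte-Carlo
null assembled from the posterior noise-scale draws (a sum of n_r Laplace
variates for the TRE), and discoveries are thresholded by the expected
false discovery rate EFDR(t) = sum (1-p_i) 1{p_i>=t} / sum 1{p_i>=t}.

Residue-level results are returned as tidy DataFrames (one row per residue
x timepoint, plus time-averaged rows labelled "avg").
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import PeptideTable, coupling_matrix, residue_uptake_matrix
from .sampler import PosteriorSamples, posterior_mean_uptake

__all__ = [
    "mean_residue_uptake_at",
    "reconstruction_errors",
    "residue_errors",
    "effect_probabilities",
    "efdr",
    "efdr_threshold",
    "differential_tre",
]


def mean_residue_uptake_at(samples: PosteriorSamples, times) -> np.ndarray:
    """Posterior-mean residue uptake evaluated on an arbitrary time grid."""
    times = np.asarray(times, dtype=float)
    if samples.n_samples == 0:
        raise ValueError("no stored samples")
    if times.shape == samples.times.shape and np.allclose(times, samples.times):
        return posterior_mean_uptake(samples)
    acc = np.zeros((samples.n_residues, times.size))
    for st in samples.states:
        acc += residue_uptake_matrix(st, samples.n_residues, times)
    return acc / samples.n_samples


def reconstruction_errors(
    samples: PosteriorSamples, table: PeptideTable
) -> pd.DataFrame:
    """Per-observation reconstructive error RE = y - posterior-mean
    prediction, in amide units, with the length-normalized variant.

    Every peptide in ``table`` must lie within the fitted protein range;
    predictions are sums of posterior-mean residue uptakes over the
    peptide's exchangeable set (linearity makes this identical to averaging
    per-sample peptide predictions).
    """
    table = table.informative()
    if table.n_residues > samples.n_residues:
        raise ValueError(
            f"table spans {table.n_residues} residues but the model covers "
            f"{samples.n_residues}")
    mean_mu = mean_residue_uptake_at(samples, table.times)
    C = coupling_matrix(table.peptides, samples.n_residues)
    l = C.sum(axis=1)
    P = C @ mean_mu                                    # amide units
    pid = {p.id: i for i, p in enumerate(table.peptides)}
    tid = {t: m for m, t in enumerate(table.times)}
    out = table.data.copy()
    i = out["peptide"].map(pid).to_numpy()
    m = out["time"].map(tid).to_numpy()
    y = out["uptake"].to_numpy(dtype=float) * l[i]
    out["predicted"] = P[i, m]
    out["re"] = y - out["predicted"]
    out["re_norm"] = out["re"] / l[i]
    out["l"] = l[i]
    return out


def residue_errors(
    re_table: pd.DataFrame,
    peptides: Sequence,
    n_residues: int,
) -> pd.DataFrame:
    """Per-residue error statistics from a reconstruction-error table.

    Replicates are averaged per (peptide, time) before combining; n_r is
    the redundancy (covering-peptide count).  Residues with no coverage are
    reported with NaN statistics, never zero.
    """
    per_pep = (re_table.groupby(["peptide", "time"], as_index=False)
               .agg(re_norm=("re_norm", "mean")))
    C = coupling_matrix(peptides, n_residues)
    pid = {p.id: i for i, p in enumerate(peptides)}
    times = np.array(sorted(per_pep["time"].unique()))
    tid = {t: m for m, t in enumerate(times)}
    E = np.full((len(peptides), times.size), np.nan)
    for row in per_pep.itertuples(index=False):
        E[pid[row.peptide], tid[row.time]] = row.re_norm
    n_r = C.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tre = C.T @ np.nan_to_num(E)
        are = C.T @ np.abs(np.nan_to_num(E))
        signed = tre / n_r[:, None]
        are_mean = are / n_r[:, None]
    rows = []
    for r in range(n_residues):
        for m, t in enumerate(times):
            if n_r[r] == 0:
                rows.append((r + 1, t, 0, np.nan, np.nan, np.nan))
            else:
                rows.append((r + 1, t, int(n_r[r]), signed[r, m],
                             are_mean[r, m], tre[r, m]))
    return pd.DataFrame(
        rows, columns=["residue", "time", "n", "signed_are", "are", "tre"])


def effect_probabilities(
    values: np.ndarray,
    n_r: np.ndarray,
    sigma_draws: np.ndarray,
    statistic: str = "tre",
    rng: Optional[np.random.Generator] = None,
    inner: int = 1,
) -> np.ndarray:
    """Monte-Carlo probability of effect per residue.

    For the TRE the null draw per posterior sample is a sum of n_r
    independent Laplace(0, sigma^(m)) variates and the probability is
    P(|TRE_r| > |null|); for the (Signed)ARE a single Laplace draw is used.
    NaN inputs (uncovered residues) give NaN probabilities.
    """
    rng = rng or np.random.default_rng()
    values = np.asarray(values, dtype=float)
    n_r = np.asarray(n_r, dtype=int)
    sig = np.repeat(np.asarray(sigma_draws, dtype=float), inner)
    S = sig.size
    if S == 0:
        raise ValueError("need at least one posterior sigma draw")
    R = values.shape[0]
    if statistic in ("are", "signed_are"):
        null = rng.laplace(size=(R, S)) * sig[None, :]
    elif statistic == "tre":
        nmax = max(int(n_r.max()), 1)
        lap = rng.laplace(size=(R, S, nmax))
        mask = np.arange(nmax)[None, :] < n_r[:, None]
        null = (lap * mask[:, None, :]).sum(axis=2) * sig[None, :]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    vals = values[:, None]
    if statistic == "signed_are":
        p = np.mean(vals > null, axis=1)
    elif statistic == "are":
        p = np.mean(vals > np.abs(null), axis=1)
    else:
        p = np.mean(np.abs(vals) > np.abs(null), axis=1)
    p = np.where(np.isfinite(values) & (n_r > 0), p, np.nan)
    return p


def efdr(probabilities: np.ndarray, threshold: float) -> float:
    """Expected false discovery rate of calling p_i >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    p = p[np.isfinite(p)]
    called = p >= threshold
    if not called.any():
        raise ValueError(f"no probability reaches threshold {threshold}")
    return float(np.sum((1.0 - p)[called]) / np.sum(called))


def efdr_threshold(probabilities: np.ndarray, level: float = 0.05
                   ) -> Optional[float]:
    """Probability cutoff controlling the EFDR at ``level``.

    Scans the observed probabilities from the largest downwards and returns
    the smallest observed p such that the EFDR stays below the level at it
    and at every larger observed p; None if even the largest observed
    probability fails.
    """
    p = np.asarray(probabilities, dtype=float)
    p = np.unique(p[np.isfinite(p)])[::-1]
    best = None
    for cand in p:
        if efdr(probabilities, cand) < level:
            best = float(cand)
        else:
            break
    return best


def differential_tre(
    samples: PosteriorSamples,
    reference: PeptideTable,
    rng: Optional[np.random.Generator] = None,
    efdr_level: float = 0.05,
    inner: int = 1,
) -> pd.DataFrame:
    """Residue-level differential analysis against a reference (APO) state.

    The model is fitted on the state of interest; its posterior-mean
    predictions are compared against the reference observations peptide by
    peptide.  The difference is predicted-minus-observed, so protection in
    the fitted state (reduced uptake relative to the reference) gives
    negative TRE.  Returns per-timepoint rows plus time-averaged rows
    (time = "avg"); for the averaged rows the Monte-Carlo null is likewise
    a mean over timepoints of independent Laplace sums.  Each row carries
    the probability of effect and a boolean EFDR call at ``efdr_level``.
    """
    rng = rng or np.random.default_rng()
    reference = reference.informative()
    if len(reference.states) > 1:
        raise ValueError(f"reference table has several states: {reference.states}")
    re = reconstruction_errors(samples, reference)
    # predicted - observed: flip the reconstruction-error sign
    re["re_norm"] = -re["re_norm"]
    per_res = residue_errors(re, reference.peptides, samples.n_residues)
    times = np.array(sorted(per_res["time"].unique()))
    M = times.size
    sigma = samples.sigma_draws

    wide = per_res.pivot(index="residue", columns="time", values="tre")
    n_r = (per_res.groupby("residue")["n"].first()
           .reindex(wide.index).to_numpy())

    frames = []
    for t in times:
        sub = per_res[per_res["time"] == t].copy()
        sub["prob"] = effect_probabilities(
            sub["tre"].to_numpy(), sub["n"].to_numpy(), sigma,
            statistic="tre", rng=rng, inner=inner)
        frames.append(sub)

    avg = per_res.groupby("residue", as_index=False).agg(
        n=("n", "first"), signed_are=("signed_are", "mean"),
        are=("are", "mean"), tre=("tre", "mean"))
    # null for the time-average: mean of M independent Laplace sums
    sig_rep = np.repeat(sigma, inner)
    nmax = max(int(np.nanmax(n_r)) if np.isfinite(n_r).any() else 1, 1)
    lap = rng.laplace(size=(len(avg), sig_rep.size, M, nmax))
    mask = np.arange(nmax)[None, :] < np.nan_to_num(n_r)[:, None]
    null_avg = (lap * mask[:, None, None, :]).sum(axis=3).mean(axis=2) \
        * sig_rep[None, :]
    prob_avg = np.mean(np.abs(avg["tre"].to_numpy())[:, None] > np.abs(null_avg),
                       axis=1)
    avg["prob"] = np.where(avg["n"] > 0, prob_avg, np.nan)
    avg["time"] = "avg"
    frames.append(avg[["residue", "time", "n", "signed_are", "are", "tre",
                       "prob"]])

    out = pd.concat(frames, ignore_index=True)
    out["efdr_call"] = False
    for t in out["time"].unique():
        m = out["time"] == t
        cut = efdr_threshold(out.loc[m, "prob"].to_numpy(), efdr_level)
        if cut is not None:
            out.loc[m, "efdr_call"] = out.loc[m, "prob"] >= cut
    return out
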
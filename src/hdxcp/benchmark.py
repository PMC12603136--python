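"""Leave-digests-out benchmark for residue-level HDX methods.

Different proteases digest the same protein into different peptide maps
while the underlying residue-level exchange is identical.  A method is
therefore scored by fitting on one digest and predicting the peptide
uptakes of the held-out digests (sums of inferred residue values over each
held-out peptide's exchangeable set).  Accuracy is summarised by the median
absolute deviation (MAD) between predicted and observed uptake per digest
and timepoint, with bootstrap resampling over peptides for uncertainty, and
physical plausibility by bounds/monotonicity violation rates.

Residual scale differences between digest experiments (even after
fully-deuterated-control normalisation) are removed by a per-timepoint
multiplicative correction estimated from the peptides common to both
digests.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import PeptideTable

__all__ = [
    "digest_correction_factor",
    "apply_correction",
    "leave_digests_out",
    "mad_bootstrap",
    "violation_rates",
    "benchmark_report",
]


def _common_keys(a: PeptideTable, b: PeptideTable) -> set:
    key = lambda p: (p.sequence, p.start, p.end)
    return {key(p) for p in a.peptides} & {key(p) for p in b.peptides}


def digest_correction_factor(
    table_a: PeptideTable, table_b: PeptideTable
) -> dict:
    """Per-timepoint factor putting table_b on table_a's uptake scale.

    factor_t = median(common-peptide uptakes of a at t) /
               median(common-peptide uptakes of b at t),
    computed over the peptides (same sequence and coordinates) present in
    both digests.  table_b uptakes should be multiplied by factor_t.
    """
    common = _common_keys(table_a, table_b)
    if not common:
        raise ValueError("the two tables share no peptides")
    ids_a = {p.id for p in table_a.peptides
             if (p.sequence, p.start, p.end) in common}
    ids_b = {p.id for p in table_b.peptides
             if (p.sequence, p.start, p.end) in common}
    factors = {}
    for t in sorted(set(table_a.times) & set(table_b.times)):
        ua = table_a.data.query("peptide in @ids_a and time == @t")["uptake"]
        ub = table_b.data.query("peptide in @ids_b and time == @t")["uptake"]
        if ua.empty or ub.empty:
            raise ValueError(f"no common observations at time {t}")
        factors[float(t)] = float(np.median(ua) / np.median(ub))
    return factors


def apply_correction(table: PeptideTable, factors: Mapping[float, float]
                     ) -> PeptideTable:
    """Multiply uptakes by the per-timepoint correction factors."""
    data = table.data.copy()
    data["uptake"] = data["uptake"] * data["time"].map(
        lambda t: factors.get(float(t), 1.0))
    return PeptideTable(table.peptides, data, n_residues=table.n_residues)


def _method_matrix(method, table: PeptideTable) -> np.ndarray:
    """Run a plug-in method: an estimator (fit_predict / fit +
    residue_uptake_) or a plain callable from table to (R, T) matrix."""
    if hasattr(method, "fit_predict"):
        return np.asarray(method.fit_predict(table), dtype=float)
    if hasattr(method, "fit"):
        return np.asarray(method.fit(table).residue_uptake_, dtype=float)
    return np.asarray(method(table), dtype=float)


def leave_digests_out(
    train_table: PeptideTable,
    held_out: Mapping[str, PeptideTable],
    method,
    correct: bool = True,
) -> tuple:
    """Fit a method on one digest and pair its predictions with held-out
    observations.

    Returns (records, excluded): ``records`` has one row per held-out
    (digest, peptide, time) with predicted and observed fraction-of-FD
    uptake; peptides whose exchangeable set touches a residue with zero
    training coverage, or where the method returns no value, are excluded
    and counted in ``excluded``.
    """
    R = train_table.n_residues
    U = _method_matrix(method, train_table)
    if U.shape[0] != R:
        raise ValueError(
            f"method returned {U.shape[0]} residues, expected {R}")
    train_cov = train_table.informative().redundancy()
    times = train_table.times
    tid = {float(t): m for m, t in enumerate(times)}

    rows, excluded = [], {}
    for name, ho in held_out.items():
        ho = ho.informative()
        if ho.n_residues > R:
            raise ValueError(f"held-out digest {name} spans residues beyond "
                             f"the training protein length {R}")
        if correct:
            ho = apply_correction(ho, digest_correction_factor(train_table, ho))
        n_excl = 0
        obs = (ho.data.groupby(["peptide", "time"], as_index=False)
               .agg(uptake=("uptake", "mean")))
        pep = {p.id: p for p in ho.peptides}
        for row in obs.itertuples(index=False):
            p = pep[row.peptide]
            t = float(row.time)
            if t not in tid:
                n_excl += 1
                continue
            vals = U[[r - 1 for r in p.exch], tid[t]]
            covered = all(train_cov[r - 1] > 0 for r in p.exch)
            if not covered or not np.all(np.isfinite(vals)):
                n_excl += 1
                continue
            rows.append((name, p.id, t, float(np.sum(vals)) / p.l,
                         float(row.uptake)))
        excluded[name] = n_excl
    records = pd.DataFrame(
        rows, columns=["digest", "peptide", "time", "predicted", "observed"])
    return records, excluded


def mad_bootstrap(
    records: pd.DataFrame,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Bootstrap distribution of the MAD per (digest, timepoint).

    MAD = median(|predicted - observed|); peptides are the resampled unit
    (they are the exchangeable observational unit, residues are not).
    Returns one row per (digest, time) with the plug-in MAD and 2.5/97.5%
    bootstrap quantiles.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for (digest, t), grp in records.groupby(["digest", "time"]):
        err = np.abs(grp["predicted"] - grp["observed"]).to_numpy()
        n = err.size
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.median(err[idx], axis=1)
        out.append((digest, t, float(np.median(err)),
                    float(np.quantile(boots, 0.025)),
                    float(np.quantile(boots, 0.975)),
                    float(boots.mean()), n))
    return pd.DataFrame(out, columns=[
        "digest", "time", "mad", "ci_low", "ci_high", "boot_mean", "n_peptides"])


def violation_rates(U: np.ndarray, eps: float = 1e-9) -> tuple:
    """Physical-plausibility rates of a residue x time uptake matrix.

    Returns (bounds violation %, monotonicity violation %): the percentage
    of entries outside [0 - eps, 1 + eps] and of consecutive-time pairs
    decreasing by more than eps.  Rows with NaN (uncovered residues) are
    ignored.
    """
    U = np.asarray(U, dtype=float)
    finite = np.isfinite(U)
    n_entries = int(finite.sum())
    if n_entries == 0:
        return float("nan"), float("nan")
    bounds = np.sum((U < -eps) | (U > 1.0 + eps), where=finite,
                    initial=0)
    d = np.diff(U, axis=1)
    dm = np.isfinite(d)
    mono = np.sum(d < -eps, where=dm, initial=0)
    n_pairs = int(dm.sum())
    return (100.0 * bounds / n_entries,
            100.0 * mono / n_pairs if n_pairs else float("nan"))


def benchmark_report(
    train_table: PeptideTable,
    held_out: Mapping[str, PeptideTable],
    methods: Mapping[str, object],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run the full leave-digests-out comparison.

    One row per (method, digest, timepoint) with the MAD, its bootstrap
    interval, and the method's violation percentages on the training fit.
    """
    frames = []
    for name, method in methods.items():
        U = _method_matrix(method, train_table)
        bounds_pct, mono_pct = violation_rates(U)
        recs, excl = leave_digests_out(
            train_table, held_out, lambda _t, _U=U: _U)
        mads = mad_bootstrap(recs, n_boot=n_boot, seed=seed)
        mads.insert(0, "method", name)
        mads["bounds_violation_pct"] = bounds_pct
        mads["mono_violation_pct"] = mono_pct
        mads["n_excluded"] = mads["digest"].map(excl)
        frames.append(mads)
    return pd.concat(frames, ignore_index=True)
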
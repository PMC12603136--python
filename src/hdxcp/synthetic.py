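"""Synthetic HDX-MS data: ground-truth kinetics, peptide maps, noisy
observations, and localized protection effects.

The generator draws the truth from the model's own prior (piecewise-
constant kinetics with a Poisson number of change points), emulates
protease digests as random peptide maps with controllable coverage, and
adds Laplace observation noise whose scale grows with peptide length.
Default scales mirror a small benchmark protein: ~100 residues, 50-70
peptides of 5-20 amino acids, exposure times {15, 150, 1500, 15000} s,
three replicates.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ChainState,
    Hyperparameters,
    Peptide,
    PeptideTable,
    coupling_matrix,
    residue_uptake_matrix,
    sample_theta_prior,
)

__all__ = [
    "DEFAULT_TIMES",
    "random_sequence",
    "realistic_hyperparameters",
    "simulate_truth",
    "simulate_peptide_map",
    "simulate_uptake_data",
    "add_measurement_noise",
    "apply_protection_effect",
]

DEFAULT_TIMES = (15.0, 150.0, 1500.0, 15000.0)

_AA = "ACDEFGHIKLMNQRSTVWY"  # proline added separately


def realistic_hyperparameters(n_residues: int,
                              times: Sequence[float] = DEFAULT_TIMES,
                              **overrides) -> Hyperparameters:
    """Hyperparameters whose prior draws give experimentally plausible
    kinetics: segment exchange rates are centred on the reciprocal of the
    geometric-mean exposure time, so simulated uptake curves actually
    traverse (0, 1) within the measured window instead of saturating
    before the first timepoint.  Used by the simulation protocols when a
    ground truth is drawn."""
    gm = float(np.exp(np.mean(np.log(np.asarray(times, dtype=float)))))
    overrides.setdefault("d_alpha", 25.0)
    overrides.setdefault("d_beta", 25.0 / gm)   # hyper-rate concentrates ~gm
    overrides.setdefault("b_alpha", 25.0)
    overrides.setdefault("b_beta", 25.0 / gm)
    return Hyperparameters.default_for(n_residues, **overrides)


def random_sequence(n_residues: int, rng: np.random.Generator,
                    proline_frac: float = 0.04) -> str:
    """Random amino-acid sequence with a given proline frequency."""
    seq = rng.choice(list(_AA), size=n_residues)
    pro = rng.uniform(size=n_residues) < proline_frac
    seq[pro] = "P"
    return "".join(seq)


def simulate_truth(
    n_residues: int,
    hyper: Hyperparameters | None = None,
    seed: Optional[int] = None,
) -> ChainState:
    """Draw a ground-truth chain state from the prior: K ~ Pois(lam),
    ordered-uniform change points on (1, R), segment parameters from the
    hierarchical priors (hyper-rates drawn from their hyperpriors)."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    hyper = hyper or Hyperparameters.default_for(n_residues)
    rng = np.random.default_rng(seed)
    d_rate = rng.gamma(hyper.d_alpha, 1.0 / hyper.d_beta)
    b_rate = rng.gamma(hyper.b_alpha, 1.0 / hyper.b_beta)
    K = int(rng.poisson(hyper.lam))
    tau = np.sort(rng.uniform(1.0, n_residues, size=K))
    theta = sample_theta_prior(hyper, d_rate, b_rate, rng, K + 1)
    return ChainState(tau=tau, theta=theta, log_sigma=hyper.sigma_m,
                      d_rate=float(d_rate), b_rate=float(b_rate))


def simulate_peptide_map(
    n_residues: int,
    n_peptides: int = 60,
    length_range: tuple = (5, 20),
    seed: Optional[int] = None,
    sequence: Optional[str] = None,
    min_redundancy: int = 0,
    max_extra: int = 200,
    id_prefix: str = "pep",
) -> list:
    """Random digest: peptides with uniform start and length.

    With ``min_redundancy`` > 0, additional peptides are appended (up to
    ``max_extra``) targeting the least-covered exchangeable position until
    every coverable residue is covered by at least that many peptides.
    Different seeds emulate different protease digests of the same protein.
    """
    if n_peptides < 1 or length_range[0] < 3:
        raise ValueError("need n_peptides >= 1 and peptide length >= 3")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = random_sequence(n_residues, rng)
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    peptides = []
    seen = set()

    def add(start, length):
        end = min(start + length - 1, n_residues)
        if end - start + 1 < 3 or (start, end) in seen:
            return
        seen.add((start, end))
        pep = Peptide(
            id=f"{id_prefix}{len(peptides):03d}_{start}_{end}",
            sequence=sequence[start - 1:end],
            start=start, end=end,
        )
        if pep.informative:
            peptides.append(pep)

    lo, hi = length_range
    while len(peptides) < n_peptides:
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, max(n_residues - length + 1, 2)))
        add(start, length)

    if min_redundancy > 0:
        # coverable = can appear in some peptide's exchangeable set
        coverable = np.array(
            [r >= 3 and sequence[r - 1].upper() != "P"
             for r in range(1, n_residues + 1)])
        for _ in range(max_extra):
            red = np.zeros(n_residues, dtype=int)
            for p in peptides:
                for r in p.exch:
                    red[r - 1] += 1
            deficit = coverable & (red < min_redundancy)
            if not deficit.any():
                break
            r = int(np.flatnonzero(deficit)[0]) + 1
            length = int(rng.integers(lo, hi + 1))
            start = int(np.clip(r - 2 - rng.integers(0, max(length - 3, 1)),
                                1, max(r - 2, 1)))
            add(start, length)
    return peptides


def simulate_uptake_data(
    truth: ChainState,
    peptides: Sequence[Peptide],
    times: Sequence[float] = DEFAULT_TIMES,
    replicates: int = 3,
    sigma: float = 0.01,
    seed: Optional[int] = None,
    state: str = "apo",
    n_residues: Optional[int] = None,
) -> PeptideTable:
    """Noisy peptide observations from the forward model.

    The location is the sum of residue uptakes over each peptide's
    exchangeable set; noise is Laplace with scale l_i * sigma**2 in amide
    units, matching the observation model.  Stored uptake is re-normalized
    to the fraction-of-fully-deuterated scale (divided by l_i).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    peptides = [p for p in peptides if p.informative]
    R = int(n_residues or max(p.end for p in peptides))
    rng = np.random.default_rng(seed)
    C = coupling_matrix(peptides, R)
    mu = residue_uptake_matrix(truth, R, times)
    P = C @ mu                                    # amide units
    l = C.sum(axis=1)

    rows = []
    for i, pep in enumerate(peptides):
        scale = l[i] * sigma ** 2
        for m, t in enumerate(times):
            noise = rng.laplace(0.0, scale, size=replicates) if sigma > 0 \
                else np.zeros(replicates)
            for rep in range(replicates):
                rows.append((pep.id, state, t, rep + 1,
                             (P[i, m] + noise[rep]) / l[i]))
    data = pd.DataFrame(rows, columns=["peptide", "state", "time",
                                       "replicate", "uptake"])
    return PeptideTable(peptides, data, n_residues=R)


def add_measurement_noise(table: PeptideTable, sd: float,
                          seed: Optional[int] = None) -> PeptideTable:
    """Degrade an existing dataset with extra Gaussian measurement noise
    (standard deviation in fraction-of-fully-deuterated units per peptide).
    Emulates adding noise on top of an already-noisy experiment, the
    protocol used to probe sigma as a resolution metric."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    data["uptake"] = data["uptake"] + rng.normal(0.0, sd, len(data))
    return PeptideTable(table.peptides, data, n_residues=table.n_residues)


def apply_protection_effect(
    table: PeptideTable,
    residue: int,
    factor: float,
    state: Optional[str] = None,
    new_state: Optional[str] = None,
) -> PeptideTable:
    """Localized protection: multiply the uptake of every peptide whose
    exchangeable set covers ``residue`` by ``factor`` (e.g. 0.80 is a
    strong protection, 0.95 a weak one), at all times and replicates."""
    if not (0.0 < factor <= 1.0):
        raise ValueError("factor must lie in (0, 1]")
    covering = {p.id for p in table.peptides if residue in p.exch}
    if not covering:
        raise ValueError(f"residue {residue} is covered by no peptide")
    data = table.data.copy()
    mask = data["peptide"].isin(covering)
    if state is not None:
        mask &= data["state"] == state
    data.loc[mask, "uptake"] *= factor
    if new_state is not None:
        data["state"] = new_state
    return PeptideTable(table.peptides, data, n_residues=table.n_residues)
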
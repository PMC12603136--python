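"""Readers and writers: peptide-table CSV, residue-results CSV, chain
checkpoints (JSON) and PDB B-factor export.

The native peptide-table dialect is a tidy CSV with columns
(sequence, start, end, state, exposure, replicate, uptake) and optional
(fd_uptake, maxuptake); coordinates are 1-based inclusive protein
numbering.  A column-mapping dict makes the reader tolerant of
HDExaminer/DynamX-style state-data exports, whose layouts vary between
versions; unknown columns are preserved in the observation frame but
ignored by the model.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import ChainState, Peptide, PeptideTable
from .sampler import PosteriorSamples, SamplerConfig

__all__ = [
    "read_peptide_table",
    "write_peptide_table",
    "normalize_to_fd",
    "write_residue_csv",
    "samples_to_json",
    "samples_from_json",
    "write_bfactor_pdb",
]

NATIVE_COLUMNS = {
    "sequence": "sequence", "start": "start", "end": "end",
    "state": "state", "exposure": "time", "replicate": "replicate",
    "uptake": "uptake",
}
DYNAMX_COLUMNS = {
    "Sequence": "sequence", "Start": "start", "End": "end",
    "State": "state", "Exposure": "time", "File": "replicate",
    "Uptake": "uptake", "MaxUptake": "maxuptake",
}


def read_peptide_table(
    path,
    dialect: str = "native",
    column_map: Optional[Mapping[str, str]] = None,
    n_residues: Optional[int] = None,
) -> PeptideTable:
    """Read a peptide-level uptake CSV into a PeptideTable.

    ``dialect`` selects a built-in column mapping ("native" or "dynamx");
    ``column_map`` overrides it for other exports.  Uptake is taken as
    given (normalize with :func:`normalize_to_fd` if it is in Daltons).
    """
    mapping = dict(column_map or
                   {"native": NATIVE_COLUMNS, "dynamx": DYNAMX_COLUMNS}[dialect])
    df = pd.read_csv(path)
    missing = [c for c in mapping if mapping[c] in
               ("sequence", "start", "end", "state", "time", "replicate",
                "uptake") and c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.rename(columns=mapping)

    for col in ("uptake", "time"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            bad = list(df.index[df[col].isna()][:5])
            raise ValueError(f"{path}: non-numeric {col} at rows {bad}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = list(df.index[df["start"] >= df["end"]][:5])
        raise ValueError(f"{path}: start >= end at rows {bad}")

    peptides = {}
    ids = []
    for row in df.itertuples(index=False):
        pid = f"{row.start}_{row.end}_{row.sequence}"
        ids.append(pid)
        if pid not in peptides:
            peptides[pid] = Peptide(id=pid, sequence=row.sequence,
                                    start=row.start, end=row.end)
    df = df.assign(peptide=ids)
    keep = ["peptide", "state", "time", "replicate", "uptake"] + [
        c for c in df.columns
        if c not in ("peptide", "state", "time", "replicate", "uptake",
                     "sequence", "start", "end")]
    return PeptideTable(list(peptides.values()), df[keep],
                        n_residues=n_residues)


def write_peptide_table(table: PeptideTable, path) -> None:
    """Write the native tidy dialect; read_peptide_table round-trips it."""
    pep = {p.id: p for p in table.peptides}
    df = table.data.copy()
    df["sequence"] = df["peptide"].map(lambda i: pep[i].sequence)
    df["start"] = df["peptide"].map(lambda i: pep[i].start)
    df["end"] = df["peptide"].map(lambda i: pep[i].end)
    df = df.rename(columns={"time": "exposure"})
    cols = ["sequence", "start", "end", "state", "exposure", "replicate",
            "uptake"]
    cols += [c for c in df.columns if c not in cols + ["peptide", "time"]]
    df[cols].to_csv(path, index=False)


def normalize_to_fd(table: PeptideTable, fd: Mapping[str, float] | pd.DataFrame
                    ) -> PeptideTable:
    """Divide uptake by each peptide's fully-deuterated-control uptake,
    yielding fractional uptake.  Noisy fractions above 1 are preserved
    (clipping is a modelling concern, not an I/O one); peptides with FD
    <= 0 are dropped with a warning; peptides without FD raise."""
    if isinstance(fd, pd.DataFrame):
        fd = dict(zip(fd["peptide"], fd["fd_uptake"]))
    missing = [p.id for p in table.peptides if p.id not in fd]
    if missing:
        raise ValueError(f"no FD control for peptides: {missing[:10]}")
    bad = {pid for pid, v in fd.items() if not v > 0}
    if bad:
        warnings.warn(f"dropping {len(bad)} peptides with non-positive FD")
    keep = [p for p in table.peptides if p.id not in bad]
    data = table.data[table.data["peptide"].isin({p.id for p in keep})].copy()
    data["uptake"] = data["uptake"] / data["peptide"].map(fd)
    return PeptideTable(keep, data, n_residues=table.n_residues)


def write_residue_csv(df: pd.DataFrame, path, method: str = "model",
                      state: str = "state") -> None:
    """Residue-level results CSV shared by the model and the baselines."""
    out = df.copy()
    out.insert(0, "method", method)
    out.insert(1, "state", state)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# chain checkpointing


def samples_to_json(samples: PosteriorSamples, path) -> None:
    """Checkpoint the thinned chain.  Layout: {"meta": {...}, "states":
    [{"tau": [...], "theta": [[pi,p,b,d], ...], "log_sigma": s,
    "d_rate": x, "b_rate": x}, ...]}."""
    payload = {
        "meta": {
            "n_residues": samples.n_residues,
            "times": list(map(float, samples.times)),
            "seed": samples.seed,
            "acceptance": {k: list(v) for k, v in samples.acceptance.items()},
            "config": {
                "n_iter": samples.config.n_iter,
                "burn_in": samples.config.burn_in,
                "thin": samples.config.thin,
                "rho": samples.config.rho,
            },
        },
        "states": [
            {"tau": s.tau.tolist(), "theta": s.theta.tolist(),
             "log_sigma": s.log_sigma, "d_rate": s.d_rate, "b_rate": s.b_rate}
            for s in samples.states
        ],
    }
    Path(path).write_text(json.dumps(payload))


def samples_from_json(path) -> PosteriorSamples:
    from .model import residue_uptake_matrix

    payload = json.loads(Path(path).read_text())
    meta = payload["meta"]
    states = [ChainState(tau=np.array(s["tau"]), theta=np.array(s["theta"]),
                         log_sigma=s["log_sigma"], d_rate=s["d_rate"],
                         b_rate=s["b_rate"])
              for s in payload["states"]]
    times = np.array(meta["times"])
    draws = np.array([residue_uptake_matrix(s, meta["n_residues"], times)
                      for s in states])
    cfg = SamplerConfig(seed=meta["seed"], **meta["config"])
    return PosteriorSamples(
        states=states, residue_uptake_draws=draws, times=times,
        n_residues=meta["n_residues"],
        acceptance={k: tuple(v) for k, v in meta["acceptance"].items()},
        config=cfg, seed=meta["seed"])


def write_bfactor_pdb(pdb_in, pdb_out, values: Mapping[int, float],
                      default: float = 0.0) -> None:
    """Copy a PDB file with the B-factor column replaced by per-residue
    values (e.g. TRE or probability) for structure colouring."""
    out_lines = []
    for line in Path(pdb_in).read_text().splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                resnum = int(line[22:26])
            except ValueError:
                resnum = None
            v = values.get(resnum, default)
            line = f"{line[:60]}{min(max(v, -99.99), 999.99):6.2f}{line[66:]}"
        out_lines.append(line)
    Path(pdb_out).write_text("".join(out_lines))
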
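"""TSV round-tripping for every table the pipeline produces.

All tabular I/O is tab-separated text with a header row, decimal points,
no thousands separators, and ``NA`` as the missing-value token. Floats are
written with ``repr``-level precision so write-then-read is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SweepPoint, Trajectory
from .network import IncidenceMatrix, NetworkError, PrunedNetwork
from .specialization import SpecializationResult
from .stats import WindowResult
from .synthetic import HostRecord

__all__ = [
    "SchemaError",
    "hosts_to_frame", "write_hosts", "read_hosts",
    "write_incidence", "read_incidence", "write_edges", "read_edges",
    "write_specialization", "write_cluster_shares", "write_prune_audit",
    "write_windows", "write_sweep", "write_trajectory",
]

_CSV_KW = dict(sep="\t", na_rep="NA", index=False, float_format="%.17g")

HOST_COLUMNS = ["host_id", "growth_rate", "min_doubling_time", "ogt", "ecosystem"]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def hosts_to_frame(hosts: Sequence[HostRecord]) -> pd.DataFrame:
    trait_names = sorted({t for h in hosts for t in h.traits})
    rows = [
        {
            "host_id": h.host_id,
            "growth_rate": h.growth_rate,
            "min_doubling_time": h.min_doubling_time,
            "ogt": h.ogt,
            "ecosystem": h.ecosystem,
            **{t: h.traits.get(t, 0) for t in trait_names},
        }
        for h in hosts
    ]
    return pd.DataFrame(rows, columns=HOST_COLUMNS + trait_names)


def write_hosts(hosts: Sequence[HostRecord] | pd.DataFrame, path: str | Path) -> None:
    df = hosts if isinstance(hosts, pd.DataFrame) else hosts_to_frame(hosts)
    df.to_csv(path, **_CSV_KW)


def read_hosts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in HOST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"host table {path}: missing column(s) {missing}")
    return df


def write_incidence(matrix: IncidenceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.a, index=list(matrix.host_ids),
                      columns=list(matrix.cluster_ids))
    df.to_csv(path, sep="\t", index_label="host_id")


def read_incidence(path: str | Path) -> IncidenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="host_id")
    values = df.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise SchemaError(
            f"incidence table {path}: cell (host {df.index[i]!r}, "
            f"cluster {df.columns[j]!r}) is {values[i, j]!r}, not 0/1"
        )
    return IncidenceMatrix(tuple(str(h) for h in df.index),
                           tuple(str(c) for c in df.columns),
                           values.astype(np.int8))


def write_edges(matrix: IncidenceMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.to_edges(), columns=["host_id", "cluster_id"]).to_csv(
        path, **_CSV_KW)


def read_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("host_id", "cluster_id"):
        if col not in df.columns:
            raise SchemaError(f"edge list {path}: missing column {col!r}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based incl. header
        raise NetworkError(f"edge list {path}: blank field on line {row}")
    return list(df[["host_id", "cluster_id"]].itertuples(index=False, name=None))


def write_specialization(result: SpecializationResult, path: str | Path) -> None:
    pd.DataFrame({
        "host_id": list(result.host_ids),
        "degree": result.degree,
        "d": result.d,
        "d_min": result.d_min,
        "d_max": result.d_max,
        "d_prime": result.d_prime,
        "degenerate": result.degenerate.astype(int),
    }).to_csv(path, **_CSV_KW)


def write_cluster_shares(result: SpecializationResult, matrix: IncidenceMatrix,
                         path: str | Path) -> None:
    pd.DataFrame({
        "cluster_id": list(result.cluster_ids),
        "degree": matrix.cluster_degrees(),
        "q": result.q,
    }).to_csv(path, **_CSV_KW)


def write_prune_audit(pruned: PrunedNetwork, path: str | Path) -> None:
    rows = [{"node_id": h, "side": "host", "reason": r}
            for h, r in pruned.removed_hosts]
    rows += [{"node_id": c, "side": "cluster", "reason": r}
             for c, r in pruned.removed_clusters]
    pd.DataFrame(rows, columns=["node_id", "side", "reason"]).to_csv(
        path, **_CSV_KW)


def write_windows(windows: Sequence[WindowResult], path: str | Path) -> None:
    rows = []
    for w in windows:
        f = w.fit
        rows.append({
            "low": w.low, "high": w.high, "n": w.n,
            "retained": int(w.retained),
            "slope": f.slope if f else np.nan,
            "slope_se": f.slope_se if f else np.nan,
            "r": f.r if f else np.nan,
            "p": f.p if f else np.nan,
            "p_adj": (f.p_adj if f and f.p_adj is not None else np.nan),
        })
    pd.DataFrame(rows).to_csv(path, **_CSV_KW)


def write_sweep(points: Sequence[SweepPoint], path: str | Path) -> None:
    pd.DataFrame([{
        "scenario": pt.scenario, "switch_mode": pt.switch_mode,
        "V_minus": pt.v_minus, "d": pt.d, "status": pt.status,
    } for pt in points]).to_csv(path, **_CSV_KW)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    I = traj.b_lysogen.shape[1]
    data = {"time": traj.times, "B_plus": traj.b_plus, "B_minus": traj.b_minus}
    for i in range(I):
        data[f"B_lysogen_{i + 1}"] = traj.b_lysogen[:, i]
    data.update({
        "P": traj.p, "N": traj.n, "S": traj.s, "d": traj.d_series(),
        "lambda": traj.lam, "xi": np.full(traj.times.size, traj.xi),
        "conservation_residual": traj.conservation_residual,
    })
    pd.DataFrame(data).to_csv(path, **_CSV_KW)
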
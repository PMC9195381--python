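"""Shannon-based host specialization index d and its standardization d'.

For host *i* in a binary bipartite incidence matrix, specialization is the
Kullback-Leibler divergence of the host's partner-use proportions ``p'_ij``
from the network-wide partner availability ``q_j``::

    d_i = sum_j p'_ij * ln(p'_ij / q_j)        (natural log, partners only)

with ``p'_ij = a_ij / A_i`` (``A_i`` = host link total) and
``q_j = column_sum_j / m`` (``m`` = grand link total). ``d_i`` is min-max
standardized to ``d'_i = (d_i - d_min) / (d_max - d_min)`` in [0, 1]: 0 is an
extreme generalist whose partner use matches availability, 1 an extreme
specialist on a partner nobody else uses.

Bounds follow the published construction of the index: ``d_max = ln(m / A_i)``
and ``d_min`` from the most availability-proportional *integer* reallocation
of the host's ``A_i`` links (largest-remainder apportionment against ``q``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import IncidenceMatrix, NetworkError

__all__ = [
    "SpecializationResult",
    "partner_share",
    "virus_share",
    "shannon_specialization",
    "dmin_dmax",
    "standardized_d",
    "distribution_moments",
]

DminMode = Literal["algorithmic", "zero"]


@dataclass(frozen=True)
class SpecializationResult:
    """Per-host d, bounds and d', plus the cluster marginals q."""

    host_ids: tuple[str, ...]
    cluster_ids: tuple[str, ...]
    degree: np.ndarray          # A_i per host
    d: np.ndarray
    d_min: np.ndarray
    d_max: np.ndarray
    d_prime: np.ndarray
    degenerate: np.ndarray      # True where d_max == d_min (d' forced to 0)
    q: np.ndarray               # availability per cluster, sums to 1


def _check_nonempty(matrix: IncidenceMatrix) -> None:
    if matrix.n_links == 0:
        raise NetworkError("matrix has no links")


def partner_share(matrix: IncidenceMatrix, host: int | str) -> np.ndarray:
    """Partner-use proportions p'_i of one host (zeros at non-partners)."""
    i = matrix.host_ids.index(host) if isinstance(host, str) else host
    row = matrix.a[i].astype(float)
    total = row.sum()
    if total == 0:
        raise NetworkError(
            f"host {matrix.host_ids[i]!r} has degree 0; prune orphans first"
        )
    return row / total


def virus_share(matrix: IncidenceMatrix) -> np.ndarray:
    """Availability q_j: share of all links held by each viral cluster."""
    _check_nonempty(matrix)
    col = matrix.cluster_degrees().astype(float)
    return col / col.sum()


def shannon_specialization(matrix: IncidenceMatrix, host: int | str) -> float:
    """KL divergence d_i of host i's partner use from availability (nats)."""
    p = partner_share(matrix, host)
    q = virus_share(matrix)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _apportion(total: int, q: np.ndarray) -> np.ndarray:
    """Largest-remainder integer apportionment of `total` units over weights q."""
    ideal = total * q
    base = np.floor(ideal).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        remainder = ideal - base
        # stable tie-break on index keeps the result deterministic
        order = np.lexsort((np.arange(q.size), -remainder))
        base[order[:short]] += 1
    return base


def _kl_from_counts(counts: np.ndarray, q: np.ndarray) -> float:
    total = counts.sum()
    mask = counts > 0
    p = counts[mask] / total
    return float(np.sum(p * np.log(p / q[mask])))


def dmin_dmax(
    matrix: IncidenceMatrix,
    host: int | str,
    d_min_mode: DminMode = "algorithmic",
) -> tuple[float, float]:
    """Bounds (d_min, d_max) for host i's specialization.

    d_max = ln(m / A_i): all A_i links placed on clusters used by nobody else.
    d_min ("algorithmic"): KL of the largest-remainder apportionment of A_i
    links against q -- the closest integer approximation to p' = q -- clipped
    to [0, d_i] so the ordering d_min <= d <= d_max always holds. Mode "zero"
    uses the simpler lower bound 0 of the continuous relaxation.
    """
    i = matrix.host_ids.index(host) if isinstance(host, str) else host
    a_i = int(matrix.a[i].sum())
    if a_i == 0:
        raise NetworkError(f"host {matrix.host_ids[i]!r} has degree 0")
    m = matrix.n_links
    d_max = float(np.log(m / a_i))
    if d_min_mode == "zero":
        return 0.0, d_max
    q = virus_share(matrix)
    counts = _apportion(a_i, q)
    d_alloc = _kl_from_counts(counts, q)
    d_obs = shannon_specialization(matrix, i)
    d_min = float(np.clip(d_alloc, 0.0, min(d_obs, d_max)))
    return d_min, d_max


def standardized_d(
    matrix: IncidenceMatrix,
    d_min_mode: DminMode = "algorithmic",
) -> SpecializationResult:
    """Compute d, d_min, d_max and d' for every host of a (pruned) network.

    Hosts with d_max == d_min carry d' = 0 and a degenerate flag instead of
    NaN, so downstream regressions stay total while remaining auditable.
    """
    _check_nonempty(matrix)
    A = matrix.host_degrees()
    if (A == 0).any():
        bad = [h for h, k in zip(matrix.host_ids, A) if k == 0]
        raise NetworkError(f"degree-0 hosts present (prune first): {bad[:5]}")
    m = matrix.n_links
    q = virus_share(matrix)
    logq = np.log(q)

    P = matrix.a / A[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(matrix.a > 0, P * (np.log(np.where(P > 0, P, 1.0)) - logq), 0.0)
    d = terms.sum(axis=1)

    d_max = np.log(m / A)
    if d_min_mode == "zero":
        d_min = np.zeros_like(d)
    else:
        # d_min depends only on A_i given q: cache per distinct degree
        cache: dict[int, float] = {}
        d_min = np.empty_like(d)
        for idx, a_i in enumerate(A):
            k = int(a_i)
            if k not in cache:
                cache[k] = _kl_from_counts(_apportion(k, q), q)
            d_min[idx] = cache[k]
        d_min = np.clip(d_min, 0.0, np.minimum(d, d_max))

    span = d_max - d_min
    degenerate = span <= 0
    d_prime = np.zeros_like(d)
    ok = ~degenerate
    d_prime[ok] = (d[ok] - d_min[ok]) / span[ok]
    d_prime = np.clip(d_prime, 0.0, 1.0)
    return SpecializationResult(
        host_ids=matrix.host_ids,
        cluster_ids=matrix.cluster_ids,
        degree=A,
        d=d,
        d_min=d_min,
        d_max=d_max,
        d_prime=d_prime,
        degenerate=degenerate,
        q=q,
    )


def distribution_moments(values: np.ndarray) -> dict:
    """Mean, SD, skewness and excess kurtosis of a sample.

    Skewness and kurtosis are the standardized central-moment (biased,
    "population") definitions, with excess kurtosis 0 for a normal
    distribution. A constant sample yields SD 0 and NaN shape moments with
    ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError(f"need at least 4 finite values, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return {"mean": mean, "sd": 0.0, "skewness": float("nan"),
                "kurtosis": float("nan"), "degenerate": True}
    z = (x - mean) / x.std(ddof=0)
    return {
        "mean": mean,
        "sd": sd,
        "skewness": float(np.mean(z**3)),
        "kurtosis": float(np.mean(z**4) - 3.0),
        "degenerate": False,
    }
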
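"""Degree-distribution diagnostics.

The degree k of a node is the number of nonzero entries in its row of the
interaction matrix.  A random (Erdos-Renyi) graph on n nodes with edge
probability q has the binomial degree law

    p(k) = C(n-1, k) q^k (1-q)^(n-1-k),

which for n -> inf at fixed nq = lambda becomes the Poisson law
p(k) = exp(-lambda) lambda^k / k!  (mean = variance = lambda).  Scale-free
networks instead show a power-law tail p(k) ~ k^(-gamma).  The empirical
p(k) of each subnetwork is compared against the Poisson law with lambda
set to the observed mean degree (method of moments) and against a
least-squares power-law fit on the log-log histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .network_io import InteractionMatrix, SubnetworkGroup


@dataclass
class DegreeDistribution:
    """Per-node degrees and the empirical degree probabilities p(k)."""

    degrees: np.ndarray
    ks: np.ndarray          # observed degree values, ascending
    pk: np.ndarray          # empirical probability of each observed k

    @property
    def mean_k(self) -> float:
        return float(self.degrees.mean())

    @property
    def max_k(self) -> int:
        return int(self.degrees.max())


@dataclass(frozen=True)
class DegreeLaw:
    """Reference degree law: binomial random graph, Poisson limit, or power law."""

    family: str              # binomial_rg | poisson_limit | power_law
    n: int | None = None     # binomial_rg
    q: float | None = None   # binomial_rg
    lam: float | None = None  # poisson_limit
    gamma: float | None = None  # power_law

    def __post_init__(self):
        if self.family == "binomial_rg":
            if self.n is None or self.q is None or not 0.0 <= self.q <= 1.0:
                raise ValueError("binomial_rg needs n and q in [0, 1]")
        elif self.family == "poisson_limit":
            if self.lam is None or self.lam <= 0:
                raise ValueError("poisson_limit needs lambda > 0")
        elif self.family == "power_law":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("power_law needs gamma > 0")
        else:
            raise ValueError(f"unknown degree-law family {self.family!r}")


def degree_distribution(M: InteractionMatrix) -> DegreeDistribution:
    """Row sums of the interaction matrix and the empirical p(k)."""
    if M.size == 0:
        raise ValueError("empty interaction matrix")
    degrees = M.entries.sum(axis=1).astype(np.int64)
    ks, counts = np.unique(degrees, return_counts=True)
    return DegreeDistribution(degrees=degrees, ks=ks, pk=counts / len(degrees))


def reference_pmf(law: DegreeLaw, k, k_range: tuple[int, int] | None = None):
    """Evaluate a reference degree law at integer degree(s) k.

    ``power_law`` returns the unnormalized k^(-gamma) unless ``k_range``
    is given, in which case the values are normalized over that inclusive
    integer range.
    """
    k = np.asarray(k)
    if law.family == "binomial_rg":
        return scipy.stats.binom.pmf(k, law.n - 1, law.q)
    if law.family == "poisson_limit":
        return scipy.stats.poisson.pmf(k, law.lam)
    kk = np.asarray(k, dtype=float)
    vals = np.where(kk >= 1, np.maximum(kk, 1.0) ** -law.gamma, 0.0)
    if k_range is not None:
        lo, hi = k_range
        z = np.sum(np.arange(max(lo, 1), hi + 1, dtype=float) ** -law.gamma)
        vals = vals / z
    return vals


@dataclass
class DegreeFitSummary:
    """Goodness of a reference law against an empirical p(k)."""

    law: DegreeLaw
    total_variation: float
    residuals: np.ndarray    # pk_empirical - pk_law at each observed k
    fitted_gamma: float | None = None


def compare_degree_law(dist: DegreeDistribution, law: DegreeLaw) -> DegreeFitSummary:
    """Total-variation distance between empirical p(k) and a reference law.

    For ``poisson_limit`` the rate is set to the observed mean degree
    (method of moments) regardless of the value stored in ``law``.  For
    ``power_law`` gamma is fitted by least squares on log p(k) vs log k
    over k >= 1 and the fitted law (normalized over 1..max_k) is scored.
    TV is computed over k = 0..max_k plus the law's tail mass beyond.
    """
    kmax = int(max(dist.max_k, dist.ks[-1]))
    k_all = np.arange(kmax + 1)
    p_emp = np.zeros(kmax + 1)
    p_emp[dist.ks] = dist.pk

    fitted_gamma = None
    if law.family == "poisson_limit":
        law = DegreeLaw(family="poisson_limit", lam=dist.mean_k)
        p_law = reference_pmf(law, k_all)
        tail = float(scipy.stats.poisson.sf(kmax, law.lam))
    elif law.family == "power_law":
        mask = (dist.ks >= 1) & (dist.pk > 0)
        if mask.sum() < 3:
            raise ValueError("power-law fit needs >= 3 distinct degrees k >= 1")
        slope, intercept = np.polyfit(np.log(dist.ks[mask]),
                                      np.log(dist.pk[mask]), 1)
        fitted_gamma = -float(slope)
        law = DegreeLaw(family="power_law", gamma=fitted_gamma)
        p_law = reference_pmf(law, k_all, k_range=(1, kmax))
        tail = 0.0
    else:
        p_law = reference_pmf(law, k_all)
        tail = float(scipy.stats.binom.sf(kmax, law.n - 1, law.q))

    tv = 0.5 * (np.abs(p_emp - p_law).sum() + tail)
    residuals = p_emp[dist.ks] - p_law[dist.ks]
    return DegreeFitSummary(law=law, total_variation=float(tv),
                            residuals=residuals, fitted_gamma=fitted_gamma)


def group_degrees(group: SubnetworkGroup) -> np.ndarray:
    """Degrees of the group's incident nodes, without materializing M."""
    counts: dict[str, int] = {}
    for (u, v) in group.edges:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
    return np.array([counts[n] for n in group.incident_nodes], dtype=np.int64)


def summarize_groups(groups: list[SubnetworkGroup]) -> pd.DataFrame:
    """Per-group graph statistics: node count, frequency range, mean/max k."""
    rows = []
    for g in groups:
        deg = group_degrees(g)
        lo, hi = g.frequency_range
        rows.append({
            "group": g.label,
            "n_nodes": len(g.incident_nodes),
            "n_edges": len(g.edges),
            "freq_low": lo,
            "freq_high": hi,
            "mean_k": float(deg.mean()) if len(deg) else float("nan"),
            "max_k": int(deg.max()) if len(deg) else 0,
        })
    return pd.DataFrame(rows)
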
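"""Theoretical spacing laws, empirical P(s), and per-segment KS tests.

Two universal nearest-neighbor spacing laws are compared against the data:

* the beta-family surmise  P(s) = a_b s^b exp(-b_b s^2)  with the
  Gamma-function constants

      a_b = 2 G((2+b)/2)^(b+1) / G((1+b)/2)^(b+2),
      b_b = ( G((2+b)/2) / G((1+b)/2) )^2,

  which for b = 1 (GOE, the Wigner distribution) reduces to
  P(s) = (pi s / 2) exp(-pi s^2 / 4) with a_1 = pi/2, b_1 = pi/4 —
  eigenvalue repulsion, P(0) = 0;

* the Poisson law of RMT, P(s) = exp(-s) — uncorrelated eigenvalues
  (the exponential distribution of statistics).

Both are unit-mean by construction, matching unfolded spacings.

The empirical P(s) is a per-segment density histogram (bin width 0.2)
averaged pointwise across segments.  Each segment's n-1 spacings are
tested against a fully specified law with the one-sample
Kolmogorov-Smirnov test; a segment is consistent with the law when its
p-value exceeds the significance level (alpha = 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.special
import scipy.stats

from .spectral import Segment

logger = logging.getLogger("rmtnet")

#: crossover sample size between the exact and asymptotic KS p-value
KS_EXACT_MAX_M = 500


class SpacingLaw:
    """A fully specified (parameter-free) spacing distribution."""

    name: str

    def pdf(self, s):
        raise NotImplementedError

    def cdf(self, s):
        raise NotImplementedError


class WignerBeta(SpacingLaw):
    """Beta-family surmise; beta = 1 (GOE), 2 (GUE) or 4 (GSE)."""

    def __init__(self, beta: int = 1):
        if beta not in (1, 2, 4):
            raise ValueError(f"beta must be 1, 2 or 4, got {beta}")
        self.beta = beta
        g2 = scipy.special.gamma((2 + beta) / 2)
        g1 = scipy.special.gamma((1 + beta) / 2)
        self.a = 2 * g2 ** (beta + 1) / g1 ** (beta + 2)
        self.b = (g2 / g1) ** 2
        self.name = f"wigner_beta{beta}"

    def pdf(self, s):
        s = np.asarray(s, dtype=float)
        return self.a * s ** self.beta * np.exp(-self.b * s ** 2)

    def cdf(self, s):
        # closed form via the regularized lower incomplete gamma function;
        # the prefactor a*G((b+1)/2)/(2 b^((b+1)/2)) equals 1 identically
        s = np.asarray(s, dtype=float)
        return scipy.special.gammainc((self.beta + 1) / 2, self.b * s ** 2)


class PoissonLaw(SpacingLaw):
    """P(s) = exp(-s): spacings of uncorrelated levels."""

    name = "poisson"

    def pdf(self, s):
        return np.exp(-np.asarray(s, dtype=float))

    def cdf(self, s):
        return -np.expm1(-np.asarray(s, dtype=float))


WIGNER = WignerBeta(1)
POISSON = PoissonLaw()


# ---------------------------------------------------------------------------
# empirical P(s)


@dataclass
class SpacingHistogram:
    """Segment-averaged spacing density on a uniform grid from 0."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_segments_averaged: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def empirical_P_of_s(segments: list[Segment], bin_width: float = 0.2) -> SpacingHistogram:
    """Pointwise mean of per-segment normalized spacing histograms.

    Bins are left-closed right-open, start at 0, and extend past the
    largest observed spacing.  Degenerate segments are skipped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    usable = [seg for seg in segments if not seg.degenerate]
    n_skipped = len(segments) - len(usable)
    if n_skipped:
        logger.info("empirical_P_of_s: skipping %d degenerate segment(s)", n_skipped)
    if not usable:
        raise ValueError("all segments are degenerate; no spacings to histogram")
    smax = max(float(np.max(seg.spacings)) for seg in usable)
    n_bins = int(math.floor(smax / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    densities = np.empty((len(usable), n_bins))
    for i, seg in enumerate(usable):
        counts, _ = np.histogram(seg.spacings, bins=edges)
        densities[i] = counts / (len(seg.spacings) * bin_width)
    return SpacingHistogram(
        bin_edges=edges,
        density=densities.mean(axis=0),
        n_segments_averaged=len(usable),
    )


# ---------------------------------------------------------------------------
# hypothesis testing


@dataclass
class KSResult:
    """One-sample KS test of spacings against a spacing law."""

    law: str
    statistic: float
    p_value: float
    sample_size: int
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        return self.p_value > self.alpha


def ks_statistic(sample: np.ndarray, law: SpacingLaw) -> float:
    """Sup-distance D between the empirical and hypothesized cdf."""
    x = np.sort(np.asarray(sample, dtype=float))
    m = len(x)
    f = law.cdf(x)
    i = np.arange(1, m + 1)
    return float(np.max(np.maximum(i / m - f, f - (i - 1) / m)))


def ks_test(sample: np.ndarray, law: SpacingLaw, alpha: float = 0.05) -> KSResult:
    """One-sample two-sided KS test against a fully specified law.

    The p-value is exact for samples up to ``KS_EXACT_MAX_M`` points and
    uses the asymptotic Kolmogorov series beyond.
    """
    sample = np.asarray(sample, dtype=float)
    m = len(sample)
    if m < 5:
        raise ValueError(f"KS test needs at least 5 spacings, got {m}")
    method = "exact" if m <= KS_EXACT_MAX_M else "asymp"
    res = scipy.stats.kstest(sample, law.cdf, method=method)
    return KSResult(law=law.name, statistic=float(res.statistic),
                    p_value=float(res.pvalue), sample_size=m, alpha=alpha)


@dataclass
class SegmentClassification:
    """Per-segment KS outcomes for one law, in supplementary-table layout."""

    law: str
    alpha: float
    table: list[tuple[int, float, float, float, float]]  # index, lo, hi, center, p
    passing_indices: list[int]

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_passing(self) -> int:
        return len(self.passing_indices)

    @property
    def pass_fraction(self) -> float:
        return self.n_passing / self.n_tested if self.n_tested else float("nan")


def classify_segments(
    segments: list[Segment], law: SpacingLaw, alpha: float = 0.05
) -> tuple[list[Segment], SegmentClassification]:
    """KS-test every non-degenerate segment; keep those with p > alpha."""
    table = []
    passing: list[Segment] = []
    passing_idx: list[int] = []
    n_too_small = 0
    for seg in segments:
        if seg.degenerate:
            continue
        if len(seg.spacings) < 5:
            n_too_small += 1
            continue
        res = ks_test(seg.spacings, law, alpha=alpha)
        lo, hi = seg.boundary
        table.append((seg.index, lo, hi, seg.center, res.p_value))
        if res.passed:
            passing.append(seg)
            passing_idx.append(seg.index)
    if n_too_small:
        logger.info("classify_segments: %d segment(s) with <5 spacings skipped",
                    n_too_small)
    summary = SegmentClassification(law=law.name, alpha=alpha, table=table,
                                    passing_indices=passing_idx)
    return passing, summary
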
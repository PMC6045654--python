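"""Eigenvalue spectra, tail trimming, segmentation, and local unfolding.

The spectrum of the interaction matrix is sorted ascending, the 5% of
eigenvalues lying in the density tails is discarded, and the retained bulk
is cut into L contiguous segments of n eigenvalues each.  Within a segment
spanning [x_1, x_n] the local mean spacing is D = (x_n - x_1)/n, and each
eigenvalue is unfolded to

    lambda_i = (x_i - x_1) / D = n (x_i - x_1) / (x_n - x_1),

so the unfolded values run from 0 to n and the n-1 nearest-neighbor
spacings have mean n/(n-1) exactly.  Unfolding is invariant under affine
maps x -> a x + b (a > 0), so the matrix scaling convention is irrelevant.

At N = 8000 and 95% coverage this yields the segment counts
L = 76, 38, 25, 19 for n = 100, 200, 300, 400.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .network_io import InteractionMatrix

logger = logging.getLogger("rmtnet")


@dataclass
class Spectrum:
    """Eigenvalues sorted ascending, with a provenance label."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.values) < 0):
            raise ValueError("spectrum values must be sorted ascending")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SegmentationSpec:
    """Segment size n, spectrum coverage, and resulting segment count L."""

    n: int
    coverage: float
    L: int

    @staticmethod
    def plan(N: int, n: int, coverage: float = 0.95) -> "SegmentationSpec":
        kept = math.floor(coverage * N)
        return SegmentationSpec(n=n, coverage=coverage, L=kept // n)


@dataclass
class Segment:
    """A block of n consecutive eigenvalues with its unfolded spacings.

    ``degenerate`` marks segments of zero width (all raw values equal):
    those carry no spacing information and are excluded from statistics.
    """

    index: int
    raw: np.ndarray
    unfolded: np.ndarray | None
    spacings: np.ndarray | None
    degenerate: bool = False

    @property
    def boundary(self) -> tuple[float, float]:
        return float(self.raw[0]), float(self.raw[-1])

    @property
    def center(self) -> float:
        lo, hi = self.boundary
        return 0.5 * (lo + hi)

    @property
    def n(self) -> int:
        return len(self.raw)


def eigenvalues(M: InteractionMatrix | np.ndarray, source: str = "") -> Spectrum:
    """All real eigenvalues of a symmetric matrix, sorted ascending."""
    arr = M.entries if isinstance(M, InteractionMatrix) else np.asarray(M, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    if arr.size and not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if arr.size == 0:
        return Spectrum(values=np.empty(0), source=source)
    vals = scipy.linalg.eigvalsh(arr)
    return Spectrum(values=np.sort(vals), source=source)


def unfold(raw: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Unfold one segment; returns (unfolded values, spacings).

    Returns (None, None) for a degenerate segment (zero eigenvalue span).
    Zero spacings from exact degeneracies inside a non-degenerate segment
    are retained.
    """
    raw = np.asarray(raw, dtype=np.float64)
    n = len(raw)
    if n < 2:
        raise ValueError("a segment needs at least 2 eigenvalues")
    span = raw[-1] - raw[0]
    if span <= 0.0:
        return None, None
    lam = n * (raw - raw[0]) / span
    return lam, np.diff(lam)


def trim_and_segment(
    spec: Spectrum, n: int, coverage: float = 0.95
) -> tuple[list[Segment], SegmentationSpec]:
    """Trim the spectrum tails and cut the bulk into equal segments.

    ``floor(coverage * N)`` eigenvalues are kept: the tail loss is split
    symmetrically, the lower tail taking the ceiling half.  The kept run
    is cut into ``L = kept // n`` segments of exactly n values; the
    ``kept mod n`` leftover values are discarded evenly from both ends of
    the kept run (the extra one from the upper end).
    """
    if n < 2:
        raise ValueError("segment size n must be >= 2")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    N = len(spec)
    kept_count = math.floor(coverage * N)
    if kept_count < n:
        raise ValueError(
            f"too few eigenvalues: coverage keeps {kept_count} < segment size {n}"
        )
    drop = N - kept_count
    lo_drop = math.ceil(drop / 2)
    kept = spec.values[lo_drop: lo_drop + kept_count]

    L = kept_count // n
    leftover = kept_count - L * n
    lo_trim = leftover // 2
    used = kept[lo_trim: lo_trim + L * n]
    if drop or leftover:
        logger.info(
            "trim_and_segment(n=%d): dropped %d tail + %d leftover eigenvalues, L=%d",
            n, drop, leftover, L,
        )

    segments: list[Segment] = []
    n_degenerate = 0
    for i in range(L):
        raw = used[i * n: (i + 1) * n]
        lam, sp = unfold(raw)
        degen = lam is None
        n_degenerate += degen
        segments.append(Segment(index=i + 1, raw=raw, unfolded=lam,
                                spacings=sp, degenerate=degen))
    if n_degenerate:
        logger.warning("trim_and_segment(n=%d): %d degenerate segment(s) "
                       "excluded from spacing statistics", n, n_degenerate)
    return segments, SegmentationSpec(n=n, coverage=coverage, L=L)


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    np.savetxt(path, spec.values, fmt="%.12g")


def write_segment_table(segments: list[Segment], path: str | Path) -> None:
    """TSV: index, x_low, x_high, center, n."""
    with Path(path).open("w") as fh:
        fh.write("index\tx_low\tx_high\tcenter\tn\n")
        for seg in segments:
            lo, hi = seg.boundary
            fh.write(f"{seg.index}\t{lo:.10g}\t{hi:.10g}\t{seg.center:.10g}\t{seg.n}\n")
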
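"""Profile-similarity measures: Spearman rank correlation and ratio histograms.

Spearman is used rather than Pearson because the log2-ratio distributions of
label-free proteomic profiles are not well described by any parametric
family; the rank correlation is invariant under any strictly monotone
transform of either profile.  Ties receive average ranks (the rank-Pearson
definition), which reduces to the classical ``1 - 6*sum(d^2)/(n(n^2-1))``
formula when all ranks are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from pathtriad.profile_io import ProteinRatioProfile


@dataclass
class SimilarityResult:
    """Spearman coefficient plus the plot-ready data behind it."""

    r_s: float | None
    n: int
    scatter: np.ndarray | None = None  # shape (n, 2): paired log2 ratios
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (bin_edges, counts)


def spearman(x: ProteinRatioProfile, y: ProteinRatioProfile) -> SimilarityResult:
    """Spearman rank correlation over the proteins shared by two profiles.

    Only proteins present in both profiles enter the calculation; at least
    three shared proteins are required for a coefficient to be reported.
    """
    shared = sorted(x.symbols & y.symbols)
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 shared proteins for a Spearman coefficient, "
            f"got {len(shared)} between {x.name!r} and {y.name!r}"
        )
    xv = np.array([x.ratio(s) for s in shared], dtype=float)
    yv = np.array([y.ratio(s) for s in shared], dtype=float)
    r_s = float(stats.spearmanr(xv, yv).statistic)
    return SimilarityResult(r_s=r_s, n=len(shared), scatter=np.column_stack([xv, yv]))


def ratio_histogram(
    p: ProteinRatioProfile, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a profile's log2 ratios with bins centred on zero.

    Bin edges are placed at odd multiples of ``bin_width / 2`` so that 0 is
    a bin centre — the spike of unchanged proteins falls into a single bin
    instead of being split at an edge.  Counts sum to the profile size.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    values = p.as_series().to_numpy()
    if len(values) == 0:
        raise ValueError(f"profile {p.name!r} is empty")
    # smallest symmetric range of zero-centred bins covering all values
    k_lo = int(np.floor((values.min() + bin_width / 2) / bin_width))
    k_hi = int(np.ceil((values.max() - bin_width / 2) / bin_width))
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * bin_width
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts
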
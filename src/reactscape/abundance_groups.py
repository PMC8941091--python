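"""Abundance-group thresholds from rank abundance curve curvature.

Instead of a fixed relative-abundance cutoff, the abundant/moderate/rare
split is derived empirically: the rank abundance curve (per-OTU mean CSS
abundance, sorted descending) is inspected on a log10 abundance scale and
the two leading local maxima of its downward acceleration — the second
discrete difference along rank, after moving-average smoothing — mark where
the curve's decay rate breaks.  The abundances at those two ranks become the
abundant/moderate and moderate/rare thresholds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal

from .tables import NormalizedTable


@dataclasses.dataclass
class AbundanceThresholds:
    habitat: str
    t_abundant: float
    t_moderate: float
    rank_abundant: int
    rank_moderate: int
    single_threshold: bool = False  # True when only one curvature break was found

    def __post_init__(self):
        if not self.single_threshold and not self.t_abundant > self.t_moderate > 0:
            raise ValueError("thresholds must satisfy t_abundant > t_moderate > 0")


def rank_abundance_curve(table: NormalizedTable, sample_ids=None) -> np.ndarray:
    """Per-OTU mean abundance over the selected samples, sorted descending.

    Zero-mean OTUs are dropped; the result is the stratum's rank abundance
    curve.
    """
    df = table.values if sample_ids is None else table.values[list(sample_ids)]
    if df.shape[1] == 0:
        raise ValueError("empty stratum")
    means = df.mean(axis=1).to_numpy()
    means = means[means > 0]
    if means.size < 3:
        raise ValueError("need at least 3 OTUs with nonzero mean abundance")
    return np.sort(means)[::-1]


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    sm = np.convolve(yp, kernel, mode="same")
    return sm[pad : pad + len(y)] if pad else sm


def acceleration_profile(curve: np.ndarray, smooth_window: int = 5) -> np.ndarray:
    """Downward acceleration of log10 abundance along rank.

    Element i corresponds to rank i+2 (1-based): the negated second
    difference of the smoothed log10 curve.  A pure geometric decay
    (log-linear in rank) is zero everywhere; breaks toward a steeper decay
    produce positive peaks.
    """
    y = _smooth(np.log10(curve), smooth_window)
    return -np.diff(y, n=2)


def acceleration_thresholds(
    curve: np.ndarray, smooth_window: int = 5, habitat: str = "pooled"
) -> AbundanceThresholds:
    """Thresholds at the first and second local acceleration maxima.

    Raises if the curve is too short; with fewer than two interior local
    maxima, a flagged single-threshold result (or an error when none exist)
    is returned.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 5:
        raise ValueError("rank abundance curve must have at least 5 OTUs")
    # rounding removes float jitter so flat plateaus stay flat and peak
    # ranks are exactly invariant to rescaling the curve
    acc = np.round(acceleration_profile(curve, smooth_window), 12)
    # interior local maxima of the acceleration signal, in rank order;
    # a minimum separation of the smoothing window merges the ripple that
    # smoothing spreads around a single curvature break
    maxima, _ = signal.find_peaks(acc, height=1e-10, distance=max(1, smooth_window))
    maxima = list(maxima)
    if not maxima:
        raise ValueError("no local acceleration maxima: curve has no curvature breaks")
    ranks = [int(i) + 2 for i in maxima]  # acc[i] sits at 1-based rank i+2
    r1 = ranks[0]
    if len(ranks) == 1:
        return AbundanceThresholds(
            habitat=habitat,
            t_abundant=float(curve[r1 - 1]),
            t_moderate=float(curve[r1 - 1]),
            rank_abundant=r1,
            rank_moderate=r1,
            single_threshold=True,
        )
    r2 = ranks[1]
    return AbundanceThresholds(
        habitat=habitat,
        t_abundant=float(curve[r1 - 1]),
        t_moderate=float(curve[r2 - 1]),
        rank_abundant=r1,
        rank_moderate=r2,
    )


def assign_abundance_groups(
    table: NormalizedTable, thresholds: AbundanceThresholds, sample_ids=None
) -> pd.Series:
    """Label each OTU abundant / moderate / rare / absent by its stratum mean."""
    df = table.values if sample_ids is None else table.values[list(sample_ids)]
    means = df.mean(axis=1)
    labels = pd.Series("absent", index=means.index, name="group")
    labels[means > 0] = "rare"
    labels[means >= thresholds.t_moderate] = "moderate"
    labels[means >= thresholds.t_abundant] = "abundant"
    labels[means == 0] = "absent"
    return labels


def piecewise_geometric_curve(
    break_ranks, decay_rates, n_ranks: int, top: float = 1e4
) -> np.ndarray:
    """Synthetic rank abundance curve with planted decay-rate breaks.

    Geometric (log-linear in rank) segments separated at ``break_ranks``,
    each segment decaying by its rate per rank step; used to validate
    threshold recovery since the curvature maxima are exactly at the breaks.
    """
    if len(decay_rates) != len(break_ranks) + 1:
        raise ValueError("need one decay rate per segment")
    log_y = np.empty(n_ranks)
    log_y[0] = np.log10(top)
    bounds = list(break_ranks) + [n_ranks]
    seg = 0
    for i in range(1, n_ranks):
        if i + 1 > bounds[seg] and seg < len(decay_rates) - 1:
            seg += 1
        log_y[i] = log_y[i - 1] - decay_rates[seg]
    return 10.0**log_y
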
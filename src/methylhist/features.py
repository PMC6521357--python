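"""Histogram features: p-value-weighted, distance-voted 10-bin histograms.

Each cytosine's evidence is condensed into a bin value
``b = |m1 - m2| * exp(1 - p)`` which boosts significant differences; the b
track is smoothed over neighbouring cytosines (spatial correlation), min-max
scaled per chromosome to [0, 1], and then, for every cytosine, the scaled
values of the w surrounding sites cast distance-weighted votes into a 10-bin
histogram that is normalized to sum to one.  That histogram is the feature
vector the classifier sees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureParams",
    "bin_value",
    "smooth",
    "scale_chromosome",
    "vote_weight",
    "histogram_feature",
    "featurize_chromosome",
]


@dataclass(frozen=True)
class FeatureParams:
    """Feature hyperparameters.

    w           window size in cytosines (odd; 11 for CG, 51 for CH)
    d           maximum vote distance in bp
    bins        histogram bin count over [0, 1]
    smooth_span moving-average span in cytosines (odd)
    """

    w: int = 11
    d: float = 250.0
    bins: int = 10
    smooth_span: int = 3

    def __post_init__(self) -> None:
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("w must be odd and >= 3")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        if self.smooth_span < 1 or self.smooth_span % 2 == 0:
            raise ValueError("smooth_span must be odd and >= 1")


CG_PARAMS = FeatureParams(w=11)
CH_PARAMS = FeatureParams(w=51)


def default_params(context: str) -> FeatureParams:
    """Context-specific defaults: window 11 for CG, 51 for CH/CHG/CHH."""
    return CG_PARAMS if context == "CG" else CH_PARAMS


def bin_value(m1, m2, p):
    """b = |m1 − m2| · e^(1 − p); range [0, e]."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    p = np.asarray(p, dtype=float)
    for name, v in (("m1", m1), ("m2", m2), ("p", p)):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    b = np.abs(m1 - m2) * np.exp(1.0 - p)
    return b if b.ndim else float(b)


def smooth(b_track, span: int = 3):
    """Centered moving average over cytosine index, one chromosome at a time.

    The window shrinks symmetrically near the chromosome ends, so the first
    and last values are averaged over fewer sites (a single site at the very
    edge) rather than padded with invented data.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    x = np.asarray(b_track, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    h = span // 2
    idx = np.arange(n)
    hw = np.minimum(h, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = (csum[idx + hw + 1] - csum[idx - hw]) / (2 * hw + 1)
    return out


def scale_chromosome(track):
    """Min-max scale a per-chromosome track to [0, 1]; constant tracks map to 0."""
    x = np.asarray(track, dtype=float)
    if len(x) == 0:
        return x.copy()
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def vote_weight(l, l_c, d: float):
    """Distance vote v = 1 − |l − l_c|/d if |l − l_c| < d, else 0."""
    if d <= 0:
        raise ValueError("d must be positive")
    dist = np.abs(np.asarray(l, dtype=float) - np.asarray(l_c, dtype=float))
    v = np.where(dist < d, 1.0 - dist / d, 0.0)
    return v if v.ndim else float(v)


def _bin_index(b_s, bins: int) -> np.ndarray:
    # b_s = 1.0 falls in the top bin (clamped floor)
    return np.minimum((np.asarray(b_s, dtype=float) * bins).astype(int), bins - 1)


def histogram_feature(positions, b_s, center_index: int, params: FeatureParams):
    """Vote histogram for one cytosine from its w-site window.

    ``positions`` / ``b_s`` describe the (already windowed or full) track;
    the window of ``params.w`` sites centered on ``center_index`` is used,
    truncated at the track ends.  Each windowed site adds its distance vote
    to the bin indexed by its scaled value; the tally is normalized to sum
    to one, or returned as the all-zero sentinel when no site votes.
    """
    positions = np.asarray(positions, dtype=float)
    b_s = np.asarray(b_s, dtype=float)
    n = len(positions)
    h = params.w // 2
    lo = max(0, center_index - h)
    hi = min(n, center_index + h + 1)
    v = vote_weight(positions[lo:hi], positions[center_index], params.d)
    bins = _bin_index(b_s[lo:hi], params.bins)
    hist = np.zeros(params.bins)
    np.add.at(hist, bins, v)
    total = hist.sum()
    if total <= 0:
        return hist
    return hist / total


def featurize_chromosome(positions, b_s, params: FeatureParams) -> np.ndarray:
    """Feature matrix for a sorted single-chromosome track (one row per site).

    Equivalent to calling :func:`histogram_feature` at every site, computed
    with a vectorized sweep over window offsets.  Rows sum to 1 except for
    the all-zero degenerate sentinel.
    """
    positions = np.asarray(positions, dtype=float)
    b_s = np.asarray(b_s, dtype=float)
    n = len(positions)
    hist = np.zeros((n, params.bins))
    if n == 0:
        return hist
    h = params.w // 2
    bins = _bin_index(b_s, params.bins)
    for off in range(-h, h + 1):
        i0 = max(0, -off)
        i1 = min(n, n - off)
        if i0 >= i1:
            continue
        centers = np.arange(i0, i1)
        others = centers + off
        v = vote_weight(positions[others], positions[centers], params.d)
        np.add.at(hist, (centers, bins[others]), v)
    totals = hist.sum(axis=1, keepdims=True)
    nz = totals[:, 0] > 0
    hist[nz] /= totals[nz]
    return hist
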
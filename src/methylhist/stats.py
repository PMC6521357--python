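"""Per-cytosine differential statistics.

For each cytosine the two treatment groups are compared through a
coverage-weighted test: with replicates, a weighted logistic regression of
group label on methylation level and a chi-square(1) likelihood-ratio test
against the intercept-only model; without replicates, a pooled two-proportion
z-test.  Read coverage enters as an observation weight
``w(t) = 2/(1+exp(-t/scale)) - 1`` so that uncovered sites carry no evidence
and deeply covered sites saturate near weight 1.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "COVERAGE_SCALE",
    "RIDGE",
    "P_FLOOR",
    "methylation_level",
    "coverage_weight",
    "pvalue_replicates",
    "pvalue_single",
    "align_counts",
    "pair_site_stats",
]

log = logging.getLogger(__name__)

COVERAGE_SCALE = 10.0  # reads; w(10) ~ 0.46, w(30) ~ 0.91
RIDGE = 1e-4           # slope penalty stabilizing separated fits
P_FLOOR = 1e-300
_MAX_ITER = 50
_ETA_CLIP = 35.0


def methylation_level(mc, t):
    """mc/t elementwise; 0 where t == 0 (such sites get zero weight anyway)."""
    mc = np.asarray(mc, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(mc > t):
        raise ValueError("mc exceeds t")
    if np.any(mc < 0) or np.any(t < 0):
        raise ValueError("negative counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        lvl = np.where(t > 0, mc / np.maximum(t, 1.0), 0.0)
    return lvl if lvl.ndim else float(lvl)


def coverage_weight(t, scale: float = COVERAGE_SCALE):
    """Logistic coverage weight 2·sigma(t/scale) − 1, in [0, 1).

    Strictly increasing in t, 0 at t=0, approaching 1 at high depth.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    t = np.asarray(t, dtype=float)
    w = 2.0 * expit(t / scale) - 1.0
    return w if w.ndim else float(w)


def _weighted_loglik(y: np.ndarray, w: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return np.sum(w * (y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)), axis=-1)


def _lrt_track(
    x: np.ndarray, y: np.ndarray, w: np.ndarray,
    ridge: float = RIDGE, max_iter: int = _MAX_ITER,
) -> np.ndarray:
    """Vectorized weighted-logistic LRT over many sites at once.

    x : (n_sites, n_obs) methylation levels (predictor)
    y : (n_obs,) binary group labels (outcome)
    w : (n_sites, n_obs) observation weights

    Returns the chi-square(1) tail probability of twice the log-likelihood
    gain of {intercept + level} over {intercept only}.  The slope carries a
    small ridge penalty so perfectly separating sites stay finite; the test
    statistic itself uses the unpenalized log-likelihood.
    """
    n, m = x.shape
    y = np.broadcast_to(y, (n, m)).astype(float)
    sw = w.sum(axis=1)
    active = sw > 0
    # intercept-only MLE is the weighted mean (exact; intercept unpenalized)
    mu0 = np.where(active, (w * y).sum(axis=1) / np.maximum(sw, 1e-30), 0.5)
    mu0c = np.clip(mu0, 1e-12, 1 - 1e-12)
    ll0 = _weighted_loglik(y, w, mu0c[:, None])

    b0 = np.log(mu0c / (1 - mu0c))
    b1 = np.zeros(n)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        r = w * (y - mu)
        v = w * mu * (1.0 - mu)
        g0 = r.sum(axis=1)
        g1 = (r * x).sum(axis=1) - ridge * b1
        h00 = v.sum(axis=1) + 1e-12
        h01 = (v * x).sum(axis=1)
        h11 = (v * x * x).sum(axis=1) + ridge + 1e-12
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        s0 = (h11 * g0 - h01 * g1) / det
        s1 = (h00 * g1 - h01 * g0) / det
        # damp huge steps (separation) instead of overshooting
        step = np.maximum(np.abs(s0), np.abs(s1))
        damp = np.where(step > 10.0, 10.0 / np.maximum(step, 1e-30), 1.0)
        b0 = b0 + damp * s0
        b1 = b1 + damp * s1
        if np.max(step, initial=0.0) < 1e-10:
            break

    eta = np.clip(b0[:, None] + b1[:, None] * x, -_ETA_CLIP, _ETA_CLIP)
    ll1 = _weighted_loglik(y, w, expit(eta))
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = chi2.sf(stat, df=1)
    # no contrast -> no evidence
    wsum_g1 = (w * y).sum(axis=1)
    wsum_g0 = (w * (1 - y)).sum(axis=1)
    p = np.where((wsum_g1 <= 0) | (wsum_g0 <= 0), 1.0, p)
    return np.clip(p, P_FLOOR, 1.0)


def pvalue_replicates(levels, labels, weights, ridge: float = RIDGE) -> float:
    """Weighted logistic-regression LRT p-value for one cytosine.

    ``levels`` are per-replicate methylation levels (continuous predictor),
    ``labels`` the binary group membership (outcome), ``weights`` the
    per-replicate coverage weights.  Requires at least two observations per
    group; when one group carries zero total weight the site has no evidence
    and p = 1 is returned with a warning.
    """
    x = np.asarray(levels, dtype=float)[None, :]
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)[None, :]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two observations per group")
    if w.sum() == 0 or (w[0][y == 1]).sum() == 0 or (w[0][y == 0]).sum() == 0:
        warnings.warn("site carries no evidence (zero weight in a group); p = 1")
        return 1.0
    return float(_lrt_track(x, y, w, ridge=ridge)[0])


def pvalue_single(mc1, t1, mc2, t2):
    """Two-sided pooled two-proportion z-test (no-replicate comparison).

    Pooled proportion p̂ = (mc1+mc2)/(t1+t2);
    z = (m1 − m2) / sqrt(p̂(1−p̂)(1/t1 + 1/t2)); p = 2(1 − Φ(|z|)).
    Degenerate pools (p̂ ∈ {0, 1}) and zero-coverage sites give p = 1.
    """
    mc1 = np.asarray(mc1, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    mc2 = np.asarray(mc2, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    scalar = mc1.ndim == 0
    mc1, t1, mc2, t2 = np.atleast_1d(mc1, t1, mc2, t2)
    covered = (t1 > 0) & (t2 > 0)
    if not covered.all():
        warnings.warn("zero-coverage site(s) in z-test; returning p = 1 there")
    t1s = np.maximum(t1, 1.0)
    t2s = np.maximum(t2, 1.0)
    m1 = mc1 / t1s
    m2 = mc2 / t2s
    pooled = (mc1 + mc2) / np.maximum(t1 + t2, 1.0)
    var = pooled * (1.0 - pooled) * (1.0 / t1s + 1.0 / t2s)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (m1 - m2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where((pooled <= 0) | (pooled >= 1) | ~covered, 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)
    return float(p[0]) if scalar else p


# ---------------------------------------------------------------------------
# track-level computation for the calling pipeline


def align_counts(tables) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Align samples on the union of (chrom, pos) keys.

    Returns (index frame with chrom/pos sorted, MC, T) where MC and T are
    (n_sites, n_samples) arrays; a site absent from a sample has t = 0 and
    therefore zero weight downstream.
    """
    keyed = []
    for tbl in tables:
        df = tbl.sites.set_index(["chrom", "pos"])[["mc", "t"]]
        if df.index.has_duplicates:
            raise ValueError(f"duplicate (chrom, pos) in sample {tbl.sample_id}")
        keyed.append(df)
    union = keyed[0].index
    for df in keyed[1:]:
        union = union.union(df.index)
    union = union.sortlevel(["chrom", "pos"])[0] if union.nlevels else union
    n = len(union)
    mc = np.zeros((n, len(keyed)), dtype=np.int64)
    t = np.zeros((n, len(keyed)), dtype=np.int64)
    for j, df in enumerate(keyed):
        sub = df.reindex(union)
        mc[:, j] = sub["mc"].fillna(0).to_numpy()
        t[:, j] = sub["t"].fillna(0).to_numpy()
    idx = union.to_frame(index=False)
    return idx, mc, t


def pair_site_stats(
    group1, group2, scale: float = COVERAGE_SCALE, ridge: float = RIDGE
) -> pd.DataFrame:
    """Per-site m1, m2 and p for a two-group comparison.

    ``group1`` / ``group2`` are lists of :class:`~methylhist.io.MethylomeTable`
    replicates.  Group mean levels are coverage-weighted means of replicate
    levels.  The test depends on design: replicated groups use the weighted
    logistic LRT; single-replicate designs (or a singleton group, whose LRT
    degrees of freedom collapse) use the pooled z-test on summed counts.

    Returns a frame with columns chrom, pos, m1, m2, p.
    """
    n1, n2 = len(group1), len(group2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need at least one sample")
    idx, mc, t = align_counts(list(group1) + list(group2))
    lvl = methylation_level(mc, t)
    w = coverage_weight(t, scale)
    cols1 = np.arange(n1)
    cols2 = np.arange(n1, n1 + n2)

    def _gmean(cols):
        ws = w[:, cols].sum(axis=1)
        num = (w[:, cols] * lvl[:, cols]).sum(axis=1)
        return np.where(ws > 0, num / np.maximum(ws, 1e-30), 0.0)

    m1 = _gmean(cols1)
    m2 = _gmean(cols2)

    if n1 >= 2 and n2 >= 2:
        labels = np.r_[np.zeros(n1), np.ones(n2)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = _lrt_track(lvl, labels, w, ridge=ridge)
    else:
        # pooled counts per group; exact design for 1 vs 1, fallback otherwise
        mc1 = mc[:, cols1].sum(axis=1)
        t1 = t[:, cols1].sum(axis=1)
        mc2 = mc[:, cols2].sum(axis=1)
        t2 = t[:, cols2].sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = pvalue_single(mc1, t1, mc2, t2)
        p = np.atleast_1d(p)

    out = idx.copy()
    out["m1"] = m1
    out["m2"] = m2
    out["p"] = p
    log.debug("pair_site_stats: %d sites, design %dx%d", len(out), n1, n2)
    return out
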
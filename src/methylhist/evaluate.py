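"""Truth-versus-prediction scoring by reciprocal interval overlap.

A truth region counts as recovered at stringency f when some prediction
overlaps it by at least f of both intervals' lengths (reciprocal overlap =
min of the two one-sided fractions); TPR and PPV are the recovered fractions
of truth and predictions respectively, swept over a 50-100% grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "EvalCurve",
    "reciprocal_overlap",
    "tpr_ppv",
    "replicate_study",
    "boundary_displacements",
]


@dataclass
class EvalCurve:
    """TPR/PPV over a reciprocal-overlap threshold grid (percent)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    ppv: np.ndarray
    n_truth: int
    n_pred: int

    def at(self, threshold: float) -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.tpr[i]), float(self.ppv[i])


def _interval(x) -> tuple[str, float, float]:
    if hasattr(x, "chrom"):
        return x.chrom, float(x.start), float(x.stop)
    return str(x[0]), float(x[1]), float(x[2])


def reciprocal_overlap(a, b) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 across chromosomes."""
    ca, sa, ea = _interval(a)
    cb, sb, eb = _interval(b)
    if ca != cb:
        return 0.0
    ov = min(ea, eb) - max(sa, sb)
    if ov <= 0:
        return 0.0
    return min(ov / (ea - sa), ov / (eb - sb))


def _best_overlaps(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    """Per-truth and per-prediction best reciprocal overlap with the other set."""
    best_t = np.zeros(len(truth))
    best_p = np.zeros(len(predicted))
    by_chrom: dict[str, list[tuple[int, float, float]]] = {}
    for j, p in enumerate(predicted):
        c, s, e = _interval(p)
        by_chrom.setdefault(c, []).append((j, s, e))
    for i, t in enumerate(truth):
        c, s, e = _interval(t)
        for j, ps, pe in by_chrom.get(c, ()):
            ov = min(e, pe) - max(s, ps)
            if ov <= 0:
                continue
            rec = min(ov / (e - s), ov / (pe - ps))
            if rec > best_t[i]:
                best_t[i] = rec
            if rec > best_p[j]:
                best_p[j] = rec
    return best_t, best_p


DEFAULT_GRID = np.arange(50, 101, 5)


def tpr_ppv(truth, predicted, thresholds=DEFAULT_GRID) -> EvalCurve:
    """Recovery curves over the reciprocal-overlap grid (percent units).

    TPR: truth regions with at least one prediction at reciprocal overlap
    >= f, out of all truth regions.  PPV: predictions with at least one
    truth at >= f, out of all predictions (0 when there are none).
    Many-to-one matches are allowed, per the count-based definitions.
    """
    truth = list(truth)
    predicted = list(predicted)
    if not truth:
        raise ValueError("truth set must be non-empty")
    thresholds = np.asarray(thresholds, dtype=float)
    best_t, best_p = _best_overlaps(truth, predicted)
    eps = 1e-12
    tpr = np.array([(best_t >= f / 100.0 - eps).mean() for f in thresholds])
    if predicted:
        ppv = np.array([(best_p >= f / 100.0 - eps).mean() for f in thresholds])
    else:
        ppv = np.zeros(len(thresholds))
        tpr = np.zeros(len(thresholds))
    return EvalCurve(
        thresholds=thresholds, tpr=tpr, ppv=ppv,
        n_truth=len(truth), n_pred=len(predicted),
    )


def replicate_study(
    cfg, pipeline: Callable, n_sims: int = 5, thresholds=DEFAULT_GRID
) -> pd.DataFrame:
    """Mean and SD of TPR/PPV over independent simulation seeds.

    ``pipeline(cfg)`` must run one simulate -> call round and return
    (truth regions, predicted regions).  Seeds are ``cfg.seed + i``.
    """
    from dataclasses import replace

    curves = []
    for i in range(n_sims):
        truth, predicted = pipeline(replace(cfg, seed=cfg.seed + i))
        curves.append(tpr_ppv(truth, predicted, thresholds))
    tpr = np.vstack([c.tpr for c in curves])
    ppv = np.vstack([c.ppv for c in curves])
    return pd.DataFrame(
        {
            "threshold": np.asarray(thresholds, dtype=float),
            "tpr_mean": tpr.mean(axis=0),
            "tpr_sd": tpr.std(axis=0, ddof=0),
            "ppv_mean": ppv.mean(axis=0),
            "ppv_sd": ppv.std(axis=0, ddof=0),
        }
    )


def boundary_displacements(
    truth, predicted, site_positions, min_overlap: float = 0.5
) -> np.ndarray:
    """Boundary error in cytosine positions for matched truth/prediction pairs.

    For every truth region whose best-matching prediction reaches the
    reciprocal-overlap floor, counts how many sorted track sites separate
    the true and predicted start, and likewise the stops; returns the
    flattened per-edge displacement array.  ``site_positions`` are the
    1-based coordinates of the full sorted track on the same chromosome
    set (single-chromosome benchmarks pass one array).
    """
    pos = np.sort(np.asarray(site_positions))
    out = []
    for t in truth:
        best, best_p = 0.0, None
        for p in predicted:
            rec = reciprocal_overlap(t, p)
            if rec > best:
                best, best_p = rec, p
        if best_p is None or best < min_overlap:
            continue
        ct, st, et = _interval(t)
        cp, sp, ep = _interval(best_p)
        for a, b in ((st, sp), (et, ep)):
            lo, hi = sorted((a, b))
            # sites strictly between the two boundary coordinates (0-based bp)
            out.append(int(np.searchsorted(pos - 1, hi, side="left")
                           - np.searchsorted(pos - 1, lo, side="left")))
    return np.asarray(out, dtype=int)
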
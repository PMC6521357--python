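"""Training-set construction, linear max-margin training and score calibration.

Every cytosine inside a labeled region is an independent training sample:
its 10-bin histogram feature with the region's DMR/non-DMR label.  A linear
soft-margin classifier (hinge loss, class-balanced) separates the two, and a
Platt-style logistic calibration maps decision values into (0, 1) prediction
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .features import FeatureParams, default_params
from .io import RegionLabel
from . import features as _feat
from . import stats as _stats

__all__ = [
    "TrainedModel",
    "TrainingSet",
    "TRAINING_FILTERS",
    "select_training_regions",
    "build_training_set",
    "train",
    "predict_scores",
]


@dataclass
class TrainedModel:
    """Linear decision weights plus calibration and feature hyperparameters."""

    weights: np.ndarray          # length = bins
    intercept: float
    calib_a: float               # score = sigma(calib_a * decision + calib_b)
    calib_b: float
    params: FeatureParams
    context: str                 # "CG" or "CH"
    version: str = "1.0"

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.weights):
            raise ValueError(
                f"feature width {X.shape[-1] if X.ndim else '?'} != {len(self.weights)}"
            )
        return X @ self.weights + self.intercept


@dataclass
class TrainingSet:
    """Feature rows with binary labels (1 = DMR) and region provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray  # region index per row

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")


# Region-level selection thresholds by context: (dmr_min_diff, nondmr_max_diff,
# min_len, max_len).  CG: strong differences in medium-size regions; CH
# methylation differences are much smaller, with a wider size range.
TRAINING_FILTERS = {
    "CG": {"dmr_min_diff": 0.3, "nondmr_max_diff": 0.1, "len_range": (500, 2500)},
    "CH": {"dmr_min_diff": 0.05, "nondmr_max_diff": 0.02, "len_range": (500, 5000)},
}


def select_training_regions(candidates, context: str = "CG") -> list[RegionLabel]:
    """Label candidate regions as DMR / nonDMR by the context-specific filters.

    ``candidates`` is an iterable of (chrom, start, stop, mean_abs_diff)
    records (attribute or tuple access).  A candidate inside the size range
    becomes DMR when its mean |m1−m2| exceeds the context's DMR threshold,
    nonDMR when below the non-DMR ceiling; everything else is dropped.
    """
    if context not in TRAINING_FILTERS:
        raise ValueError(f"context must be one of {sorted(TRAINING_FILTERS)}")
    flt = TRAINING_FILTERS[context]
    lo, hi = flt["len_range"]
    out: list[RegionLabel] = []
    for c in candidates:
        chrom, start, stop, diff = (
            (c.chrom, c.start, c.stop, c.mean_abs_diff)
            if hasattr(c, "mean_abs_diff")
            else (c[0], c[1], c[2], c[3])
        )
        length = stop - start
        if not (lo <= length <= hi):
            continue
        if diff > flt["dmr_min_diff"]:
            out.append(RegionLabel(chrom, start, stop, "DMR"))
        elif diff < flt["nondmr_max_diff"]:
            out.append(RegionLabel(chrom, start, stop, "nonDMR"))
    if not any(r.label == "DMR" for r in out) or not any(
        r.label == "nonDMR" for r in out
    ):
        raise ValueError("training filters left no region in one of the classes")
    return out


def compute_site_features(
    group1, group2, params: FeatureParams
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genome-wide per-site stats and feature matrix for a group pair.

    Returns (stats frame with chrom/pos/m1/m2/p/b/b_s, feature matrix).
    The b track is smoothed then min-max scaled per chromosome before
    voting, so windows see their flanking genomic context.
    """
    st = _stats.pair_site_stats(group1, group2)
    st["b"] = _feat.bin_value(st["m1"].to_numpy(), st["m2"].to_numpy(), st["p"].to_numpy())
    b_s = np.empty(len(st))
    X = np.zeros((len(st), params.bins))
    for _, idx in st.groupby("chrom", sort=False).indices.items():
        track = st["b"].to_numpy()[idx]
        sm = _feat.smooth(track, params.smooth_span)
        sc = _feat.scale_chromosome(sm)
        b_s[idx] = sc
        X[idx] = _feat.featurize_chromosome(st["pos"].to_numpy()[idx], sc, params)
    st["b_s"] = b_s
    return st, X


def _rows_in_regions(st: pd.DataFrame, regions) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row mask, labels and provenance for sites falling inside labeled regions."""
    take: list[int] = []
    labels: list[int] = []
    prov: list[int] = []
    pos0 = st["pos"].to_numpy() - 1  # 0-based site coordinate
    chroms = st["chrom"].to_numpy()
    for ridx, r in enumerate(regions):
        mask = (chroms == r.chrom) & (pos0 >= r.start) & (pos0 < r.stop)
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            warnings.warn(
                f"labeled region {r.chrom}:{r.start}-{r.stop} contains no covered "
                "cytosine; skipped"
            )
            continue
        take.extend(hits.tolist())
        labels.extend([1 if r.label == "DMR" else 0] * len(hits))
        prov.extend([ridx] * len(hits))
    return np.asarray(take, dtype=int), np.asarray(labels, dtype=int), np.asarray(prov, dtype=int)


def build_training_set(group1, group2, regions, params: FeatureParams) -> TrainingSet:
    """Featurize the genome and collect rows for cytosines in labeled regions."""
    if not regions:
        raise ValueError("no labeled regions supplied")
    st, X = compute_site_features(group1, group2, params)
    take, labels, prov = _rows_in_regions(st, regions)
    if len(take) == 0:
        raise ValueError("no labeled region contained a covered cytosine")
    return TrainingSet(features=X[take], labels=labels, provenance=prov)


def train(ts: TrainingSet, C: float = 1.0, seed: int = 0,
          params: FeatureParams | None = None, context: str = "CG") -> TrainedModel:
    """Fit the linear soft-margin classifier and Platt calibration.

    Class weights are balanced (DMR cytosines are the rarer class in real
    training data); the calibration is a 1-D logistic fit of the training
    decision values against the labels, giving scores in (0, 1).
    """
    classes = np.unique(ts.labels)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    params = params or default_params(context)
    clf = LinearSVC(C=C, class_weight="balanced", random_state=seed, max_iter=20000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(ts.features, ts.labels)
    decision = clf.decision_function(ts.features)
    calib = LogisticRegression(C=1e6, max_iter=1000)
    calib.fit(decision[:, None], ts.labels)
    return TrainedModel(
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        calib_a=float(calib.coef_[0, 0]),
        calib_b=float(calib.intercept_[0]),
        params=params,
        context=context,
    )


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Calibrated prediction scores in (0, 1) for feature rows.

    All-zero sentinel rows pass through the same formula (decision equals
    the intercept), so every site receives a score.
    """
    d = model.decision(X)
    return expit(model.calib_a * d + model.calib_b)
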
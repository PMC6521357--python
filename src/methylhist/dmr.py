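"""Assembly of scored cytosines into boundary-refined DMRs.

Sites whose calibrated prediction score clears the cutoff become candidates;
nearby candidates (inter-candidate distance below ``max_gap``) merge into
preliminary regions that retain every intervening site as a member.  Region
boundaries are then trimmed inward until k consecutive member sites carry a
raw bin value b at or above ``b_threshold``; regions without such a run are
discarded.  Multi-group (time-series) designs score every group pair with
the same model, sum the pair scores per cytosine, and report per-pair mean
differences and directionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import features as _feat
from . import model as _model
from . import stats as _stats

__all__ = [
    "CallParams",
    "DMR",
    "ScoredSite",
    "group_candidates",
    "refine_boundaries",
    "call_pairwise",
    "call_timeseries",
]


@dataclass(frozen=True)
class CallParams:
    """DMR-calling thresholds.

    score_cutoff  candidate sites have score > cutoff (per pair comparison)
    max_gap       candidates closer than this many bp merge (exclusive bound)
    k             consecutive sites required at the boundary
    b_threshold   minimum raw bin value b for boundary runs
    min_sites     optional post-filter: keep DMRs with n_sites > min_sites
    min_delta     optional post-filter: keep DMRs with mean |m1−m2| > min_delta
    """

    score_cutoff: float = 0.1
    max_gap: float = 500.0
    k: int = 3
    b_threshold: float = 0.1
    min_sites: int | None = None
    min_delta: float | None = None

    def __post_init__(self) -> None:
        if self.score_cutoff < 0 or self.max_gap < 0 or self.b_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class ScoredSite:
    """One cytosine's calling state (mostly for introspection/debugging)."""

    chrom: str
    pos: int
    score: float
    b: float
    m: tuple[float, ...]

    @property
    def direction(self) -> int:
        return 1 if self.m[0] >= self.m[1] else -1


@dataclass
class DMR:
    """A called region (0-based half-open) with member-site summaries."""

    chrom: str
    start: int
    stop: int
    n_sites: int
    mean_levels: tuple[float, ...]
    mean_abs_diff: float
    mean_score: float
    direction: str  # "hyper"/"hypo" with respect to group 1
    pair_metrics: dict[tuple[int, int], tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError("DMR must span at least one base")
        if self.n_sites < 1:
            raise ValueError("DMR must contain at least one site")

    @property
    def delta(self) -> float:
        """Region-level methylation change: |mean level group 1 − group 2|.

        Site-level noise cancels in this signed-mean form, unlike
        ``mean_abs_diff`` (the mean of per-site absolute differences), so it
        is the quantity the delta post-filter thresholds.
        """
        return abs(self.mean_levels[0] - self.mean_levels[1])


def group_candidates(positions, scores, params: CallParams) -> list[tuple[int, int]]:
    """Merge candidate sites into preliminary regions.

    Returns (first_index, last_index) member spans (inclusive, indices into
    the sorted single-chromosome track).  A candidate is a site with score
    strictly above the cutoff; consecutive candidates merge while the bp
    distance between them is strictly below ``max_gap``.  Non-candidate
    sites inside a span are members (they participate in refinement and
    summaries).
    """
    positions = np.asarray(positions)
    scores = np.asarray(scores, dtype=float)
    cand = np.flatnonzero(scores > params.score_cutoff)
    if len(cand) == 0:
        return []
    gaps = np.diff(positions[cand])
    breaks = np.flatnonzero(gaps >= params.max_gap)
    spans = []
    start = 0
    for brk in breaks:
        spans.append((int(cand[start]), int(cand[brk])))
        start = brk + 1
    spans.append((int(cand[start]), int(cand[-1])))
    return spans


def refine_boundaries(b_values, params: CallParams) -> tuple[int, int] | None:
    """Trim a region's boundaries to runs of k consecutive sites with b >= threshold.

    Given the member b values, returns (left, right) member indices of the
    refined span, or None when no run of length k exists (region discarded).
    The left boundary is the first site starting such a run; the right
    boundary is the last site ending one.
    """
    b = np.asarray(b_values, dtype=float)
    k = params.k
    if len(b) < k:
        return None
    ok = (b >= params.b_threshold).astype(float)
    runs = np.convolve(ok, np.ones(k), mode="valid")  # runs[i] == k -> run starts at i
    starts = np.flatnonzero(runs >= k - 1e-9)
    if len(starts) == 0:
        return None
    return int(starts[0]), int(starts[-1] + k - 1)


def _summarize(
    chrom: str,
    pos: np.ndarray,
    members: np.ndarray,
    group_means: np.ndarray,   # (n_sites, n_groups)
    abs_diff: np.ndarray,
    scores: np.ndarray,
    pair_stats: dict[tuple[int, int], np.ndarray] | None,
) -> DMR:
    m = group_means[members].mean(axis=0)
    diff = float(abs_diff[members].mean())
    score = float(scores[members].mean())
    direction = "hyper" if m[0] - m[1] >= 0 else "hypo"
    pair_metrics: dict[tuple[int, int], tuple[float, str]] = {}
    if pair_stats:
        for (a, b), dvals in pair_stats.items():
            dm = float(dvals[members].mean())
            pair_metrics[(a, b)] = (abs(dm), "hyper" if dm >= 0 else "hypo")
    return DMR(
        chrom=chrom,
        start=int(pos[members[0]]) - 1,
        stop=int(pos[members[-1]]),
        n_sites=len(members),
        mean_levels=tuple(float(x) for x in m),
        mean_abs_diff=diff,
        mean_score=score,
        direction=direction,
        pair_metrics=pair_metrics,
    )


def _post_filter(dmrs: list[DMR], params: CallParams) -> list[DMR]:
    out = dmrs
    if params.min_sites is not None:
        out = [d for d in out if d.n_sites > params.min_sites]
    if params.min_delta is not None:
        out = [d for d in out if d.delta > params.min_delta]
    return out


def _call_chromosome(
    chrom: str,
    pos: np.ndarray,
    scores: np.ndarray,
    b: np.ndarray,
    group_means: np.ndarray,
    abs_diff: np.ndarray,
    params: CallParams,
    pair_stats=None,
    score_cutoff: float | None = None,
) -> list[DMR]:
    eff = params if score_cutoff is None else CallParams(
        score_cutoff=score_cutoff, max_gap=params.max_gap, k=params.k,
        b_threshold=params.b_threshold, min_sites=params.min_sites,
        min_delta=params.min_delta,
    )
    out: list[DMR] = []
    for first, last in group_candidates(pos, scores, eff):
        members = np.arange(first, last + 1)
        bounds = refine_boundaries(b[members], params)
        if bounds is None:
            continue
        members = members[bounds[0] : bounds[1] + 1]
        out.append(
            _summarize(chrom, pos, members, group_means, abs_diff, scores, pair_stats)
        )
    return _post_filter(out, params)


def call_pairwise(group1, group2, model: _model.TrainedModel,
                  params: CallParams | None = None) -> list[DMR]:
    """Call DMRs between two treatment groups (single or multiple replicates).

    Per chromosome: per-site statistics -> histogram features -> calibrated
    scores -> candidate grouping -> boundary refinement -> summaries and
    optional post-filters.  Deterministic given inputs and model.
    """
    params = params or CallParams()
    st, X = _model.compute_site_features(group1, group2, model.params)
    scores = _model.predict_scores(model, X)
    dmrs: list[DMR] = []
    m1 = st["m1"].to_numpy()
    m2 = st["m2"].to_numpy()
    b = st["b"].to_numpy()
    pos = st["pos"].to_numpy()
    chroms = st["chrom"].to_numpy()
    gm = np.column_stack([m1, m2])
    ad = np.abs(m1 - m2)
    for chrom, idx in st.groupby("chrom", sort=True).indices.items():
        dmrs.extend(
            _call_chromosome(
                str(chrom), pos[idx], scores[idx], b[idx], gm[idx], ad[idx], params
            )
        )
    return dmrs


def call_timeseries(groups, model: _model.TrainedModel,
                    params: CallParams | None = None) -> list[DMR]:
    """Call DMRs across n >= 3 groups (time points) with per-pair metrics.

    Every one of the C(n, 2) group pairs is scored with the same model; the
    per-cytosine final score is the sum of pair scores and the candidate
    cutoff scales to ``score_cutoff * C(n, 2)`` to keep the per-pair
    semantics.  Refinement uses, at each site, the maximum Eq.-1 bin value
    over pairs; the output carries each pair's mean level difference and
    direction over member sites.
    """
    n = len(groups)
    if n < 3:
        raise ValueError("need at least 3 groups; use call_pairwise for 2")
    params = params or CallParams()
    pairs = list(combinations(range(n), 2))

    master: pd.DataFrame | None = None
    sum_scores: np.ndarray | None = None
    max_b: np.ndarray | None = None
    group_level_sum: dict[int, np.ndarray] = {}
    group_level_cnt: dict[int, int] = {}
    pair_diff: dict[tuple[int, int], np.ndarray] = {}

    # All samples are aligned to a master site index so pair scores can be
    # summed per cytosine.
    all_tables = [t for g in groups for t in g]
    idx, _, _ = _stats.align_counts(all_tables)
    key = idx.set_index(["chrom", "pos"]).index

    def _align(frame: pd.DataFrame, col: str) -> np.ndarray:
        s = frame.set_index(["chrom", "pos"])[col].reindex(key)
        return s.fillna(0.0).to_numpy()

    for a, bidx in pairs:
        st, X = _model.compute_site_features(groups[a], groups[bidx], model.params)
        sc = _model.predict_scores(model, X)
        st = st.assign(score=sc)
        aligned_score = _align(st, "score")
        aligned_b = _align(st, "b")
        diff = _align(st.assign(diff=st["m1"] - st["m2"]), "diff")
        if master is None:
            master = idx.copy()
            sum_scores = np.zeros(len(master))
            max_b = np.zeros(len(master))
        sum_scores += aligned_score
        max_b = np.maximum(max_b, aligned_b)
        pair_diff[(a, bidx)] = diff
        for g, col in ((a, "m1"), (bidx, "m2")):
            vals = _align(st, col)
            group_level_sum[g] = group_level_sum.get(g, 0) + vals
            group_level_cnt[g] = group_level_cnt.get(g, 0) + 1

    group_means = np.column_stack(
        [group_level_sum[g] / group_level_cnt[g] for g in range(n)]
    )
    # overall spread: mean absolute pairwise difference per site
    ad = np.mean(np.abs(np.column_stack(list(pair_diff.values()))), axis=1)
    pos = master["pos"].to_numpy()
    chroms = master["chrom"].to_numpy()
    cutoff = params.score_cutoff * len(pairs)
    out: list[DMR] = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        ps = {pk: pv[sel] for pk, pv in pair_diff.items()}
        out.extend(
            _call_chromosome(
                str(chrom), pos[sel], sum_scores[sel], max_b[sel],
                group_means[sel], ad[sel], params, pair_stats=ps,
                score_cutoff=cutoff,
            )
        )
    return out
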
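"""Synthetic WGBS benchmarks with ground truth.

Read counts follow a beta-binomial scheme: per site and replicate, coverage
is negative-binomially distributed and the methylated count is binomial with
a success probability drawn from a beta distribution.  DMR sites use
Beta(6, 1.5) in group 1 versus Beta(1.5, 6) in group 2 (means 0.8 vs 0.2);
background sites are either held at a fixed level of 0.7 (class 1) or drawn
from Beta(2, 2) independently per site and replicate (class 2, with high
within- and between-group variability that makes detection much harder).

A second generator emits a labeled training genome: candidate regions with
graded effect sizes over a heterogeneous background, filtered through the
region-level training thresholds so that emitted labels satisfy them
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GroupDesign, MethylomeTable, RegionLabel, METHYLOME_COLUMNS

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_benchmark",
    "simulate_training_regions",
    "shuffle_labels",
]


@dataclass(frozen=True)
class SimConfig:
    """Benchmark generator settings.

    sim_class          1 (fixed background 0.7) or 2 (Beta(2, 2) background)
    n_dmr, n_non_dmr   labeled region counts (0 DMRs gives a null genome)
    reps_per_group     replicates per treatment group
    dmr_beta_g1/g2     beta parameters of DMR methylation levels per group
    class1_background  fixed background level for class 1
    class2_background_beta  beta parameters of the class-2 background
    site_gap           mean inter-cytosine gap in bp (geometric)
    coverage_mean      negative-binomial coverage mean (reads)
    coverage_size      negative-binomial size (dispersion; larger = tighter)
    dmr_len_range      region length range in bp (both DMR and non-DMR)
    spacer_bp          buffer between consecutive truth regions
    shared_background  class 2 only: share the per-site background draw
                       across replicates and groups instead of redrawing
    chrom              chromosome name for the synthetic genome
    seed               RNG seed
    """

    sim_class: int = 1
    n_dmr: int = 2142
    n_non_dmr: int = 2142
    reps_per_group: int = 3
    dmr_beta_g1: tuple[float, float] = (6.0, 1.5)
    dmr_beta_g2: tuple[float, float] = (1.5, 6.0)
    class1_background: float = 0.7
    class2_background_beta: tuple[float, float] = (2.0, 2.0)
    site_gap: float = 100.0
    coverage_mean: float = 10.0
    coverage_size: float = 5.0
    dmr_len_range: tuple[int, int] = (500, 2500)
    spacer_bp: int = 1500
    shared_background: bool = False
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim_class not in (1, 2):
            raise ValueError("sim_class must be 1 or 2")
        for a, b in (self.dmr_beta_g1, self.dmr_beta_g2, self.class2_background_beta):
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be positive")
        if self.n_dmr < 0 or self.n_non_dmr < 0 or self.n_dmr + self.n_non_dmr < 1:
            raise ValueError("need at least one region")
        if self.dmr_len_range[0] > self.dmr_len_range[1] or self.dmr_len_range[0] < 1:
            raise ValueError("invalid length range")
        if self.site_gap <= 0 or self.coverage_mean <= 0 or self.coverage_size <= 0:
            raise ValueError("site_gap, coverage_mean and coverage_size must be > 0")


@dataclass
class TruthSet:
    """Ground-truth regions (sorted, non-overlapping) with effect summaries."""

    regions: list[RegionLabel]
    effects: pd.DataFrame  # one row per region: label, n_sites, mean_abs_diff

    @property
    def dmrs(self) -> list[RegionLabel]:
        return [r for r in self.regions if r.label == "DMR"]


def _nb_coverage(rng: np.random.Generator, cfg: SimConfig, shape) -> np.ndarray:
    size = cfg.coverage_size
    p = size / (size + cfg.coverage_mean)
    return rng.negative_binomial(size, p, size=shape)


def _layout(rng: np.random.Generator, cfg: SimConfig):
    """Interleave DMR and non-DMR intervals separated by spacers.

    Returns (intervals, labels, genome_end); intervals are 0-based half-open.
    Spacers keep truth regions far enough apart that calls cannot merge
    across them.
    """
    labels = ["DMR"] * cfg.n_dmr + ["nonDMR"] * cfg.n_non_dmr
    order = np.arange(len(labels))
    if cfg.n_dmr and cfg.n_non_dmr:
        # strict alternation as far as counts allow, then the remainder
        a = [i for i, l in enumerate(labels) if l == "DMR"]
        b = [i for i, l in enumerate(labels) if l == "nonDMR"]
        order = []
        while a or b:
            if a:
                order.append(a.pop(0))
            if b:
                order.append(b.pop(0))
        order = np.asarray(order)
    lens = rng.integers(cfg.dmr_len_range[0], cfg.dmr_len_range[1] + 1,
                        size=len(labels))
    intervals = []
    cursor = cfg.spacer_bp
    out_labels = []
    for i in order:
        intervals.append((cursor, cursor + int(lens[i])))
        out_labels.append(labels[i])
        cursor += int(lens[i]) + cfg.spacer_bp
    return intervals, out_labels, cursor


def _site_positions(rng: np.random.Generator, cfg: SimConfig, genome_end: int) -> np.ndarray:
    est = int(genome_end / cfg.site_gap * 1.3) + 64
    gaps = rng.geometric(1.0 / cfg.site_gap, size=est)
    pos = np.cumsum(gaps)
    while pos[-1] < genome_end:
        extra = rng.geometric(1.0 / cfg.site_gap, size=est // 2 + 16)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos <= genome_end].astype(np.int64)


def _tables(cfg: SimConfig, pos: np.ndarray, mc: np.ndarray, t: np.ndarray,
            group: int, rep: int) -> MethylomeTable:
    df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "strand": "+",
            "context": "CG",
            "mc": mc,
            "t": t,
        }
    )[METHYLOME_COLUMNS]
    return MethylomeTable(sample_id=f"g{group}_rep{rep}", sites=df)


def simulate_benchmark(cfg: SimConfig) -> tuple[list[MethylomeTable], list[MethylomeTable], TruthSet]:
    """Simulate two treatment groups with replicates plus the truth set.

    Deterministic under ``cfg.seed``.  Truth intervals are recorded as the
    tight span of the sites they contain, matching how calls report their
    bounds.  Raises when the layout is infeasible (it never is with a
    positive spacer, but guard anyway).
    """
    rng = np.random.default_rng(cfg.seed)
    intervals, labels, genome_end = _layout(rng, cfg)
    if intervals and intervals[-1][1] > genome_end:
        raise ValueError("region layout exceeds genome span")
    pos = _site_positions(rng, cfg, genome_end)
    n = len(pos)

    # map sites to truth regions
    starts = np.array([iv[0] for iv in intervals])
    stops = np.array([iv[1] for iv in intervals])
    region_of = np.searchsorted(stops, pos - 1, side="right")
    region_of = np.where(
        (region_of < len(intervals)) & (pos - 1 >= starts[np.minimum(region_of, len(starts) - 1)]),
        region_of,
        -1,
    )
    in_dmr = np.zeros(n, dtype=bool)
    for i, lab in enumerate(labels):
        if lab == "DMR":
            in_dmr |= region_of == i

    reps = cfg.reps_per_group
    groups: list[list[MethylomeTable]] = [[], []]
    levels_sum = np.zeros((n, 2))
    weight_sum = np.zeros((n, 2))

    shared_bg = None
    if cfg.sim_class == 2 and cfg.shared_background:
        a, b = cfg.class2_background_beta
        shared_bg = rng.beta(a, b, size=n)

    for g, beta_dmr in enumerate((cfg.dmr_beta_g1, cfg.dmr_beta_g2)):
        for r in range(reps):
            t = _nb_coverage(rng, cfg, n)
            pi = np.empty(n)
            if cfg.sim_class == 1:
                pi[:] = cfg.class1_background
            elif shared_bg is not None:
                pi[:] = shared_bg
            else:
                a, b = cfg.class2_background_beta
                pi[:] = rng.beta(a, b, size=n)
            if in_dmr.any():
                pi[in_dmr] = rng.beta(beta_dmr[0], beta_dmr[1], size=int(in_dmr.sum()))
            mc = rng.binomial(t, pi)
            groups[g].append(_tables(cfg, pos, mc, t, g + 1, r + 1))
            lvl = np.where(t > 0, mc / np.maximum(t, 1), 0.0)
            w = np.where(t > 0, 1.0, 0.0)
            levels_sum[:, g] += lvl * w
            weight_sum[:, g] += w

    with np.errstate(invalid="ignore"):
        gmean = levels_sum / np.maximum(weight_sum, 1e-30)
    abs_diff = np.abs(gmean[:, 0] - gmean[:, 1])

    regions: list[RegionLabel] = []
    rows = []
    for i, (lab, (s0, s1)) in enumerate(zip(labels, intervals)):
        member = np.flatnonzero(region_of == i)
        if len(member) == 0:
            continue
        tight = RegionLabel(cfg.chrom, int(pos[member[0]]) - 1, int(pos[member[-1]]), lab)
        regions.append(tight)
        rows.append(
            {
                "chrom": cfg.chrom,
                "start": tight.start,
                "stop": tight.stop,
                "label": lab,
                "n_sites": len(member),
                "mean_abs_diff": float(abs_diff[member].mean()),
                "delta": float(abs((gmean[member, 0] - gmean[member, 1]).mean())),
            }
        )
    truth = TruthSet(regions=regions, effects=pd.DataFrame(rows))
    return groups[0], groups[1], truth


# ---------------------------------------------------------------------------
# training genome


def simulate_training_regions(
    cfg: SimConfig, context: str = "CG"
) -> tuple[list[MethylomeTable], list[MethylomeTable], list[RegionLabel]]:
    """Simulate a labeled training genome.

    Candidate DMR regions carry graded effect sizes (levels 0.5 ± delta/2 at
    beta concentration 7.5, delta in [0.1, 0.7]); the background alternates
    between fixed-level segments and beta-noise segments at concentrations
    20 and 4, emulating both quiet and variable genomic background.  The
    realized per-region mean |m1 - m2| is then passed through the
    region-level training filters, so the emitted DMR/nonDMR labels satisfy
    them exactly.
    """
    from .model import select_training_regions  # circular-safe local import

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.dmr_len_range
    intervals, labels, genome_end = _layout(rng, cfg)
    pos = _site_positions(rng, cfg, genome_end)
    n = len(pos)
    starts = np.array([iv[0] for iv in intervals])
    stops = np.array([iv[1] for iv in intervals])
    region_of = np.searchsorted(stops, pos - 1, side="right")
    region_of = np.where(
        (region_of < len(intervals)) & (pos - 1 >= starts[np.minimum(region_of, len(starts) - 1)]),
        region_of,
        -1,
    )

    # Per-region generative settings.  Background segments mix quiet
    # fixed-level stretches with beta-noise at two concentrations; the noisy
    # majority concentrates near level 0.5 where beta variance peaks, so the
    # classifier sees hard negative windows, not just flat background.
    # DMR effects are graded but strong (delta 0.5-0.8): training regions
    # emulate the high-confidence differential peaks a supervised caller is
    # built from, while weak and sub-threshold windows enter through the
    # noisy background and flanking segments.
    deltas = np.zeros(len(intervals))
    bg_kind = rng.choice(3, size=len(intervals) + 1, p=[0.1, 0.1, 0.8])
    bg_level = np.where(
        bg_kind == 2,
        rng.uniform(0.35, 0.65, size=len(intervals) + 1),
        rng.uniform(0.25, 0.9, size=len(intervals) + 1),
    )
    for i, lab in enumerate(labels):
        if lab == "DMR":
            deltas[i] = rng.uniform(0.5, 0.8)

    reps = cfg.reps_per_group
    groups: list[list[MethylomeTable]] = [[], []]
    levels_sum = np.zeros((n, 2))
    weight_sum = np.zeros((n, 2))
    kappa_dmr = 7.5
    site_region = np.maximum(region_of, -1)

    for g in range(2):
        sign = 1.0 if g == 0 else -1.0
        for r in range(reps):
            t = _nb_coverage(rng, cfg, n)
            mu = np.empty(n)
            # background (including spacers): by segment kind
            for i in range(-1, len(intervals)):
                sel = site_region == i
                if not sel.any():
                    continue
                kind = bg_kind[i + 1]
                level = bg_level[i + 1]
                if i >= 0 and labels[i] == "DMR":
                    m = np.clip(0.5 + sign * deltas[i] / 2.0, 0.02, 0.98)
                    mu[sel] = rng.beta(m * kappa_dmr, (1 - m) * kappa_dmr, size=sel.sum())
                elif kind == 0:
                    mu[sel] = level
                else:
                    kappa = 20.0 if kind == 1 else 4.0
                    mu[sel] = rng.beta(level * kappa, (1 - level) * kappa, size=sel.sum())
            mc = rng.binomial(t, mu)
            groups[g].append(_tables(cfg, pos, mc, t, g + 1, r + 1))
            lvl = np.where(t > 0, mc / np.maximum(t, 1), 0.0)
            w = np.where(t > 0, 1.0, 0.0)
            levels_sum[:, g] += lvl * w
            weight_sum[:, g] += w

    gmean = levels_sum / np.maximum(weight_sum, 1e-30)
    signed_diff = gmean[:, 0] - gmean[:, 1]

    # Candidate regions: the laid-out intervals plus the spacer segments
    # between them.  Spacers flank DMR candidates, so windows straddling a
    # DMR boundary appear among the non-DMR-labeled rows — like real
    # background regions adjacent to differential peaks.  The region-level
    # average methylation difference is the signed mean over the region's
    # sites (site noise cancels), then absolute value.
    candidate_intervals = list(intervals)
    spacer_edges = [0] + [iv[1] for iv in intervals]
    spacer_nexts = [iv[0] for iv in intervals] + [genome_end]
    for s0, s1 in zip(spacer_edges, spacer_nexts):
        if s1 - s0 >= 500:
            candidate_intervals.append((s0, s1))
    candidates = []
    for i, (s0, s1) in enumerate(candidate_intervals):
        if i < len(intervals):
            member = np.flatnonzero(region_of == i)
        else:
            member = np.flatnonzero((pos - 1 >= s0) & (pos - 1 < s1))
        if len(member) == 0:
            continue
        candidates.append(
            (cfg.chrom, int(pos[member[0]]) - 1, int(pos[member[-1]]),
             float(abs(signed_diff[member].mean())))
        )
    try:
        regions = select_training_regions(candidates, context=context)
    except ValueError as exc:
        raise ValueError(
            "training filters eliminated a class; widen the effect-size grid "
            "or region counts"
        ) from exc
    return groups[0], groups[1], regions


def shuffle_labels(design: GroupDesign, scheme: int | None = None):
    """Cross-group replicate pairings for null-calibration runs.

    For a 2x2 design the two permuted pairings put one replicate of each
    original group into each artificial group.  ``scheme`` selects a single
    pairing (0-based); None returns the list of all pairings.  ``scheme=-1``
    returns the identity design unchanged.
    """
    if design.n_groups != 2:
        raise ValueError("label shuffling is defined for 2-group designs")
    (la, ids_a), (lb, ids_b) = design.groups.items()
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("need at least two replicates per group to shuffle")
    if scheme == -1:
        return design
    pairings = []
    for offset in range(1, len(ids_b) + 1):
        g1, g2 = [], []
        for i in range(len(ids_a)):
            if i % 2 == 0:
                g1.append(ids_a[i])
            else:
                g2.append(ids_a[i])
        for j in range(len(ids_b)):
            if (j + offset) % 2 == 0:
                g1.append(ids_b[j])
            else:
                g2.append(ids_b[j])
        if g1 and g2:
            pairings.append(GroupDesign({la: g1, lb: g2}, context=design.context))
        if len(pairings) == 2:
            break
    if scheme is not None:
        return pairings[scheme]
    return pairings
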
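"""Reading and writing of methylome tables, labeled regions, DMR calls and models.

Methylome tables follow the allc convention: one row per cytosine with
1-based coordinates, strand, sequence context (CG/CHG/CHH) and read counts
(``mc`` methylated, ``t`` total).  All emitted interval files are 0-based
half-open BED; the coordinate conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METHYLOME_COLUMNS",
    "MethylomeFormatError",
    "ModelFormatError",
    "MethylomeTable",
    "GroupDesign",
    "RegionLabel",
    "read_methylome",
    "write_methylome",
    "combine_cg_strands",
    "read_regions",
    "write_regions",
    "write_dmrs",
    "read_dmrs",
    "save_model",
    "load_model",
]

METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "t"]

_CONTEXTS = {"CG", "CHG", "CHH"}
_STRANDS = {"+", "-"}

MODEL_FORMAT_VERSION = "1.0"


class MethylomeFormatError(ValueError):
    """Raised for malformed methylome input (bad counts, strand, context)."""


class ModelFormatError(ValueError):
    """Raised when a serialized model file is truncated, stale or invalid."""


@dataclass
class MethylomeTable:
    """Per-sample cytosine table, sorted by (chrom, pos).

    ``sites`` holds columns chrom, pos, strand, context, mc, t.  At most one
    record per (chrom, pos, strand).
    """

    sample_id: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METHYLOME_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"methylome table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class GroupDesign:
    """Ordered mapping of treatment-group labels to sample ids."""

    groups: dict[str, list[str]]
    context: str = "CG"

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a design needs at least two groups")
        all_ids: list[str] = []
        for label, ids in self.groups.items():
            if not ids:
                raise ValueError(f"group {label!r} has no samples")
            all_ids.extend(ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("sample ids must be unique across groups")

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class RegionLabel:
    """A labeled genomic interval (0-based half-open) used for training."""

    chrom: str
    start: int
    stop: int
    label: str  # "DMR" or "nonDMR"

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.stop}")

    @property
    def length(self) -> int:
        return self.stop - self.start


def _detect_header(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    if len(fields) < 6:
        return False
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def read_methylome(
    path: str | Path,
    context: str | None = None,
    sample_id: str | None = None,
) -> MethylomeTable:
    """Read a tab-delimited allc-style cytosine table.

    Parameters
    ----------
    path
        TSV with columns [chrom, pos, strand, context, mc, t]; a header line
        is auto-detected (non-numeric ``pos`` field).
    context
        Optional filter: "CG", "CHG", "CHH", or "CH" (= CHG and CHH jointly).
    sample_id
        Defaults to the file stem.

    Raises
    ------
    MethylomeFormatError
        On a malformed row (mc > t, negative counts, bad strand/context),
        naming the offending 1-based line number, or when no rows survive
        the context filter.
    """
    path = Path(path)
    has_header = _detect_header(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=METHYLOME_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    offset = 2 if has_header else 1  # data row i -> file line i + offset

    def _fail(mask: pd.Series, why: str) -> None:
        idx = int(np.flatnonzero(mask.to_numpy())[0])
        raise MethylomeFormatError(f"{path}, line {idx + offset}: {why}")

    for col in ("pos", "mc", "t"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            _fail(numeric.isna(), f"non-numeric {col!r} field")
        df[col] = numeric.astype(np.int64)
    if (df["pos"] < 1).any():
        _fail(df["pos"] < 1, "position must be >= 1")
    if (df["mc"] < 0).any() or (df["t"] < 0).any():
        _fail((df["mc"] < 0) | (df["t"] < 0), "negative read count")
    if (df["mc"] > df["t"]).any():
        _fail(df["mc"] > df["t"], "mc exceeds total count t")
    bad_strand = ~df["strand"].isin(_STRANDS)
    if bad_strand.any():
        _fail(bad_strand, "strand must be '+' or '-'")
    bad_ctx = ~df["context"].isin(_CONTEXTS)
    if bad_ctx.any():
        _fail(bad_ctx, "context must be CG, CHG or CHH")

    if context is not None:
        wanted = {"CHG", "CHH"} if context == "CH" else {context}
        if not wanted <= _CONTEXTS:
            raise ValueError(f"unknown context filter {context!r}")
        df = df[df["context"].isin(wanted)]
    if df.empty:
        raise MethylomeFormatError(
            f"{path}: no cytosines left after context filter {context!r}"
        )
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return MethylomeTable(sample_id=sample_id or path.stem, sites=df)


def write_methylome(table: MethylomeTable, path: str | Path) -> None:
    """Write a methylome table as headerless TSV (inverse of read_methylome)."""
    table.sites[METHYLOME_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def combine_cg_strands(table: MethylomeTable) -> MethylomeTable:
    """Pool Watson/Crick counts of each CG dyad into one record.

    A Watson cytosine at pos i (+) and the Crick cytosine at pos i+1 (-)
    are merged at pos i (strand +) with summed mc and t.  Unpaired sites
    pass through; a lone Crick site at pos j is reported at its Watson
    position j-1.  Total mc and t are conserved.
    """
    df = table.sites
    if not (df["context"] == "CG").all():
        raise ValueError("combine_cg_strands requires CG-context input")
    anchor = df["pos"].to_numpy(copy=True)
    crick = (df["strand"] == "-").to_numpy()
    anchor[crick] -= 1
    out = (
        df.assign(pos=anchor)
        .groupby(["chrom", "pos"], as_index=False, sort=True)
        .agg(mc=("mc", "sum"), t=("t", "sum"))
    )
    out["strand"] = "+"
    out["context"] = "CG"
    out = out[METHYLOME_COLUMNS].sort_values(["chrom", "pos"], kind="mergesort")
    return MethylomeTable(sample_id=table.sample_id, sites=out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# labeled regions (BED4: chrom, start, stop, label)

def read_regions(path: str | Path) -> list[RegionLabel]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "stop", "label"],
        dtype={"chrom": str, "label": str},
    )
    return [
        RegionLabel(r.chrom, int(r.start), int(r.stop), r.label)
        for r in df.itertuples()
    ]


def write_regions(regions: Iterable[RegionLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.stop}\t{r.label}\n")


# ---------------------------------------------------------------------------
# DMR output: BED6+ with extra columns

_DMR_HEADER = [
    "#chrom", "start", "stop", "name", "score", "strand",
    "n_sites", "mean_levels", "mean_abs_diff", "mean_score", "direction",
    "pair_metrics",
]


def write_dmrs(dmrs: Sequence, path: str | Path) -> None:
    """Write DMR calls as BED6+ (0-based half-open).

    Extra columns: member-site count, comma-joined per-group mean levels,
    mean |level difference|, mean prediction score, direction, and (for
    multi-group calls) semicolon-joined per-pair "i-j:diff:direction"
    metrics.  The BED score column is round(1000 * mean_score).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_DMR_HEADER) + "\n")
        for i, d in enumerate(dmrs):
            levels = ",".join(f"{m:.6g}" for m in d.mean_levels)
            if d.pair_metrics:
                pairs = ";".join(
                    f"{a}-{b}:{diff:.6g}:{direction}"
                    for (a, b), (diff, direction) in sorted(d.pair_metrics.items())
                )
            else:
                pairs = "."
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.stop}\tDMR_{i + 1}\t"
                f"{round(1000 * d.mean_score)}\t.\t{d.n_sites}\t{levels}\t"
                f"{d.mean_abs_diff:.6g}\t{d.mean_score:.6g}\t{d.direction}\t{pairs}\n"
            )


def read_dmrs(path: str | Path) -> list:
    """Read a file written by :func:`write_dmrs` back into DMR records."""
    from .dmr import DMR  # local import: io must not depend on dmr at import time

    out: list[DMR] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            pair_metrics: dict[tuple[int, int], tuple[float, str]] = {}
            if f[11] != ".":
                for item in f[11].split(";"):
                    key, diff, direction = item.split(":")
                    a, b = key.split("-")
                    pair_metrics[(int(a), int(b))] = (float(diff), direction)
            out.append(
                DMR(
                    chrom=f[0],
                    start=int(f[1]),
                    stop=int(f[2]),
                    n_sites=int(f[6]),
                    mean_levels=tuple(float(x) for x in f[7].split(",")),
                    mean_abs_diff=float(f[8]),
                    mean_score=float(f[9]),
                    direction=f[10],
                    pair_metrics=pair_metrics,
                )
            )
    return out


# ---------------------------------------------------------------------------
# model serialization (versioned JSON)

_MODEL_FIELDS = {
    "format_version", "weights", "intercept", "calib_a", "calib_b",
    "params", "context",
}


def save_model(model, path: str | Path) -> None:
    """Serialize a trained model to a portable versioned JSON file."""
    from .features import FeatureParams  # noqa: F401  (type referenced in load)

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "weights": [float(w) for w in model.weights],
        "intercept": float(model.intercept),
        "calib_a": float(model.calib_a),
        "calib_b": float(model.calib_b),
        "params": {
            "w": model.params.w,
            "d": model.params.d,
            "bins": model.params.bins,
            "smooth_span": model.params.smooth_span,
        },
        "context": model.context,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; round-trips exactly.

    Raises :class:`ModelFormatError` on truncated files, missing fields or
    a format-version mismatch.
    """
    from .features import FeatureParams
    from .model import TrainedModel

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(payload, dict) or not _MODEL_FIELDS <= set(payload):
        missing = _MODEL_FIELDS - set(payload) if isinstance(payload, dict) else _MODEL_FIELDS
        raise ModelFormatError(f"{path}: missing fields {sorted(missing)}")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {payload['format_version']!r} != "
            f"{MODEL_FORMAT_VERSION!r}"
        )
    p = payload["params"]
    params = FeatureParams(
        w=int(p["w"]), d=float(p["d"]), bins=int(p["bins"]),
        smooth_span=int(p["smooth_span"]),
    )
    return TrainedModel(
        weights=np.asarray(payload["weights"], dtype=float),
        intercept=float(payload["intercept"]),
        calib_a=float(payload["calib_a"]),
        calib_b=float(payload["calib_b"]),
        params=params,
        context=str(payload["context"]),
        version=str(payload["format_version"]),
    )
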
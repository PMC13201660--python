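"""Statistical calling of significant read start/end sites (cleavage sites).

Along the reference, the per-position abundance of alignment starts and ends
is computed.  Within each template interval the baseline is the mean and
sample standard deviation of those per-position counts; a position is called
when its count is at least mean + k*SD (k = 2 by default).  Positions
covered by several overlapping template intervals use the mean of the
interval means and the mean of the interval SDs; positions outside every
interval fall back to a whole-reference baseline.  Sites are only reported
when their baseline SD is positive (a uniform interval carries no signal).
Replicate consensus keeps a (position, kind) pair present in at least
``min_replicates`` of the replicate call lists (2 of 3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import ReadSet
from .refmodel import TemplateSet

__all__ = [
    "SiteCallConfig",
    "SiteCall",
    "boundary_counts",
    "significant_sites",
    "replicate_consensus",
    "export_sites",
    "read_sites",
]


@dataclass(frozen=True)
class SiteCallConfig:
    sd_multiplier: float = 2.0
    min_replicates: int = 2
    replicate_total: int = 3

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if not (1 <= self.min_replicates <= self.replicate_total):
            raise ValueError("need 1 <= min_replicates <= replicate_total")


@dataclass
class SiteCall:
    """A significant boundary position (1-based)."""

    position: int
    kind: str  # {"start", "end"}
    count: int
    threshold_used: float
    template_context: list[str] = field(default_factory=list)
    replicate_counts: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.kind not in {"start", "end"}:
            raise ValueError(f"invalid site kind {self.kind!r}")
        if self.count < self.threshold_used:
            raise ValueError("called site count below its threshold")


def boundary_counts(rs: ReadSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-position start and end counts along the reference.

    ``startvec[i]`` counts reads whose first aligned base is 0-based i;
    ``endvec[i]`` counts reads whose *last* aligned base is 0-based i (so a
    read spanning [s, e) contributes to ``endvec[e-1]``).  Each vector sums
    to the number of reads.
    """
    startvec = np.zeros(rs.ref_length, dtype=np.int64)
    endvec = np.zeros(rs.ref_length, dtype=np.int64)
    for r in rs.records:
        startvec[r.start] += 1
        endvec[r.end - 1] += 1
    return startvec, endvec


def _interval_baselines(
    vec: np.ndarray, ts: TemplateSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position pooled (mean of means, mean of SDs, n covering templates)."""
    L = len(vec)
    sum_means = np.zeros(L)
    sum_sds = np.zeros(L)
    n_cov = np.zeros(L, dtype=np.int64)
    for entry in ts:
        s0, e0 = entry.interval0()
        if e0 - s0 < 2:
            warnings.warn(
                f"template {entry.name!r} has fewer than 2 positions; "
                "skipped for site calling (SD undefined)",
                stacklevel=3,
            )
            continue
        window = vec[s0:e0]
        mean = float(window.mean())
        sd = float(window.std(ddof=1))
        sum_means[s0:e0] += mean
        sum_sds[s0:e0] += sd
        n_cov[s0:e0] += 1
    return sum_means, sum_sds, n_cov


def significant_sites(
    vec: np.ndarray,
    ts: TemplateSet,
    cfg: SiteCallConfig = SiteCallConfig(),
    kind: str = "start",
) -> list[SiteCall]:
    """Call positions whose count reaches mean + k*SD of their local baseline.

    The baseline is computed per template interval (sample SD, n-1); for
    positions under several intervals the threshold pools the mean of the
    interval means and the mean of the interval SDs.  Positions outside
    every interval use the whole-reference mean/SD.  Positions with zero
    pooled SD are never called, and only positions with a positive count are
    reported.
    """
    vec = np.asarray(vec)
    sum_means, sum_sds, n_cov = _interval_baselines(vec, ts)
    covered = n_cov > 0
    mean_of_means = np.zeros(len(vec))
    mean_of_sds = np.zeros(len(vec))
    np.divide(sum_means, n_cov, out=mean_of_means, where=covered)
    np.divide(sum_sds, n_cov, out=mean_of_sds, where=covered)
    global_mean = float(vec.mean())
    global_sd = float(vec.std(ddof=1)) if len(vec) > 1 else 0.0
    mean_of_means[~covered] = global_mean
    mean_of_sds[~covered] = global_sd
    threshold = mean_of_means + cfg.sd_multiplier * mean_of_sds
    callable_mask = (mean_of_sds > 0) & (vec > 0) & (vec >= threshold)
    calls = []
    for pos0 in np.flatnonzero(callable_mask):
        context = [
            e.name
            for e in ts
            if e.interval0()[0] <= pos0 < e.interval0()[1] and e.length >= 2
        ]
        calls.append(
            SiteCall(
                position=int(pos0) + 1,
                kind=kind,
                count=int(vec[pos0]),
                threshold_used=float(threshold[pos0]),
                template_context=context,
            )
        )
    return calls


def replicate_consensus(
    calls_per_replicate: Sequence[Sequence[SiteCall]],
    cfg: SiteCallConfig = SiteCallConfig(),
) -> list[SiteCall]:
    """Keep (position, kind) pairs present in >= min_replicates replicate lists.

    The consensus call reports the per-replicate count vector (0 where the
    replicate did not call the site) and the smallest threshold among the
    replicates that called it.
    """
    n_rep = len(calls_per_replicate)
    if n_rep < cfg.min_replicates:
        raise ValueError(
            f"need at least {cfg.min_replicates} replicate call lists, got {n_rep}"
        )
    by_key: dict[tuple[int, str], list[Optional[SiteCall]]] = {}
    for i, calls in enumerate(calls_per_replicate):
        for call in calls:
            key = (call.position, call.kind)
            by_key.setdefault(key, [None] * n_rep)[i] = call
    out = []
    for (pos, kind), percall in sorted(by_key.items()):
        present = [c for c in percall if c is not None]
        if len(present) < cfg.min_replicates:
            continue
        context = sorted({t for c in present for t in c.template_context})
        out.append(
            SiteCall(
                position=pos,
                kind=kind,
                count=max(c.count for c in present),
                threshold_used=min(c.threshold_used for c in present),
                template_context=context,
                replicate_counts=[c.count if c is not None else 0 for c in percall],
            )
        )
    return out


_BED_COLORS = {"start": "0,170,0", "end": "255,140,0"}  # start green, end orange


def export_sites(
    calls: Sequence[SiteCall],
    tsv_path: Optional[str | Path] = None,
    bed_path: Optional[str | Path] = None,
    ref_name: str = "45SN1",
) -> pd.DataFrame:
    """Write site calls as TSV and colour-coded BED9 (start green, end orange)."""
    df = pd.DataFrame(
        {
            "position": [c.position for c in calls],
            "kind": [c.kind for c in calls],
            "count": [c.count for c in calls],
            "threshold": [c.threshold_used for c in calls],
            "templates": [";".join(c.template_context) for c in calls],
        }
    )
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in calls:
                s0 = c.position - 1
                score = min(1000, c.count)
                fh.write(
                    f"{ref_name}\t{s0}\t{s0 + 1}\t{c.kind}_{c.position}\t{score}\t+"
                    f"\t{s0}\t{s0 + 1}\t{_BED_COLORS[c.kind]}\n"
                )
    return df


def read_sites(tsv_path: str | Path) -> list[SiteCall]:
    """Round-trip loader for the TSV written by :func:`export_sites`."""
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            SiteCall(
                position=int(row.position),
                kind=str(row.kind),
                count=int(row.count),
                threshold_used=float(row.threshold),
                template_context=str(row.templates).split(";") if row.templates else [],
            )
        )
    return calls
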
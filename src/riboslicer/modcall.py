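"""Per-site RNA-modification stoichiometry from base-modification evidence.

Two complementary signals are combined for pseudouridine (and other)
detection on the single pre-rRNA reference:

* basecaller modification probabilities (SAM MM/ML tags): a read is called
  modified at a position when its probability reaches ``prob_threshold``
  (0.95 by default, inclusive), and the site stoichiometry (mod_ratio) is
  the fraction of probability-carrying reads called modified;
* the U-to-C mismatch ratio: pseudouridine perturbs basecalling and shows
  up as C calls at reference-U positions; the ratio divides C calls by the
  non-deleted coverage (a deleted base expresses no identity).

Sites below ``min_site_ratio`` (10 %) in *every* condition are filtered out,
so an in vitro transcribed (IVT) control contributes no sites on its own.
Stoichiometry can be resolved per precursor using the supervised read
assignments, and raw-current evidence around a locus is summarised as the
mean of per-read z-normalised means with semi-standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import ReadSet, coverage
from .refmodel import ReferenceModel, TemplateSet
from .template_quant import Assignment, UNASSIGNED

__all__ = [
    "ModConfig",
    "call_modified",
    "site_stoichiometry",
    "filter_sites",
    "precursor_stoichiometry",
    "SignalWindowSummary",
    "signal_window_summary",
]


@dataclass(frozen=True)
class ModConfig:
    prob_threshold: float = 0.95
    min_site_ratio: float = 0.10
    min_coverage: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.prob_threshold <= 1):
            raise ValueError("prob_threshold must lie in (0, 1]")
        if not (0 <= self.min_site_ratio <= 1):
            raise ValueError("min_site_ratio must lie in [0, 1]")


def call_modified(
    read_probs: Mapping[int, float], cfg: ModConfig = ModConfig()
) -> dict[int, bool]:
    """Binary per-position modification calls for one read (inclusive threshold)."""
    for p in read_probs.values():
        if not (0.0 <= p <= 1.0):
            raise ValueError("modification probabilities must lie in [0, 1]")
    return {pos: p >= cfg.prob_threshold for pos, p in read_probs.items()}


def _stoichiometry_counts(
    records, cfg: ModConfig
) -> tuple[dict[int, int], dict[int, int]]:
    """Per-position (reads with a probability record, reads called modified)."""
    n_prob: dict[int, int] = {}
    n_mod: dict[int, int] = {}
    for r in records:
        if not r.mod_probs:
            continue
        for pos, p in r.mod_probs.items():
            n_prob[pos] = n_prob.get(pos, 0) + 1
            if p >= cfg.prob_threshold:
                n_mod[pos] = n_mod.get(pos, 0) + 1
    return n_prob, n_mod


def site_stoichiometry(
    rs: ReadSet,
    cfg: ModConfig = ModConfig(),
    pileup: Optional[pd.DataFrame] = None,
    ref: Optional[ReferenceModel] = None,
    condition: Optional[str] = None,
    precursor: str = "all",
) -> pd.DataFrame:
    """Per-site modification stoichiometry for one ReadSet.

    ``mod_ratio`` divides modified reads by the reads carrying a probability
    record at the position; it is NaN (never 0) where no read carries a
    record.  When a mismatch ``pileup`` (see
    :func:`riboslicer.ingest.mismatch_pileup`) and the reference are
    supplied, the U-to-C mismatch ratio is reported at reference-U
    positions, with deletions excluded from the denominator.  Sites with
    coverage below ``cfg.min_coverage`` are flagged ``low_coverage``.
    """
    n_prob, n_mod = _stoichiometry_counts(rs.records, cfg)
    cov = coverage(rs)
    positions = sorted(n_prob)
    rows = []
    for pos in positions:
        denom = n_prob[pos]
        ratio = n_mod.get(pos, 0) / denom if denom else float("nan")
        c_ratio = float("nan")
        if pileup is not None and ref is not None and ref.base(pos) == "T":
            row = pileup.loc[pos + 1]
            non_del = int(row["coverage"]) - int(row["deletion"])
            c_ratio = int(row["C"]) / non_del if non_del > 0 else float("nan")
        rows.append(
            {
                "position": pos + 1,
                "mod_ratio": ratio,
                "mismatch_c_ratio": c_ratio,
                "coverage": int(cov[pos]),
                "n_prob_reads": denom,
                "condition": rs.condition if condition is None else condition,
                "precursor": precursor,
                "low_coverage": int(cov[pos]) < cfg.min_coverage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "mod_ratio",
            "mismatch_c_ratio",
            "coverage",
            "n_prob_reads",
            "condition",
            "precursor",
            "low_coverage",
        ],
    )


def filter_sites(
    stoich: pd.DataFrame | Mapping[str, pd.DataFrame],
    cfg: ModConfig = ModConfig(),
    per_condition: bool = False,
) -> list[int]:
    """Apply the site-level stoichiometry filter across conditions.

    By default a site is retained iff its mod_ratio reaches
    ``cfg.min_site_ratio`` (inclusive) in at least one condition -- i.e. a
    site below the threshold in *every* condition is removed.  With
    ``per_condition=True`` the alternative reading is applied: the site must
    reach the threshold in every condition in which it was measured.
    Low-coverage measurements never count toward retention.  Returns sorted
    1-based positions.
    """
    if isinstance(stoich, Mapping):
        frames = [
            df.assign(condition=cond) if "condition" not in df else df
            for cond, df in stoich.items()
        ]
        df = pd.concat(frames, ignore_index=True)
    else:
        df = stoich
    if df.empty:
        return []
    ok = (
        (df["mod_ratio"] >= cfg.min_site_ratio)
        & df["mod_ratio"].notna()
        & ~df["low_coverage"].astype(bool)
    )
    grouped = ok.groupby(df["position"])
    keep = grouped.all() if per_condition else grouped.any()
    return sorted(int(p) for p in keep.index[keep])


def precursor_stoichiometry(
    rs: ReadSet,
    assignments: Sequence[Assignment],
    ts: TemplateSet,
    cfg: ModConfig = ModConfig(),
    sites: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Modification stoichiometry resolved per precursor (rows) and site (columns).

    Reads are grouped by their supervised template assignment and the
    mod_ratio is recomputed within each group.  ``sites`` restricts the
    columns to the given 1-based positions (default: every position carrying
    a probability record).  A cell is NaN when the site lies outside the
    precursor's interval or no read of that precursor carries a record
    there.  The "all" row pools every read and therefore equals the
    record-count-weighted mean of the per-precursor rows.
    """
    if len(assignments) != len(rs.records):
        raise ValueError("assignments do not cover the ReadSet")
    groups: dict[str, list] = {}
    for a, r in zip(assignments, rs.records):
        groups.setdefault(a.template, []).append(r)
    all_prob, all_mod = _stoichiometry_counts(rs.records, cfg)
    if sites is None:
        site_list = sorted(p + 1 for p in all_prob)
    else:
        site_list = sorted(int(s) for s in sites)
    data: dict[str, list[float]] = {}
    index = []
    for name in list(ts.names) + [UNASSIGNED]:
        if name not in groups:
            continue
        n_prob, n_mod = _stoichiometry_counts(groups[name], cfg)
        row = []
        if name in ts:
            s0, e0 = ts[name].interval0()
        else:
            s0, e0 = 0, rs.ref_length
        for site in site_list:
            pos = site - 1
            if not (s0 <= pos < e0) or n_prob.get(pos, 0) == 0:
                row.append(float("nan"))
            else:
                row.append(n_mod.get(pos, 0) / n_prob[pos])
        index.append(name)
        data[name] = row
    all_row = [
        (all_mod.get(site - 1, 0) / all_prob[site - 1])
        if all_prob.get(site - 1, 0)
        else float("nan")
        for site in site_list
    ]
    out = pd.DataFrame(
        [data[name] for name in index] + [all_row],
        index=index + ["all"],
        columns=site_list,
    )
    out.index.name = "precursor"
    out.columns.name = "position"
    return out


@dataclass
class SignalWindowSummary:
    """Z-normalised current summary over a +/-10-nt window around a locus."""

    locus: int  # 1-based
    offsets: np.ndarray  # -10 .. +10
    mean_of_means: np.ndarray
    semi_sd_lower: np.ndarray
    semi_sd_upper: np.ndarray
    n_reads: int

    def __post_init__(self) -> None:
        if len(self.offsets) != 21:
            raise ValueError("signal window must cover exactly 21 offsets (-10..+10)")
        if (self.semi_sd_lower < 0).any() or (self.semi_sd_upper < 0).any():
            raise ValueError("semi-standard deviations must be non-negative")


def signal_window_summary(
    signal_table: pd.DataFrame, locus: int
) -> SignalWindowSummary:
    """Summarise per-read z-normalised current means around a locus.

    ``signal_table`` has columns read_id/offset/z_mean, one row per read and
    offset in -10..+10 (the contract of an upstream resquiggling step).  Per
    offset the mean over reads is computed, with the dispersion summarised
    separately below and above the mean: the lower (upper) semi-SD is the
    root mean square deviation of the values strictly below (above) the
    per-offset mean; an empty side yields 0.
    """
    required = {"read_id", "offset", "z_mean"}
    if required - set(signal_table.columns):
        raise ValueError("signal table needs columns read_id/offset/z_mean")
    if signal_table.empty:
        raise ValueError(f"no reads cover locus {locus}")
    offsets = np.arange(-10, 11)
    present = set(signal_table["offset"].astype(int))
    missing = set(offsets.tolist()) - present
    if missing:
        raise ValueError(f"signal table is missing offsets: {sorted(missing)}")
    means = np.empty(21)
    lower = np.empty(21)
    upper = np.empty(21)
    for i, off in enumerate(offsets):
        vals = signal_table.loc[
            signal_table["offset"].astype(int) == off, "z_mean"
        ].to_numpy(dtype=float)
        m = vals.mean()
        below = vals[vals < m]
        above = vals[vals > m]
        means[i] = m
        lower[i] = math.sqrt(np.mean((below - m) ** 2)) if below.size else 0.0
        upper[i] = math.sqrt(np.mean((above - m) ** 2)) if above.size else 0.0
    return SignalWindowSummary(
        locus=locus,
        offsets=offsets,
        mean_of_means=means,
        semi_sd_lower=lower,
        semi_sd_upper=upper,
        n_reads=signal_table["read_id"].nunique(),
    )
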
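"""Supervised quantification of pre-rRNA intermediates by reciprocal overlap.

Every read is assigned to the catalogued intermediate that maximises the
minimal reciprocal overlap (MRO)

    MRO(read, template) = min(O / len(read), O / len(template)),

where O is the length of the intersection of the two reference intervals.
The score is symmetric and lies in [0, 1]; a read disjoint from every
template is "unassigned".  Assignments are turned into absolute counts,
reads-per-million (RPM) and log10 RPM, and condition contrasts (log2 fold
change of mean RPM with a Welch t-test per intermediate, BH-adjusted).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ReadSet
from .refmodel import TemplateSet

__all__ = [
    "Assignment",
    "mro",
    "assign_reads",
    "quantify",
    "summarize_conditions",
    "compare_conditions",
    "export_intermediate_beds",
    "abundance_heatmap",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    template: str
    mro: float

    def __post_init__(self) -> None:
        if (self.mro == 0.0) != (self.template == UNASSIGNED):
            raise ValueError("mro must be 0 exactly for unassigned reads")


def mro(read: tuple[int, int], template: tuple[int, int]) -> float:
    """Minimal reciprocal overlap of two 0-based half-open intervals."""
    rs, re_ = read
    ts, te = template
    if re_ <= rs or te <= ts:
        raise ValueError("zero-length interval")
    overlap = max(0, min(re_, te) - max(rs, ts))
    return min(overlap / (re_ - rs), overlap / (te - ts))


def assign_reads(
    rs: ReadSet, ts: TemplateSet, min_mro: float = 0.0
) -> list[Assignment]:
    """Assign each read to its argmax-MRO template.

    Ties at the maximal score are broken deterministically: prefer the
    template whose length is closest to the read's, then the
    lexicographically smallest name.  A read whose best score is <= min_mro
    (default 0: any positive overlap assigns) is "unassigned".
    """
    if len(ts) == 0:
        raise ValueError("cannot assign reads against an empty template set")
    names = ts.names
    t0 = np.array([e.interval0() for e in ts], dtype=np.int64)
    tstart, tend = t0[:, 0], t0[:, 1]
    tlen = (tend - tstart).astype(np.float64)
    starts = rs.starts()
    ends = rs.ends()
    rlen = (ends - starts).astype(np.float64)
    overlap = np.maximum(
        0,
        np.minimum(ends[:, None], tend[None, :])
        - np.maximum(starts[:, None], tstart[None, :]),
    ).astype(np.float64)
    score = np.minimum(overlap / rlen[:, None], overlap / tlen[None, :])
    best = score.max(axis=1) if len(ts) else np.zeros(len(rs))
    out: list[Assignment] = []
    for i, r in enumerate(rs.records):
        if best[i] <= min_mro:
            out.append(Assignment(r.read_id, UNASSIGNED, 0.0))
            continue
        cand = np.flatnonzero(score[i] == best[i])
        if len(cand) > 1:
            j = min(cand, key=lambda k: (abs(tlen[k] - rlen[i]), names[k]))
        else:
            j = cand[0]
        out.append(Assignment(r.read_id, names[j], float(best[i])))
    return out


def quantify(
    assignments: Sequence[Assignment],
    rs: ReadSet,
    ts: Optional[TemplateSet] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Absolute counts, RPM and log10 RPM per template for one replicate.

    RPM = count / total_aligned * 1e6.  ``pseudocount`` (in RPM units,
    default 1) is added before taking log10 so that absent species remain
    finite on heatmaps.  The returned table has one row per template in
    ``ts`` (or per observed template) plus "unassigned"; counts sum to the
    ReadSet size.
    """
    if rs.total_aligned == 0:
        raise ValueError("cannot quantify an empty ReadSet")
    if len(assignments) != rs.total_aligned:
        raise ValueError("assignments do not match the ReadSet")
    universe = list(ts.names) if ts is not None else sorted(
        {a.template for a in assignments} - {UNASSIGNED}
    )
    counts = {name: 0 for name in universe}
    counts[UNASSIGNED] = 0
    for a in assignments:
        if a.template not in counts:
            counts[a.template] = 0
        counts[a.template] += 1
    rows = []
    for name, count in counts.items():
        rpm = count / rs.total_aligned * 1e6
        rows.append(
            {
                "template": name,
                "condition": rs.condition,
                "replicate": rs.replicate,
                "count": count,
                "rpm": rpm,
                "log10_rpm": math.log10(rpm + pseudocount) if rpm + pseudocount > 0 else float("-inf"),
            }
        )
    return pd.DataFrame(rows)


def summarize_conditions(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Replicate mean and SD of RPM per (template, condition).

    ``log10_mean_rpm`` is log10 of the replicate-mean RPM (plus pseudocount),
    the quantity displayed on abundance heatmaps; set
    ``pseudocount=0`` for raw values.
    """
    g = table.groupby(["template", "condition"])["rpm"]
    out = g.agg(mean_rpm="mean", sd_rpm="std", n_replicates="count").reset_index()
    out["log10_mean_rpm"] = np.log10(out["mean_rpm"] + pseudocount)
    return out


def compare_conditions(
    a: pd.DataFrame, b: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-template log2 fold change (b over a) with Welch t-test and BH q-values.

    ``a`` and ``b`` are quantify() tables (replicates concatenated) sharing
    the same template universe.  With a single replicate per condition only
    the fold change is reported and p-values are NaN.
    """
    ta, tb = set(a["template"]), set(b["template"])
    if ta != tb:
        raise ValueError("abundance tables do not share the same template universe")
    rows = []
    for template in sorted(ta):
        ra = a.loc[a["template"] == template, "rpm"].to_numpy(dtype=float)
        rb = b.loc[b["template"] == template, "rpm"].to_numpy(dtype=float)
        log2fc = math.log2((rb.mean() + pseudocount) / (ra.mean() + pseudocount))
        if len(ra) >= 2 and len(rb) >= 2:
            if np.allclose(ra, rb):
                pval = 1.0
            else:
                pval = float(stats.ttest_ind(rb, ra, equal_var=False).pvalue)
                if math.isnan(pval):  # zero variance in both groups, unequal means
                    pval = 0.0 if ra.mean() != rb.mean() else 1.0
        else:
            pval = float("nan")
        rows.append(
            {
                "template": template,
                "mean_rpm_a": ra.mean(),
                "mean_rpm_b": rb.mean(),
                "log2fc": log2fc,
                "pvalue": pval,
            }
        )
    out = pd.DataFrame(rows)
    mask = out["pvalue"].notna()
    out["qvalue"] = np.nan
    if mask.any():
        out.loc[mask, "qvalue"] = multipletests(
            out.loc[mask, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def _safe_filename(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._+-]", "_", name)


def export_intermediate_beds(
    assignments: Sequence[Assignment],
    rs: ReadSet,
    ref_name: str,
    outdir: str | Path,
    ts: Optional[TemplateSet] = None,
) -> dict[str, Path]:
    """Write one BED file of read intervals per template (plus unassigned.bed).

    Empty templates still produce an (empty) file so downstream tooling can
    rely on the full set being present.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe = list(ts.names) if ts is not None else sorted(
        {a.template for a in assignments} - {UNASSIGNED}
    )
    universe.append(UNASSIGNED)
    handles = {name: open(outdir / f"{_safe_filename(name)}.bed", "w") for name in universe}
    try:
        for a, r in zip(assignments, rs.records):
            handles[a.template].write(
                f"{ref_name}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n"
            )
    finally:
        for fh in handles.values():
            fh.close()
    return {name: outdir / f"{_safe_filename(name)}.bed" for name in universe}


def abundance_heatmap(
    summary: pd.DataFrame,
    path: Optional[str | Path] = None,
    value: str = "log10_mean_rpm",
):
    """Render a template x condition heatmap of (log10) mean RPM."""
    from matplotlib.figure import Figure

    pivot = summary.pivot(index="template", columns="condition", values=value)
    fig = Figure(figsize=(6, 0.3 * len(pivot) + 2))
    ax = fig.add_subplot(111)
    im = ax.imshow(pivot.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
    fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
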
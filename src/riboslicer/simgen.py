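"""Synthetic long-read generator for the pre-rRNA pipeline.

Emits ReadSets (and SAM files with MM/ML base-modification tags) with fully
known ground truth: template proportions, Gaussian boundary jitter,
geometric exonucleolytic trails (one-nucleotide-at-a-time boundary
retraction), uniform background fragments, planted large deletions,
replicate/condition structure with per-template fold changes, and planted
per-site modification stoichiometries.  Every downstream module is tested
against data from this generator.

All randomness flows from a single integer seed; identical configurations
produce byte-identical SAM output.  Replicates derive their seeds from the
master seed through a fixed integer mix (see :func:`derive_seed`) so each
replicate is independently reproducible.
"""

from __future__ import annotations

import array
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .ingest import ReadRecord, ReadSet
from .refmodel import ReferenceModel, TemplateSet

__all__ = [
    "SimConfig",
    "SimulatedReads",
    "make_reference",
    "simulate_reads",
    "simulate_modifications",
    "simulate_knockdown",
    "write_sam",
    "derive_seed",
    "sim_config_from_yaml",
]

BACKGROUND = "background"
# SAM base-modification code for pseudouridine (ChEBI:17802) on T/U.
PSEU_CODE = "17802"


def derive_seed(master: int, index: int) -> int:
    """Deterministic per-replicate seed from a master seed (below 2^31)."""
    return (master * 2654435761 + 9973 * (index + 1)) % (2**31)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated ReadSet.

    ``template_proportions`` must sum to 1 (within 1e-9); ``jitter_sd`` is
    the SD (nt) of the rounded-Gaussian boundary noise; ``trail_decay`` is
    the geometric continuation probability q of exonucleolytic boundary
    retraction (P(k nt removed) = (1-q) q^k; None/0 disables trails);
    ``background_rate`` is the fraction of uniform-random fragments;
    ``planted_sites`` maps 1-based U positions to modification stoichiometry;
    ``planted_deletion`` is an optional 1-based (position, length) deletion
    written into every read that fully spans it.
    """

    seed: int = 0
    n_reads: int = 10_000
    template_proportions: dict[str, float] = field(default_factory=dict)
    jitter_sd: float = 0.0
    trail_decay: Optional[float] = None
    background_rate: float = 0.0
    planted_sites: list[tuple[int, float]] = field(default_factory=list)
    planted_deletion: Optional[tuple[int, int]] = None
    condition_fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.template_proportions:
            total = sum(self.template_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"template proportions must sum to 1, got {total:.12f}"
                )
        if self.trail_decay is not None and not (0 <= self.trail_decay <= 1):
            raise ValueError("trail_decay must lie in [0, 1]")
        if not (0 <= self.background_rate <= 1):
            raise ValueError("background_rate must lie in [0, 1]")
        for pos, stoich in self.planted_sites:
            if not (0.0 <= stoich <= 1.0):
                raise ValueError(f"stoichiometry at {pos} outside [0, 1]")


@dataclass
class SimulatedReads:
    """A simulated ReadSet together with its per-read ground truth."""

    reads: ReadSet
    truth: pd.DataFrame  # columns: read_id, template, start, end


def make_reference(
    length: int = 13_351, seed: int = 7, name: str = "synthetic_45SN1"
) -> ReferenceModel:
    """A synthetic 45SN1-length reference with uniform base composition."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return ReferenceModel(name=name, sequence=seq)


# 3' retraction (end shrinks: exosome-like 3'->5' trimming) for species
# maturing their 3' end; 5' retraction for spacer fragments and aberrant
# species being chewed 5'->3'.
_TRAIL_5P_CATEGORIES = {"spacer-fragment", "aberrant"}


def simulate_reads(
    ts: TemplateSet,
    cfg: SimConfig,
    ref_length: int,
    sample: str = "sim",
    condition: str = "",
    replicate: int = 1,
) -> SimulatedReads:
    """Draw reads from template proportions with jitter, trails and background."""
    props = cfg.template_proportions
    if not props:
        raise ValueError("template_proportions must be provided")
    unknown = set(props) - set(ts.names)
    if unknown:
        raise ValueError(f"unknown template names in proportions: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    names = sorted(props)
    p = np.array([props[n] for n in names], dtype=float)
    p = p / p.sum()
    n = cfg.n_reads
    is_bg = rng.random(n) < cfg.background_rate
    choice = rng.choice(len(names), size=n, p=p)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    labels: list[str] = []
    intervals = {name: ts[name].interval0() for name in names}
    categories = {name: ts[name].category for name in names}
    jit = (
        np.rint(rng.normal(0.0, cfg.jitter_sd, size=(n, 2))).astype(np.int64)
        if cfg.jitter_sd > 0
        else np.zeros((n, 2), dtype=np.int64)
    )
    if cfg.trail_decay and cfg.trail_decay > 0 and cfg.trail_decay < 1:
        trail = rng.geometric(1.0 - cfg.trail_decay, size=n) - 1
    elif cfg.trail_decay == 1.0:
        raise ValueError("trail_decay of exactly 1 yields unbounded trails")
    else:
        trail = np.zeros(n, dtype=np.int64)
    bg_s = rng.integers(0, ref_length - 1, size=n)
    bg_e = bg_s + 1 + (rng.random(n) * (ref_length - bg_s)).astype(np.int64)

    for i in range(n):
        if is_bg[i]:
            starts[i], ends[i] = bg_s[i], bg_e[i]
            labels.append(BACKGROUND)
            continue
        name = names[choice[i]]
        s0, e0 = intervals[name]
        s = s0 + jit[i, 0]
        e = e0 + jit[i, 1]
        if trail[i] > 0:
            if categories[name] in _TRAIL_5P_CATEGORIES:
                s += trail[i]
            else:
                e -= trail[i]
        s = max(0, min(s, ref_length - 1))
        e = max(s + 1, min(e, ref_length))
        starts[i], ends[i] = s, e
        labels.append(name)

    records = []
    for i in range(n):
        deletions = []
        if cfg.planted_deletion is not None:
            dpos0 = cfg.planted_deletion[0] - 1
            dlen = cfg.planted_deletion[1]
            if starts[i] < dpos0 and dpos0 + dlen < ends[i]:
                deletions.append((dpos0, dlen))
        records.append(
            ReadRecord(
                read_id=f"{sample}_r{replicate}_{i:06d}",
                start=int(starts[i]),
                end=int(ends[i]),
                deletions=deletions,
            )
        )
    rs = ReadSet(
        records=records,
        ref_length=ref_length,
        sample=sample,
        condition=condition,
        replicate=replicate,
    )
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "template": labels,
            "start": starts,
            "end": ends,
        }
    )
    return SimulatedReads(reads=rs, truth=truth)


def simulate_modifications(
    rs: ReadSet,
    cfg: SimConfig,
    ref: ReferenceModel,
    mod_mean: float = 0.99,
    unmod_mean: float = 0.02,
    noise_sd: float = 0.02,
    c_mismatch_prob: float = 0.0,
) -> ReadSet:
    """Attach modification probabilities (and optional U->C mismatches) to reads.

    Every reference-U position covered by a read receives a probability
    record: at a planted site each read is modified with probability equal
    to the planted stoichiometry, drawing its probability from a clipped
    Normal(``mod_mean``, ``noise_sd``); everywhere else (and for unmodified
    reads) from a clipped Normal(``unmod_mean``, ``noise_sd``).  With
    ``c_mismatch_prob`` > 0, that fraction of *modified* reads basecalls C
    instead of U at the site (mimicking pseudouridine-induced mismatches);
    such reads carry no probability record there, since the modification
    tag indexes called U bases.
    """
    rng = np.random.default_rng((cfg.seed * 7919 + 13) % (2**31))
    seq = np.frombuffer(ref.sequence.upper().encode(), dtype="S1")
    u_positions = np.flatnonzero((seq == b"T") | (seq == b"U"))
    planted = {pos - 1: stoich for pos, stoich in cfg.planted_sites}
    for pos0, _ in planted.items():
        if not (0 <= pos0 < ref.length):
            raise ValueError(f"planted site {pos0 + 1} outside the reference")
        if seq[pos0] not in (b"T", b"U"):
            raise ValueError(f"planted site {pos0 + 1} is not a U in the reference")
    out_records = []
    for r in rs.records:
        lo = np.searchsorted(u_positions, r.start)
        hi = np.searchsorted(u_positions, r.end)
        pos = u_positions[lo:hi]
        if r.deletions:
            deleted = np.zeros(len(pos), dtype=bool)
            for ds, dl in r.deletions:
                deleted |= (pos >= ds) & (pos < ds + dl)
            pos = pos[~deleted]
        probs = np.clip(rng.normal(unmod_mean, noise_sd, size=len(pos)), 0.0, 1.0)
        basecalls = dict(r.basecalls) if r.basecalls else {}
        drop: set[int] = set()
        for j, p0 in enumerate(pos):
            stoich = planted.get(int(p0))
            if stoich is None:
                continue
            if rng.random() < stoich:  # this molecule is modified here
                if c_mismatch_prob > 0 and rng.random() < c_mismatch_prob:
                    basecalls[int(p0)] = "C"
                    drop.add(j)
                else:
                    probs[j] = np.clip(rng.normal(mod_mean, noise_sd), 0.0, 1.0)
        mod_probs = {
            int(p0): float(probs[j]) for j, p0 in enumerate(pos) if j not in drop
        }
        out_records.append(
            ReadRecord(
                read_id=r.read_id,
                start=r.start,
                end=r.end,
                strand=r.strand,
                deletions=list(r.deletions),
                mod_probs=mod_probs or None,
                basecalls=basecalls or None,
                has_sequence=True,
            )
        )
    return ReadSet(
        records=out_records,
        ref_length=rs.ref_length,
        sample=rs.sample,
        condition=rs.condition,
        replicate=rs.replicate,
    )


def simulate_knockdown(
    ts: TemplateSet,
    cfg: SimConfig,
    fold_changes: Optional[dict[str, float]] = None,
    n_replicates: int = 3,
    ref_length: Optional[int] = None,
) -> tuple[list[SimulatedReads], list[SimulatedReads]]:
    """Paired control/knockdown replicate sets with per-template fold changes.

    Knockdown proportions are the control proportions multiplied by the fold
    changes and renormalised.  Each replicate draws an independent seed from
    the master seed, so replicate RPMs differ but share their expectation.
    """
    fold_changes = fold_changes or cfg.condition_fold_changes
    unknown = set(fold_changes) - set(cfg.template_proportions)
    if unknown:
        raise ValueError(f"fold changes reference unknown templates: {sorted(unknown)}")
    if ref_length is None:
        if ts.ref_length is None:
            raise ValueError("ref_length required when the TemplateSet carries none")
        ref_length = ts.ref_length
    kd_props = {
        name: p * fold_changes.get(name, 1.0)
        for name, p in cfg.template_proportions.items()
    }
    total = sum(kd_props.values())
    kd_props = {name: p / total for name, p in kd_props.items()}
    ctrl, kd = [], []
    for i in range(n_replicates):
        cfg_ctrl = replace(cfg, seed=derive_seed(cfg.seed, i))
        ctrl.append(
            simulate_reads(
                ts, cfg_ctrl, ref_length, sample=f"ctrl_rep{i + 1}",
                condition="control", replicate=i + 1,
            )
        )
        cfg_kd = replace(
            cfg,
            seed=derive_seed(cfg.seed, 100 + i),
            template_proportions=kd_props,
        )
        kd.append(
            simulate_reads(
                ts, cfg_kd, ref_length, sample=f"kd_rep{i + 1}",
                condition="knockdown", replicate=i + 1,
            )
        )
    return ctrl, kd


def _read_segments(r: ReadRecord) -> tuple[list[tuple[int, int, int]], list[tuple[int, int]]]:
    """Aligned (ref_start, ref_end, query_offset) segments and the CIGAR."""
    segs = []
    cigar = []
    q = 0
    cur = r.start
    for ds, dl in sorted(r.deletions):
        if ds > cur:
            cigar.append((0, ds - cur))
            segs.append((cur, ds, q))
            q += ds - cur
        cigar.append((2, dl))
        cur = ds + dl
    if r.end > cur:
        cigar.append((0, r.end - cur))
        segs.append((cur, r.end, q))
    return segs, cigar


def _query_sequence(r: ReadRecord, ref: ReferenceModel, segs) -> str:
    parts = []
    calls = r.basecalls or {}
    for s, e, _q in segs:
        chunk = list(ref.sequence[s:e].upper().replace("U", "T"))
        for pos, base in calls.items():
            if s <= pos < e:
                chunk[pos - s] = base
        parts.append("".join(chunk))
    return "".join(parts)


def _mm_ml_tags(
    r: ReadRecord, qseq: str, segs
) -> Optional[tuple[str, array.array]]:
    """Encode mod_probs as MM/ML strings over called-T positions."""
    if not r.mod_probs:
        return None
    ref2q = {}
    for s, e, q in segs:
        for pos in range(s, e):
            ref2q[pos] = q + (pos - s)
    t_qpos = [i for i, ch in enumerate(qseq) if ch == "T"]
    t_index = {qpos: k for k, qpos in enumerate(t_qpos)}
    entries = []
    for pos in sorted(r.mod_probs):
        qpos = ref2q.get(pos)
        if qpos is None or qpos not in t_index:
            continue  # deleted or mismatched base carries no T-mod record
        entries.append((t_index[qpos], r.mod_probs[pos]))
    if not entries:
        return None
    deltas = []
    prev = -1
    quals = array.array("B")
    for t_i, p in entries:
        deltas.append(t_i - prev - 1)
        prev = t_i
        quals.append(min(255, max(0, round(p * 255))))
    mm = f"T+{PSEU_CODE}?," + ",".join(str(d) for d in deltas) + ";"
    return mm, quals


def write_sam(
    rs: ReadSet, ref: ReferenceModel, path: str | Path, binary: bool = False
) -> None:
    """Write a ReadSet as SAM (or BAM) against the single reference.

    Query sequences are reconstructed from the reference with any recorded
    mismatch basecalls substituted; modification probabilities are encoded
    as standard MM/ML tags; planted deletions appear in the CIGAR.  Output
    is deterministic for a given ReadSet.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    }
    mode = "wb" if binary else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for r in rs.records:
            segs, cigar = _read_segments(r)
            qseq = _query_sequence(r, ref, segs)
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = qseq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(qseq))
            tags = _mm_ml_tags(r, qseq, segs)
            if tags is not None:
                mm, quals = tags
                a.set_tag("MM", mm, value_type="Z")
                a.set_tag("ML", quals)
            out.write(a)


def write_truth_table(sim: SimulatedReads, path: str | Path) -> None:
    sim.truth.to_csv(path, sep="\t", index=False)


def sim_config_from_yaml(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file mirroring the dataclass fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "planted_sites" in raw and raw["planted_sites"] is not None:
        raw["planted_sites"] = [
            (int(p), float(s)) for p, s in raw["planted_sites"]
        ]
    if "planted_deletion" in raw and raw["planted_deletion"] is not None:
        raw["planted_deletion"] = tuple(int(v) for v in raw["planted_deletion"])
    return SimConfig(**raw)
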
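"""Parse long-read alignments against the single pre-rRNA reference.

Reads are reduced to their aligned reference span (soft-clipped bases never
extend the span), their CIGAR deletion spans, and -- when present -- sparse
per-base modification probabilities decoded from standard SAM MM/ML
base-modification tags and sparse mismatch basecalls relative to the
reference.  Only primary, forward-strand alignments are retained: the rRNA
template is single-stranded, so a reverse alignment is an artefact; reverse
alignments are counted and reported as a warning.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .refmodel import ReferenceModel

__all__ = [
    "ReadRecord",
    "ReadSet",
    "read_alignments",
    "coverage",
    "detect_large_deletions",
    "mismatch_pileup",
]


@dataclass
class ReadRecord:
    """One aligned read, reduced to its reference footprint.

    ``start``/``end`` are 0-based half-open on the reference.  ``deletions``
    holds ``(del_start, del_length)`` pairs (0-based).  ``mod_probs`` maps a
    0-based reference position to a modification probability in [0, 1];
    ``basecalls`` sparsely maps a 0-based reference position to the called
    base where it *differs* from the reference (matches are implicit, which
    keeps 10^5-read sets cheap); ``has_sequence`` records whether the source
    alignment carried a query sequence at all.
    """

    read_id: str
    start: int
    end: int
    strand: str = "+"
    deletions: list[tuple[int, int]] = field(default_factory=list)
    mod_probs: Optional[dict[int, float]] = None
    basecalls: Optional[dict[int, str]] = None
    has_sequence: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read {self.read_id!r}: invalid span [{self.start}, {self.end})"
            )
        for ds, dl in self.deletions:
            if dl < 1 or ds < self.start or ds + dl > self.end:
                raise ValueError(
                    f"read {self.read_id!r}: deletion ({ds}, {dl}) outside aligned span"
                )
        if self.mod_probs:
            bad = [p for p in self.mod_probs.values() if not (0.0 <= p <= 1.0)]
            if bad:
                raise ValueError(
                    f"read {self.read_id!r}: modification probabilities outside [0, 1]"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def deleted_positions(self):
        for ds, dl in self.deletions:
            yield from range(ds, ds + dl)


@dataclass
class ReadSet:
    """A set of aligned reads from one sample/replicate/condition."""

    records: list[ReadRecord]
    ref_length: int
    sample: str = "sample"
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        for r in self.records:
            if r.end > self.ref_length:
                raise ValueError(
                    f"read {r.read_id!r} extends past the reference "
                    f"({r.end} > {self.ref_length})"
                )

    @property
    def total_aligned(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def starts(self) -> np.ndarray:
        return np.fromiter((r.start for r in self.records), dtype=np.int64, count=len(self.records))

    def ends(self) -> np.ndarray:
        return np.fromiter((r.end for r in self.records), dtype=np.int64, count=len(self.records))


def _open_alignment(path: str | Path) -> pysam.AlignmentFile:
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    return pysam.AlignmentFile(path, mode, check_sq=False)


def _decode_mod_probs(aln: pysam.AlignedSegment) -> Optional[dict[int, float]]:
    """Decode MM/ML base-modification tags into reference-space probabilities.

    8-bit ML qualities are scaled to [0, 1] by v/255 per the SAM
    base-modification specification.  Query positions are lifted to reference
    positions via the aligned pairs; insertions (no reference position) are
    dropped.
    """
    try:
        mods = aln.modified_bases
    except Exception:
        return None
    if not mods:
        return None
    q2r = {q: r for q, r in aln.get_aligned_pairs(matches_only=True)}
    out: dict[int, float] = {}
    for (_base, strand, _code), entries in mods.items():
        if strand != 0:  # modification called on the opposite strand
            continue
        for qpos, qual in entries:
            rpos = q2r.get(qpos)
            if rpos is None or qual is None:
                continue
            out[rpos] = qual / 255.0
    return out or None


def _mismatches(aln: pysam.AlignedSegment, ref: ReferenceModel) -> dict[int, str]:
    seq = aln.query_sequence
    out: dict[int, str] = {}
    for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
        called = seq[qpos].upper()
        if called == "U":
            called = "T"
        if called != ref.base(rpos):
            out[rpos] = called
    return out


def read_alignments(
    path: str | Path,
    ref: ReferenceModel,
    sample: str = "sample",
    condition: str = "",
    replicate: int = 1,
) -> ReadSet:
    """Load primary forward-strand alignments from a SAM/BAM file.

    MM/ML tags, when present, are decoded into per-read ``mod_probs``; when
    the query sequence is present, mismatching basecalls are recorded
    sparsely.  A file whose header names a different reference raises; a file
    with no mapped reads yields an empty ReadSet with a warning.
    """
    records: list[ReadRecord] = []
    n_reverse = 0
    with _open_alignment(path) as af:
        if ref.name not in af.references:
            raise ValueError(
                f"alignment file {path} is not against reference {ref.name!r} "
                f"(found {list(af.references)})"
            )
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != ref.name:
                raise ValueError(
                    f"alignment of read {aln.query_name!r} targets "
                    f"{aln.reference_name!r}, expected {ref.name!r}"
                )
            if aln.is_reverse:
                n_reverse += 1
                continue
            deletions = []
            rpos = aln.reference_start
            for op, ln in aln.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    rpos += ln
                elif op == 2:  # D
                    deletions.append((rpos, ln))
                    rpos += ln
                elif op == 3:  # N behaves like a deletion span on the reference
                    deletions.append((rpos, ln))
                    rpos += ln
            has_seq = aln.query_sequence is not None
            records.append(
                ReadRecord(
                    read_id=aln.query_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="+",
                    deletions=deletions,
                    mod_probs=_decode_mod_probs(aln),
                    basecalls=_mismatches(aln, ref) if has_seq else None,
                    has_sequence=has_seq,
                )
            )
    if n_reverse:
        warnings.warn(
            f"{n_reverse} reverse-strand alignments in {path} were discarded",
            stacklevel=2,
        )
    if not records:
        warnings.warn(f"no mapped forward-strand reads in {path}", stacklevel=2)
    return ReadSet(
        records=records,
        ref_length=ref.length,
        sample=sample,
        condition=condition,
        replicate=replicate,
    )


def coverage(rs: ReadSet) -> np.ndarray:
    """Per-position read coverage: position i counts reads with start <= i < end."""
    diff = np.zeros(rs.ref_length + 1, dtype=np.int64)
    for r in rs.records:
        diff[r.start] += 1
        diff[r.end] -= 1
    return np.cumsum(diff[:-1])


def write_bedgraph(cov: np.ndarray, ref_name: str, path: str | Path) -> None:
    """Write a coverage vector as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        i = 0
        n = len(cov)
        while i < n:
            j = i
            while j < n and cov[j] == cov[i]:
                j += 1
            if cov[i] != 0:
                fh.write(f"{ref_name}\t{i}\t{j}\t{int(cov[i])}\n")
            i = j


def detect_large_deletions(
    rs: ReadSet, min_len: int = 50, tolerance: int = 20
) -> pd.DataFrame:
    """Aggregate large intra-read deletion spans across reads.

    Deletions of length >= ``min_len`` are clustered: a span joins the
    current cluster when both boundaries agree with the cluster's first span
    within ``tolerance`` nt.  The table reports the modal boundaries of each
    cluster (1-based inclusive), sorted by supporting-read count.  Spans are
    sorted before clustering, so the result is invariant to read order.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    spans = sorted(
        (ds, ds + dl)
        for r in rs.records
        for ds, dl in r.deletions
        if dl >= min_len
    )
    clusters: list[list[tuple[int, int]]] = []
    for span in spans:
        if clusters:
            ref_s, ref_e = clusters[-1][0]
            if abs(span[0] - ref_s) <= tolerance and abs(span[1] - ref_e) <= tolerance:
                clusters[-1].append(span)
                continue
        clusters.append([span])
    rows = []
    for members in clusters:
        counter = Counter(members)
        top = max(counter.values())
        modal_s, modal_e = min(sp for sp, c in counter.items() if c == top)
        rows.append(
            {
                "del_start": modal_s + 1,
                "del_end": modal_e,  # 1-based inclusive end == 0-based exclusive
                "length": modal_e - modal_s,
                "supporting_reads": len(members),
            }
        )
    df = pd.DataFrame(rows, columns=["del_start", "del_end", "length", "supporting_reads"])
    if len(df):
        df = df.sort_values(
            ["supporting_reads", "del_start"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


_PILEUP_BASES = ("A", "C", "G", "U", "N")


def mismatch_pileup(rs: ReadSet, ref: ReferenceModel) -> pd.DataFrame:
    """Per-position base-call counts (A/C/G/U/N calls plus deletions).

    Requires reads loaded from alignments that carried a query sequence.
    Matching calls are reconstructed from coverage minus recorded mismatches
    and deletions, so the column sums plus deletions equal coverage at every
    position.  U and T are treated as the same base.
    """
    if not any(r.has_sequence for r in rs.records):
        raise ValueError(
            "mismatch pileup needs basecalls: load alignments whose records "
            "include the query sequence"
        )
    L = rs.ref_length
    counts = {b: np.zeros(L, dtype=np.int64) for b in _PILEUP_BASES}
    dels = np.zeros(L, dtype=np.int64)
    mism_total = np.zeros(L, dtype=np.int64)
    cov = coverage(rs)
    for r in rs.records:
        for pos in r.deleted_positions():
            dels[pos] += 1
        if r.basecalls:
            for pos, base in r.basecalls.items():
                b = "U" if base in ("T", "U") else base
                if b not in counts:
                    b = "N"
                counts[b][pos] += 1
                mism_total[pos] += 1
    matches = cov - dels - mism_total
    ref_arr = np.frombuffer(ref.sequence.upper().encode(), dtype="S1")
    for base, key in ((b"A", "A"), (b"C", "C"), (b"G", "G"), (b"T", "U"), (b"U", "U"), (b"N", "N")):
        mask = ref_arr == base
        counts[key][mask] += matches[mask]
    df = pd.DataFrame({b: counts[b] for b in _PILEUP_BASES})
    df["deletion"] = dels
    df["coverage"] = cov
    df.index = pd.RangeIndex(1, L + 1, name="position")
    return df
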
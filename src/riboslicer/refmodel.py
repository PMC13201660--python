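"""Reference coordinate system, processing-site catalogue and template table.

Everything downstream of this module works against a *single* reference
sequence: the 45S/47S primary pre-rRNA transcript.  This module holds

* :class:`ReferenceModel` -- the reference sequence itself,
* :class:`ProcessingSite` -- named cleavage positions (01, A0, 1, E, C, 2,
  B1, 4', 4a, 4, 3', 02 and sub-forms),
* :class:`TemplateSet` -- the catalogue of named intermediates (47S, 45S,
  30S, 21S, 18S-E and its extension series, 32S, 12S, 7S, the mature rRNAs,
  spacer fragments, and aberrant species such as 34S and 36S-C).

All user-facing coordinates (TSV tables, BED exports) are 1-based and
inclusive on both ends; the 0-based half-open convention used internally is
confined to :meth:`TemplateEntry.interval0` and the BED writers.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceModel",
    "ProcessingSite",
    "TemplateEntry",
    "TemplateSet",
    "load_reference",
    "load_template_table",
    "write_template_table",
    "load_processing_sites",
    "default_template_set",
    "default_processing_sites",
    "extend_with_hubs",
]

_VALID_BASES = set("ACGTUN")
TEMPLATE_CATEGORIES = {
    "precursor",
    "mature",
    "spacer-fragment",
    "aberrant",
    "extension-series",
}


@dataclass(frozen=True)
class ReferenceModel:
    """The single pre-rRNA reference sequence (45SN1-equivalent)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"reference {self.name!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"reference {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position0: int) -> str:
        """Uppercase base at a 0-based position, with U normalised to T."""
        b = self.sequence[position0].upper()
        return "T" if b == "U" else b


@dataclass(frozen=True)
class ProcessingSite:
    """A named cleavage position on the reference (1-based)."""

    name: str
    position: int
    side: str = "both"  # {start-generating -> "start", end-generating -> "end", "both"}
    provenance: str = "literature"  # {"literature", "this-work"}

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site {self.name!r}: position must be >= 1")
        if self.side not in {"start", "end", "both"}:
            raise ValueError(f"site {self.name!r}: invalid side {self.side!r}")


@dataclass(frozen=True)
class TemplateEntry:
    """One named intermediate interval, 1-based inclusive on both ends."""

    name: str
    start: int
    end: int
    category: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"template {self.name!r}: invalid interval {self.start}..{self.end}"
            )
        if self.category not in TEMPLATE_CATEGORIES:
            raise ValueError(
                f"template {self.name!r}: unknown category {self.category!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interval0(self) -> tuple[int, int]:
        """The interval as 0-based half-open ``(start, end)``."""
        return self.start - 1, self.end


class TemplateSet:
    """An ordered, name-unique collection of template intervals."""

    def __init__(self, entries: Iterable[TemplateEntry], ref_length: Optional[int] = None):
        self.entries: list[TemplateEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.name in seen:
                raise ValueError(f"duplicate template name {e.name!r}")
            seen.add(e.name)
        self.ref_length = ref_length
        if ref_length is not None:
            for e in self.entries:
                if e.end > ref_length:
                    raise ValueError(
                        f"template {e.name!r} ({e.start}..{e.end}) exceeds the "
                        f"reference length {ref_length}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TemplateEntry]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def __getitem__(self, name: str) -> TemplateEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "start": [e.start for e in self.entries],
                "end": [e.end for e in self.entries],
                "category": [e.category for e in self.entries],
            }
        )

    def to_bed(self, path: str | Path, ref_name: str) -> None:
        """Write BED6 (0-based half-open, per the BED standard)."""
        with open(path, "w") as fh:
            for e in self.entries:
                s0, e0 = e.interval0()
                fh.write(f"{ref_name}\t{s0}\t{e0}\t{e.name}\t0\t+\n")


def load_reference(path: str | Path) -> ReferenceModel:
    """Load the single-record reference FASTA.

    Raises ``ValueError`` if the file holds zero or more than one record, or
    if the record sequence is empty.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one sequence record in {path}, found {len(records)}"
        )
    rec = records[0]
    return ReferenceModel(name=rec.id, sequence=str(rec.seq).upper())


def load_template_table(path: str | Path, ref_length: Optional[int] = None) -> TemplateSet:
    """Read a template table TSV with columns name/start/end/category."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "start", "end", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"template table {path} is missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        if row.end < row.start:
            raise ValueError(
                f"template table row {row.name!r}: end {row.end} < start {row.start}"
            )
        entries.append(
            TemplateEntry(str(row.name), int(row.start), int(row.end), str(row.category))
        )
    return TemplateSet(entries, ref_length=ref_length)


def write_template_table(ts: TemplateSet, path: str | Path) -> None:
    ts.to_frame().to_csv(path, sep="\t", index=False)


def load_processing_sites(
    path: str | Path, ref_length: Optional[int] = None
) -> list[ProcessingSite]:
    """Read a processing-site table TSV with columns name/position/side/provenance."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "position"}
    if required - set(df.columns):
        raise ValueError(f"site table {path} must have columns name/position")
    sites = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        name = str(row.name)
        if name in seen:
            raise ValueError(f"duplicate processing-site name {name!r}")
        seen.add(name)
        pos = int(row.position)
        if ref_length is not None and pos > ref_length:
            raise ValueError(f"site {name!r} position {pos} exceeds reference length")
        sites.append(
            ProcessingSite(
                name=name,
                position=pos,
                side=str(getattr(row, "side", "both")),
                provenance=str(getattr(row, "provenance", "literature")),
            )
        )
    return sites


def _data_path(fname: str) -> Path:
    return Path(str(importlib.resources.files("riboslicer").joinpath("data", fname)))


def default_template_set(ref_length: Optional[int] = None) -> TemplateSet:
    """The packaged literature-derived template catalogue (45SN1 coordinates)."""
    return load_template_table(_data_path("templates_45sn1.tsv"), ref_length=ref_length)


def default_processing_sites(ref_length: Optional[int] = None) -> list[ProcessingSite]:
    """The packaged processing-site catalogue (45SN1 coordinates)."""
    return load_processing_sites(
        _data_path("processing_sites_45sn1.tsv"), ref_length=ref_length
    )


def extend_with_hubs(
    ts: TemplateSet,
    hubs,
    min_reads: int = 10,
    names: Optional[dict[tuple[int, int], str]] = None,
    category: str = "precursor",
) -> TemplateSet:
    """Add boundary hubs to the template catalogue as new intermediates.

    Each retained hub (``total_reads >= min_reads``) contributes one entry
    whose interval is the hub apex ``(start, end)`` cell converted to 1-based
    inclusive coordinates.  Entries whose interval is already present (under
    any name) are skipped, so the operation is idempotent.  ``names`` maps an
    apex cell to a user-supplied label; otherwise entries are auto-named
    ``novel_<start>_<end>`` (1-based coordinates).
    """
    names = names or {}
    existing = {(e.start, e.end) for e in ts.entries}
    taken = set(ts.names)
    new_entries = list(ts.entries)
    for hub in hubs:
        if hub.total_reads < min_reads:
            continue
        s0, e0 = hub.apex
        start1, end1 = s0 + 1, e0  # 0-based half-open cell -> 1-based inclusive
        if ts.ref_length is not None and (start1 < 1 or end1 > ts.ref_length):
            raise ValueError(f"hub apex {hub.apex} lies outside the reference")
        if end1 < start1:
            raise ValueError(f"hub apex {hub.apex} is not a valid interval")
        if (start1, end1) in existing:
            continue
        label = names.get(hub.apex, f"novel_{start1}_{end1}")
        if label in taken:
            raise ValueError(f"hub-derived template name {label!r} already exists")
        new_entries.append(TemplateEntry(label, start1, end1, category))
        existing.add((start1, end1))
        taken.add(label)
    return TemplateSet(new_entries, ref_length=ts.ref_length)
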
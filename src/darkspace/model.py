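"""Core data model: proteins, domain hits, region annotations.

Coordinates are 1-based and inclusive on both ends throughout the
package, matching HMMER alignment coordinates and TMHMM output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

#: The four region types tracked alongside domains.
REGION_TYPES = ("LC", "TM", "CC", "SP")

#: Domain hit sources.
DOMAIN_SOURCES = ("pfam", "cdd")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: identifier, length and optional residues.

    The residue string is auxiliary (coverage accounting needs only
    lengths) and does not participate in equality or hashing.
    """

    seq_id: str
    length: int
    sequence: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise DataError("seq_id must be non-empty")
        if self.length < 1:
            raise DataError(f"{self.seq_id}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise DataError(
                f"{self.seq_id}: sequence has {len(self.sequence)} residues "
                f"but length is {self.length}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One aligned domain match (Pfam or CDD) on a protein."""

    seq_id: str
    model_name: str
    start: int
    end: int
    bit_score: float
    evalue: float
    source: str
    model_acc: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"{self.seq_id}/{self.model_name}: invalid coordinates "
                f"({self.start}, {self.end})"
            )
        if self.evalue < 0:
            raise DataError(f"{self.seq_id}/{self.model_name}: negative E-value")
        if self.source not in DOMAIN_SOURCES:
            raise DataError(f"unknown domain source {self.source!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainHit") -> bool:
        """Closed-interval overlap: sharing at least one residue."""
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class RegionAnnotation:
    """One low-complexity / transmembrane / coiled-coil / signal-peptide interval."""

    seq_id: str
    region_type: str
    start: int
    end: int
    source_tool: str

    def __post_init__(self) -> None:
        if self.region_type not in REGION_TYPES:
            raise DataError(f"unknown region type {self.region_type!r}")
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"{self.seq_id}/{self.region_type}: invalid coordinates "
                f"({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationTable:
    """A proteome with its domain hits and region annotations.

    Every hit and region must refer to a known protein and lie within
    its length; :meth:`validate` enforces this.
    """

    proteins: list[ProteinRecord] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    regions: list[RegionAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.proteins:
            if p.seq_id in seen:
                raise DataError(f"duplicate protein identifier {p.seq_id!r}")
            seen.add(p.seq_id)

    def validate(self) -> None:
        lengths = {p.seq_id: p.length for p in self.proteins}
        for hit in self.domain_hits:
            if hit.seq_id not in lengths:
                raise DataError(f"domain hit for unknown protein {hit.seq_id!r}")
            if hit.end > lengths[hit.seq_id]:
                raise DataError(
                    f"{hit.seq_id}/{hit.model_name}: end {hit.end} exceeds "
                    f"protein length {lengths[hit.seq_id]}"
                )
        for reg in self.regions:
            if reg.seq_id not in lengths:
                raise DataError(f"region for unknown protein {reg.seq_id!r}")
            if reg.end > lengths[reg.seq_id]:
                raise DataError(
                    f"{reg.seq_id}/{reg.region_type}: end {reg.end} exceeds "
                    f"protein length {lengths[reg.seq_id]}"
                )

    def protein_ids(self) -> list[str]:
        return [p.seq_id for p in self.proteins]

    def hits_for(self, seq_id: str, source: Optional[str] = None) -> list[DomainHit]:
        return [
            h
            for h in self.domain_hits
            if h.seq_id == seq_id and (source is None or h.source == source)
        ]

    def regions_for(self, seq_id: str) -> list[RegionAnnotation]:
        return [r for r in self.regions if r.seq_id == seq_id]

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.proteins)

    def __eq__(self, other: object) -> bool:
        # order-insensitive: tables are equal when they hold the same
        # proteins, hits and regions as sets
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return (
            set(self.proteins) == set(other.proteins)
            and set(self.domain_hits) == set(other.domain_hits)
            and set(self.regions) == set(other.regions)
        )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge closed 1-based intervals into a sorted, disjoint list.

    Adjacent intervals (end + 1 == next start) are merged too, since
    they cover a contiguous residue range.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
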
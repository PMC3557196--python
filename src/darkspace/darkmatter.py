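"""Uncovered-segment extraction and dark-matter classification.

A protein's residues are partitioned into three exclusive classes:

* **domain** — residues inside accepted domain intervals;
* **short linker** — residues in a maximal domain-free segment that is
  shorter than the linker cutoff (default 50 aa, strict ``<``) and lies
  between two domains or between a domain and a protein terminus.  Such
  segments are too short to contain even the smallest domain bordered
  by average-size (6-8 aa) linkers, so they can safely be subtracted
  from dark matter;
* **dark matter** — everything else: long uncovered segments, and the
  whole of any protein with no domain at all (classic dark matter —
  never subtractable, whatever its length).

Regions (LC/TM/CC/SP) deliberately play no role here: none of the four
region types is found overwhelmingly outside domain boundaries, so no
region type can be confidently subtracted from dark matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from darkspace.model import DataError, ProteinRecord, merge_intervals
from darkspace.coverage_engine import ResolvedArchitecture

#: Default maximum linker length: segments shorter than this are subtractable.
DEFAULT_LINKER_MAX = 50

SEGMENT_CONTEXTS = ("n_terminal", "c_terminal", "interdomain", "full_protein")


@dataclass(frozen=True)
class UncoveredSegment:
    """A maximal domain-free interval with its positional context."""

    seq_id: str
    start: int
    end: int
    context: str

    def __post_init__(self) -> None:
        if self.context not in SEGMENT_CONTEXTS:
            raise DataError(f"unknown segment context {self.context!r}")
        if not (1 <= self.start <= self.end):
            raise DataError(f"invalid segment ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentClass:
    """An uncovered segment with its subtractability class."""

    segment: UncoveredSegment
    klass: str  # "short_linker" | "dark_matter"


@dataclass(frozen=True)
class ProteinAccounting:
    """Exclusive residue partition of one protein.

    Satisfies ``domain_aa + short_linker_aa + darkmatter_aa == length``.
    """

    seq_id: str
    length: int
    domain_aa: int
    short_linker_aa: int
    darkmatter_aa: int
    has_domain: bool


def extract_uncovered_segments(
    length: int, resolved: ResolvedArchitecture
) -> list[UncoveredSegment]:
    """Maximal domain-free segments of a protein, sorted by start.

    A protein with zero accepted domains yields a single ``full_protein``
    segment spanning the whole sequence.
    """
    if length < 1:
        raise DataError("protein length must be >= 1")
    domain_ivs = merge_intervals(resolved.intervals)
    if domain_ivs and domain_ivs[-1][1] > length:
        raise DataError(
            f"{resolved.seq_id}: accepted domain end {domain_ivs[-1][1]} "
            f"exceeds length {length}")
    if not domain_ivs:
        return [UncoveredSegment(resolved.seq_id, 1, length, "full_protein")]
    segments: list[UncoveredSegment] = []
    if domain_ivs[0][0] > 1:
        segments.append(
            UncoveredSegment(resolved.seq_id, 1, domain_ivs[0][0] - 1, "n_terminal"))
    for (_, e1), (s2, _) in zip(domain_ivs, domain_ivs[1:]):
        # merge_intervals fuses adjacent intervals, so e1 + 1 < s2 here
        segments.append(
            UncoveredSegment(resolved.seq_id, e1 + 1, s2 - 1, "interdomain"))
    if domain_ivs[-1][1] < length:
        segments.append(
            UncoveredSegment(resolved.seq_id, domain_ivs[-1][1] + 1, length,
                             "c_terminal"))
    return segments


def classify_segment(
    segment: UncoveredSegment, threshold_aa: int = DEFAULT_LINKER_MAX
) -> SegmentClass:
    """Classify an uncovered segment as short linker or dark matter.

    Strictly-shorter-than-threshold segments flanked by at least one
    domain are subtractable short linkers; a ``full_protein`` segment is
    always dark matter.
    """
    if threshold_aa < 1:
        raise ValueError(f"threshold_aa must be >= 1, got {threshold_aa}")
    if segment.context != "full_protein" and segment.length < threshold_aa:
        return SegmentClass(segment, "short_linker")
    return SegmentClass(segment, "dark_matter")


def account_protein(
    length: int,
    resolved: ResolvedArchitecture,
    threshold_aa: int = DEFAULT_LINKER_MAX,
) -> ProteinAccounting:
    """Partition a protein's residues into domain / short-linker / dark matter."""
    segments = extract_uncovered_segments(length, resolved)
    short = dark = 0
    for seg in segments:
        if classify_segment(seg, threshold_aa).klass == "short_linker":
            short += seg.length
        else:
            dark += seg.length
    domain_aa = resolved.covered_aa
    assert domain_aa + short + dark == length
    return ProteinAccounting(
        seq_id=resolved.seq_id,
        length=length,
        domain_aa=domain_aa,
        short_linker_aa=short,
        darkmatter_aa=dark,
        has_domain=bool(resolved.accepted_hits),
    )


def sequence_level_class(
    proteins: Sequence[ProteinRecord],
    resolutions: Mapping[str, ResolvedArchitecture],
) -> dict[str, float]:
    """Count proteins with at least one accepted domain vs none.

    Returns counts and fractions; ``fraction_with_domain`` and
    ``fraction_without_domain`` sum to 1.
    """
    if not proteins:
        raise DataError("empty proteome")
    n_with = 0
    for p in proteins:
        res = resolutions.get(p.seq_id)
        if res is None:
            raise DataError(f"no resolution for protein {p.seq_id!r}")
        if res.accepted_hits:
            n_with += 1
    n = len(proteins)
    return {
        "n_proteins": n,
        "n_with_domain": n_with,
        "n_without_domain": n - n_with,
        "fraction_with_domain": n_with / n,
        "fraction_without_domain": (n - n_with) / n,
    }
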
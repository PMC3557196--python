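"""Interval arithmetic for residue-level coverage accounting.

Implements the coverage rules used throughout the package:

* **Longest-domain overlap resolution** — when domain hits overlap, the
  longest hit wins.  The pairwise rule is extended to arbitrary overlap
  chains by a deterministic greedy pass: sort by (length desc, E-value
  asc, start asc, model name asc) and accept each hit that conflicts
  with no already-accepted hit.
* **Residue union** — coverage counts distinct residues; for
  non-overlapping intervals it reduces to the sum of interval lengths.
* **Domain-priority partition** — when a region (LC/TM/CC/SP) overlaps
  an accepted domain, the overlapping residues are attributed to the
  domain; the region residue is merely classified as within-domain.
* **Cross-source redundancy** — a secondary (e.g. CDD) hit is
  *confirmatory* when a large enough fraction of its residues already
  lies in the primary (Pfam) accepted coverage, otherwise *novel*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from darkspace.model import (
    DataError,
    DomainHit,
    ProteinRecord,
    RegionAnnotation,
    REGION_TYPES,
    merge_intervals,
)

#: Default minimum overlap fraction for a confirmatory secondary hit.
DEFAULT_REDUNDANCY_FRAC = 0.75


@dataclass
class ResolvedArchitecture:
    """Non-overlapping domain architecture of one protein after resolution."""

    seq_id: str
    accepted_hits: list[DomainHit]
    rejected_hits: list[tuple[DomainHit, str]]
    covered_aa: int
    length: Optional[int] = None

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return [(h.start, h.end) for h in self.accepted_hits]


@dataclass
class RegionPartition:
    """Within/outside-domain residue counts per region type."""

    within_domain_aa: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in REGION_TYPES})
    outside_domain_aa: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in REGION_TYPES})

    def total(self, region_type: str) -> int:
        return self.within_domain_aa[region_type] + self.outside_domain_aa[region_type]


@dataclass(frozen=True)
class RedundancyLabel:
    """Confirmatory/novel call for one secondary-source hit."""

    hit: DomainHit
    label: str  # "confirmatory" | "novel"
    overlap_fraction: float


def _sort_key(hit: DomainHit):
    # length desc, then deterministic tie-breaks
    return (-hit.length, hit.evalue, hit.start, hit.model_name)


def resolve_domain_overlaps(
    hits: Sequence[DomainHit],
    length: Optional[int] = None,
    policy: str = "greedy",
    seq_id: Optional[str] = None,
) -> ResolvedArchitecture:
    """Resolve overlapping domain hits for one protein.

    With the default ``greedy`` policy, hits are visited longest-first
    (ties broken by E-value, start, model name) and accepted when they
    overlap no previously accepted hit; every rejected hit therefore
    overlaps an accepted hit at least as long as itself.  The ``union``
    policy accepts every hit and counts covered residues as the union.
    """
    if policy not in ("greedy", "union"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    seq_ids = {h.seq_id for h in hits}
    if seq_id is not None:
        seq_ids.add(seq_id)
    if len(seq_ids) > 1:
        raise DataError(f"hits span multiple proteins: {sorted(seq_ids)}")
    seq_id = next(iter(seq_ids)) if seq_ids else ""
    if length is not None:
        for h in hits:
            if h.end > length:
                raise DataError(
                    f"{h.seq_id}/{h.model_name}: end {h.end} exceeds length {length}")

    if policy == "union":
        accepted = sorted(hits, key=lambda h: (h.start, h.end, h.model_name))
        covered = sum(e - s + 1 for s, e in merge_intervals(
            (h.start, h.end) for h in accepted))
        return ResolvedArchitecture(seq_id, accepted, [], covered, length)

    accepted: list[DomainHit] = []
    rejected: list[tuple[DomainHit, str]] = []
    for hit in sorted(hits, key=_sort_key):
        blocker = next((a for a in accepted if a.overlaps(hit)), None)
        if blocker is None:
            accepted.append(hit)
        else:
            rejected.append(
                (hit, f"overlaps longer or equal accepted hit {blocker.model_name}"
                      f"({blocker.start}-{blocker.end})"))
    accepted.sort(key=lambda h: h.start)
    covered = sum(h.length for h in accepted)
    return ResolvedArchitecture(seq_id, accepted, rejected, covered, length)


def residue_union(intervals: Iterable[tuple[int, int]], length: int) -> int:
    """Count distinct residues covered by >=1 interval within [1, length].

    Equals the sum of interval lengths when the intervals are pairwise
    non-overlapping (the simple additive coverage rule).
    """
    ivs = list(intervals)
    for s, e in ivs:
        if not (1 <= s <= e):
            raise DataError(f"invalid interval ({s}, {e})")
        if e > length:
            raise DataError(f"interval ({s}, {e}) exceeds length {length}")
    return sum(e - s + 1 for s, e in merge_intervals(ivs))


def domain_coverage(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    policy: str = "greedy",
) -> tuple[int, float]:
    """Resolved domain coverage of one protein: (covered_aa, fraction)."""
    if protein.length < 1:
        raise DataError(f"{protein.seq_id}: zero-length protein")
    resolved = resolve_domain_overlaps(hits, length=protein.length, policy=policy)
    return resolved.covered_aa, resolved.covered_aa / protein.length


def _clip_to_length(intervals: list[tuple[int, int]],
                    length: Optional[int]) -> list[tuple[int, int]]:
    if length is None:
        return intervals
    return [(s, min(e, length)) for s, e in intervals if s <= length]


def region_partition(
    regions: Sequence[RegionAnnotation],
    resolved: ResolvedArchitecture,
) -> RegionPartition:
    """Split annotated region residues into within- vs outside-domain counts.

    Residues covered by two annotations of the *same* type count once
    for that type (union within type); different types are counted
    independently, so one residue may contribute to several types.
    """
    for r in regions:
        if r.seq_id != resolved.seq_id:
            raise DataError(
                f"region for {r.seq_id!r} does not match resolution for "
                f"{resolved.seq_id!r}")
    domain_ivs = merge_intervals(resolved.intervals)
    part = RegionPartition()
    for rtype in REGION_TYPES:
        type_ivs = merge_intervals(
            (r.start, r.end) for r in regions if r.region_type == rtype)
        total = sum(e - s + 1 for s, e in type_ivs)
        within = _intersection_size(type_ivs, domain_ivs)
        part.within_domain_aa[rtype] = within
        part.outside_domain_aa[rtype] = total - within
    return part


def _intersection_size(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Residue count of the intersection of two disjoint sorted interval lists."""
    i = j = size = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            size += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return size


def redundancy_assessment(
    primary_hits: Sequence[DomainHit],
    secondary_hits: Sequence[DomainHit],
    min_overlap_frac: float = DEFAULT_REDUNDANCY_FRAC,
) -> list[RedundancyLabel]:
    """Label secondary-source hits as confirmatory or novel.

    The primary hits are resolved first; each secondary hit's overlap
    fraction is the share of its residues lying inside the primary
    accepted coverage.  Hits at or above ``min_overlap_frac`` are
    confirmatory (redundant with the primary source), the rest novel.
    """
    if not (0 < min_overlap_frac <= 1):
        raise ValueError(
            f"min_overlap_frac must be in (0, 1], got {min_overlap_frac}")
    seq_ids = {h.seq_id for h in primary_hits} | {h.seq_id for h in secondary_hits}
    if len(seq_ids) > 1:
        raise DataError(f"hits span multiple proteins: {sorted(seq_ids)}")
    resolved = resolve_domain_overlaps(primary_hits)
    primary_ivs = merge_intervals(resolved.intervals)
    labels: list[RedundancyLabel] = []
    for hit in sorted(secondary_hits, key=lambda h: (h.start, h.end, h.model_name)):
        inside = _intersection_size([(hit.start, hit.end)], primary_ivs)
        frac = inside / hit.length
        label = "confirmatory" if frac >= min_overlap_frac else "novel"
        labels.append(RedundancyLabel(hit=hit, label=label, overlap_fraction=frac))
    return labels
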
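"""Database-level aggregation: coverage tables, dark-matter summaries,
release comparisons and reports.

The central product is a coverage table shaped like the classic
"computational coverage of the protein sequence space" summary: total
and domain-covered residue counts for all proteins, and per region type
(LC, TM, CC, SP) the total annotated residues and the subset lying
within accepted domain boundaries.  Percentages follow the same
two-row convention: the first row divides every cell by the total
sequence space, the second divides the region cells by the domain
space (the all-proteins cell of the second row is the overall domain
coverage).  The "all regions" column is the SUM across the four types
(a residue annotated as both LC and TM counts twice); a union-based
alternative is reported alongside under a distinct label when computed
from per-protein annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import pandas as pd

from darkspace.model import AnnotationTable, DataError, REGION_TYPES, merge_intervals
from darkspace.coverage_engine import (
    region_partition,
    resolve_domain_overlaps,
    _intersection_size,
)
from darkspace.darkmatter import DEFAULT_LINKER_MAX, account_protein


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals.

    Used only at presentation time; internal counts stay exact integers.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sci3(x: Union[int, float]) -> str:
    """Scientific notation with 3 significant digits, e.g. ``2.90E+09``."""
    return f"{float(x):.2E}"


@dataclass
class SpaceTable:
    """Residue counts of the sequence space and its domain-covered part."""

    total_aa: int
    domain_aa: int
    region_total_aa: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in REGION_TYPES})
    region_within_aa: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in REGION_TYPES})
    # union-across-types alternative (computable only from raw annotations)
    all_regions_total_union_aa: Optional[int] = None
    all_regions_within_union_aa: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.domain_aa <= self.total_aa):
            raise DataError(
                f"domain_aa {self.domain_aa} outside [0, total_aa={self.total_aa}]")
        for t in REGION_TYPES:
            if self.region_within_aa[t] > self.region_total_aa[t]:
                raise DataError(
                    f"{t}: within-domain {self.region_within_aa[t]} exceeds "
                    f"total {self.region_total_aa[t]}")

    @property
    def all_regions_total_aa(self) -> int:
        return sum(self.region_total_aa[t] for t in REGION_TYPES)

    @property
    def all_regions_within_aa(self) -> int:
        return sum(self.region_within_aa[t] for t in REGION_TYPES)


@dataclass(frozen=True)
class DarkMatterSummary:
    """Dark-matter accounting of a sequence space, counts and percentages."""

    total_aa: int
    domain_aa: int
    short_linker_aa: int
    darkmatter_aa: int
    pct_domain: float
    pct_classic_dark: float
    pct_short_linker: float
    pct_expanded_dark: float


@dataclass(frozen=True)
class ReleaseSnapshot:
    """Domain coverage of one database release."""

    label: str
    total_aa: int
    pct_domain: float

    @property
    def darkmatter_aa(self) -> float:
        return self.total_aa * (100.0 - self.pct_domain) / 100.0


@dataclass
class ReleaseComparison:
    """Ordered snapshots with consecutive coverage deltas (pct points)."""

    snapshots: list[ReleaseSnapshot]
    deltas: list[float]
    darkmatter_aa: list[float]
    total_ratios: list[float]


def aggregate(
    table: AnnotationTable,
    threshold_aa: int = DEFAULT_LINKER_MAX,
    sources: Sequence[str] = ("pfam",),
    policy: str = "greedy",
    tm_source: str = "tmhmm",
) -> tuple[SpaceTable, DarkMatterSummary]:
    """Aggregate per-protein accounting over a whole annotation table.

    Domain coverage uses hits from ``sources`` (Pfam only by default —
    the domain space is defined by curated domain models; CDD hits are
    assessed separately for redundancy).  TM regions are taken from
    ``tm_source`` only, so that a proteome annotated by both TMHMM and
    Phobius does not double count helices.
    """
    if not table.proteins:
        raise DataError("empty proteome")
    table.validate()
    total_aa = domain_aa = short_aa = 0
    reg_total = {t: 0 for t in REGION_TYPES}
    reg_within = {t: 0 for t in REGION_TYPES}
    union_total = union_within = 0
    for protein in table.proteins:
        hits = [h for h in table.hits_for(protein.seq_id) if h.source in sources]
        resolved = resolve_domain_overlaps(hits, length=protein.length,
                                           policy=policy, seq_id=protein.seq_id)
        acc = account_protein(protein.length, resolved, threshold_aa)
        total_aa += protein.length
        domain_aa += acc.domain_aa
        short_aa += acc.short_linker_aa
        regions = [
            r for r in table.regions_for(protein.seq_id)
            if r.region_type != "TM" or r.source_tool == tm_source
        ]
        part = region_partition(regions, resolved)
        for t in REGION_TYPES:
            reg_total[t] += part.total(t)
            reg_within[t] += part.within_domain_aa[t]
        all_ivs = merge_intervals((r.start, r.end) for r in regions)
        union_total += sum(e - s + 1 for s, e in all_ivs)
        union_within += _intersection_size(all_ivs,
                                           merge_intervals(resolved.intervals))
    space = SpaceTable(
        total_aa=total_aa,
        domain_aa=domain_aa,
        region_total_aa=reg_total,
        region_within_aa=reg_within,
        all_regions_total_union_aa=union_total,
        all_regions_within_union_aa=union_within,
    )
    summary = darkmatter_summary(total_aa, domain_aa, short_aa)
    return space, summary


def percent_table(space: SpaceTable) -> dict[str, dict[str, float]]:
    """Two-row percentage view of a :class:`SpaceTable`.

    ``total_space`` row: every cell divided by the total sequence space.
    ``domain_space`` row: the all-proteins cell is the overall domain
    coverage (domain / total); region cells are the within-domain counts
    divided by the domain space.  All cells rounded half-up to 1 decimal.
    """
    if space.total_aa <= 0:
        raise DataError("total_aa must be positive for percentages")
    if space.domain_aa <= 0:
        raise DataError("domain_aa must be positive for domain-space percentages")
    row1 = {"all_proteins": 100.0}
    row2 = {"all_proteins": round_half_up(100.0 * space.domain_aa / space.total_aa)}
    for t in REGION_TYPES:
        row1[t] = round_half_up(100.0 * space.region_total_aa[t] / space.total_aa)
        row2[t] = round_half_up(100.0 * space.region_within_aa[t] / space.domain_aa)
    row1["all_regions"] = round_half_up(
        100.0 * space.all_regions_total_aa / space.total_aa)
    row2["all_regions"] = round_half_up(
        100.0 * space.all_regions_within_aa / space.domain_aa)
    return {"total_space": row1, "domain_space": row2}


def darkmatter_summary(
    total_aa: int, domain_aa: int, short_linker_aa: int
) -> DarkMatterSummary:
    """Dark-matter percentages from residue counts.

    Classic dark matter is everything outside domains; expanded dark
    matter additionally subtracts the short-linker residues:
    ``pct_expanded_dark = 100 * (total - domain - linker) / total``.
    """
    if total_aa <= 0:
        raise DataError("total_aa must be positive")
    if domain_aa + short_linker_aa > total_aa:
        raise DataError(
            f"domain_aa + short_linker_aa = {domain_aa + short_linker_aa} "
            f"exceeds total_aa {total_aa}")
    dark = total_aa - domain_aa - short_linker_aa
    return DarkMatterSummary(
        total_aa=total_aa,
        domain_aa=domain_aa,
        short_linker_aa=short_linker_aa,
        darkmatter_aa=dark,
        pct_domain=round_half_up(100.0 * domain_aa / total_aa),
        pct_classic_dark=round_half_up(100.0 * (total_aa - domain_aa) / total_aa),
        pct_short_linker=round_half_up(100.0 * short_linker_aa / total_aa),
        pct_expanded_dark=round_half_up(100.0 * dark / total_aa),
    )


def compare_releases(snapshots: Sequence[ReleaseSnapshot]) -> ReleaseComparison:
    """Consecutive coverage deltas across ordered database releases.

    Also reports the absolute dark-matter size of each snapshot and the
    total-size ratio between consecutive releases, to expose the
    pattern of relative coverage improving while absolute dark matter
    keeps growing.
    """
    if len(snapshots) < 2:
        raise DataError("need at least two snapshots to compare")
    deltas = [
        round_half_up(b.pct_domain - a.pct_domain)
        for a, b in zip(snapshots, snapshots[1:])
    ]
    ratios = [
        b.total_aa / a.total_aa for a, b in zip(snapshots, snapshots[1:])
    ]
    return ReleaseComparison(
        snapshots=list(snapshots),
        deltas=deltas,
        darkmatter_aa=[s.darkmatter_aa for s in snapshots],
        total_ratios=ratios,
    )


REPORT_COLUMNS = ["section", "row", "column", "aa_sci", "aa_raw", "pct"]


def write_report(
    space: SpaceTable,
    summary: DarkMatterSummary,
    path,
    format: str = "tsv",
    provenance: Optional[dict] = None,
) -> None:
    """Write a coverage + dark-matter report.

    ``tsv`` emits a long-format table (one row per cell) with counts in
    both 3-significant-digit scientific notation and raw integers, plus
    the percentage view; ``text`` emits key:value lines; ``json`` dumps
    every count and percentage (with optional provenance).
    """
    if format == "tsv":
        _write_report_tsv(space, summary, path)
    elif format == "text":
        _write_report_text(space, summary, path)
    elif format == "json":
        payload = report_dict(space, summary)
        if provenance:
            payload["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def report_dict(space: SpaceTable, summary: DarkMatterSummary) -> dict:
    pct = percent_table(space)
    return {
        "space": {
            "total_aa": space.total_aa,
            "domain_aa": space.domain_aa,
            "region_total_aa": dict(space.region_total_aa),
            "region_within_aa": dict(space.region_within_aa),
            "all_regions_total_aa": space.all_regions_total_aa,
            "all_regions_within_aa": space.all_regions_within_aa,
            "all_regions_total_union_aa": space.all_regions_total_union_aa,
            "all_regions_within_union_aa": space.all_regions_within_union_aa,
        },
        "percent": pct,
        "darkmatter": {
            "total_aa": summary.total_aa,
            "domain_aa": summary.domain_aa,
            "short_linker_aa": summary.short_linker_aa,
            "darkmatter_aa": summary.darkmatter_aa,
            "pct_domain": summary.pct_domain,
            "pct_classic_dark": summary.pct_classic_dark,
            "pct_short_linker": summary.pct_short_linker,
            "pct_expanded_dark": summary.pct_expanded_dark,
        },
    }


def _write_report_tsv(space: SpaceTable, summary: DarkMatterSummary, path) -> None:
    pct = percent_table(space)
    rows = []

    def cell(row_name, col, aa, pct_val):
        rows.append(dict(section="space", row=row_name, column=col,
                         aa_sci=sci3(aa), aa_raw=int(aa), pct=pct_val))

    cell("total_space", "all_proteins", space.total_aa,
         pct["total_space"]["all_proteins"])
    for t in REGION_TYPES:
        cell("total_space", t, space.region_total_aa[t], pct["total_space"][t])
    cell("total_space", "all_regions", space.all_regions_total_aa,
         pct["total_space"]["all_regions"])
    cell("domain_space", "all_proteins", space.domain_aa,
         pct["domain_space"]["all_proteins"])
    for t in REGION_TYPES:
        cell("domain_space", t, space.region_within_aa[t], pct["domain_space"][t])
    cell("domain_space", "all_regions", space.all_regions_within_aa,
         pct["domain_space"]["all_regions"])
    if space.all_regions_total_union_aa is not None:
        cell("total_space", "all_regions_union", space.all_regions_total_union_aa,
             round_half_up(100.0 * space.all_regions_total_union_aa / space.total_aa))
    if space.all_regions_within_union_aa is not None:
        cell("domain_space", "all_regions_union", space.all_regions_within_union_aa,
             round_half_up(
                 100.0 * space.all_regions_within_union_aa / space.domain_aa))
    for key, aa, p in [
        ("domain", summary.domain_aa, summary.pct_domain),
        ("classic_dark", summary.total_aa - summary.domain_aa,
         summary.pct_classic_dark),
        ("short_linker", summary.short_linker_aa, summary.pct_short_linker),
        ("expanded_dark", summary.darkmatter_aa, summary.pct_expanded_dark),
    ]:
        rows.append(dict(section="darkmatter", row=key, column="",
                         aa_sci=sci3(aa), aa_raw=int(aa), pct=p))
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def _write_report_text(space: SpaceTable, summary: DarkMatterSummary, path) -> None:
    pct = percent_table(space)
    lines = [
        f"total_aa: {space.total_aa} ({sci3(space.total_aa)})",
        f"domain_aa: {space.domain_aa} ({sci3(space.domain_aa)})",
        f"pct_domain: {summary.pct_domain}",
        f"pct_classic_dark: {summary.pct_classic_dark}",
        f"pct_short_linker: {summary.pct_short_linker}",
        f"pct_expanded_dark: {summary.pct_expanded_dark}",
    ]
    for t in REGION_TYPES:
        lines.append(f"{t}_total_aa: {space.region_total_aa[t]} "
                     f"(pct {pct['total_space'][t]})")
        lines.append(f"{t}_within_domain_aa: {space.region_within_aa[t]} "
                     f"(pct_of_domain {pct['domain_space'][t]})")
    lines.append(f"all_regions_total_aa: {space.all_regions_total_aa} "
                 f"(pct {pct['total_space']['all_regions']})")
    lines.append(f"all_regions_within_aa: {space.all_regions_within_aa} "
                 f"(pct_of_domain {pct['domain_space']['all_regions']})")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report_tsv(path) -> tuple[SpaceTable, DarkMatterSummary]:
    """Re-parse a TSV report into its counts (round-trip of the raw cells)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    sp = df[df["section"] == "space"].set_index(["row", "column"])["aa_raw"]
    reg_total = {t: int(sp[("total_space", t)]) for t in REGION_TYPES}
    reg_within = {t: int(sp[("domain_space", t)]) for t in REGION_TYPES}
    union_t = (int(sp[("total_space", "all_regions_union")])
               if ("total_space", "all_regions_union") in sp.index else None)
    union_w = (int(sp[("domain_space", "all_regions_union")])
               if ("domain_space", "all_regions_union") in sp.index else None)
    space = SpaceTable(
        total_aa=int(sp[("total_space", "all_proteins")]),
        domain_aa=int(sp[("domain_space", "all_proteins")]),
        region_total_aa=reg_total,
        region_within_aa=reg_within,
        all_regions_total_union_aa=union_t,
        all_regions_within_union_aa=union_w,
    )
    dm = df[df["section"] == "darkmatter"].set_index("row")["aa_raw"]
    summary = darkmatter_summary(
        space.total_aa, space.domain_aa, int(dm["short_linker"]))
    return space, summary
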
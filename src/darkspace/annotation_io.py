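"""Readers for predictor output dialects and the unified annotation TSV.

Supported inputs
----------------
* FASTA protein sequences (lengths and identifiers),
* HMMER3 ``hmmscan --domtblout`` per-domain tables (Pfam),
* RPS-BLAST 12-column tabular hits (CDD),
* TMHMM2 long-format output (transmembrane helices),
* SEG ``-l`` interval lists (low complexity),
* Phobius feature lines (signal peptides and transmembrane helices),
* PairCoil2 per-residue tables (coiled coils),

plus a unified tab-separated annotation table that losslessly stores a
whole :class:`~darkspace.model.AnnotationTable`.

All coordinates are 1-based inclusive.  Hits are expected to have been
produced with the curated per-family gathering thresholds (``--cut_ga``)
upstream, so no E-value filtering is applied here; an optional
``max_ievalue`` post-filter is available on :func:`parse_domtblout`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO

from darkspace.model import (
    AnnotationTable,
    DataError,
    DomainHit,
    ProteinRecord,
    RegionAnnotation,
    REGION_TYPES,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Column order of the unified annotation TSV.
TSV_COLUMNS = [
    "seq_id",
    "seq_len",
    "category",
    "type",
    "name",
    "accession",
    "start",
    "end",
    "bit_score",
    "evalue",
]


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The identifier is the header token before the first whitespace; the
    length is the residue count of the (possibly wrapped) sequence.
    Duplicate identifiers raise :class:`DataError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").replace("\t", "")
        records.append(ProteinRecord(seq_id=rec.id, length=len(seq), sequence=seq))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def parse_domtblout(
    path: PathLike,
    source: str = "pfam",
    coords: str = "ali",
    max_ievalue: Optional[float] = None,
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` per-domain table.

    Parameters
    ----------
    source:
        Hit source recorded on each :class:`DomainHit` (``pfam`` by default).
    coords:
        ``"ali"`` takes the alignment coordinate pair (columns 18-19),
        ``"env"`` the envelope pair (columns 20-21).  Alignment
        coordinates are the conservative (smaller) choice and the default.
    max_ievalue:
        Optional post-filter on the per-domain independent E-value.
        ``None`` (default) keeps every row, as appropriate for tables
        already filtered by the gathering thresholds.
    """
    if coords not in ("ali", "env"):
        raise ValueError(f"coords must be 'ali' or 'env', got {coords!r}")
    lo, hi = (17, 18) if coords == "ali" else (19, 20)
    hits: list[DomainHit] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 22)
            if len(fields) < 22:
                raise DataError(
                    f"{path}:{lineno}: expected >=22 domtblout columns, "
                    f"got {len(fields)}"
                )
            target, target_acc, query = fields[0], fields[1], fields[3]
            try:
                ievalue = float(fields[12])
                score = float(fields[13])
                start = int(fields[lo])
                end = int(fields[hi])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if start > end:
                logger.warning(
                    "%s:%d: rejected row with start > end (%d > %d)",
                    path, lineno, start, end,
                )
                continue
            if max_ievalue is not None and ievalue > max_ievalue:
                continue
            key = (query, target, start, end)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                DomainHit(
                    seq_id=query,
                    model_name=target,
                    model_acc=None if target_acc == "-" else target_acc,
                    start=start,
                    end=end,
                    bit_score=score,
                    evalue=ievalue,
                    source=source,
                )
            )
    return hits


def parse_rpsblast_tab(path: PathLike) -> list[DomainHit]:
    """Parse 12-column RPS-BLAST tabular output (``-outfmt 6``) as CDD hits.

    Query coordinates come from columns 7-8; reversed coordinate pairs
    are normalised by swapping (and logged).
    """
    hits: list[DomainHit] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise DataError(
                    f"{path}:{lineno}: expected 12 tabular columns, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                start, end = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
                score = float(fields[11])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if start > end:
                logger.warning(
                    "%s:%d: swapped reversed query coordinates (%d, %d)",
                    path, lineno, start, end,
                )
                start, end = end, start
            # strip the gnl|CDD| prefix down to the profile identifier
            name = subject.split("|")[-1] if "|" in subject else subject
            key = (query, name, start, end)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                DomainHit(
                    seq_id=query,
                    model_name=name,
                    model_acc=subject if subject != name else None,
                    start=start,
                    end=end,
                    bit_score=score,
                    evalue=evalue,
                    source="cdd",
                )
            )
    return hits


def parse_tmhmm(path: PathLike) -> list[RegionAnnotation]:
    """Parse TMHMM2 long-format output; only ``TMhelix`` rows become regions."""
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                warnings.warn(f"{path}:{lineno}: skipping malformed TMHMM line",
                              stacklevel=2)
                continue
            seq_id, _prog, label, start, end = fields
            if label != "TMhelix":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                warnings.warn(f"{path}:{lineno}: skipping malformed TMHMM line",
                              stacklevel=2)
                continue
            regions.append(RegionAnnotation(seq_id, "TM", s, e, "tmhmm"))
    return regions


def parse_seg(path: PathLike) -> list[RegionAnnotation]:
    """Parse SEG ``-l`` interval-list output into low-complexity regions.

    Each segment is announced by a header line ``>seq_id(start-end) ...``;
    intervening sequence lines are ignored.
    """
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line.startswith(">"):
                continue
            header = line[1:].split()[0]
            if "(" not in header or not header.endswith(")"):
                raise DataError(
                    f"{path}:{lineno}: expected SEG -l header '>id(start-end)', "
                    f"got {line!r}"
                )
            seq_id, coords = header[:-1].split("(", 1)
            try:
                start_s, end_s = coords.split("-", 1)
                s, e = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataError(
                    f"{path}:{lineno}: bad SEG coordinates {coords!r}"
                ) from exc
            regions.append(RegionAnnotation(seq_id, "LC", s, e, "seg"))
    return regions


def parse_phobius(path: PathLike) -> list[RegionAnnotation]:
    """Parse Phobius output with ``ID``/``FT`` feature lines.

    ``SIGNAL`` features become SP regions; ``TRANSMEM`` features become
    TM regions tagged ``source_tool="phobius"``.  By convention TMHMM is
    the authority for the TM column, so downstream totals exclude
    Phobius TM regions unless explicitly configured otherwise.
    """
    regions: list[RegionAnnotation] = []
    seq_id: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("//"):
                continue
            fields = line.split()
            if fields[0] == "ID":
                if len(fields) < 2:
                    raise DataError(f"{path}:{lineno}: ID line without identifier")
                seq_id = fields[1]
            elif fields[0] == "FT":
                if seq_id is None:
                    raise DataError(f"{path}:{lineno}: FT line before any ID line")
                if len(fields) >= 2 and fields[1] in ("DOMAIN", "TOPO_DOM"):
                    continue  # cytoplasmic/non-cytoplasmic topology: not regions
                if len(fields) < 4 or fields[1] not in ("SIGNAL", "TRANSMEM"):
                    raise DataError(
                        f"{path}:{lineno}: unrecognized Phobius feature line "
                        f"{line!r}; expected 'FT SIGNAL|TRANSMEM start end'"
                    )
                try:
                    s, e = int(fields[2]), int(fields[3])
                except ValueError as exc:
                    raise DataError(
                        f"{path}:{lineno}: bad Phobius coordinates"
                    ) from exc
                rtype = "SP" if fields[1] == "SIGNAL" else "TM"
                regions.append(RegionAnnotation(seq_id, rtype, s, e, "phobius"))
            else:
                raise DataError(
                    f"{path}:{lineno}: unrecognized Phobius line {line!r}; "
                    f"expected ID/FT records"
                )
    return regions


def parse_paircoil2(path: PathLike, threshold: Optional[float] = None) -> list[RegionAnnotation]:
    """Parse a PairCoil2 per-residue table into coiled-coil intervals.

    The table holds one ``position residue score`` row per residue under
    ``> seq_id`` block headers.  Runs of consecutive residues with score
    >= the coiled-coil probability threshold (taken from a
    ``# threshold=...`` header comment, else 0.5) are merged into CC
    intervals.
    """
    regions: list[RegionAnnotation] = []
    seq_id: Optional[str] = None
    run_start: Optional[int] = None
    prev_pos: Optional[int] = None

    def close_run() -> None:
        nonlocal run_start
        if seq_id is not None and run_start is not None and prev_pos is not None:
            regions.append(RegionAnnotation(seq_id, "CC", run_start, prev_pos,
                                            "paircoil2"))
        run_start = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "threshold=" in line and threshold is None:
                    threshold = float(line.split("threshold=")[1].split()[0])
                continue
            if line.startswith(">"):
                close_run()
                seq_id = line[1:].strip().split()[0]
                prev_pos = None
                continue
            fields = line.split()
            if seq_id is None or len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: unrecognized PairCoil2 line {line!r}; "
                    f"expected '> id' headers and 'pos residue score' rows"
                )
            try:
                pos = int(fields[0])
                score = float(fields[-1])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad PairCoil2 row") from exc
            cut = 0.5 if threshold is None else threshold
            if score >= cut:
                if run_start is None or (prev_pos is not None and pos != prev_pos + 1):
                    close_run()
                    run_start = pos
                prev_pos = pos
            else:
                close_run()
                prev_pos = pos
    close_run()
    return regions


def write_annotation_tsv(table: AnnotationTable, path: PathLike) -> None:
    """Write an :class:`AnnotationTable` to the unified TSV.

    Rows are sorted by (seq_id, category, start): protein rows first
    (category ``protein``), then domains, then regions.
    """
    lengths = {p.seq_id: p.length for p in table.proteins}
    rows: list[dict] = []
    for p in table.proteins:
        rows.append(dict(seq_id=p.seq_id, seq_len=p.length, category="protein",
                         type="", name="", accession="", start="", end="",
                         bit_score="", evalue=""))
    for h in table.domain_hits:
        rows.append(dict(seq_id=h.seq_id, seq_len=lengths.get(h.seq_id, ""),
                         category="domain", type=h.source, name=h.model_name,
                         accession=h.model_acc or "", start=h.start, end=h.end,
                         bit_score=repr(h.bit_score), evalue=repr(h.evalue)))
    for r in table.regions:
        rows.append(dict(seq_id=r.seq_id, seq_len=lengths.get(r.seq_id, ""),
                         category="region", type=r.region_type, name=r.source_tool,
                         accession="", start=r.start, end=r.end,
                         bit_score="", evalue=""))
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    order = {"protein": 0, "domain": 1, "region": 2}
    df["_cat"] = df["category"].map(order)
    df["_start"] = pd.to_numeric(df["start"], errors="coerce").fillna(0)
    df = df.sort_values(["seq_id", "_cat", "_start", "name"], kind="stable")
    df = df.drop(columns=["_cat", "_start"])
    df.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: PathLike) -> AnnotationTable:
    """Read the unified annotation TSV back into an :class:`AnnotationTable`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing TSV columns {missing}")
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    regions: list[RegionAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        cat = row.category
        if cat == "protein":
            proteins.append(ProteinRecord(row.seq_id, int(row.seq_len)))
        elif cat == "domain":
            if row.type not in ("pfam", "cdd"):
                raise DataError(f"{path}:{i}: unknown domain source {row.type!r}")
            hits.append(DomainHit(
                seq_id=row.seq_id, model_name=row.name,
                model_acc=row.accession or None,
                start=int(row.start), end=int(row.end),
                bit_score=float(row.bit_score), evalue=float(row.evalue),
                source=row.type))
        elif cat == "region":
            if row.type not in REGION_TYPES:
                raise DataError(f"{path}:{i}: unknown region type {row.type!r}")
            regions.append(RegionAnnotation(
                row.seq_id, row.type, int(row.start), int(row.end), row.name))
        else:
            raise DataError(f"{path}:{i}: unknown category {cat!r}")
    table = AnnotationTable(proteins=proteins, domain_hits=hits, regions=regions)
    table.validate()
    return table
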
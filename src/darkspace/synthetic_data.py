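"""Synthetic proteome generator with full ground truth.

Generates proteomes with planted domain architectures and region
annotations and emits them in every input dialect the package reads
(FASTA, HMMER3 domtblout, RPS-BLAST tabular, TMHMM2 long format, SEG
interval lists, Phobius feature lines, PairCoil2 per-residue tables),
so every pipeline stage is testable without external data.

Architectures are built left to right: an optional N-terminal signal
peptide and tail, then domains alternating with short linkers, then a
C-terminal tail.  Default distributions emulate the broad statistics of
real domain architectures: domain lengths bounded to 40-700 aa with a
mean near 100 aa, interdomain linkers averaging ~7 aa, transmembrane
helices of ~21 aa, N-terminal signal peptides of 15-30 aa.  Planted
domains never overlap one another; overlap-resolution logic is
exercised by a decoy mode that injects strictly shorter overlapping
hits whose expected resolution (rejection) is known.

Amino-acid composition is uniform random — residue identity is
irrelevant to coverage accounting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from darkspace.model import (
    AnnotationTable,
    DataError,
    DomainHit,
    ProteinRecord,
    RegionAnnotation,
    merge_intervals,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# length distributions with exact means (closed form or finite enumeration)

@dataclass(frozen=True)
class UniformInt:
    """Uniform integer on [lo, hi], inclusive."""

    lo: int
    hi: int

    def __post_init__(self):
        if not (0 <= self.lo <= self.hi):
            raise DataError(f"invalid UniformInt bounds ({self.lo}, {self.hi})")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.lo, self.hi + 1))

    def mean(self) -> float:
        return (self.lo + self.hi) / 2.0


@dataclass(frozen=True)
class BoundedGeometric:
    """``offset + min(G, cap - offset)`` with G geometric (mean ``mean_excess``).

    G counts failures: ``P(G = k) = (1 - p) ** k * p`` with
    ``p = 1 / (1 + mean_excess)``.  The truncated mean is closed-form:
    ``E[min(G, m)] = (1 - p) * (1 - (1 - p) ** m) / p``.
    """

    offset: int
    mean_excess: float
    cap: int

    def __post_init__(self):
        if self.offset < 0 or self.cap < self.offset or self.mean_excess < 0:
            raise DataError("invalid BoundedGeometric parameters")

    @property
    def _p(self) -> float:
        return 1.0 / (1.0 + self.mean_excess)

    def sample(self, rng: np.random.Generator) -> int:
        # numpy's geometric counts trials (>=1); failures = trials - 1
        g = int(rng.geometric(self._p)) - 1
        return self.offset + min(g, self.cap - self.offset)

    def mean(self) -> float:
        p, m = self._p, self.cap - self.offset
        return self.offset + (1 - p) * (1 - (1 - p) ** m) / p


@dataclass(frozen=True)
class TruncatedGeometric:
    """Integer on [lo, hi] with ``P(k) proportional to ratio ** (k - lo)``."""

    lo: int
    hi: int
    ratio: float

    def __post_init__(self):
        if not (0 <= self.lo <= self.hi) or not (0 < self.ratio <= 1):
            raise DataError("invalid TruncatedGeometric parameters")

    def _pmf(self) -> np.ndarray:
        w = np.array([self.ratio ** (k - self.lo)
                      for k in range(self.lo, self.hi + 1)])
        return w / w.sum()

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(np.arange(self.lo, self.hi + 1), p=self._pmf()))

    def mean(self) -> float:
        return float(np.arange(self.lo, self.hi + 1) @ self._pmf())


Distribution = Union[UniformInt, BoundedGeometric, TruncatedGeometric]

_DIST_KINDS = {
    "uniform_int": UniformInt,
    "bounded_geometric": BoundedGeometric,
    "truncated_geometric": TruncatedGeometric,
}


def dist_from_spec(spec: dict) -> Distribution:
    kind = spec.get("kind")
    if kind not in _DIST_KINDS:
        raise DataError(f"unknown distribution kind {kind!r}")
    kwargs = {k: v for k, v in spec.items() if k != "kind"}
    return _DIST_KINDS[kind](**kwargs)


def dist_to_spec(dist: Distribution) -> dict:
    kind = {v: k for k, v in _DIST_KINDS.items()}[type(dist)]
    return {"kind": kind, **dataclasses.asdict(dist)}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic proteome generator.

    Defaults emulate broad statistics of real annotated proteomes:
    domains 40-700 aa with mean ~101 aa, about two domains per
    domain-bearing protein, ~7-aa interdomain linkers, 28% of proteins
    domain-free (large-database surveys assign roughly 72% of sequences
    to known families), ~21-aa TM helices on a fifth of proteins, and
    N-terminal signal peptides of 15-30 aa on a tenth.
    """

    n_proteins: int = 200
    seed: int = 0
    fraction_domain_free: float = 0.28
    # architecture
    domain_count: Distribution = field(
        default_factory=lambda: TruncatedGeometric(1, 6, 0.5))
    domain_length: Distribution = field(
        default_factory=lambda: BoundedGeometric(40, 61.0, 700))
    linker_length: Distribution = field(
        default_factory=lambda: UniformInt(4, 10))
    terminal_tail: Distribution = field(
        default_factory=lambda: BoundedGeometric(0, 15.0, 120))
    domain_free_length: Distribution = field(
        default_factory=lambda: UniformInt(60, 400))
    # regions
    sp_prob: float = 0.10
    sp_length: Distribution = field(default_factory=lambda: UniformInt(15, 30))
    sp_extra_tail: Distribution = field(
        default_factory=lambda: BoundedGeometric(0, 5.0, 30))
    tm_protein_prob: float = 0.20
    tm_count: Distribution = field(default_factory=lambda: UniformInt(1, 7))
    tm_length: Distribution = field(default_factory=lambda: UniformInt(21, 21))
    lc_count: Distribution = field(default_factory=lambda: UniformInt(0, 2))
    lc_length: Distribution = field(default_factory=lambda: UniformInt(8, 30))
    cc_prob: float = 0.15
    cc_length: Distribution = field(default_factory=lambda: UniformInt(21, 60))
    region_within_domain_prob: float = 0.5
    # cross-source and decoy overlays
    cdd_confirm_prob: float = 0.5
    cdd_fulllen_prob: float = 0.05
    decoy_rate: float = 0.0
    # accounting
    linker_threshold_aa: int = 50
    with_sequences: bool = True

    def __post_init__(self):
        for name in ("fraction_domain_free", "sp_prob", "tm_protein_prob",
                     "cc_prob", "region_within_domain_prob", "cdd_confirm_prob",
                     "cdd_fulllen_prob", "decoy_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 0:
            raise DataError("n_proteins must be >= 0")
        if self.linker_threshold_aa < 1:
            raise DataError("linker_threshold_aa must be >= 1")
        for name in ("domain_count", "domain_length", "linker_length",
                     "terminal_tail", "domain_free_length", "sp_length",
                     "sp_extra_tail", "tm_count", "tm_length", "lc_count",
                     "lc_length", "cc_length"):
            if isinstance(getattr(self, name), dict):
                setattr(self, name, dist_from_spec(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            raw[f.name] = dist_to_spec(v) if not isinstance(
                v, (int, float, bool)) else v
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class ProteinTruth:
    """Planted architecture and derived accounting of one protein."""

    seq_id: str
    length: int
    domains: list[tuple[str, int, int]]
    regions: list[tuple[str, int, int]]
    domain_aa: int
    short_linker_aa: int
    darkmatter_aa: int
    segment_classes: list[tuple[int, int, str, str]]  # start, end, context, class

    @property
    def has_domain(self) -> bool:
        return bool(self.domains)


@dataclass
class GroundTruth:
    """Global bookkeeping of a generated proteome."""

    proteins: list[ProteinTruth]
    threshold_aa: int
    seed: int

    @property
    def total_aa(self) -> int:
        return sum(p.length for p in self.proteins)

    @property
    def domain_aa(self) -> int:
        return sum(p.domain_aa for p in self.proteins)

    @property
    def global_coverage(self) -> float:
        return self.domain_aa / self.total_aa if self.total_aa else 0.0

    @property
    def n_domain_free(self) -> int:
        return sum(1 for p in self.proteins if not p.has_domain)


def _truth_segments(length: int, domains: list[tuple[str, int, int]],
                    threshold: int) -> list[tuple[int, int, str, str]]:
    """Independent complement/classification bookkeeping for the truth record."""
    if not domains:
        return [(1, length, "full_protein", "dark_matter")]
    ivs = merge_intervals((s, e) for _, s, e in domains)
    out = []
    if ivs[0][0] > 1:
        out.append((1, ivs[0][0] - 1, "n_terminal"))
    for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
        out.append((e1 + 1, s2 - 1, "interdomain"))
    if ivs[-1][1] < length:
        out.append((ivs[-1][1] + 1, length, "c_terminal"))
    return [
        (s, e, ctx,
         "short_linker" if (e - s + 1) < threshold else "dark_matter")
        for s, e, ctx in out
    ]


# ---------------------------------------------------------------------------
# generation

def _place_region(rng: np.random.Generator, length: int, rlen: int,
                  domains: list[tuple[str, int, int]],
                  within_prob: float) -> tuple[int, int]:
    """Pick a start for a region overlay; optionally bias into a domain."""
    rlen = min(rlen, length)
    if domains and rng.random() < within_prob:
        _, ds, de = domains[int(rng.integers(len(domains)))]
        start = int(rng.integers(ds, de + 1))
    else:
        start = int(rng.integers(1, length - rlen + 2))
    end = min(start + rlen - 1, length)
    return start, end


def generate_proteome(
    config: GeneratorConfig,
) -> tuple[AnnotationTable, GroundTruth]:
    """Generate a proteome with planted architectures; deterministic per seed.

    The emitted domain hits are the planted domains themselves (scores
    high, E-values far below any filter), so a pipeline consuming them
    recovers the planted coverage exactly.
    """
    rng = np.random.default_rng(config.seed)
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    regions: list[RegionAnnotation] = []
    truths: list[ProteinTruth] = []

    for i in range(config.n_proteins):
        seq_id = f"syn{i:05d}"
        domains: list[tuple[str, int, int]] = []
        prot_regions: list[tuple[str, int, int]] = []
        domain_free = rng.random() < config.fraction_domain_free

        if domain_free:
            length = config.domain_free_length.sample(rng)
            has_sp = rng.random() < config.sp_prob
            if has_sp:
                sp_len = min(config.sp_length.sample(rng), length)
                prot_regions.append(("SP", 1, sp_len))
        else:
            pos = 0
            if rng.random() < config.sp_prob:
                sp_len = config.sp_length.sample(rng)
                prot_regions.append(("SP", 1, sp_len))
                pos = sp_len + config.sp_extra_tail.sample(rng)
            else:
                pos = config.terminal_tail.sample(rng)
            n_dom = config.domain_count.sample(rng)
            for d in range(n_dom):
                dlen = config.domain_length.sample(rng)
                name = f"DOM{int(rng.integers(0, 500)):04d}"
                domains.append((name, pos + 1, pos + dlen))
                pos += dlen
                if d < n_dom - 1:
                    pos += config.linker_length.sample(rng)
            pos += config.terminal_tail.sample(rng)
            length = pos

        # region overlays
        if rng.random() < config.tm_protein_prob:
            for _ in range(config.tm_count.sample(rng)):
                s, e = _place_region(rng, length, config.tm_length.sample(rng),
                                     domains, config.region_within_domain_prob)
                prot_regions.append(("TM", s, e))
        for _ in range(config.lc_count.sample(rng)):
            s, e = _place_region(rng, length, config.lc_length.sample(rng),
                                 domains, config.region_within_domain_prob)
            prot_regions.append(("LC", s, e))
        if rng.random() < config.cc_prob:
            s, e = _place_region(rng, length, config.cc_length.sample(rng),
                                 domains, config.region_within_domain_prob)
            prot_regions.append(("CC", s, e))

        seq = ("".join(rng.choice(AMINO_ACIDS, size=length))
               if config.with_sequences else None)
        proteins.append(ProteinRecord(seq_id, length, seq))

        for name, s, e in domains:
            evalue = 10.0 ** -int(rng.integers(10, 60))
            score = round(float((e - s + 1) * 1.5 + rng.integers(0, 50)), 1)
            hits.append(DomainHit(seq_id, name, s, e, score, evalue, "pfam",
                                  model_acc=f"PF{name[3:]:>05s}.1"))
            # decoy overlay: a strictly shorter hit overlapping this domain,
            # with a worse E-value; the greedy rule must reject it
            if config.decoy_rate and rng.random() < config.decoy_rate:
                dlen = e - s + 1
                if dlen >= 3:
                    cut = max(1, dlen // 3)
                    ds = s + int(rng.integers(0, cut))
                    de = min(e + int(rng.integers(0, cut)), length)
                    if de - ds < dlen - 1:  # strictly shorter
                        hits.append(DomainHit(
                            seq_id, f"DEC{name[3:]}", ds, de,
                            round(score / 2, 1), 10.0 ** -int(rng.integers(3, 9)),
                            "pfam", model_acc=f"PF9{name[3:]:>04s}.1"))
            # CDD overlays: confirmatory duplicate and/or full-length profile
            if rng.random() < config.cdd_confirm_prob:
                cd_name = f"cd{name[3:]:>05s}"
                hits.append(DomainHit(
                    seq_id, cd_name, s, e, round(score * 0.8, 1),
                    10.0 ** -int(rng.integers(5, 40)), "cdd",
                    model_acc=f"gnl|CDD|{cd_name}"))
        if domains and rng.random() < config.cdd_fulllen_prob:
            prk_name = f"PRK{int(rng.integers(10000, 20000))}"
            hits.append(DomainHit(
                seq_id, prk_name, 1, length,
                round(length * 0.9, 1), 10.0 ** -int(rng.integers(5, 40)), "cdd",
                model_acc=f"gnl|CDD|{prk_name}"))

        source_for = {"TM": "tmhmm", "LC": "seg", "CC": "paircoil2",
                      "SP": "phobius"}
        for rtype, s, e in prot_regions:
            regions.append(RegionAnnotation(seq_id, rtype, s, e,
                                            source_for[rtype]))

        dom_aa = sum(e - s + 1 for _, s, e in domains)
        segs = _truth_segments(length, domains, config.linker_threshold_aa)
        short_aa = sum(e - s + 1 for s, e, _, k in segs if k == "short_linker")
        dark_aa = sum(e - s + 1 for s, e, _, k in segs if k == "dark_matter")
        truths.append(ProteinTruth(
            seq_id=seq_id, length=length, domains=domains,
            regions=prot_regions, domain_aa=dom_aa, short_linker_aa=short_aa,
            darkmatter_aa=dark_aa, segment_classes=segs))

    table = AnnotationTable(proteins=proteins, domain_hits=hits, regions=regions)
    table.validate()
    return table, GroundTruth(proteins=truths,
                              threshold_aa=config.linker_threshold_aa,
                              seed=config.seed)


def planted_coverage(config: GeneratorConfig) -> float:
    """Analytic expected global domain coverage under a configuration.

    Global coverage is total domain residues over total residues, so the
    expectation is a ratio of per-protein expectations (both linear in
    the configured distribution means, which are exact).
    """
    f = config.fraction_domain_free
    e_ndom = config.domain_count.mean()
    e_dom_aa = (1 - f) * e_ndom * config.domain_length.mean()
    e_ntail = (config.sp_prob
               * (config.sp_length.mean() + config.sp_extra_tail.mean())
               + (1 - config.sp_prob) * config.terminal_tail.mean())
    e_len_domainful = (e_ndom * config.domain_length.mean()
                       + (e_ndom - 1) * config.linker_length.mean()
                       + e_ntail + config.terminal_tail.mean())
    e_len = f * config.domain_free_length.mean() + (1 - f) * e_len_domainful
    if e_len == 0:
        return 0.0
    return e_dom_aa / e_len


# ---------------------------------------------------------------------------
# format emission

DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession"
    "   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score"
    "  bias  from    to  from    to  from    to  acc description of target\n"
)


def emit_formats(table: AnnotationTable, ground_truth: Optional[GroundTruth],
                 out_dir) -> dict[str, Path]:
    """Write a proteome in every supported dialect plus unified/ground-truth TSVs.

    Re-parsing each dialect reproduces the corresponding slice of the
    table exactly.  Returns a mapping of format name to written path.
    """
    from darkspace import annotation_io  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = {p.seq_id: p.length for p in table.proteins}
    paths: dict[str, Path] = {}

    # FASTA
    fasta = out / "proteome.fasta"
    with open(fasta, "w") as fh:
        for p in table.proteins:
            seq = p.sequence or "X" * p.length
            fh.write(f">{p.seq_id}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")
    paths["fasta"] = fasta

    # HMMER3 domtblout (Pfam hits)
    domtbl = out / "pfam.domtblout"
    with open(domtbl, "w") as fh:
        fh.write(DOMTBL_HEADER)
        pfam = [h for h in table.domain_hits if h.source == "pfam"]
        for h in sorted(pfam, key=lambda h: (h.seq_id, h.start, h.model_name)):
            qlen = lengths[h.seq_id]
            env_from = max(1, h.start - 2)
            env_to = min(qlen, h.end + 2)
            fh.write(
                f"{h.model_name} {h.model_acc or '-'} {h.length} {h.seq_id} - "
                f"{qlen} {h.evalue:.2g} {h.bit_score:.1f} 0.1 1 1 "
                f"{h.evalue:.2g} {h.evalue:.2g} {h.bit_score:.1f} 0.1 "
                f"1 {h.length} {h.start} {h.end} {env_from} {env_to} 0.95 -\n")
    paths["domtblout"] = domtbl

    # RPS-BLAST tabular (CDD hits)
    rps = out / "cdd.rpsblast.tsv"
    with open(rps, "w") as fh:
        cdd = [h for h in table.domain_hits if h.source == "cdd"]
        for h in sorted(cdd, key=lambda h: (h.seq_id, h.start, h.model_name)):
            subject = h.model_acc or h.model_name
            fh.write("\t".join(map(str, [
                h.seq_id, subject, "35.0", h.length, h.length // 3, 1,
                h.start, h.end, 1, h.length, f"{h.evalue:.2g}",
                f"{h.bit_score:.1f}"])) + "\n")
    paths["rpsblast"] = rps

    # TMHMM long format
    tmf = out / "tm.tmhmm.txt"
    with open(tmf, "w") as fh:
        tm = [r for r in table.regions
              if r.region_type == "TM" and r.source_tool == "tmhmm"]
        by_seq: dict[str, list] = {}
        for r in tm:
            by_seq.setdefault(r.seq_id, []).append(r)
        for seq_id in sorted(by_seq):
            fh.write(f"{seq_id}\tTMHMM2.0\tinside\t1\t{lengths[seq_id]}\n")
            for r in sorted(by_seq[seq_id], key=lambda r: r.start):
                fh.write(f"{seq_id}\tTMHMM2.0\tTMhelix\t{r.start}\t{r.end}\n")
    paths["tmhmm"] = tmf

    # SEG -l interval list
    segf = out / "lc.seg.txt"
    seqs = {p.seq_id: p.sequence or "x" * p.length for p in table.proteins}
    with open(segf, "w") as fh:
        lc = [r for r in table.regions if r.region_type == "LC"]
        for r in sorted(lc, key=lambda r: (r.seq_id, r.start)):
            fh.write(f">{r.seq_id}({r.start}-{r.end}) complexity=1.90 (12/2.20/2.50)\n")
            fh.write(seqs[r.seq_id][r.start - 1:r.end].lower() + "\n")
    paths["seg"] = segf

    # Phobius feature lines (signal peptides)
    phob = out / "sp.phobius.txt"
    with open(phob, "w") as fh:
        sp = [r for r in table.regions if r.region_type == "SP"]
        by_seq = {}
        for r in sp:
            by_seq.setdefault(r.seq_id, []).append(r)
        for seq_id in sorted(by_seq):
            fh.write(f"ID   {seq_id}\n")
            for r in sorted(by_seq[seq_id], key=lambda r: r.start):
                fh.write(f"FT   SIGNAL   {r.start}   {r.end}\n")
            fh.write("//\n")
    paths["phobius"] = phob

    # PairCoil2 per-residue table (only proteins with CC annotations)
    pc = out / "cc.paircoil2.txt"
    with open(pc, "w") as fh:
        fh.write("# paircoil2 threshold=0.5\n")
        cc = [r for r in table.regions if r.region_type == "CC"]
        by_seq = {}
        for r in cc:
            by_seq.setdefault(r.seq_id, []).append(r)
        for seq_id in sorted(by_seq):
            inside = set()
            for r in by_seq[seq_id]:
                inside.update(range(r.start, r.end + 1))
            seq = seqs[seq_id]
            fh.write(f"> {seq_id}\n")
            for pos in range(1, lengths[seq_id] + 1):
                score = 0.90 if pos in inside else 0.02
                fh.write(f"{pos} {seq[pos - 1]} {score:.2f}\n")
    paths["paircoil2"] = pc

    # unified annotation TSV
    tsv = out / "annotations.tsv"
    annotation_io.write_annotation_tsv(table, tsv)
    paths["tsv"] = tsv

    # ground truth
    if ground_truth is not None:
        gt_tsv = out / "groundtruth.tsv"
        with open(gt_tsv, "w") as fh:
            fh.write("seq_id\tlength\tdomain_aa\tshort_linker_aa\t"
                     "darkmatter_aa\thas_domain\n")
            for t in ground_truth.proteins:
                fh.write(f"{t.seq_id}\t{t.length}\t{t.domain_aa}\t"
                         f"{t.short_linker_aa}\t{t.darkmatter_aa}\t"
                         f"{int(t.has_domain)}\n")
        gt_json = out / "groundtruth.json"
        with open(gt_json, "w") as fh:
            json.dump({
                "seed": ground_truth.seed,
                "threshold_aa": ground_truth.threshold_aa,
                "total_aa": ground_truth.total_aa,
                "domain_aa": ground_truth.domain_aa,
                "global_coverage": ground_truth.global_coverage,
                "n_proteins": len(ground_truth.proteins),
                "n_domain_free": ground_truth.n_domain_free,
            }, fh, indent=2)
            fh.write("\n")
        paths["groundtruth_tsv"] = gt_tsv
        paths["groundtruth_json"] = gt_json
    return paths
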
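# Methods

## Coverage model

The package models a protein database as a set of sequences, each
carrying domain hits (Pfam profile-HMM matches; optionally CDD PSSM
matches) and region annotations (low complexity, transmembrane helix,
coiled coil, signal peptide). All coordinates are 1-based and
inclusive; two intervals overlap when they share at least one residue.
Residue coverage of non-overlapping intervals is the sum of their
lengths; in general it is the residue union.

### Overlap resolution

The longest-domain rule for a pair of overlapping hits — keep the
longer — is extended to arbitrary overlap chains by a deterministic
greedy pass: sort hits by (length desc, E-value asc, start asc, model
name asc) and accept each hit that overlaps no previously accepted
hit. This yields a certificate that makes the rule testable: accepted
hits are pairwise disjoint, and every rejected hit overlaps an
accepted hit at least as long as itself. The rule is deliberately not
coverage-maximising: a long hit spanning two shorter non-overlapping
hits excludes both (a documented property, exercised in the tests).
How the original pairwise rule behaved on chains of three or more
mutually overlapping hits is genuinely underdetermined, so the policy
is configurable (`--overlap-policy greedy|union`); `union` accepts
everything and counts the residue union.

Domain coordinates are taken from the domtblout *alignment* coordinate
pair by default — the conservative (smaller) choice — with
`--coords env` switching to envelope coordinates. Hits are assumed to
have passed the curated per-family gathering thresholds upstream
(`hmmscan --cut_ga`), so no E-value filter is applied by default; an
optional `--max-ievalue` post-filter exists for tables produced
otherwise.

### Dark-matter accounting

Uncovered segments are the maximal intervals outside accepted domains,
tagged n_terminal / c_terminal / interdomain / full_protein. A segment
is a subtractable **short linker** iff it is strictly shorter than the
linker cutoff (default 50 aa) *and* borders at least one domain. The
strict inequality follows the "less than 50 aa" convention; the cutoff
is configurable (`--linker-max`). The rationale for 50 aa: the
smallest domains are just under 50 aa and domains are always separated
by at least a small linker (average 6–8 aa), so no segment under 50 aa
can hide a domain. A domain-free protein is classic dark matter in its
entirety, whatever its length — subtractability never applies to it.
Per protein the partition is exclusive and exhaustive:
`domain_aa + short_linker_aa + darkmatter_aa = length`.

Classic dark matter of a database is `100·(1 − Σdomain/Σtotal)` %;
expanded dark matter additionally subtracts short-linker residues.
Region annotations never reduce dark matter: the within/outside-domain
partition (below) shows no region type lies overwhelmingly outside
domains, so none can be confidently subtracted.

### Region partition

When a domain and a region overlap, the domain has priority: the
shared residues count as domain coverage, and the region residue is
merely classified *within-domain*. Within one region type, residues
covered by two annotations count once (union); across types they count
independently, so the "all regions" cells of the coverage table are
row sums — a residue annotated as both LC and TM contributes twice.
This sum convention matches how such tables are conventionally
printed; since it is not the only defensible choice, aggregation also
reports a union-across-types alternative under a distinct label.
TM annotations are taken from TMHMM only by default; Phobius
contributes signal peptides, and its TM calls are kept (tagged
`source_tool=phobius`) but excluded from totals unless
`--tm-source phobius`, to avoid double counting helices.

### Cross-source redundancy

CDD profiles partially duplicate Pfam. For each secondary (CDD) hit
the overlap fraction is the share of its residues inside the resolved
primary (Pfam) coverage; at or above the threshold (default 0.75,
`--redundancy-frac`) the hit is *confirmatory*, otherwise *novel*
(e.g. a full-protein profile spanning an uncovered terminus). The 0.75
default is this package's choice — the distinction is qualitative and
no canonical value exists. Because CDD profiles often cover full-length
proteins rather than domains, the domain space itself is defined by
Pfam hits only by default (`--sources pfam`); CDD can be added
explicitly.

### Percentages and rounding

Counts are exact integers throughout; rounding (half-up, 1 decimal)
happens only at presentation. The percentage table has two rows: cells
of the first are divided by the total sequence space; region cells of
the second by the domain space, with the all-proteins cell of that row
being overall domain coverage. Release comparisons operate on stored
snapshot summaries (label, total aa, coverage %) and report
consecutive percentage-point deltas, total-size ratios and absolute
dark-matter sizes; they never re-run upstream predictors.

## Synthetic proteome generator

The generator builds each protein left to right: an optional
N-terminal signal peptide and tail, then domains alternating with
linkers, then a C-terminal tail. Defaults (all configurable via YAML):

| parameter | default | rationale |
| --- | --- | --- |
| domain length | geometric, offset 40, cap 700, mean ≈ 101 aa | domains span 40–700 aa with a mean near 100 |
| domains per domain-bearing protein | truncated geometric on 1–6, mean ≈ 1.9 | most proteins have one or two domains |
| linker length | uniform 4–10 aa (mean 7) | average interdomain linker is 6–8 aa |
| terminal tails | geometric, mean ≈ 15 aa, cap 120 | short uncovered termini |
| fraction domain-free | 0.28 | large-database surveys assign ~72 % of sequences to families |
| domain-free protein length | uniform 60–400 aa | hypothetical-protein length range |
| TM helix | 21 aa, 1–7 per membrane protein (20 % of proteins) | canonical helix span |
| signal peptide | 15–30 aa, N-terminal, 10 % of proteins | typical SP lengths |
| LC / CC segments | 0–2 of 8–30 aa; 15 % chance of one 21–60 aa | interdomain low-complexity/coiled-coil stretches |

Planted domains never overlap; the overlap machinery is exercised by a
decoy mode (`decoy_rate`) that injects strictly shorter overlapping
hits with worse E-values whose expected resolution (rejection) is
known, leaving ground-truth coverage unchanged. Region overlays may
deliberately overlap domains (probability `region_within_domain_prob`,
default 0.5) to exercise the partition logic. Emitted scores and
E-values are far below any filter and use round representations so
that text emission and re-parsing are lossless.

Every length distribution exposes an exact mean (closed form for the
truncated geometric, enumeration for finite supports), so the expected
global coverage `planted_coverage` is analytic: a ratio of per-protein
expectations, which is the correct target for the sum/sum empirical
coverage. Statistical recovery tests compare seed-averaged empirical
coverage against it at three standard errors.

### What the generator does and does not emulate

It reproduces the *bookkeeping* structure of real data — formats,
coordinate conventions, architecture statistics, cross-source
redundancy, overlap conflicts — with exact ground truth. It does not
emulate realistic amino-acid composition, homology between proteins,
predictor false positives/negatives, or correlated placement of
regions and domain families. Passing tests therefore demonstrate that
the accounting is correct given predictor outputs, not that the
predictors themselves are accurate.

## Numerical and degenerate-case conventions

* Ties in overlap resolution break by E-value, then start, then model
  name, making results independent of input order.
* Duplicate identical hits (same protein, model, coordinates) are
  dropped at parse time.
* RPS-BLAST rows with reversed query coordinates are normalised by
  swapping (logged); domtblout rows with start > end are rejected
  (logged).
* Empty proteomes are an error for aggregation; empty hit sets yield a
  single full-protein dark-matter segment.
* Zero denominators (empty total or domain space) raise errors rather
  than emitting NaN percentages.

## Problem sizes

The bundled test and acceptance runs use synthetic proteomes of
150–2,000 proteins and 20-seed replicates of 300–400 proteins, sizes
at which every check (exact recovery, conservation, 3-SE statistical
agreement) is stable and the whole suite runs in seconds. Database
scale figures quoted in reports (5.64E9 aa etc.) enter only as
arithmetic inputs; the package does not attempt proteome downloads or
predictor execution.

## Known limitations

* The greedy longest-domain rule is one determination of an
  underdetermined pairwise rule; `union` mode bounds the effect.
* The unified TSV stores identifiers and lengths, not residues; round
  trips preserve sequences only through FASTA.
* PairCoil2 and SEG output dialects vary between builds; the supported
  dialects are the per-residue table with a threshold header and the
  `-l` interval list respectively.
* Redundancy labels are per-hit, not per-profile-family; no attempt is
  made to decide whether a novel CDD hit represents a real domain.
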
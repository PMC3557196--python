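"""Shared fixtures and per-residue bitmap oracles.

The bitmap oracles recompute residue counts position by position and
are deliberately independent of the interval arithmetic they check.
"""

from __future__ import annotations

import pytest

from darkspace.synthetic_data import GeneratorConfig, generate_proteome


def bitmap_union(intervals, length):
    """Residues covered by >=1 interval, counted position by position."""
    covered = [False] * (length + 1)
    for s, e in intervals:
        for pos in range(s, e + 1):
            covered[pos] = True
    return sum(covered[1:])


def bitmap_partition(region_intervals, domain_intervals, length):
    """(within, outside) residue counts of a region-type union vs domains."""
    in_dom = [False] * (length + 1)
    for s, e in domain_intervals:
        for pos in range(s, e + 1):
            in_dom[pos] = True
    in_reg = [False] * (length + 1)
    for s, e in region_intervals:
        for pos in range(s, e + 1):
            in_reg[pos] = True
    within = sum(1 for pos in range(1, length + 1) if in_reg[pos] and in_dom[pos])
    outside = sum(1 for pos in range(1, length + 1) if in_reg[pos] and not in_dom[pos])
    return within, outside


def bitmap_complement(domain_intervals, length):
    """Maximal uncovered (start, end) runs, scanned position by position."""
    in_dom = [False] * (length + 2)
    for s, e in domain_intervals:
        for pos in range(s, e + 1):
            in_dom[pos] = True
    runs, start = [], None
    for pos in range(1, length + 1):
        if not in_dom[pos] and start is None:
            start = pos
        elif in_dom[pos] and start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, length))
    return runs


@pytest.fixture(scope="session")
def small_proteome():
    """A deterministic 150-protein synthetic proteome with ground truth."""
    cfg = GeneratorConfig(n_proteins=150, seed=11)
    return cfg, *generate_proteome(cfg)
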
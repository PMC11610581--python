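"""Structural haplotype comparison: equivalence, distinct fraction,
heterozygosity, and copy-number tallies.

Two haplotypes are structurally equivalent when >= 90% of BOTH sequences can
be mapped to one another in a single alignment, where "a single alignment"
is a single colinear, orientation-consistent chain of pairwise alignment
records with gaps of at most ``max_gap`` (default 1 kbp) on either sequence.
The equivalence relation is symmetric but deliberately not transitively
closed: the distinct fraction counts haplotypes equivalent to no other, and
structural heterozygosity the fraction of samples whose two haplotypes are
not equivalent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentRecord
from .simulate import ParalogCopy
from .synteny import _chainable

logger = logging.getLogger("tandemdup")


@dataclass(frozen=True)
class HaplotypePair:
    hap_a: str
    len_a: int
    hap_b: str
    len_b: int
    alignments: tuple[AlignmentRecord, ...]


@dataclass(frozen=True)
class StructureSummary:
    n_haplotypes: int
    n_distinct: int
    distinct_fraction: float
    n_samples: int
    n_het_samples: int
    heterozygosity: float


def _union_len(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of possibly overlapping intervals."""
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def structurally_equivalent(
    pair: HaplotypePair, threshold: float = 0.90, max_gap: int = 1_000
) -> bool:
    """True when some single alignment chain covers >= ``threshold`` of both
    haplotypes' lengths.  Coverage counts chained aligned bases without
    double-counting overlapping records on either sequence."""
    if pair.len_a <= 0 or pair.len_b <= 0:
        raise ValueError("haplotype lengths must be > 0")
    if not pair.alignments:
        return False
    recs = sorted(pair.alignments, key=lambda a: (a.target.start, a.target.end))
    chains: list[list[AlignmentRecord]] = []
    for rec in recs:
        if chains and _chainable(chains[-1][-1], rec, max_gap):
            chains[-1].append(rec)
        else:
            chains.append([rec])
    for chain in chains:
        cov_a = _union_len([(r.target.start, r.target.end) for r in chain])
        cov_b = _union_len([(r.query.start, r.query.end) for r in chain])
        if cov_a / pair.len_a >= threshold and cov_b / pair.len_b >= threshold:
            return True
    return False


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def distinct_fraction(
    haplotypes: Sequence[str], pairwise: Mapping[tuple[str, str], bool]
) -> tuple[int, float]:
    """Count haplotypes with no structurally equivalent partner in the pool.

    ``pairwise`` must contain every unordered pair (keys sorted
    lexicographically)."""
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1 :]:
            if _pair_key(a, b) not in pairwise:
                raise ValueError(f"missing equivalence result for pair {a}, {b}")
    n_distinct = 0
    for a in haplotypes:
        if not any(
            pairwise[_pair_key(a, b)] for b in haplotypes if b != a
        ):
            n_distinct += 1
    frac = n_distinct / len(haplotypes) if haplotypes else 0.0
    return n_distinct, frac


def structural_heterozygosity(
    samples: Sequence[tuple[Optional[str], Optional[str]]],
    pairwise: Mapping[tuple[str, str], bool],
) -> float:
    """Fraction of samples whose two haplotypes are not structurally
    equivalent.  Samples missing a haplotype are excluded with a warning."""
    n_used = 0
    n_het = 0
    for h1, h2 in samples:
        if h1 is None or h2 is None:
            logger.warning("structural_heterozygosity: sample with one haplotype excluded")
            continue
        n_used += 1
        if not pairwise[_pair_key(h1, h2)]:
            n_het += 1
    if n_used == 0:
        raise ValueError("no complete samples")
    return n_het / n_used


def summarize_structure(
    haplotypes: Sequence[str],
    samples: Sequence[tuple[str, str]],
    pairwise: Mapping[tuple[str, str], bool],
) -> StructureSummary:
    n_distinct, frac = distinct_fraction(haplotypes, pairwise)
    het = structural_heterozygosity(samples, pairwise)
    n_het = round(het * len(samples))
    return StructureSummary(
        n_haplotypes=len(haplotypes),
        n_distinct=n_distinct,
        distinct_fraction=frac,
        n_samples=len(samples),
        n_het_samples=n_het,
        heterozygosity=het,
    )


@dataclass(frozen=True)
class CopyNumberTable:
    """Per-haplotype per-cluster copy counts plus diplotype totals.

    ``theoretical_diplotype_range`` is computed from the observed
    per-cluster haplotype ranges as (2 * sum of minima, 2 * sum of maxima):
    the extreme diplotypes combine the least/most copy-rich haplotype in
    every cluster on both homologs.
    """

    per_haplotype: pd.DataFrame  # index: haplotype, columns: cluster
    diplotype_totals: pd.Series  # index: sample
    theoretical_diplotype_range: tuple[int, int]


def copy_number_table(copies: Iterable[ParalogCopy]) -> CopyNumberTable:
    rows = []
    for c in copies:
        if not c.cluster:
            raise ValueError(f"copy {c.copy_id} lacks a cluster label")
        rows.append((c.sample, c.haplotype, c.cluster))
    if not rows:
        empty = pd.DataFrame()
        return CopyNumberTable(empty, pd.Series(dtype=int), (0, 0))
    df = pd.DataFrame(rows, columns=["sample", "haplotype", "cluster"])
    df["hap_name"] = df["sample"] + "_h" + df["haplotype"].astype(str)
    per_hap = (
        df.groupby(["hap_name", "cluster"]).size().unstack(fill_value=0).sort_index()
    )
    totals = df.groupby("sample").size().sort_index()
    lo = 2 * int(per_hap.min(axis=0).sum())
    hi = 2 * int(per_hap.max(axis=0).sum())
    return CopyNumberTable(per_hap, totals, (lo, hi))


def theoretical_diplotype_range(
    cluster_ranges: Sequence[tuple[int, int]]
) -> tuple[int, int]:
    """Diplotype copy-number extremes from per-haplotype per-cluster ranges:
    e.g. ranges [1,14] and [2,14] give (6, 56)."""
    lo = 2 * sum(r[0] for r in cluster_ranges)
    hi = 2 * sum(r[1] for r in cluster_ranges)
    return lo, hi
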
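"""Synteny-block calling and the breakpoint-proximity permutation test.

Blocks are maximal chains of colinear, orientation-consistent pairwise
alignments between one target/query chromosome pair (default parameters
max_gap = 200 kbp, min_block_size = 1 Mbp, min_subblock_size = 50 kbp).
Block edges on the target chromosome, excluding chromosome ends, are the
breakpoints.  The permutation test asks whether annotated elements (e.g.
~11 kbp duplication units) sit closer to those breakpoints than random
placement would produce: each permutation redraws the same number of blocks
of the same length per chromosome — uniformly over the chromosome or
restricted to a segmental-duplication track — and the empirical p-value is
the add-one estimator (1 + #{null medians <= observed}) / (N + 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import AlignmentRecord, GenomicInterval

logger = logging.getLogger("tandemdup")


@dataclass(frozen=True)
class SyntenyBlock:
    target: GenomicInterval
    query: GenomicInterval
    orientation: str  # "direct" | "inverted"


@dataclass(frozen=True)
class PermutationResult:
    observed_median: float
    null_medians: np.ndarray
    n_perm: int
    p_empirical: float
    sampling_domain: str


def _chainable(a: AlignmentRecord, b: AlignmentRecord, max_gap: int) -> bool:
    """Can record b extend a chain ending in a?  Records must share
    orientation, be colinear on both genomes, and leave gaps <= max_gap."""
    if a.query.strand != b.query.strand:
        return False
    t_gap = b.target.start - a.target.end
    if t_gap > max_gap:
        return False
    if b.target.start < a.target.start:
        return False
    if a.query.strand == "+":
        if b.query.start < a.query.start:
            return False
        q_gap = b.query.start - a.query.end
    else:
        # inverted: query coordinates decrease as the target advances
        if b.query.end > a.query.end:
            return False
        q_gap = a.query.start - b.query.end
    return q_gap <= max_gap


def call_synteny_blocks(
    alignments: Sequence[AlignmentRecord],
    max_gap: int = 200_000,
    min_block_size: int = 1_000_000,
    min_subblock_size: int = 50_000,
) -> list[SyntenyBlock]:
    """Chain alignments into synteny blocks.

    Records with target span >= min_subblock_size are sorted by target start
    and chained while consecutive records are orientation-consistent,
    colinear, and gapped by <= max_gap on both genomes.  Chains whose target
    or query span is < min_block_size are dropped; surviving blocks are made
    non-overlapping on the target (larger blocks win).
    """
    if not alignments:
        return []
    tnames = {a.target.seq_name for a in alignments}
    qnames = {a.query.seq_name for a in alignments}
    if len(tnames) > 1 or len(qnames) > 1:
        raise ValueError(f"mixed chromosome names: targets={tnames}, queries={qnames}")
    recs = [a for a in alignments if a.target.length >= min_subblock_size]
    recs.sort(key=lambda a: (a.target.start, a.target.end))
    chains: list[list[AlignmentRecord]] = []
    for rec in recs:
        if chains and _chainable(chains[-1][-1], rec, max_gap):
            chains[-1].append(rec)
        else:
            chains.append([rec])
    blocks: list[SyntenyBlock] = []
    for chain in chains:
        t0 = min(a.target.start for a in chain)
        t1 = max(a.target.end for a in chain)
        q0 = min(a.query.start for a in chain)
        q1 = max(a.query.end for a in chain)
        if t1 - t0 < min_block_size or q1 - q0 < min_block_size:
            continue
        strand = chain[0].query.strand
        blocks.append(
            SyntenyBlock(
                target=GenomicInterval(chain[0].target.seq_name, t0, t1, "+"),
                query=GenomicInterval(chain[0].query.seq_name, q0, q1, strand),
                orientation="direct" if strand == "+" else "inverted",
            )
        )
    # resolve target overlaps: larger spans win
    blocks.sort(key=lambda b: -b.target.length)
    kept: list[SyntenyBlock] = []
    for b in blocks:
        if all(not b.target.overlaps(k.target) for k in kept):
            kept.append(b)
    kept.sort(key=lambda b: b.target.start)
    logger.info("call_synteny_blocks: %d alignments -> %d blocks", len(alignments), len(kept))
    return kept


def breakpoints_from_blocks(blocks: Sequence[SyntenyBlock], chrom_len: int) -> list[int]:
    """Interior block-boundary positions on the target chromosome.

    Both edges of every block are candidate breaks; positions within 1 bp of
    the chromosome ends are excluded and duplicates collapsed.
    """
    pos = {p for b in blocks for p in (b.target.start, b.target.end)}
    return sorted(p for p in pos if 1 < p < chrom_len - 1)


def _element_distance(start: int, end: int, breaks: np.ndarray) -> float:
    """Distance from an element [start, end) to the nearest break: 0 if a
    break falls within the element, else the gap to the nearer edge."""
    idx = np.searchsorted(breaks, start)
    left = start - breaks[idx - 1] if idx > 0 else np.inf
    right = max(0, breaks[idx] - end) if idx < len(breaks) else np.inf
    return float(min(left, right))


def median_break_distance(
    elements: Sequence[GenomicInterval],
    breaks_by_chrom: Mapping[str, Sequence[int]],
) -> float:
    """Median distance from elements to their nearest synteny break, pooled
    across chromosomes.  Elements on chromosomes without breaks are skipped
    with a warning; if none remain, an error is raised."""
    dists: list[float] = []
    skipped = 0
    for el in elements:
        breaks = breaks_by_chrom.get(el.seq_name)
        if not breaks:
            skipped += 1
            continue
        dists.append(_element_distance(el.start, el.end, np.sort(np.asarray(breaks))))
    if skipped:
        logger.warning("median_break_distance: %d elements on chromosomes without breaks", skipped)
    if not dists:
        raise ValueError("no element has a break on its chromosome")
    return float(np.median(dists))


def _null_distances(
    n_perm: int,
    m: int,
    block_len: int,
    breaks: np.ndarray,
    chrom_len: int,
    rng: np.random.Generator,
    domain_intervals: Optional[list[tuple[int, int]]],
) -> np.ndarray:
    """(n_perm, m) distances from randomly placed blocks to nearest break."""
    if domain_intervals is None:
        hi = chrom_len - block_len
        if hi < 0:
            raise ValueError(f"block_len {block_len} exceeds chromosome length {chrom_len}")
        starts = rng.integers(0, hi + 1, size=(n_perm, m))
    else:
        spans = np.array([max(0, e - s - block_len + 1) for s, e in domain_intervals])
        if spans.sum() <= 0:
            raise ValueError("sd_track intervals shorter than block_len")
        offs = np.array([s for s, _ in domain_intervals])
        which = rng.choice(len(spans), size=(n_perm, m), p=spans / spans.sum())
        within = rng.integers(0, spans[which])
        starts = offs[which] + within
    ends = starts + block_len
    idx = np.searchsorted(breaks, starts)
    left = np.where(idx > 0, starts - breaks[np.maximum(idx - 1, 0)], np.inf)
    right_break = breaks[np.minimum(idx, len(breaks) - 1)]
    right = np.where(idx < len(breaks), np.maximum(0, right_break - ends), np.inf)
    return np.minimum(left, right)


def permutation_test(
    elements_per_chrom: Mapping[str, Sequence[GenomicInterval]],
    breaks_by_chrom: Mapping[str, Sequence[int]],
    chrom_lens: Mapping[str, int],
    n_perm: int = 5_000,
    block_len: Optional[int] = None,
    sampling_domain: str = "whole_chromosome",
    sd_track: Optional[Mapping[str, Sequence[GenomicInterval]]] = None,
    seed: int = 0,
) -> PermutationResult:
    """Median-distance permutation test for element/breakpoint association.

    Per permutation, the same number of blocks of length ``block_len``
    (default: mean length of the true elements) as true elements is drawn on
    each chromosome — uniformly, or restricted to a segmental-duplication
    track — and the pooled median distance to the nearest break recomputed.
    Sampled blocks may overlap each other or true elements; ties (null ==
    observed) count against the observed value.
    """
    if sampling_domain not in ("whole_chromosome", "sd_restricted"):
        raise ValueError(f"unknown sampling domain {sampling_domain!r}")
    all_elements = [el for els in elements_per_chrom.values() for el in els]
    observed = median_break_distance(all_elements, breaks_by_chrom)
    if block_len is None:
        block_len = int(round(np.mean([el.length for el in all_elements])))
    if block_len <= 0:
        raise ValueError("block_len must be > 0")
    rng = np.random.default_rng(seed)
    logger.info(
        "permutation_test: n_perm=%d block_len=%d domain=%s seed=%d",
        n_perm, block_len, sampling_domain, seed,
    )
    per_chrom: list[np.ndarray] = []
    for chrom, els in elements_per_chrom.items():
        breaks = np.sort(np.asarray(breaks_by_chrom.get(chrom, []), dtype=int))
        els = [el for el in els if len(breaks)]
        if not els:
            continue
        domain = None
        if sampling_domain == "sd_restricted":
            if not sd_track or chrom not in sd_track:
                raise ValueError(f"sd_restricted sampling without sd_track on {chrom}")
            domain = [(iv.start, iv.end) for iv in sd_track[chrom] if iv.length >= block_len]
            if not domain:
                raise ValueError(
                    f"sd_track on {chrom} has no interval of length >= {block_len}"
                )
        per_chrom.append(
            _null_distances(
                n_perm, len(els), block_len, breaks, chrom_lens[chrom], rng, domain
            )
        )
    null_medians = np.median(np.concatenate(per_chrom, axis=1), axis=1)
    b = int(np.sum(null_medians <= observed))
    p = (1 + b) / (n_perm + 1)
    return PermutationResult(
        observed_median=observed,
        null_medians=null_medians,
        n_perm=n_perm,
        p_empirical=p,
        sampling_domain=sampling_domain,
    )
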
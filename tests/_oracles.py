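"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive re-derivations: they never call the code paths
they verify.
"""
from __future__ import annotations

import itertools

import numpy as np

from tandemdup.io import AlignmentRecord, GenomicInterval
from tandemdup.synteny import SyntenyBlock


def exhaustive_synteny_blocks(
    alignments, max_gap, min_block_size, min_subblock_size
):
    """Chain alignments by explicit enumeration of consecutive runs.

    Walks records sorted by target start and re-derives, pair by pair, the
    chaining condition (same orientation, colinear on both genomes, gaps at
    most max_gap); maximal runs become candidate blocks, small blocks are
    dropped, and target overlaps are resolved largest-first.
    """
    recs = sorted(
        (a for a in alignments if a.target.end - a.target.start >= min_subblock_size),
        key=lambda a: (a.target.start, a.target.end),
    )

    def ok(a, b):
        if a.query.strand != b.query.strand:
            return False
        if b.target.start < a.target.start or b.target.start - a.target.end > max_gap:
            return False
        if a.query.strand == "+":
            return b.query.start >= a.query.start and b.query.start - a.query.end <= max_gap
        return b.query.end <= a.query.end and a.query.start - b.query.end <= max_gap

    runs = []
    i = 0
    while i < len(recs):
        j = i
        while j + 1 < len(recs) and ok(recs[j], recs[j + 1]):
            j += 1
        runs.append(recs[i : j + 1])
        i = j + 1

    candidates = []
    for run in runs:
        t0 = min(r.target.start for r in run)
        t1 = max(r.target.end for r in run)
        q0 = min(r.query.start for r in run)
        q1 = max(r.query.end for r in run)
        if t1 - t0 >= min_block_size and q1 - q0 >= min_block_size:
            strand = run[0].query.strand
            candidates.append(
                SyntenyBlock(
                    target=GenomicInterval(run[0].target.seq_name, t0, t1, "+"),
                    query=GenomicInterval(run[0].query.seq_name, q0, q1, strand),
                    orientation="direct" if strand == "+" else "inverted",
                )
            )
    kept = []
    for b in sorted(candidates, key=lambda b: -(b.target.end - b.target.start)):
        if all(
            b.target.end <= k.target.start or k.target.end <= b.target.start
            for k in kept
        ):
            kept.append(b)
    return sorted(kept, key=lambda b: b.target.start)


def random_alignment_set(rng, n_records, chrom_len=10_000_000):
    """Random small alignment sets for chaining cross-checks."""
    recs = []
    for _ in range(n_records):
        t0 = int(rng.integers(0, chrom_len - 200_000))
        span = int(rng.integers(30_000, 900_000))
        t1 = min(t0 + span, chrom_len)
        q0 = int(rng.integers(0, chrom_len - span))
        strand = "+" if rng.random() < 0.5 else "-"
        recs.append(
            AlignmentRecord(
                query=GenomicInterval("q", q0, q0 + (t1 - t0), strand),
                target=GenomicInterval("t", t0, t1, "+"),
                query_len=chrom_len,
                target_len=chrom_len,
                matches=t1 - t0,
                aln_len=t1 - t0,
            )
        )
    return recs


def brute_force_distinct(haplotypes, pairwise):
    """Distinct haplotypes by explicit all-pairs scan."""
    n = 0
    for a in haplotypes:
        alone = True
        for b in haplotypes:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if pairwise[key]:
                alone = False
        n += alone
    return n, n / len(haplotypes)


def brute_force_pi(seqs, window, step):
    """Windowed pairwise diversity by a plain double loop over pairs and
    columns."""
    L = len(seqs[0])
    out = []
    for start in range(0, L - window + 1, step):
        vals = []
        undefined = False
        for a, b in itertools.combinations(seqs, 2):
            mm = ok = 0
            for x, y in zip(a[start : start + window], b[start : start + window]):
                if x != "-" and y != "-":
                    ok += 1
                    mm += x != y
            if ok == 0:
                undefined = True
                break
            vals.append(mm / ok)
        out.append(None if undefined else float(np.mean(vals)))
    return out


def translation_consequence(ref_cds: str, alt_seq: str):
    """(residues_lost, extension_length, stop_recovered) by independent
    translate-and-compare using Biopython."""
    from Bio.Seq import Seq

    ref_prot = str(Seq(ref_cds).translate(to_stop=True))
    alt_trim = alt_seq[: len(alt_seq) - len(alt_seq) % 3]
    alt_full = str(Seq(alt_trim).translate())
    stop_recovered = "*" in alt_full
    alt_prot = alt_full.split("*")[0]
    lcp = 0
    while lcp < min(len(ref_prot), len(alt_prot)) and ref_prot[lcp] == alt_prot[lcp]:
        lcp += 1
    return len(ref_prot) - lcp, len(alt_prot) - lcp, stop_recovered
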
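"""Read k-mer depth, copy-number estimation, and assembly QC flags.

Copy number is estimated FastCN-style from exact canonical k-mer depth:
reads are k-merised (default k = 32), each reference position's depth is the
number of read k-mers identical to the canonical k-mer starting there, and a
haploid-equivalent baseline is calibrated on declared single-copy control
intervals (median window depth / control ploidy).  The copy number of a
region is then its mean positional depth over the baseline — a genome-wide
(diploid-total) estimate when the reads come from a diploid sample.

Exact matching replaces the reference pipeline's small mismatch tolerance;
with error-containing or allelically diverged reads a fraction of k-mers
fails to match exactly, so depth experiments are run with matching read and
locus divergence settings (see the methods note).

QC flags come from origin-true read pileups: collapse candidates are
positions where the second most frequent base is unexpectedly common, and
clusters of such positions (>= 5 candidates within ``min_run`` bp of each
other) are flagged, annotated with whether depth is also elevated.  Gaps are
maximal zero-coverage runs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import GenomicInterval, SequenceRecord
from .simulate import CollapseTruth, encode

logger = logging.getLogger("tandemdup")


@dataclass
class DepthProfile:
    reference: str
    k: int
    window: int
    positional: np.ndarray  # per reference k-mer start position
    window_depth: np.ndarray
    baseline: Optional[float] = None  # haploid-equivalent depth


@dataclass(frozen=True)
class CnEstimate:
    region: GenomicInterval
    cn: float
    source: str  # "assembly" | "read_depth"


@dataclass(frozen=True)
class QcFlag:
    region: GenomicInterval
    kind: str  # "collapse" | "gap"
    evidence: float  # peak secondary-base fraction, or zero-coverage length
    depth_elevated: Optional[bool] = None


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit k-mer values (uint64) for every window start; requires
    codes in {0..3} (positions containing other symbols are dropped by the
    caller)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | c[j : j + n]
    return vals


def canonical_kmers(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-collapsed k-mer values: elementwise min of the forward k-mer
    and its reverse complement."""
    fwd = _kmer_values(seq_codes, k)
    rc = _kmer_values(3 - seq_codes[::-1], k)[::-1]
    return np.minimum(fwd, rc)


def _batch_canonical_kmers(mat: np.ndarray, k: int) -> np.ndarray:
    """canonical_kmers over the rows of an (n_reads, read_len) code matrix."""
    n, rlen = mat.shape
    m = rlen - k + 1
    c = mat.astype(np.uint64)
    rc_c = (np.uint64(3) - c)[:, ::-1]
    fwd = np.zeros((n, m), dtype=np.uint64)
    rev = np.zeros((n, m), dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[:, j : j + m]
        rev = (rev << np.uint64(2)) | rc_c[:, j : j + m]
    return np.minimum(fwd, rev[:, ::-1])


def kmer_depth(
    reads: Sequence[SequenceRecord],
    reference: SequenceRecord,
    control: Sequence[GenomicInterval],
    k: int = 32,
    window: int = 500,
    control_ploidy: int = 2,
) -> DepthProfile:
    """Exact canonical k-mer depth of reads over a reference.

    depth[i] = number of read k-mers equal to the reference k-mer starting
    at i.  The haploid-equivalent baseline is the median window depth over
    the control (single-copy) intervals divided by ``control_ploidy``.
    """
    ref_codes = encode(reference.bases)
    if len(ref_codes) < k:
        raise ValueError("reference shorter than k")
    ref_kmers = canonical_kmers(ref_codes, k)
    # batch equal-length reads into one matrix so k-mer packing is a single
    # vectorized pass per length class
    by_len: dict[int, list[str]] = {}
    for r in reads:
        if len(r.bases) >= k:
            by_len.setdefault(len(r.bases), []).append(r.bases)
    read_arrays = []
    for rlen, seqs in by_len.items():
        mat = encode("".join(seqs)).reshape(len(seqs), rlen)
        read_arrays.append(_batch_canonical_kmers(mat, k).ravel())
    if read_arrays:
        read_kmers = np.sort(np.concatenate(read_arrays))
        lo = np.searchsorted(read_kmers, ref_kmers, side="left")
        hi = np.searchsorted(read_kmers, ref_kmers, side="right")
        positional = (hi - lo).astype(float)
    else:
        positional = np.zeros(len(ref_kmers))
    n_win = len(positional) // window
    window_depth = (
        positional[: n_win * window].reshape(n_win, window).mean(axis=1)
        if n_win
        else np.array([positional.mean()])
    )
    profile = DepthProfile(
        reference=reference.name,
        k=k,
        window=window,
        positional=positional,
        window_depth=window_depth,
    )
    if control:
        ctrl_windows = []
        for iv in control:
            w0, w1 = iv.start // window, max(iv.start // window + 1, iv.end // window)
            ctrl_windows.append(window_depth[w0 : min(w1, len(window_depth))])
        ctrl = np.concatenate(ctrl_windows)
        baseline = float(np.median(ctrl)) / control_ploidy
        if baseline <= 0:
            raise ValueError("control intervals have zero depth; baseline unusable")
        profile.baseline = baseline
    logger.info(
        "kmer_depth: %d reads vs %s (k=%d), baseline=%s",
        len(reads), reference.name, k, profile.baseline,
    )
    return profile


def estimate_cn(profile: DepthProfile, region: GenomicInterval) -> CnEstimate:
    """Copy number of a region: mean positional depth / haploid baseline."""
    if profile.baseline is None:
        raise ValueError("no baseline set; supply control intervals to kmer_depth")
    if region.start >= len(profile.positional):
        raise ValueError(f"region {region} outside depth profile")
    end = min(region.end, len(profile.positional))
    mean_depth = float(profile.positional[region.start : end].mean())
    return CnEstimate(region=region, cn=mean_depth / profile.baseline, source="read_depth")


# ---------------------------------------------------------------------------
# pileups


def pileup_from_origins(
    assembly_len: int,
    reads: Sequence[SequenceRecord],
    origins: Mapping[str, tuple[str, int]],
    coord_map: Optional[Sequence[CollapseTruth]] = None,
) -> np.ndarray:
    """(L, 4) base-count pileup from origin-true read placement.

    ``origins`` maps read name -> (haplotype name, start on that haplotype).
    When the assembly was collapsed, ``coord_map`` (the collapse truth)
    redirects reads originating inside a removed copy onto the retained
    copy and shifts downstream reads left; reads straddling a collapse
    boundary are dropped.
    """
    counts = np.zeros(assembly_len * 4, dtype=np.int64)
    pos_chunks = []
    dropped = 0
    for read in reads:
        _, start = origins[read.name]
        rlen = len(read.bases)
        if coord_map:
            mapped = _map_start(start, rlen, coord_map)
            if mapped is None:
                dropped += 1
                continue
            start = mapped
        if start + rlen > assembly_len:
            dropped += 1
            continue
        codes = encode(read.bases)
        pos = (np.arange(start, start + rlen) * 4 + codes).astype(np.int64)
        pos_chunks.append(pos[codes < 4])
    if pos_chunks:
        allpos = np.concatenate(pos_chunks)
        counts = np.bincount(allpos, minlength=assembly_len * 4)
    if dropped:
        logger.info("pileup_from_origins: %d reads dropped at collapse boundaries", dropped)
    return counts.reshape(assembly_len, 4)


def _map_start(start: int, rlen: int, truths: Sequence[CollapseTruth]) -> Optional[int]:
    for t in truths:
        rs, re_ = t.removed.start, t.removed.end
        if start + rlen <= rs:
            return start
        if rs <= start and start + rlen <= re_:
            # read from the removed copy: place it on the retained copy
            return t.retained.start + (start - rs)
        if start >= re_:
            return start - t.removed_len
        return None  # straddles a boundary
    return start


def collapse_flags(
    pileup: np.ndarray,
    secondary_threshold: float = 0.01,
    min_secondary_count: int = 2,
    min_run: int = 500,
    min_candidates: int = 5,
    depth_factor: float = 1.5,
) -> list[QcFlag]:
    """Flag stretches with elevated secondary-base frequency as collapses.

    Candidate positions have a second most frequent base seen at least
    ``min_secondary_count`` times and above ``secondary_threshold`` of the
    position's depth.  Candidates within ``min_run`` bp of each other are
    clustered; clusters with >= ``min_candidates`` members are flagged,
    annotated with whether mean depth over the cluster exceeds
    ``depth_factor`` x the genome-median depth.
    """
    depth = pileup.sum(axis=1)
    sorted_counts = np.sort(pileup, axis=1)
    secondary = sorted_counts[:, -2]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, secondary / np.maximum(depth, 1), 0.0)
    cand = (secondary >= min_secondary_count) & (frac > secondary_threshold)
    positions = np.flatnonzero(cand)
    flags: list[QcFlag] = []
    if len(positions) == 0:
        return flags
    median_depth = float(np.median(depth[depth > 0])) if np.any(depth > 0) else 0.0
    cluster_start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or positions[i] - positions[i - 1] > min_run:
            members = positions[cluster_start:i]
            cluster_start = i
            if len(members) >= min_candidates:
                lo, hi = int(members[0]), int(members[-1]) + 1
                run_depth = float(depth[lo:hi].mean())
                flags.append(
                    QcFlag(
                        region=GenomicInterval("assembly", lo, hi),
                        kind="collapse",
                        evidence=float(frac[members].max()),
                        depth_elevated=bool(
                            median_depth > 0 and run_depth > depth_factor * median_depth
                        ),
                    )
                )
    logger.info("collapse_flags: %d candidate sites -> %d flags", len(positions), len(flags))
    return flags


def gap_flags(pileup: np.ndarray, min_gap: int = 100) -> list[QcFlag]:
    """Maximal zero-coverage runs of >= min_gap bp."""
    depth = pileup.sum(axis=1)
    zero = depth == 0
    flags: list[QcFlag] = []
    boundaries = np.flatnonzero(np.diff(np.concatenate([[0], zero.view(np.int8), [0]])))
    for lo, hi in zip(boundaries[::2], boundaries[1::2]):
        if hi - lo >= min_gap:
            flags.append(
                QcFlag(
                    region=GenomicInterval("assembly", int(lo), int(hi)),
                    kind="gap",
                    evidence=float(hi - lo),
                )
            )
    return flags


def assembly_copy_number(copies_per_sample: Mapping[str, int]) -> dict[str, CnEstimate]:
    """Assembly-mode CN: annotated diplotype copy count per sample."""
    return {
        s: CnEstimate(
            region=GenomicInterval(s, 0, 1), cn=float(n), source="assembly"
        )
        for s, n in copies_per_sample.items()
    }
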
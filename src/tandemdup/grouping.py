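"""Paralog grouping from SNV distances and windowed nucleotide diversity.

Copies of a duplicated gene are grouped into population-level paralog groups
by (1) computing pairwise SNV distances (substitutions per 10 kbp of aligned,
non-gap sequence), (2) building a neighbor-joining tree rooted on an
outgroup, and (3) recursively emitting, root-down, the maximal clades whose
intra-clade variation stays within a cutoff of ``multiplier x allelic_rate``
(default 1.5 x 15.3 = 22.95 SNVs per 10 kbp).  Emitted clades with fewer
than ``min_members`` members (default 10) are reported as unassigned rather
than named groups.

Intra-clade variation is by default the MEAN pairwise distance among the
clade's leaves, the same scale as the allelic-variation yardstick (itself an
average rate); this keeps grouping robust to single hypermutated copies,
which under a max-pairwise reading would shatter an otherwise tight clade.
``GroupingParams(statistic="max")`` selects the conservative max-pairwise
reading instead.

Neighbor joining is used in place of maximum-likelihood tree inference: the
grouping criterion depends only on the distance matrix and the clade
structure, not on branch-length likelihoods.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import skbio
from skbio.tree import TreeNode, nj

from .io import GenomicInterval

logger = logging.getLogger("tandemdup")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric SNV distance matrix in substitutions per 10 kbp."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(self.d < 0) or np.any(np.diag(self.d) != 0):
            raise ValueError("distances must be >= 0 with a zero diagonal")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class GroupingParams:
    allelic_rate: float = 15.3
    multiplier: float = 1.5
    min_members: int = 10
    statistic: str = "mean"  # intra-clade variation: "mean" or "max" pairwise

    @property
    def cutoff(self) -> float:
        return self.multiplier * self.allelic_rate

    def __post_init__(self) -> None:
        if self.allelic_rate <= 0 or self.multiplier <= 0 or self.min_members <= 0:
            raise ValueError("grouping parameters must be positive")
        if self.statistic not in ("mean", "max"):
            raise ValueError("statistic must be 'mean' or 'max'")


@dataclass(frozen=True)
class ParalogPartition:
    groups: dict[str, tuple[str, ...]]
    unassigned: tuple[str, ...]

    def group_of(self) -> dict[str, Optional[str]]:
        out: dict[str, Optional[str]] = {m: None for m in self.unassigned}
        for name, members in self.groups.items():
            for m in members:
                out[m] = name
        return out


@dataclass(frozen=True)
class DiversityWindow:
    interval: GenomicInterval
    pi: Optional[float]
    percentile: Optional[float]
    flagged: bool = False


def snv_distance_matrix(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise SNV distances from aligned sequences (gaps as ``-``).

    d(i, j) = mismatching non-gap columns / non-gap aligned columns x 10000.
    A pair with zero non-gap overlap is an error.
    """
    labels = tuple(aligned.keys())
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.vstack([np.frombuffer(aligned[l].encode(), dtype=np.uint8) for l in labels])
    gap = arr == ord("-")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(f"pair {labels[i]}, {labels[j]}: no comparable columns")
            mm = int(np.sum(arr[i][ok] != arr[j][ok]))
            d[i, j] = d[j, i] = mm / n_ok * 10_000.0
    return DistanceMatrix(labels, d)


def build_nj_tree(dm: DistanceMatrix, outgroup: str) -> TreeNode:
    """Neighbor-joining tree rooted on the outgroup's pendant edge."""
    if outgroup not in dm.labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    skdm = skbio.DistanceMatrix(dm.d, ids=list(dm.labels))
    tree = nj(skdm)
    out_leaf = tree.find(outgroup)
    rooted = tree.root_at(out_leaf.parent)
    return rooted


def decompose_groups(
    tree: TreeNode,
    dm: DistanceMatrix,
    params: GroupingParams = GroupingParams(),
    outgroup: Optional[str] = None,
    name_map: Optional[Mapping[str, str]] = None,
) -> ParalogPartition:
    """Decompose a rooted tree into population-level paralog groups.

    Traversing root-down, a clade is emitted as soon as its intra-clade
    variation (mean pairwise distance among its non-outgroup leaves by
    default, max with ``params.statistic == "max"``) is <= cutoff;
    descendants of an emitted clade are not revisited, so emitted clades are
    maximal and nested ties cannot occur.  Emitted clades with < min_members
    go to ``unassigned``.  Groups are named by their lexicographically
    smallest member, through ``name_map`` when given.
    """
    cutoff = params.cutoff
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    index = {l: i for i, l in enumerate(dm.labels)}

    def intra_variation(leaves: list[str]) -> float:
        if len(leaves) < 2:
            return 0.0
        idx = [index[l] for l in leaves]
        sub = dm.d[np.ix_(idx, idx)]
        if params.statistic == "max":
            return float(sub.max())
        n = len(idx)
        return float(sub.sum() / (n * (n - 1)))  # mean over unordered pairs

    emitted: list[list[str]] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        leaves = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        leaves = [l for l in leaves if l != outgroup]
        if not leaves:
            continue
        missing = [l for l in leaves if l not in index]
        if missing:
            raise ValueError(f"tree leaves missing from distance matrix: {missing}")
        if intra_variation(leaves) <= cutoff:
            emitted.append(leaves)
        else:
            stack.extend(node.children)

    groups: dict[str, tuple[str, ...]] = {}
    unassigned: list[str] = []
    for members in emitted:
        if len(members) >= params.min_members:
            key = min(members)
            name = name_map.get(key, key) if name_map else key
            groups[name] = tuple(sorted(members))
        else:
            unassigned.extend(members)
    logger.info(
        "decompose_groups: %d groups, %d unassigned (cutoff=%.2f, min_members=%d)",
        len(groups), len(unassigned), cutoff, params.min_members,
    )
    return ParalogPartition(groups=groups, unassigned=tuple(sorted(unassigned)))


def windowed_diversity(
    aligned: Sequence[str],
    window: int,
    step: Optional[int] = None,
    seq_name: str = "alignment",
) -> list[DiversityWindow]:
    """Windowed pairwise nucleotide diversity with percentile ranks.

    Per window, pi is the mean over all sequence pairs of (mismatching
    non-gap columns / non-gap columns).  Windows where some pair has zero
    comparable columns are flagged with undefined pi.  Percentiles use the
    fraction of windows with strictly smaller pi plus half the ties, x100.
    Windows are non-overlapping by default (step = window).
    """
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    L = len(aligned[0])
    if any(len(s) != L for s in aligned):
        raise ValueError("aligned sequences must have equal length")
    if window > L:
        raise ValueError("window exceeds alignment length")
    step = step or window
    arr = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in aligned])
    gap = arr == ord("-")
    n = len(aligned)
    starts = list(range(0, L - window + 1, step))
    # prefix sums per pair of mismatches and comparable columns
    pair_mm = []
    pair_ok = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            mm = ok & (arr[i] != arr[j])
            pair_mm.append(np.concatenate([[0], np.cumsum(mm)]))
            pair_ok.append(np.concatenate([[0], np.cumsum(ok)]))
    pair_mm = np.vstack(pair_mm)
    pair_ok = np.vstack(pair_ok)

    pis: list[Optional[float]] = []
    for s in starts:
        mm = pair_mm[:, s + window] - pair_mm[:, s]
        ok = pair_ok[:, s + window] - pair_ok[:, s]
        if np.any(ok == 0):
            pis.append(None)
        else:
            pis.append(float(np.mean(mm / ok)))
    defined = np.array([p for p in pis if p is not None])
    out: list[DiversityWindow] = []
    for s, pi in zip(starts, pis):
        iv = GenomicInterval(seq_name, s, s + window)
        if pi is None:
            out.append(DiversityWindow(iv, None, None, flagged=True))
        else:
            smaller = float(np.sum(defined < pi))
            ties = float(np.sum(defined == pi))
            pct = (smaller + 0.5 * ties) / len(defined) * 100.0
            out.append(DiversityWindow(iv, pi, pct))
    return out
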
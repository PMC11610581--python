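"""Synthetic diploid haplotype pools with tandem gene-cluster expansions.

The generator emulates the data a hypervariable segmental-duplication locus
produces: diploid haplotype pools carrying clustered tandem gene expansions of
variable copy number with known structural classes, orthologous chromosomes
differing by rearrangements whose breakpoints may or may not coincide with the
duplication loci, paralog sequences with controlled allelic vs paralogous
divergence, full-length transcript reads with per-group expression weights,
and whole-genome shotgun reads at configurable depth.  Every output carries
full ground truth so downstream statistics can be tested for parameter
recovery without any external data.

Mutation model: independent uniform substitutions (Jukes-Cantor-like); no
indels inside gene copies by default.  Allelic vs paralogous divergence is
realised on an explicit genealogy — one ancestral sequence per truth group,
group ancestors derived from a shared root, each realised copy drawn from its
group ancestor — with per-branch rates chosen so that the EXPECTED pairwise
distance between two copies of the same group equals ``allelic_rate`` and
between different groups equals ``paralog_divergence`` (both in SNVs per
10 kbp, ignoring the negligible double-hit correction at these rates).

Structural variation is realised from a finite per-cluster pool of layout
templates (copy count, orientations, truth-group order) sampled with
configured probabilities, which makes the expected distinct-haplotype
fraction and structural heterozygosity available in closed form.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import AlignmentRecord, GenomicInterval, SequenceRecord, accuracy_to_phred

logger = logging.getLogger("tandemdup")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability p (uniform over
    the three alternatives)."""
    out = codes.copy()
    if p <= 0:
        return out
    n_sites = rng.binomial(len(codes), p)
    if n_sites == 0:
        return out
    sites = rng.choice(len(codes), size=n_sites, replace=False)
    out[sites] = (out[sites] + rng.integers(1, 4, size=n_sites)) % 4
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class Template:
    """One structural layout of a cluster: copy count, per-copy orientation,
    per-copy truth-group index."""

    orientations: tuple[str, ...]
    groups: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.orientations) != len(self.groups):
            raise ValueError("orientations and groups differ in length")

    @property
    def copy_count(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class ClusterSpec:
    """Specification of one tandem expansion cluster.

    With no explicit templates, one template per copy number in ``cn_range``
    is built (all copies forward, truth groups assigned cyclically) and
    sampled uniformly.
    """

    name: str
    cn_range: tuple[int, int] = (1, 14)
    unit_len: int = 11_000
    spacer_len: int = 1_000
    templates: Optional[tuple[Template, ...]] = None
    template_probs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        lo, hi = self.cn_range
        if lo > hi:
            raise ValueError(f"cluster {self.name}: cn_range min > max")
        if not (0 <= lo and hi <= 40):
            raise ValueError(f"cluster {self.name}: cn_range outside [0, 40]")

    def resolved_templates(self, n_truth_groups: int) -> tuple[tuple[Template, ...], np.ndarray]:
        if self.templates is not None:
            tpls = self.templates
        else:
            lo, hi = self.cn_range
            tpls = tuple(
                Template(
                    orientations=("+",) * n,
                    groups=tuple(i % n_truth_groups for i in range(n)),
                )
                for n in range(lo, hi + 1)
                if n > 0
            )
            if not tpls:  # cn_range == (0, 0)
                tpls = (Template((), ()),)
        if self.template_probs is not None:
            probs = np.asarray(self.template_probs, dtype=float)
            if len(probs) != len(tpls) or probs.sum() <= 0:
                raise ValueError(f"cluster {self.name}: bad template_probs")
            probs = probs / probs.sum()
        else:
            probs = np.full(len(tpls), 1.0 / len(tpls))
        return tpls, probs


@dataclass(frozen=True)
class Rearrangement:
    """One rearrangement to apply to an orthologous chromosome.

    kind: inversion | translocation | fission.
    placement: 'at_element' anchors breakpoints at annotated element
    boundaries; 'uniform' draws them uniformly.  Explicit ``positions``
    override the random placement.
    """

    kind: str
    placement: str = "uniform"
    length: int = 2_000_000
    positions: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation", "fission"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.placement not in ("at_element", "uniform"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class ReadParams:
    transcript_error: float = 0.001
    wgs_depth: float = 30.0
    wgs_read_len: int = 100
    wgs_error: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_len: int = 2_000_000
    n_samples: int = 4
    cluster_specs: tuple[ClusterSpec, ...] = (
        ClusterSpec("cluster1", cn_range=(1, 14)),
        ClusterSpec("cluster2", cn_range=(2, 14)),
    )
    allelic_rate: float = 15.3  # SNVs per 10 kbp between same-group copies
    paralog_divergence: float = 60.0  # SNVs per 10 kbp between groups
    n_truth_groups: int = 3
    rearrangements: tuple[Rearrangement, ...] = ()
    expression_weights: Optional[tuple[float, ...]] = None
    read_params: ReadParams = ReadParams()
    flank_len: int = 25_000

    def __post_init__(self) -> None:
        if self.allelic_rate < 0:
            raise ValueError("allelic_rate must be >= 0")
        if self.paralog_divergence < self.allelic_rate:
            raise ValueError("paralog_divergence must be >= allelic_rate")
        if self.expression_weights is not None:
            if len(self.expression_weights) != self.n_truth_groups:
                raise ValueError("one expression weight per truth group required")
            if any(w < 0 for w in self.expression_weights):
                raise ValueError("expression weights must be non-negative")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass(frozen=True)
class ParalogCopy:
    """An annotated gene copy on one haplotype."""

    copy_id: str
    sample: str
    haplotype: int
    cluster: str
    interval: GenomicInterval
    truth_group: Optional[str]
    sequence: str

    def __post_init__(self) -> None:
        if self.interval.length != len(self.sequence):
            raise ValueError(f"{self.copy_id}: interval/sequence length mismatch")


@dataclass(frozen=True)
class Segment:
    """A structural segment of a haplotype: its ancestral identity key,
    length, and orientation.  Two segments with equal (key, length,
    orientation) descend from the same ancestral sequence."""

    key: tuple
    length: int
    orientation: str = "+"


@dataclass
class TruthSet:
    copies: list[ParalogCopy] = field(default_factory=list)
    structure_class: dict[str, int] = field(default_factory=dict)  # hap name -> class id
    segments: dict[str, list[Segment]] = field(default_factory=dict)
    breakpoints: dict[str, list[int]] = field(default_factory=dict)
    read_origins: dict[str, str] = field(default_factory=dict)  # read -> copy_id
    wgs_origins: dict[str, tuple[str, int]] = field(default_factory=dict)

    def copies_of_hap(self, hap_name: str) -> list[ParalogCopy]:
        return [c for c in self.copies if f"{c.sample}_h{c.haplotype}" == hap_name]

    def copies_by_group(self) -> dict[str, list[ParalogCopy]]:
        out: dict[str, list[ParalogCopy]] = {}
        for c in self.copies:
            out.setdefault(c.truth_group, []).append(c)
        return out


# ---------------------------------------------------------------------------
# haplotype pool


def simulate_haplotype_pool(config: SimConfig) -> tuple[list[SequenceRecord], TruthSet]:
    """Generate a diploid haplotype pool with clustered tandem expansions.

    Each haplotype is flankL + [cluster arrays separated by spacers] + flankR.
    Per cluster a layout template is drawn from the cluster's template pool;
    copies are realised from their truth-group ancestor with allelic
    substitutions.  Haplotypes drawing the same template in every cluster
    share a structure class.
    """
    rng = np.random.default_rng(config.seed)
    logger.info("simulate_haplotype_pool: seed=%d n_samples=%d", config.seed, config.n_samples)
    half_allelic = config.allelic_rate / 2.0 / 10_000.0
    group_branch = max(config.paralog_divergence - config.allelic_rate, 0.0) / 2.0 / 10_000.0

    # ancestral material
    cluster_info = []
    for spec in config.cluster_specs:
        root = random_codes(rng, spec.unit_len)
        ancestors = [mutate(root, group_branch, rng) for _ in range(config.n_truth_groups)]
        spacer = random_codes(rng, spec.spacer_len)
        tpls, probs = spec.resolved_templates(config.n_truth_groups)
        cluster_info.append((spec, ancestors, spacer, tpls, probs))
    flank_l = random_codes(rng, config.flank_len)
    flank_r = random_codes(rng, config.flank_len)
    inter = random_codes(rng, config.flank_len // 2) if len(config.cluster_specs) > 1 else None

    haplotypes: list[SequenceRecord] = []
    truth = TruthSet()
    class_ids: dict[tuple[int, ...], int] = {}
    for s in range(config.n_samples):
        sample = f"sample{s:03d}"
        for hap in (1, 2):
            hap_name = f"{sample}_h{hap}"
            parts: list[np.ndarray] = []
            segments: list[Segment] = []
            copies: list[tuple[str, int, int, str, str]] = []  # cluster, start, end, group, strand
            pos = 0

            def emit(codes: np.ndarray, key: tuple, orientation: str = "+") -> None:
                nonlocal pos
                parts.append(codes)
                segments.append(Segment(key, len(codes), orientation))
                pos += len(codes)

            emit(mutate(flank_l, half_allelic, rng), ("flankL",))
            tpl_choice: list[int] = []
            for ci, (spec, ancestors, spacer, tpls, probs) in enumerate(cluster_info):
                if ci > 0 and inter is not None:
                    emit(mutate(inter, half_allelic, rng), ("inter", ci))
                ti = int(rng.choice(len(tpls), p=probs))
                tpl_choice.append(ti)
                tpl = tpls[ti]
                for k, (orient, g) in enumerate(zip(tpl.orientations, tpl.groups)):
                    unit = mutate(ancestors[g], half_allelic, rng)
                    if orient == "-":
                        unit = revcomp_codes(unit)
                    start = pos
                    emit(unit, ("unit", spec.name, g), orient)
                    copies.append((spec.name, start, pos, f"group{g}", orient))
                    emit(mutate(spacer, half_allelic, rng), ("spacer", spec.name))
            emit(mutate(flank_r, half_allelic, rng), ("flankR",))

            seq = decode(np.concatenate(parts))
            haplotypes.append(SequenceRecord(hap_name, seq))
            key = tuple(tpl_choice)
            truth.structure_class[hap_name] = class_ids.setdefault(key, len(class_ids))
            truth.segments[hap_name] = segments
            for j, (cluster, start, end, group, strand) in enumerate(copies):
                copy_id = f"{hap_name}_{cluster}_c{j:02d}"
                truth.copies.append(
                    ParalogCopy(
                        copy_id=copy_id,
                        sample=sample,
                        haplotype=hap,
                        cluster=cluster,
                        interval=GenomicInterval(hap_name, start, end, strand),
                        truth_group=group,
                        sequence=seq[start:end],
                    )
                )
    logger.info(
        "simulate_haplotype_pool: %d haplotypes, %d copies, %d structure classes",
        len(haplotypes), len(truth.copies), len(class_ids),
    )
    return haplotypes, truth


def expected_structural_heterozygosity(config: SimConfig) -> float:
    """Closed-form expected heterozygosity 1 - q, where q is the probability
    that a sample's two haplotypes draw the same template in every cluster."""
    q = 1.0
    for spec in config.cluster_specs:
        _, probs = spec.resolved_templates(config.n_truth_groups)
        q *= float(np.sum(probs**2))
    return 1.0 - q


def truth_pair_alignments(
    truth: TruthSet, hap_a: SequenceRecord, hap_b: SequenceRecord
) -> list[AlignmentRecord]:
    """Noise-free block alignments between two simulated haplotypes.

    Matches the longest common prefix and the longest common suffix of the
    two haplotypes' segment lists (segments match when ancestral key, length
    and orientation agree) and emits one forward alignment block per matched
    run.  Same-class haplotypes therefore yield a single full-length
    alignment; different layouts yield prefix/suffix blocks separated by the
    differing middle.
    """
    seg_a = truth.segments[hap_a.name]
    seg_b = truth.segments[hap_b.name]
    sig_a = [(s.key, s.length, s.orientation) for s in seg_a]
    sig_b = [(s.key, s.length, s.orientation) for s in seg_b]
    n_pre = 0
    while n_pre < min(len(sig_a), len(sig_b)) and sig_a[n_pre] == sig_b[n_pre]:
        n_pre += 1
    n_suf = 0
    while (
        n_suf < min(len(sig_a), len(sig_b)) - n_pre
        and sig_a[len(sig_a) - 1 - n_suf] == sig_b[len(sig_b) - 1 - n_suf]
    ):
        n_suf += 1

    def span(segs: list[Segment], i: int, j: int) -> tuple[int, int]:
        starts = np.cumsum([0] + [s.length for s in segs])
        return int(starts[i]), int(starts[j])

    out: list[AlignmentRecord] = []
    len_a, len_b = len(hap_a.bases), len(hap_b.bases)

    def block(ai: int, aj: int, bi: int, bj: int) -> None:
        a0, a1 = span(seg_a, ai, aj)
        b0, b1 = span(seg_b, bi, bj)
        if a1 <= a0:
            return
        aln_len = a1 - a0
        mism = int(
            np.sum(encode(hap_a.bases[a0:a1]) != encode(hap_b.bases[b0:b1]))
        )
        out.append(
            AlignmentRecord(
                query=GenomicInterval(hap_b.name, b0, b1, "+"),
                target=GenomicInterval(hap_a.name, a0, a1, "+"),
                query_len=len_b,
                target_len=len_a,
                matches=aln_len - mism,
                aln_len=aln_len,
                mismatches=mism,
            )
        )

    if n_pre:
        block(0, n_pre, 0, n_pre)
    if n_suf:
        block(len(seg_a) - n_suf, len(seg_a), len(seg_b) - n_suf, len(seg_b))
    return out


# ---------------------------------------------------------------------------
# rearranged ortholog


def simulate_rearranged_ortholog(
    base: SequenceRecord,
    rearrangements: Sequence[Rearrangement],
    elements: Sequence[GenomicInterval] = (),
    seed: int = 0,
    ortholog_name: Optional[str] = None,
) -> tuple[list[SequenceRecord], list[int], list[AlignmentRecord]]:
    """Apply rearrangements to a chromosome and emit exact truth alignments.

    Returns (ortholog records, truth breakpoints on the base chromosome,
    truth block alignments base-vs-ortholog).  Inverted segments are emitted
    with '-' strand on the query.  A fission splits the output into two
    records; without one, a single record is returned.  Breakpoints are the
    segment boundaries on the base chromosome, excluding its ends.
    """
    rng = np.random.default_rng(seed)
    L = len(base.bases)
    name = ortholog_name or f"{base.name}_ortholog"

    def draw_breaks(r: Rearrangement, n: int, occupied: list[tuple[int, int]]) -> list[int]:
        if r.positions is not None:
            pos = list(r.positions)
            if len(pos) != n:
                raise ValueError(f"{r.kind}: expected {n} positions, got {len(pos)}")
        elif r.placement == "at_element":
            if not elements:
                raise ValueError("at_element placement requires annotated elements")
            bounds = sorted({b for iv in elements for b in (iv.start, iv.end)})
            bounds = [b for b in bounds if 0 < b < L]
            if len(bounds) < n:
                raise ValueError("not enough element boundaries for placement")
            pos = sorted(rng.choice(bounds, size=n, replace=False).tolist())
        else:
            pos = sorted(int(x) for x in rng.integers(1, L, size=n))
        if len(set(pos)) != n:
            raise ValueError("degenerate breakpoint draw; use explicit positions")
        for p in pos:
            if not (0 < p < L):
                raise ValueError(f"breakpoint {p} outside chromosome")
        lo, hi = min(pos), max(pos)
        for a, b in occupied:
            if lo < b and a < hi:
                raise ValueError("overlapping rearrangements rejected")
        occupied.append((lo, hi))
        return pos

    # segment list over the base chromosome: (start, end, strand)
    occupied: list[tuple[int, int]] = []
    segments: list[tuple[int, int, str]] = [(0, L, "+")]
    fission_at: Optional[int] = None

    def split_at(positions: list[int]) -> None:
        nonlocal segments
        new: list[tuple[int, int, str]] = []
        for s, e, st in segments:
            cuts = [p for p in positions if s < p < e]
            edges = [s] + sorted(cuts) + [e]
            for a, b in zip(edges[:-1], edges[1:]):
                new.append((a, b, st))
        segments = new

    order_ops: list[tuple] = []
    for r in rearrangements:
        if r.kind == "inversion":
            a, b = draw_breaks(r, 2, occupied)
            order_ops.append(("inv", a, b))
        elif r.kind == "translocation":
            a, b = draw_breaks(r, 2, occupied)
            order_ops.append(("trans", a, b))
        elif r.kind == "fission":
            (a,) = draw_breaks(r, 1, occupied)
            fission_at = a
            order_ops.append(("fiss", a))

    for op in order_ops:
        if op[0] == "inv":
            _, a, b = op
            split_at([a, b])
            segments = [
                (s, e, "-" if a <= s and e <= b else st)
                for s, e, st in segments
            ]
            # reverse the order of the inverted segments
            inside = [seg for seg in segments if a <= seg[0] and seg[1] <= b]
            rest_before = [seg for seg in segments if seg[1] <= a]
            rest_after = [seg for seg in segments if seg[0] >= b]
            segments = rest_before + inside[::-1] + rest_after
        elif op[0] == "trans":
            _, a, b = op
            split_at([a, b])
            moved = [seg for seg in segments if a <= seg[0] and seg[1] <= b]
            rest = [seg for seg in segments if not (a <= seg[0] and seg[1] <= b)]
            segments = moved + rest  # move the segment to the chromosome start
        elif op[0] == "fiss":
            _, a = op
            split_at([a])

    base_codes = encode(base.bases)
    pieces: list[np.ndarray] = []
    truth_alignments: list[AlignmentRecord] = []
    qpos = 0
    boundaries: set[int] = set()
    # fission: split the *output* at the image of the fission point
    for s, e, st in segments:
        codes = base_codes[s:e]
        if st == "-":
            codes = revcomp_codes(codes)
        pieces.append(codes)
        truth_alignments.append(
            AlignmentRecord(
                query=GenomicInterval(name, qpos, qpos + (e - s), st),
                target=GenomicInterval(base.name, s, e, "+"),
                query_len=L,
                target_len=L,
                matches=e - s,
                aln_len=e - s,
                mismatches=0,
            )
        )
        qpos += e - s
        boundaries.update((s, e))
    boundaries -= {0, L}
    breaks = sorted(boundaries)

    full = decode(np.concatenate(pieces))
    if fission_at is None:
        records = [SequenceRecord(name, full)]
    else:
        # locate the fission point in output coordinates
        cut = 0
        for rec in truth_alignments:
            if rec.target.start == fission_at:
                cut = rec.query.start
                break
        records = [
            SequenceRecord(f"{name}_1", full[:cut]),
            SequenceRecord(f"{name}_2", full[cut:]),
        ]
    logger.info(
        "simulate_rearranged_ortholog: %d segments, %d breakpoints", len(segments), len(breaks)
    )
    return records, breaks, truth_alignments


# ---------------------------------------------------------------------------
# reads


def simulate_transcript_reads(
    truth: TruthSet,
    config: SimConfig,
    n_reads: int,
    seed: Optional[int] = None,
) -> list[SequenceRecord]:
    """Full-length transcript-like reads with per-truth-group expression
    weights.

    Read counts per group are multinomial in the weights; the source copy is
    uniform within the group; substitutions are injected at the configured
    per-base error rate and the quality string encodes the realised accuracy
    (uniform Phred of the realised error fraction).  Origins are recorded in
    ``truth.read_origins``.
    """
    if config.expression_weights is None:
        raise ValueError("expression_weights required for transcript simulation")
    weights = np.asarray(config.expression_weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("expression weights sum to zero")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    by_group = truth.copies_by_group()
    groups = [f"group{i}" for i in range(config.n_truth_groups)]
    for g, w in zip(groups, weights):
        if w > 0 and not by_group.get(g):
            raise ValueError(f"no copies available for expressed group {g}")
    probs = weights / weights.sum()
    choices = rng.choice(len(groups), size=n_reads, p=probs)
    err = config.read_params.transcript_error
    reads: list[SequenceRecord] = []
    for i, gi in enumerate(choices):
        copies = by_group[groups[gi]]
        copy = copies[int(rng.integers(len(copies)))]
        codes = encode(copy.sequence)
        before = codes
        codes = mutate(codes, err, rng)
        n_err = int(np.sum(before != codes))
        acc = 1.0 - n_err / len(codes)
        q = accuracy_to_phred(acc)
        name = f"tr{i:06d}"
        reads.append(SequenceRecord(name, decode(codes), (q,) * len(codes)))
        truth.read_origins[name] = copy.copy_id
    logger.info("simulate_transcript_reads: %d reads (error=%g)", n_reads, err)
    return reads


def simulate_wgs_reads(
    haplotypes: Sequence[SequenceRecord],
    depth: float,
    read_len: int,
    error: float = 0.0,
    seed: int = 0,
    truth: Optional[TruthSet] = None,
) -> list[SequenceRecord]:
    """Uniform-start shotgun reads at the given per-haplotype depth.

    Expected per-base coverage equals ``depth`` on each haplotype (so a
    diploid locus present on both haplotypes sees 2x depth over shared
    coordinates).  Origins are recorded in ``truth.wgs_origins`` when a
    TruthSet is supplied.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    idx = 0
    for hap in haplotypes:
        L = len(hap.bases)
        if read_len > L:
            raise ValueError(f"read_len {read_len} exceeds haplotype length {L}")
        n = int(round(depth * L / read_len))
        starts = rng.integers(0, L - read_len + 1, size=n)
        codes_full = encode(hap.bases) if error > 0 else None
        for s in starts:
            name = f"wgs{idx:07d}"
            if error > 0:
                bases = decode(mutate(codes_full[s : s + read_len], error, rng))
            else:
                bases = hap.bases[s : s + read_len]
            reads.append(SequenceRecord(name, bases))
            if truth is not None:
                truth.wgs_origins[name] = (hap.name, int(s))
            idx += 1
    logger.info(
        "simulate_wgs_reads: %d reads over %d haplotypes (depth=%g)", idx, len(haplotypes), depth
    )
    return reads


# ---------------------------------------------------------------------------
# collapsed assemblies


@dataclass(frozen=True)
class CollapseTruth:
    """Coordinates of an engineered assembly collapse."""

    retained: GenomicInterval  # in collapsed-assembly coordinates
    removed: GenomicInterval  # in original-haplotype coordinates
    removed_len: int


def build_collapsed_assembly(
    haplotype: SequenceRecord,
    collapse_spec: Optional[tuple[GenomicInterval, GenomicInterval]] = None,
) -> tuple[SequenceRecord, list[CollapseTruth]]:
    """Merge two copy intervals into one locus, emulating an assembly
    collapse.

    The first interval's sequence is retained; the second interval is excised
    from the assembly.  Without a collapse_spec the input is returned
    unchanged with no truth flags.
    """
    if collapse_spec is None:
        return SequenceRecord(haplotype.name, haplotype.bases), []
    keep, drop = collapse_spec
    if keep.overlaps(drop):
        raise ValueError("collapse intervals overlap")
    if drop.start < keep.start:
        raise ValueError("retained interval must precede the removed interval")
    seq = haplotype.bases[: drop.start] + haplotype.bases[drop.end :]
    retained = GenomicInterval(f"{haplotype.name}_collapsed", keep.start, keep.end, keep.strand)
    truth = CollapseTruth(retained=retained, removed=drop, removed_len=drop.length)
    return SequenceRecord(f"{haplotype.name}_collapsed", seq), [truth]
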
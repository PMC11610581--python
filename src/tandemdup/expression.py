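"""Paralog-specific transcript assignment and expression summaries.

Full-length cDNA reads are filtered (length >= 1000 bp, read accuracy
>= 99.9% from the quality string), aligned against representative copies of
each paralog group, and assigned to a group when the best alignment score
for that group beats the best score of every OTHER group by a margin
(default 10).  Reads hitting a single group are assigned outright; reads
whose margin falls below the threshold are ambiguous and excluded from
expression summaries.  Expression per group is reported as read count,
fraction of assigned reads, and count normalised by the group's median
per-haplotype copy number.

Alignment scores use a declared scheme — match +1, mismatch -2, gap open
-2, gap extend -1 — so the margin rule is exactly reproducible; PAF inputs
carrying their own AS score tags are used as-is.

``characterize_terminal_deletion`` reports the coding consequence of a
contiguous deletion in the terminal exon: deleted length, frameshift
status, reference residues lost downstream of the deletion, and the length
of the novel C-terminal extension translated in the shifted frame up to the
first downstream stop.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .io import AlignmentRecord, GenomicInterval, SequenceRecord

logger = logging.getLogger("tandemdup")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -2
GAP_EXTEND = -1


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # assigned | ambiguous | unmapped | filtered
    group: Optional[str] = None
    best_score: Optional[float] = None
    margin: Optional[float] = None
    identity: Optional[float] = None


@dataclass(frozen=True)
class ExpressionSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    normalized: dict[str, Optional[float]]
    ambiguous: int
    flagged: tuple[str, ...] = ()  # groups with zero median copy number


@dataclass(frozen=True)
class DeletionConsequence:
    deletion_length: int
    frameshift: bool
    residues_lost: int
    extension_length: int
    stop_recovered: bool


def filter_flnc(
    reads: Sequence[SequenceRecord],
    min_len: int = 1_000,
    min_accuracy: float = 0.999,
) -> list[SequenceRecord]:
    """Keep reads with length >= min_len and mean per-base accuracy
    >= min_accuracy (accuracy from mean error probability; both boundaries
    inclusive).  Reads without qualities pass the length filter only."""
    kept = []
    warned = False
    for r in reads:
        if len(r.bases) < min_len:
            continue
        acc = r.mean_accuracy()
        if acc is None:
            if not warned:
                logger.warning("filter_flnc: reads without qualities pass length filter only")
                warned = True
            kept.append(r)
        elif acc >= min_accuracy - 1e-12:
            kept.append(r)
    logger.info("filter_flnc: kept %d of %d reads", len(kept), len(reads))
    return kept


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _score_from_cigar(cigar: str, n_mismatch_in_M: int = 0) -> tuple[int, int, int, int]:
    """(score, matches, mismatches, aln_len) from an edlib extended cigar."""
    matches = mismatches = indel = 0
    score = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            matches += n
            score += MATCH_SCORE * n
        elif op in ("X", "M"):
            mismatches += n
            score += MISMATCH_SCORE * n
        else:  # I or D
            indel += n
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    return score, matches, mismatches, matches + mismatches + indel


def align_read_to_copy(
    read: SequenceRecord, copy_name: str, copy_seq: str
) -> AlignmentRecord:
    """Global alignment of a full-length read to one copy under the declared
    scoring scheme (edlib alignment path, rescored)."""
    res = edlib.align(read.bases, copy_seq, mode="NW", task="path")
    score, matches, mismatches, aln_len = _score_from_cigar(res["cigar"])
    return AlignmentRecord(
        query=GenomicInterval(read.name, 0, len(read.bases), "+"),
        target=GenomicInterval(copy_name, 0, len(copy_seq), "+"),
        query_len=len(read.bases),
        target_len=len(copy_seq),
        matches=matches,
        aln_len=aln_len,
        score=score,
        mismatches=mismatches,
    )


def align_read_to_groups(
    read: SequenceRecord, copies_by_group: Mapping[str, Sequence[tuple[str, str]]]
) -> list[tuple[str, AlignmentRecord]]:
    """Align a read against every copy of every group."""
    out = []
    for group, copies in copies_by_group.items():
        for name, seq in copies:
            out.append((group, align_read_to_copy(read, name, seq)))
    return out


def assign_read(
    read_id: str,
    group_alignments: Sequence[tuple[str, AlignmentRecord]],
    margin_threshold: float = 10.0,
) -> ReadAssignment:
    """Assign a read to the top-scoring paralog group by the margin rule.

    Scores within one group collapse to the group's best; the read is
    assigned iff the top group's score beats the best other group by
    >= margin_threshold.  Single-group reads are assigned with an infinite
    margin; no alignments means unmapped.
    """
    if not group_alignments:
        return ReadAssignment(read_id, "unmapped")
    best: dict[str, AlignmentRecord] = {}
    for group, rec in group_alignments:
        if group not in best or rec.score > best[group].score:
            best[group] = rec
    ranked = sorted(best.items(), key=lambda kv: -kv[1].score)
    top_group, top_rec = ranked[0]
    identity = top_rec.matches / top_rec.aln_len if top_rec.aln_len else 0.0
    if len(ranked) == 1:
        return ReadAssignment(
            read_id, "assigned", top_group, float(top_rec.score), math.inf, identity
        )
    margin = float(top_rec.score - ranked[1][1].score)
    if margin >= margin_threshold:
        return ReadAssignment(
            read_id, "assigned", top_group, float(top_rec.score), margin, identity
        )
    return ReadAssignment(
        read_id, "ambiguous", None, float(top_rec.score), margin, identity
    )


def detect_expressed(
    assignments: Iterable[ReadAssignment], min_identity: float = 0.999
) -> set[str]:
    """Groups supported by >= 1 assigned read at identity >= min_identity."""
    return {
        a.group
        for a in assignments
        if a.status == "assigned" and a.identity is not None and a.identity >= min_identity
    }


def summarize_expression(
    assignments: Sequence[ReadAssignment],
    copy_table: Mapping[str, Sequence[int]],
) -> ExpressionSummary:
    """Per-group read counts, fractions of assigned reads, and copy-number
    normalised expression (count / median per-haplotype copy number of the
    group, population-wide).  Ambiguous reads are counted but excluded from
    fractions.  A zero median copy number leaves the normalised value
    undefined and flags the group."""
    assigned = [a for a in assignments if a.status == "assigned"]
    ambiguous = sum(1 for a in assignments if a.status == "ambiguous")
    counts: dict[str, int] = {}
    for a in assigned:
        counts[a.group] = counts.get(a.group, 0) + 1
    for g in counts:
        if g not in copy_table:
            raise ValueError(f"group {g} absent from copy table")
    total = len(assigned)
    fractions = {g: c / total for g, c in counts.items()} if total else {}
    normalized: dict[str, Optional[float]] = {}
    flagged = []
    for g, c in counts.items():
        med = float(np.median(np.asarray(copy_table[g], dtype=float)))
        if med <= 0:
            normalized[g] = None
            flagged.append(g)
        else:
            normalized[g] = c / med
    return ExpressionSummary(
        counts=counts,
        fractions=fractions,
        normalized=normalized,
        ambiguous=ambiguous,
        flagged=tuple(flagged),
    )


_MIN_3P_CONTEXT = 6  # bp of reference 3' sequence that must re-match after the deletion


def _find_deletion(ref: str, alt: str) -> tuple[int, int]:
    """Locate a single contiguous deletion of alt relative to ref.

    Returns (position, length).  ``alt`` may extend past the reference 3'
    end (downstream sequence); everything other than the one deletion must
    match the reference base-for-base, and at least ``_MIN_3P_CONTEXT`` bp
    of reference sequence must re-match downstream of the deletion (so a
    truncation is not mistaken for a deletion).
    """
    p = 0
    limit = min(len(ref), len(alt))
    while p < limit and ref[p] == alt[p]:
        p += 1
    if p == len(ref):
        raise ValueError("no deletion found (alt contains the full reference)")
    for dl in range(1, len(ref) - p - _MIN_3P_CONTEXT + 1):
        rem = len(ref) - p - dl
        if len(alt) >= p + rem and alt[p : p + rem] == ref[p + dl :]:
            return p, dl
    raise ValueError("alt differs from ref by more than one contiguous deletion")


def characterize_terminal_deletion(
    ref_cds: str,
    alt_seq: str,
    deletion: Optional[tuple[int, int]] = None,
) -> DeletionConsequence:
    """Coding consequence of a contiguous deletion near the CDS 3' end.

    ``ref_cds`` must be a complete CDS (length divisible by 3, ending in a
    stop codon).  ``alt_seq`` is the same region with one contiguous
    deletion applied, optionally extending past the reference 3' end into
    downstream sequence.  ``deletion`` may supply (position, length)
    explicitly; otherwise it is inferred.

    residues_lost counts reference residues from the codon containing the
    deletion start through the last sense codon — the residues truncated or
    altered relative to the reference C terminus.  For a frameshift,
    extension_length counts the codons translated in the shifted frame from
    the frameshift point to the first downstream stop (the novel C
    terminus); in frame, it counts codons read past the reference stop
    position (normally 0).
    """
    ref_cds = ref_cds.upper()
    alt_seq = alt_seq.upper()
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if ref_cds[-3:] not in STOP_CODONS:
        raise ValueError("reference CDS must end in a stop codon")
    if deletion is None:
        pos, dl = _find_deletion(ref_cds, alt_seq)
    else:
        pos, dl = deletion
        if ref_cds[:pos] != alt_seq[:pos]:
            raise ValueError("declared deletion position inconsistent with sequences")
    if pos < 3:
        raise ValueError("deletion spanning the start codon is unsupported")
    frameshift = dl % 3 != 0
    cstart = pos - (pos % 3)  # first codon touched by the deletion
    residues_lost = (len(ref_cds) - 3 - cstart) // 3
    # translate alt from the affected codon to the first stop
    p_stop = None
    q = cstart
    while q + 3 <= len(alt_seq):
        if alt_seq[q : q + 3] in STOP_CODONS:
            p_stop = q
            break
        q += 3
    stop_recovered = p_stop is not None
    end = p_stop if p_stop is not None else q
    if frameshift:
        extension = (end - cstart) // 3
    else:
        ref_stop_alt = len(ref_cds) - 3 - dl
        extension = max(0, (end - ref_stop_alt) // 3)
    return DeletionConsequence(
        deletion_length=dl,
        frameshift=frameshift,
        residues_lost=residues_lost,
        extension_length=extension,
        stop_recovered=stop_recovered,
    )
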
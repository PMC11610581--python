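import math

import numpy as np
import pytest

from tandemdup.expression import (
    STOP_CODONS,
    ReadAssignment,
    align_read_to_groups,
    assign_read,
    characterize_terminal_deletion,
    detect_expressed,
    filter_flnc,
    summarize_expression,
)
from tandemdup.io import SequenceRecord
from tandemdup.simulate import ClusterSpec, ReadParams, SimConfig, simulate_haplotype_pool, simulate_transcript_reads

from conftest import random_seq, substituted
from _oracles import translation_consequence


class TestFilterFlnc:
    def test_length_boundary_is_exclusive_below(self):
        short = SequenceRecord("s", "A" * 999, (60,) * 999)
        assert filter_flnc([short]) == []

    def test_q30_read_sits_exactly_on_the_accuracy_boundary(self):
        read = SequenceRecord("r", "A" * 1_000, (30,) * 1_000)
        assert filter_flnc([read]) == [read]
        worse = SequenceRecord("w", "A" * 1_000, (29,) * 1_000)
        assert filter_flnc([worse]) == []

    def test_empty_input(self):
        assert filter_flnc([]) == []

    def test_reads_without_qualities_pass_length_filter_only(self):
        read = SequenceRecord("r", "A" * 1_500)
        assert filter_flnc([read]) == [read]


class TestAssignRead:
    def test_single_group_is_assigned_with_infinite_margin(self, rng):
        copy = random_seq(rng, 2_000)
        read = SequenceRecord("r", copy)
        ga = align_read_to_groups(read, {"A": [("a1", copy)]})
        a = assign_read("r", ga)
        assert a.status == "assigned" and a.group == "A"
        assert a.margin == math.inf
        assert a.identity == 1.0

    def test_equal_scores_are_ambiguous(self, rng):
        copy = random_seq(rng, 2_000)
        read = SequenceRecord("r", copy)
        ga = align_read_to_groups(read, {"A": [("a1", copy)], "B": [("b1", copy)]})
        a = assign_read("r", ga)
        assert a.status == "ambiguous" and a.margin == 0.0

    @pytest.mark.parametrize("n_diffs,expect", [(4, "assigned"), (3, "ambiguous")])
    def test_margin_arithmetic_under_declared_scheme(self, rng, n_diffs, expect):
        """Each substitution separating the groups moves the score by
        match(+1) -> mismatch(-2) = 3; margin = 3 * n_diffs vs threshold 10."""
        copy_a = random_seq(rng, 2_000)
        copy_b = substituted(copy_a, rng.choice(2_000, n_diffs, replace=False), rng)
        read = SequenceRecord("r", copy_a)
        ga = align_read_to_groups(read, {"A": [("a1", copy_a)], "B": [("b1", copy_b)]})
        a = assign_read("r", ga)
        assert a.status == expect
        if expect == "assigned":
            assert a.group == "A" and a.margin == 3 * n_diffs

    def test_no_alignments_is_unmapped(self):
        assert assign_read("r", []).status == "unmapped"

    def test_within_group_scores_collapse_to_best(self, rng):
        copy_a = random_seq(rng, 2_000)
        worse_a = substituted(copy_a, rng.choice(2_000, 50, replace=False), rng)
        copy_b = substituted(copy_a, rng.choice(2_000, 10, replace=False), rng)
        read = SequenceRecord("r", copy_a)
        ga = align_read_to_groups(
            read, {"A": [("a1", copy_a), ("a2", worse_a)], "B": [("b1", copy_b)]}
        )
        a = assign_read("r", ga)
        assert a.status == "assigned" and a.group == "A" and a.margin == 30


class TestDetectExpressed:
    def test_no_assigned_reads(self):
        assert detect_expressed([ReadAssignment("r", "ambiguous")]) == set()

    def test_identity_threshold(self):
        low = ReadAssignment("r", "assigned", "A", 10.0, 20.0, identity=0.998)
        hi = ReadAssignment("s", "assigned", "B", 10.0, 20.0, identity=0.9995)
        assert detect_expressed([low, hi]) == {"B"}

    def test_simulated_expressed_groups_recovered(self):
        cfg = SimConfig(
            seed=9, n_samples=2, n_truth_groups=3,
            cluster_specs=(ClusterSpec("c1", (3, 3), 2_000, 200),),
            flank_len=2_000,
            expression_weights=(1.0, 1.0, 0.0),
            read_params=ReadParams(transcript_error=0.0),
        )
        _, truth = simulate_haplotype_pool(cfg)
        reads = simulate_transcript_reads(truth, cfg, 60, seed=2)
        groups = {}
        for c in truth.copies:
            groups.setdefault(c.truth_group, []).append((c.copy_id, c.sequence))
        assignments = [
            assign_read(r.name, align_read_to_groups(r, groups)) for r in reads
        ]
        assert detect_expressed(assignments) == {"group0", "group1"}


class TestSummarizeExpression:
    def make(self, counts, ambiguous=0):
        assignments = []
        for g, n in counts.items():
            assignments += [
                ReadAssignment(f"{g}{i}", "assigned", g, 10.0, 20.0, 1.0)
                for i in range(n)
            ]
        assignments += [ReadAssignment(f"x{i}", "ambiguous") for i in range(ambiguous)]
        return assignments

    def test_single_group_fraction_one(self):
        s = summarize_expression(self.make({"A": 5}), {"A": [2, 2]})
        assert s.fractions["A"] == 1.0

    def test_copy_number_normalization(self):
        s = summarize_expression(
            self.make({"A": 200, "B": 150}), {"A": [2, 2, 2], "B": [1, 1, 1]}
        )
        assert s.normalized == {"A": 100.0, "B": 150.0}

    def test_ambiguous_reads_excluded_from_fractions(self):
        s = summarize_expression(self.make({"A": 10}, ambiguous=5), {"A": [1]})
        assert s.fractions["A"] == 1.0 and s.ambiguous == 5

    def test_missing_group_is_an_error(self):
        with pytest.raises(ValueError, match="absent"):
            summarize_expression(self.make({"A": 1}), {})

    def test_zero_median_copy_number_is_flagged(self):
        s = summarize_expression(self.make({"A": 3}), {"A": [0, 0]})
        assert s.normalized["A"] is None and s.flagged == ("A",)


def _random_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def make_frameshift_fixture(rng, del_len=43, tail_codons=17, ext_codons=41):
    """CDS whose alt form carries a faithful deletion of ``del_len`` bp
    starting 3*tail_codons bp before the stop, followed by downstream
    sequence placing the first shifted-frame stop 3*ext_codons bp after the
    frameshift point.  Returns None when the drawn reference tail cannot
    host the requested geometry (caller redraws)."""
    from Bio.Seq import Seq

    ref = "ATG" + _random_cds(rng, 100) + _random_cds(rng, tail_codons) + "TAA"
    dpos = len(ref) - 3 - 3 * tail_codons
    resid = ref[dpos + del_len :]  # deletion keeps the reference 3' remainder
    need = 3 * ext_codons - len(resid)
    if need < 0:
        return None
    for _ in range(100):
        down = "".join("ACGT"[i] for i in rng.integers(0, 4, need))
        window = resid + down
        if any(window[i : i + 3] in STOP_CODONS for i in range(0, len(window), 3)):
            continue
        alt = ref[:dpos] + window + "TAA" + _random_cds(rng, 3)
        # the first altered codon must change the amino acid, so the
        # translate-and-compare oracle pins the same frameshift point
        if Seq(ref[dpos : dpos + 3]).translate() == Seq(alt[dpos : dpos + 3]).translate():
            return None
        return ref, alt
    return None


class TestTerminalDeletion:
    def test_43bp_deletion_is_a_frameshift(self, rng):
        fixture = None
        while fixture is None:
            fixture = make_frameshift_fixture(rng)
        ref, alt = fixture
        res = characterize_terminal_deletion(ref, alt)
        assert res.deletion_length == 43
        assert res.frameshift  # 43 mod 3 = 1

    def test_in_frame_deletion_of_14_codons(self, rng):
        ref = "ATG" + _random_cds(rng, 50) + "TAA"
        dpos = len(ref) - 3 - 42
        alt = ref[:dpos] + ref[dpos + 42 :]
        # only the stop codon re-matches downstream, so the deletion is declared
        res = characterize_terminal_deletion(ref, alt, deletion=(dpos, 42))
        assert not res.frameshift
        assert res.residues_lost == 14
        assert res.extension_length == 0
        assert res.stop_recovered

    def test_canonical_fixture_17_lost_41_extension(self, rng):
        fixture = None
        while fixture is None:
            fixture = make_frameshift_fixture(rng, 43, 17, 41)
        ref, alt = fixture
        res = characterize_terminal_deletion(ref, alt)
        assert (res.residues_lost, res.extension_length) == (17, 41)
        lost, ext, stop = translation_consequence(ref, alt)
        assert (lost, ext, stop) == (17, 41, True)

    def test_agrees_with_translation_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 100:
            tail = int(rng.integers(5, 30))
            ext = int(rng.integers(3, 60))
            # keep >= 6 bp of reference 3' context after the deletion
            dl = int(rng.integers(4, 3 * tail - 2))
            if dl % 3 == 0:
                continue
            fixture = make_frameshift_fixture(rng, dl, tail, ext)
            if fixture is None:
                continue
            ref, alt = fixture
            res = characterize_terminal_deletion(ref, alt)
            lost, extension, stop = translation_consequence(ref, alt)
            assert res.residues_lost == lost
            assert res.extension_length == extension
            assert res.stop_recovered == stop
            checked += 1

    def test_multiple_deletions_rejected(self, rng):
        ref = "ATG" + _random_cds(rng, 50) + "TAA"
        alt = ref[:30] + ref[35:90] + ref[95:]
        with pytest.raises(ValueError):
            characterize_terminal_deletion(ref, alt)

    def test_start_codon_deletion_rejected(self, rng):
        ref = "ATG" + _random_cds(rng, 50) + "TAA"
        alt = ref[1:]
        with pytest.raises(ValueError):
            characterize_terminal_deletion(ref, alt)


class TestPipelineInvariance:
    def test_order_invariance_of_filter_assign_summarize(self, rng):
        copies = {f"G{i}": [(f"g{i}", random_seq(rng, 1_500))] for i in range(3)}
        reads = []
        for i in range(20):
            g = i % 3
            reads.append(
                SequenceRecord(f"r{i}", copies[f"G{g}"][0][1], (40,) * 1_500)
            )

        def run(order):
            kept = filter_flnc(order)
            assignments = [
                assign_read(r.name, align_read_to_groups(r, copies)) for r in kept
            ]
            table = {f"G{i}": [2, 3] for i in range(3)}
            s = summarize_expression(assignments, table)
            return s.counts, s.fractions

        fwd = run(reads)
        rev = run(reads[::-1])
        assert fwd == rev
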
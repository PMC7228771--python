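"""Expected alleles, junction classification, and the fixture simulator."""

import json

import numpy as np
import pytest

from geneweld.arms import FIVE_PRIME, THREE_PRIME
from geneweld.junctions import (
    ClassifyParams,
    build_expected_allele,
    classify_junction,
    deletion_plan,
    dominant_event,
    expected_junction,
    simulate_fixture,
    single_site_plan,
    summarize_precision,
    JunctionCall,
)
from geneweld.donor import build_vector
from geneweld.seqcore import CutSite, NucSequence, reverse_complement
from geneweld.synth import random_dna
from _helpers import FORBID


@pytest.fixture(scope="module")
def toy_vector():
    rng = np.random.default_rng(71)
    return build_vector(random_dna(rng, 200, FORBID), rng=rng,
                        backbone_length=120, stuffer_length=20)


@pytest.fixture(scope="module")
def genome_10kb():
    return random_dna(np.random.default_rng(72), 10_000, FORBID)


class TestExpectedAllele:
    def test_single_site_length_arithmetic(self, genome_10kb, toy_vector):
        plan = single_site_plan(genome_10kb, CutSite("g", 4000), toy_vector)
        payload = random_dna(np.random.default_rng(1), 1500, FORBID)
        allele = build_expected_allele(plan, payload)
        assert len(allele.sequence) == 11_500
        assert allele.deleted_span == 0
        assert allele.payload_interval == (4000, 5500)

    def test_deletion_span_arithmetic(self, genome_10kb, toy_vector):
        # two cuts 394 bp apart bridged by the donor
        plan = deletion_plan(genome_10kb, CutSite("g", 4000),
                             CutSite("g", 4394), toy_vector)
        payload = random_dna(np.random.default_rng(2), 1500, FORBID)
        allele = build_expected_allele(plan, payload)
        assert len(allele.sequence) == 10_000 - 394 + 1500
        assert allele.deleted_span == 394

    def test_deletion_requires_ordered_cuts(self, genome_10kb, toy_vector):
        with pytest.raises(ValueError, match="upstream"):
            deletion_plan(genome_10kb, CutSite("g", 4394), CutSite("g", 4000),
                          toy_vector)

    def test_junction_windows_match_splice_oracle(self, genome_10kb, toy_vector):
        rng = np.random.default_rng(3)
        g = str(genome_10kb)
        for _ in range(20):
            cut = int(rng.integers(100, 9900))
            payload = str(random_dna(rng, int(rng.integers(100, 800)), FORBID))
            plan = single_site_plan(genome_10kb, CutSite("g", cut), toy_vector)
            allele = build_expected_allele(plan, payload)
            # independent splice oracle
            spliced = g[:cut] + payload + g[cut:]
            assert str(allele.sequence) == spliced
            j5, j3 = allele.junction5_pos, allele.junction3_pos
            assert spliced[j5 - 30 : j5 + 30] == g[cut - 30 : cut] + payload[:30]
            assert spliced[j3 - 30 : j3 + 30] == payload[-30:] + g[cut : cut + 30]


class TestExpectedJunction:
    def _allele(self, genome_10kb, toy_vector):
        plan = single_site_plan(genome_10kb, CutSite("g", 4000), toy_vector)
        return plan, build_expected_allele(plan, toy_vector.cargo)

    def test_window_is_symmetric_around_junction(self, genome_10kb, toy_vector):
        _, allele = self._allele(genome_10kb, toy_vector)
        ref = expected_junction(allele, FIVE_PRIME, 40)
        assert len(ref.sequence) == 80
        assert ref.junction_offset == 40

    def test_three_prime_mirrors_five_prime(self, genome_10kb, toy_vector):
        _, allele = self._allele(genome_10kb, toy_vector)
        r5 = expected_junction(allele, FIVE_PRIME, 40)
        r3 = expected_junction(allele, THREE_PRIME, 40)
        assert r5.arm_interval == (40 - allele.arm5_len, 40)
        assert r3.arm_interval == (40, 40 + allele.arm3_len)

    def test_arm_subinterval_slice_equals_genomic_arm(self, genome_10kb,
                                                      toy_vector):
        plan, allele = self._allele(genome_10kb, toy_vector)
        ref = expected_junction(allele, FIVE_PRIME, 40)
        s, e = ref.arm_interval
        assert str(ref.sequence)[s:e] == str(plan.arm5.sequence)


@pytest.fixture(scope="module")
def ref5():
    fx = simulate_fixture(81, genome_len=3000, cargo_len=300, n_reads=0)
    return fx.reference5


class TestClassifyJunction:
    def test_identity_is_precise(self, ref5):
        call = classify_junction(ref5.sequence, ref5)
        assert call.precise and not call.events

    def test_reverse_complement_read_is_oriented(self, ref5):
        call = classify_junction(reverse_complement(ref5.sequence), ref5)
        assert call.precise and call.orientation == "-"

    def test_single_base_insertion_at_arm_boundary(self, ref5):
        seq = str(ref5.sequence)
        j = ref5.junction_offset
        obs = seq[:j] + "A" + seq[j:] if seq[j] != "A" else seq[:j] + "C" + seq[j:]
        call = classify_junction(obs, ref5)
        assert not call.precise
        assert [(e.kind, e.length) for e in call.events] == [("insertion", 1)]

    def test_tandem_arm_duplication(self, ref5):
        seq = str(ref5.sequence)
        s, e = ref5.arm_interval
        obs = seq[:e] + seq[s:e] + seq[e:]
        call = classify_junction(obs, ref5)
        assert not call.precise
        assert any(ev.kind == "arm_duplication" for ev in call.events)

    def test_mismatch_in_arm_breaks_precision(self, ref5):
        seq = str(ref5.sequence)
        s, e = ref5.arm_interval
        pos = (s + e) // 2
        obs = seq[:pos] + ("A" if seq[pos] != "A" else "G") + seq[pos + 1 :]
        call = classify_junction(obs, ref5)
        assert [e.kind for e in call.events] == ["mismatch_in_arm"]

    def test_mismatch_outside_arm_is_warning_only(self, ref5):
        seq = str(ref5.sequence)
        pos = 5  # well upstream of the arm
        obs = seq[:pos] + ("A" if seq[pos] != "A" else "G") + seq[pos + 1 :]
        call = classify_junction(obs, ref5)
        assert call.precise
        assert call.warnings

    def test_unalignable_read(self, ref5):
        junk = str(random_dna(np.random.default_rng(9), len(ref5.sequence), ()))
        call = classify_junction(junk, ref5)
        assert not call.precise
        assert [e.kind for e in call.events] == ["unalignable"]

    def test_short_read_rejected(self, ref5):
        with pytest.raises(ValueError, match="minimum overlap"):
            classify_junction("ACGTACGT", ref5)

    def test_deletion_event(self, ref5):
        seq = str(ref5.sequence)
        j = ref5.junction_offset
        call = classify_junction(seq[:j] + seq[j + 4 :], ref5)
        assert ("deletion", 4) in [(e.kind, e.length) for e in call.events]


class TestSummarizePrecision:
    def _call(self, precise, side=FIVE_PRIME):
        return JunctionCall(
            verdict="precise" if precise else "imprecise",
            events=(), side=side,
        )

    def test_nineteen_of_twenty(self):
        calls = [self._call(True)] * 19 + [self._call(False)]
        s = summarize_precision(calls)
        assert s.display(FIVE_PRIME) == "19/20"
        assert s.fraction(FIVE_PRIME) == pytest.approx(0.95)

    def test_zero_of_five(self):
        s = summarize_precision([self._call(False)] * 5)
        assert s.display(FIVE_PRIME) == "0/5"
        assert s.fraction(FIVE_PRIME) == 0.0

    def test_mixed_sides_tally_to_total(self):
        calls = (
            [self._call(True, FIVE_PRIME)] * 3
            + [self._call(False, FIVE_PRIME)] * 2
            + [self._call(True, THREE_PRIME)] * 4
        )
        s = summarize_precision(calls)
        assert s.per_side[FIVE_PRIME] == (3, 5)
        assert s.per_side[THREE_PRIME] == (4, 4)
        assert sum(t for _, t in s.per_side.values()) == len(calls)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        calls = [self._call(bool(rng.integers(0, 2))) for _ in range(30)]
        s1 = summarize_precision(calls)
        order = rng.permutation(len(calls))
        s2 = summarize_precision([calls[i] for i in order])
        assert s1.per_side == s2.per_side

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize_precision([])


class TestSimulateFixture:
    MIX = {"precise": 0.6, "insertion": 0.2, "deletion": 0.1, "mismatch": 0.1}

    def test_same_seed_byte_identical(self):
        a = simulate_fixture(5, genome_len=2500, cargo_len=200, n_reads=15,
                             event_mix=self.MIX)
        b = simulate_fixture(5, genome_len=2500, cargo_len=200, n_reads=15,
                             event_mix=self.MIX)
        assert json.dumps(a.manifest(), sort_keys=True) == json.dumps(
            b.manifest(), sort_keys=True
        )

    def test_different_seed_differs(self):
        a = simulate_fixture(5, genome_len=2500, cargo_len=200, n_reads=5)
        b = simulate_fixture(6, genome_len=2500, cargo_len=200, n_reads=5)
        assert a.genome != b.genome

    def test_noise_free_all_precise_recovered(self):
        fx = simulate_fixture(7, genome_len=2500, cargo_len=200, n_reads=40,
                              event_mix={"precise": 1.0}, per_base_error=0.0)
        calls = [classify_junction(r.sequence, fx.reference5) for r in fx.reads]
        assert all(c.precise for c in calls)
        assert summarize_precision(calls).fraction(FIVE_PRIME) == 1.0

    def test_truth_labels_recovered_exactly_without_noise(self):
        fx = simulate_fixture(
            8, genome_len=2500, cargo_len=200, n_reads=60,
            event_mix={**self.MIX, "precise": 0.5, "arm_duplication": 0.1},
        )
        calls = [classify_junction(r.sequence, fx.reference5) for r in fx.reads]
        assert [dominant_event(c) for c in calls] == [
            r.truth_kind for r in fx.reads
        ]

    def test_infeasible_arm_length_errors(self):
        with pytest.raises(ValueError, match="does not fit"):
            simulate_fixture(9, genome_len=100, cargo_len=50, arm_len=60)

    def test_planted_guide_is_unique_and_cut_centered(self):
        fx = simulate_fixture(10, genome_len=2500, cargo_len=200, n_reads=0)
        proto = str(fx.guide.protospacer)
        assert str(fx.genome).count(proto) == 1
        assert fx.cut.position == 2500 // 2 + 17
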
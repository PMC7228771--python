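"""Type IIS digestion, Golden Gate assembly, liberation, off-target scan,
and GenBank round trips."""

import dataclasses

import numpy as np
import pytest

from geneweld.arms import FIVE_PRIME, THREE_PRIME, make_arm_oligos
from geneweld.donor import (
    AssemblyError,
    LiberationError,
    UGRNA_PAM,
    UGRNA_SITE,
    UGRNA_SPACER,
    assemble_donor,
    build_vector,
    digest_type_iis,
    emit_record,
    liberate_cargo,
    read_record,
    ugRNA_offtarget_scan,
)
from geneweld.enzymes import BFUAI, BSPQI
from geneweld.seqcore import NucSequence, reverse_complement
from geneweld.synth import random_dna
from _helpers import FORBID, digest_circle_oracle, hamming_scan, random_assembly, rc


class TestDigest:
    def test_single_bfuai_site_linear(self):
        # ACCTGC at position 10; top cut at 10+6+4=20, bottom at 24
        seq = "A" * 10 + "ACCTGC" + "G" * 44
        frags = digest_type_iis(seq, BFUAI)
        assert len(frags) == 2
        left, right = frags
        assert left.top == seq[:20]
        assert right.top == seq[20:]
        assert right.left_overhang == seq[20:24]
        assert len(right.left_overhang) == 4
        assert left.right_overhang == rc(seq[20:24])

    def test_single_bspqi_overhang_length_three(self):
        seq = "T" * 12 + "GCTCTTC" + "A" * 41
        frags = digest_type_iis(seq, BSPQI)
        assert len(frags) == 2
        assert len(frags[1].left_overhang) == 3
        # (1/4) geometry: top cut 1 nt past the recognition 3' end
        assert frags[0].top == seq[:20]

    def test_minus_strand_site(self):
        seq = "G" * 30 + str(BFUAI.recognition_rc) + "T" * 30
        frags = digest_type_iis(seq, BFUAI)
        assert len(frags) == 2
        # cut upstream of the reverse site: top cut at 30-8=22
        assert frags[0].top == seq[:22]
        assert frags[1].left_overhang == seq[22:26]

    def test_no_site_returns_intact(self):
        seq = "ATATATATAT" * 6
        frags = digest_type_iis(seq, BFUAI)
        assert len(frags) == 1
        assert frags[0].top == seq
        assert frags[0].left_overhang == "" and frags[0].right_overhang == ""

    def test_random_circles_match_scan_and_split_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            seq = str(random_dna(rng, 5000, ()))
            frags = digest_type_iis(seq, [BFUAI, BSPQI], circular=True)
            got = sorted(
                (f.top, f.left_overhang, f.right_overhang) for f in frags
            )
            assert got == digest_circle_oracle(seq, [BFUAI, BSPQI])

    def test_circular_n_sites_n_fragments(self):
        rng = np.random.default_rng(5)
        core = str(random_dna(rng, 200, FORBID))
        seq = core[:50] + "ACCTGC" + core[50:120] + "GCTCTTC" + core[120:]
        frags = digest_type_iis(seq, [BFUAI, BSPQI], circular=True)
        assert len(frags) == 2


class TestAssembly:
    def test_component_order_in_product(self):
        fx = random_assembly(101)
        donor, vec = fx["donor"], fx["vector"]
        seq = str(donor.sequence)
        usite = str(UGRNA_SITE)
        # the product reads ... U5 .. buffer5 .. arm5 .. cargo .. arm3 ..
        # buffer3 .. U3 ... around the circle
        a5 = donor.feature("arm5")
        a3 = donor.feature("arm3")
        cg = donor.feature("cargo")
        u5 = donor.feature("ugRNA_site_5")
        assert u5.end + len(vec.buffer5) == a5.start
        assert seq[a5.start - 3 : a5.start] == str(vec.buffer5)
        assert a5.end == cg.start
        assert cg.end == a3.start
        assert seq[donor.feature("buffer3").start : donor.feature("buffer3").end] == str(vec.buffer3)
        assert donor.feature_seq("arm5") == fx["arm5"].sequence
        assert donor.feature_seq("arm3") == fx["arm3"].sequence
        assert donor.feature_seq("cargo") == vec.cargo

    def test_overhang_mismatch_names_side(self):
        fx = random_assembly(102)
        o3 = fx["oligos3"]
        bad_left = "A" + str(o3.left_overhang)[1:]
        if bad_left == str(o3.left_overhang):
            bad_left = "C" + str(o3.left_overhang)[1:]
        bad = dataclasses.replace(o3, left_overhang=NucSequence(bad_left))
        with pytest.raises(AssemblyError, match="three_prime"):
            assemble_donor(fx["vector"], fx["oligos5"], bad)

    def test_internal_site_in_arm_blocks_assembly(self):
        fx = random_assembly(103)
        arm = fx["arm5"]
        poisoned_seq = str(BSPQI.recognition) + str(arm.sequence)[7:]
        poisoned = dataclasses.replace(arm, sequence=NucSequence(poisoned_seq))
        o5 = dataclasses.replace(fx["oligos5"], arm=poisoned)
        with pytest.raises(AssemblyError, match="BspQI"):
            assemble_donor(fx["vector"], o5, fx["oligos3"])

    def test_redigestion_of_product_yields_zero_cuts(self):
        fx = random_assembly(104)
        frags = digest_type_iis(fx["donor"].sequence, [BFUAI, BSPQI],
                                circular=True)
        assert len(frags) == 1  # intact: Golden Gate completeness


class TestLiberation:
    def test_residual_geometry_and_arm_identity(self):
        fx = random_assembly(105)
        lib = liberate_cargo(fx["donor"])
        vec = fx["vector"]
        res5 = lib.residual_ends[FIVE_PRIME]
        res3 = lib.residual_ends[THREE_PRIME]
        assert len(res5) == 3 + len(UGRNA_PAM) + len(vec.buffer5)
        assert len(res3) == 3 + len(UGRNA_PAM) + len(vec.buffer3)
        # residual layout: protospacer remnant, PAM, buffer, then the arm
        assert res5 == str(UGRNA_SPACER)[-3:] + str(UGRNA_PAM) + str(vec.buffer5)
        assert lib.arm5_seq == fx["arm5"].sequence
        assert lib.arm3_seq == fx["arm3"].sequence

    def test_two_fragments_and_backbone_marker(self):
        fx = random_assembly(106)
        lib = liberate_cargo(fx["donor"])
        donor_len = len(fx["donor"].sequence)
        assert len(lib.sequence) + len(lib.backbone) == donor_len
        # the non-cargo fragment carries the vector scaffold: pull a 30-mer
        # from the middle of the backbone feature as a marker
        bb = fx["donor"].feature("backbone")
        mid = (bb.start + bb.end) // 2
        marker = str(fx["donor"].sequence)[mid : mid + 30]
        assert marker in str(lib.backbone)
        assert marker not in str(lib.sequence)

    def test_damaged_site_raises_naming_side(self):
        fx = random_assembly(107)
        donor = fx["donor"]
        u5 = donor.feature("ugRNA_site_5")
        seq = str(donor.sequence)
        broken = seq[: u5.start + 5] + ("A" if seq[u5.start + 5] != "A" else "C") + seq[u5.start + 6 :]
        damaged = dataclasses.replace(donor, sequence=NucSequence(broken))
        with pytest.raises(LiberationError, match="5' UgRNA"):
            liberate_cargo(damaged)


class TestOffTargetScan:
    def test_planted_exact_site(self):
        rng = np.random.default_rng(31)
        g = str(random_dna(rng, 3000, FORBID))
        g = g[:1500] + str(UGRNA_SITE) + g[1500 + 23 :]
        hits = ugRNA_offtarget_scan(g, max_mismatches=0)
        assert [(h.interval.start, h.strand, h.mismatches) for h in hits] == [
            (1500, "+", 0)
        ]

    def test_mismatch_budget_threshold(self):
        rng = np.random.default_rng(32)
        g = str(random_dna(rng, 2000, FORBID))
        spacer = str(UGRNA_SPACER)
        variant = "TT" + spacer[2:]  # 2 mismatches vs the spacer
        g = g[:900] + variant + "TGG" + g[900 + 23 :]
        assert any(
            h.mismatches == 2 for h in ugRNA_offtarget_scan(g, max_mismatches=2)
        )
        assert not ugRNA_offtarget_scan(g, max_mismatches=1)

    def test_matches_hamming_oracle(self):
        rng = np.random.default_rng(33)
        g = str(random_dna(rng, 5000, ()))
        for budget in (0, 2, 4):
            hits = ugRNA_offtarget_scan(g, max_mismatches=budget)
            got = sorted(
                (h.interval.start, h.strand, h.mismatches) for h in hits
            )
            assert got == hamming_scan(g, str(UGRNA_SPACER), budget)


class TestGenBank:
    def test_write_read_round_trip(self, tmp_path):
        fx = random_assembly(108)
        donor = fx["donor"]
        path = tmp_path / "donor.gb"
        emit_record(donor, path)
        seq, feats, topology = read_record(path)
        assert seq == donor.sequence
        assert topology == "circular"
        assert sorted(feats, key=lambda f: (f.start, f.label)) == sorted(
            donor.features, key=lambda f: (f.start, f.label)
        )

    def test_arm_feature_slice_oracle(self, tmp_path):
        fx = random_assembly(109)
        path = tmp_path / "donor.gb"
        emit_record(fx["donor"], path)
        seq, feats, _ = read_record(path)
        (a5,) = [f for f in feats if f.label == "arm5"]
        assert str(seq)[a5.start : a5.end] == str(fx["arm5"].sequence)

    def test_liberated_record_is_linear(self, tmp_path):
        fx = random_assembly(110)
        lib = liberate_cargo(fx["donor"])
        path = tmp_path / "cargo.gb"
        emit_record(lib, path)
        seq, feats, topology = read_record(path)
        assert topology == "linear"
        assert seq == lib.sequence

    def test_byte_stable_rewrite(self, tmp_path):
        fx = random_assembly(111)
        p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
        emit_record(fx["donor"], p1)
        emit_record(fx["donor"], p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_build_vector_rejects_cargo_with_cloning_site():
    rng = np.random.default_rng(41)
    cargo = str(random_dna(rng, 60, FORBID)) + "ACCTGC" + "TTTT"
    with pytest.raises(AssemblyError, match="ACCTGC"):
        build_vector(cargo, rng=rng)


def test_build_vector_buffer_length_is_tied_to_overhang():
    rng = np.random.default_rng(42)
    cargo = random_dna(rng, 60, FORBID)
    with pytest.raises(ValueError, match="buffer5"):
        build_vector(cargo, buffer5="AAAA", rng=rng)
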
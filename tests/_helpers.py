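"""Independent oracles and shared fixture builders for the test suite.

Everything here is deliberately written as plain brute force, separate from
the library's implementations, so it can serve as ground truth.
"""

from __future__ import annotations

import numpy as np

from geneweld.arms import ArmSpec, extract_arms, make_arm_oligos
from geneweld.donor import UGRNA_SITE, assemble_donor, build_vector, liberate_cargo
from geneweld.seqcore import CutSite, NucSequence
from geneweld.synth import both_strand_motifs, random_dna

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

FORBID = both_strand_motifs(["ACCTGC", "GCTCTTC", str(UGRNA_SITE)])


def rc(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def iupac_match(base: str, code: str) -> bool:
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return base in table[code]


def window_scan_guides(genome: str, proto: str, pam: str) -> list[tuple[int, str]]:
    """O(n*m) sliding-window guide search: (plus-strand protospacer start,
    strand) for every protospacer+PAM occurrence on either strand."""
    hits = []
    n, p, k = len(genome), len(proto), len(pam)
    for i in range(n - p - k + 1):
        if genome[i : i + p] == proto and all(
            iupac_match(genome[i + p + j], pam[j]) for j in range(k)
        ):
            hits.append((i, "+"))
    proto_rc, pam_rc = rc(proto), rc(pam)
    for i in range(n - p - k + 1):
        # minus-strand footprint: rc(pam) then rc(proto)
        if genome[i + k : i + k + p] == proto_rc and all(
            iupac_match(genome[i + j], pam_rc[j]) for j in range(k)
        ):
            hits.append((i + k, "-"))
    return sorted(hits)


def hamming_scan(genome: str, spacer: str, budget: int) -> list[tuple[int, str, int]]:
    """Brute-force off-target scan, PAM NGG exact: (protospacer plus-strand
    start, strand, mismatches)."""
    hits = []
    n, p = len(genome), len(spacer)
    for q in range(p, n - 2):
        if genome[q + 1] == "G" and genome[q + 2] == "G":
            mm = sum(a != b for a, b in zip(genome[q - p : q], spacer))
            if mm <= budget:
                hits.append((q - p, "+", mm))
    spacer_rc = rc(spacer)
    for q in range(0, n - 3 - p + 1):
        if genome[q] == "C" and genome[q + 1] == "C":
            mm = sum(a != b for a, b in zip(genome[q + 3 : q + 3 + p], spacer_rc))
            if mm <= budget:
                hits.append((q + 3, "-", mm))
    return sorted(hits)


def digest_circle_oracle(seq: str, enzymes) -> list[tuple[str, str, str]]:
    """Scan-and-split a circular molecule: returns a sorted multiset of
    (top_strand, left_overhang, right_overhang) per fragment."""
    n = len(seq)
    d = seq + seq
    cuts: dict[int, int] = {}
    for enz in enzymes:
        motif = str(enz.recognition)
        motif_rc = rc(motif)
        for i in range(n):
            if d[i : i + len(motif)] == motif:
                cuts.setdefault((i + len(motif) + enz.cut_offset_top) % n,
                                enz.overhang_length)
            if d[i : i + len(motif_rc)] == motif_rc:
                cuts.setdefault((i - enz.cut_offset_bottom) % n,
                                enz.overhang_length)
    events = sorted(cuts.items())
    if not events:
        return [(seq, "", "")]
    frags = []
    k = len(events)
    for idx, (t1, ov1) in enumerate(events):
        t2, ov2 = events[(idx + 1) % k]
        span = (t2 - t1) % n or n
        frags.append(
            (d[t1 : t1 + span], d[t1 : t1 + ov1], rc(d[t2 : t2 + ov2]))
        )
    return sorted(frags)


def anneal_oracle(top: str, bottom: str) -> tuple[str, str, str] | None:
    """Slide rc(bottom) along top looking for a perfect all-paired duplex;
    return (top 5' protrusion, duplex core, bottom 5' protrusion) of the best
    (longest) perfect annealing, or None."""
    b = rc(bottom)
    best = None
    # offset = position of b's first base under top's coordinate system
    for offset in range(-len(b) + 1, len(top)):
        lo = max(0, offset)
        hi = min(len(top), offset + len(b))
        if hi <= lo:
            continue
        if all(top[i] == b[i - offset] for i in range(lo, hi)):
            length = hi - lo
            if best is None or length > best[0]:
                best = (length, offset, lo, hi)
    if best is None:
        return None
    _, offset, lo, hi = best
    top_protrusion = top[:lo]            # single-stranded 5' end of top
    duplex = top[lo:hi]
    bottom_protrusion = bottom[: len(bottom) - (hi - offset)]
    return top_protrusion, duplex, bottom_protrusion


def random_assembly(seed: int, genome_len: int = 400, arm_choices=(12, 24, 48)):
    """Deterministic random design: genome, cut, arms, oligos, vector,
    assembled donor.  Genomes avoid cloning/UgRNA motifs, as real donor
    designs must."""
    rng = np.random.default_rng(seed)
    genome = random_dna(rng, genome_len, FORBID)
    cut = CutSite("locus", genome_len // 2)
    l5 = int(rng.choice(arm_choices))
    l3 = int(rng.choice(arm_choices))
    arm5, arm3 = extract_arms(
        genome, cut, ArmSpec("five_prime", l5), ArmSpec("three_prime", l3)
    )
    cargo = random_dna(rng, int(rng.integers(60, 200)), FORBID)
    vector = build_vector(cargo, name=f"rand{seed}", rng=rng,
                          backbone_length=120, stuffer_length=20)
    o5 = make_arm_oligos(arm5, vector)
    o3 = make_arm_oligos(arm3, vector)
    donor = assemble_donor(vector, o5, o3)
    return {
        "genome": genome, "cut": cut, "arm5": arm5, "arm3": arm3,
        "vector": vector, "oligos5": o5, "oligos3": o3, "donor": donor,
    }
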
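"""pGTag-style donor vectors: Type IIS digestion, one-pot Golden Gate arm
insertion, in-silico Cas9 liberation of the cargo, and annotated GenBank
output.

The donor model follows the pGTag architecture: a circular vector carrying a
reporter cargo, flanked on each side by a Type IIS cloning site (BfuAI for
the 5' arm, BspQI for the 3' arm) occupied by a stuffer, and further out by a
universal-guide (UgRNA) Cas9 site oriented with its PAM facing the cargo.  A
3-nt buffer without genomic homology separates the UgRNA PAM from the start
of each homology arm, so that the liberated fragment carries exactly the
programmed 12/24/48 bp of homology plus a fixed non-homologous residual
(3-nt protospacer remnant + 3-nt PAM + buffer) outside each arm.

Cloning is modeled with exact overhang complementarity: digestion removes the
stuffers together with the enzyme recognition sites, and the annealed arm
duplexes bridge backbone and cargo.  A correct assembly therefore contains no
intact recognition site of either cloning enzyme (Golden Gate completeness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .arms import FIVE_PRIME, THREE_PRIME, HomologyArm, OligoPair, _motif_hits
from .enzymes import BFUAI, BSPQI, TypeIIsEnzyme
from .seqcore import (
    GenomicInterval,
    NucSequence,
    iupac_to_regex,
    reverse_complement,
)
from .synth import both_strand_motifs, random_dna

logger = logging.getLogger(__name__)

__all__ = [
    "UGRNA_SPACER",
    "UGRNA_PAM",
    "UGRNA_SITE",
    "Fragment",
    "Feature",
    "CloningJunction",
    "VectorSpec",
    "AssembledDonor",
    "LiberatedCargo",
    "OffTargetHit",
    "AssemblyError",
    "LiberationError",
    "digest_type_iis",
    "assemble_donor",
    "liberate_cargo",
    "ugRNA_offtarget_scan",
    "build_vector",
    "emit_record",
    "to_seq_record",
    "read_record",
]

# The universal guide: an engineered spacer with no genomic target, cloned
# into the vector (not the genome) so Cas9 can liberate the cargo in vivo.
UGRNA_SPACER = NucSequence("GGGAGGCGTTCGGGCCACAG")
UGRNA_PAM = NucSequence("CGG")
UGRNA_SITE = NucSequence(UGRNA_SPACER + UGRNA_PAM)


class AssemblyError(ValueError):
    """Golden Gate assembly cannot proceed (overhang mismatch, internal
    cloning site, or malformed vector)."""


class LiberationError(ValueError):
    """A UgRNA site expected on the donor is missing or damaged."""


@dataclass(frozen=True)
class Fragment:
    """A double-stranded fragment with explicit 5' overhangs.

    ``top`` and ``bottom`` are each written 5'->3'.  ``left_overhang`` is the
    single-stranded 5' protrusion on the top strand at the left end;
    ``right_overhang`` the 5' protrusion on the bottom strand at the right
    end.  Blunt ends are empty strings.
    """

    top: str
    bottom: str
    left_overhang: str
    right_overhang: str
    label: str = ""

    def compatible_after(self, other: "Fragment") -> bool:
        """True if ``other``'s right sticky end can ligate to our left end."""
        return (
            len(other.right_overhang) > 0
            and str(reverse_complement(other.right_overhang)) == self.left_overhang
        )


@dataclass(frozen=True)
class Feature:
    label: str
    start: int
    end: int
    strand: int = 1


@dataclass(frozen=True)
class CloningJunction:
    """Per-side cloning configuration: the enzyme that opens the site and the
    two sticky ends the arm oligos must carry (top-strand left overhang,
    bottom-strand right overhang, each 5'->3' as synthesized)."""

    enzyme: TypeIIsEnzyme
    left_overhang: NucSequence
    right_overhang: NucSequence


@dataclass(frozen=True)
class VectorSpec:
    """A pGTag-style donor vector before arm cloning.

    ``sequence`` is the full circular vector (plus strand, starting at the
    5' UgRNA protospacer).  ``cargo`` is the payload between the two cloning
    sites.  ``cargo_junction_phase`` is the reading-frame offset the cargo's
    2A junction requires of the genomic cut (``None`` for promoter-driven
    cargos with no frame constraint).
    """

    name: str
    sequence: NucSequence
    cargo: NucSequence
    buffer5: NucSequence
    buffer3: NucSequence
    cloning_junctions: dict[str, CloningJunction]
    ugRNA_spacer: NucSequence = UGRNA_SPACER
    ugRNA_pam: NucSequence = UGRNA_PAM
    cargo_junction_phase: int | None = 0

    def __post_init__(self) -> None:
        site = str(self.ugRNA_spacer + self.ugRNA_pam)
        d = str(self.sequence) * 2
        n = len(self.sequence)
        n_plus = sum(1 for i in _find_all(d, site) if i < n)
        n_minus = sum(1 for i in _find_all(d, str(reverse_complement(site))) if i < n)
        if n_plus != 1 or n_minus != 1:
            raise AssemblyError(
                f"vector {self.name!r} must carry exactly two UgRNA sites "
                f"(one per orientation); found {n_plus} plus / {n_minus} minus"
            )


@dataclass(frozen=True)
class AssembledDonor:
    """Circular donor after Golden Gate insertion of both homology arms."""

    name: str
    sequence: NucSequence
    features: tuple[Feature, ...]
    circular: bool = True

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(f"no feature {label!r} on donor {self.name!r}")

    def feature_seq(self, label: str) -> NucSequence:
        f = self.feature(label)
        return NucSequence(self.sequence[f.start : f.end])


@dataclass(frozen=True)
class LiberatedCargo:
    """Linear fragment released by Cas9 cuts at both UgRNA sites."""

    name: str
    sequence: NucSequence
    arm5_interval: tuple[int, int]
    arm3_interval: tuple[int, int]
    residual_ends: dict[str, str]
    features: tuple[Feature, ...]
    backbone: NucSequence = NucSequence("")

    @property
    def arm5_seq(self) -> NucSequence:
        s, e = self.arm5_interval
        return NucSequence(self.sequence[s:e])

    @property
    def arm3_seq(self) -> NucSequence:
        s, e = self.arm3_interval
        return NucSequence(self.sequence[s:e])


@dataclass(frozen=True)
class OffTargetHit:
    interval: GenomicInterval
    strand: str
    mismatches: int
    protospacer_found: NucSequence


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while (idx := haystack.find(needle, start)) != -1:
        out.append(idx)
        start = idx + 1
    return out


def _cut_events(
    seq: str, enzymes: Sequence[TypeIIsEnzyme], circular: bool
) -> list[tuple[int, int]]:
    """Sorted (top_cut, overhang_length) events on the plus strand."""
    n = len(seq)
    search = seq + seq if circular else seq
    events: dict[int, int] = {}
    for enz in enzymes:
        m = len(enz.recognition)
        for i in _find_all(search, str(enz.recognition)):
            if circular and i >= n:
                continue
            t = i + m + enz.cut_offset_top
            b = i + m + enz.cut_offset_bottom
            if not circular and (t < 0 or b > n):
                continue  # cut would fall off the molecule end
            events.setdefault(t % n if circular else t, enz.overhang_length)
        for i in _find_all(search, str(enz.recognition_rc)):
            if circular and i >= n:
                continue
            t = i - enz.cut_offset_bottom
            b = i - enz.cut_offset_top
            if not circular and (t < 0 or b > n):
                continue
            events.setdefault(t % n if circular else t, enz.overhang_length)
    return sorted(events.items())


def digest_type_iis(
    record: str | NucSequence,
    enzyme: TypeIIsEnzyme | Sequence[TypeIIsEnzyme],
    circular: bool = False,
) -> list[Fragment]:
    """Digest a linear or circular molecule with one or more Type IIS
    enzymes, returning fragments with typed 5' overhangs.

    Recognition sites are found on both strands; a circular molecule with
    n sites yields n fragments, a linear one n+1.  Zero sites return the
    input intact (with an INFO notice).
    """
    seq = str(NucSequence(record))
    n = len(seq)
    enzymes = [enzyme] if isinstance(enzyme, TypeIIsEnzyme) else list(enzyme)
    events = _cut_events(seq, enzymes, circular)
    if not events:
        logger.info("no recognition site found; molecule returned intact")
        return [Fragment(top=seq, bottom=str(reverse_complement(seq)),
                         left_overhang="", right_overhang="")]

    d = seq + seq
    frags: list[Fragment] = []
    if circular:
        k = len(events)
        for i, (t1, ov1) in enumerate(events):
            t2, ov2 = events[(i + 1) % k]
            span = (t2 - t1) % n or n
            b1, b2 = t1 + ov1, t2 + ov2
            span_b = (b2 - b1) % n or n
            frags.append(
                Fragment(
                    top=d[t1 : t1 + span],
                    bottom=str(reverse_complement(d[b1 % n : b1 % n + span_b])),
                    left_overhang=d[t1 : t1 + ov1],
                    right_overhang=str(reverse_complement(d[t2 : t2 + ov2])),
                )
            )
    else:
        bounded = [(0, 0)] + events + [(n, 0)]
        for (t1, ov1), (t2, ov2) in zip(bounded, bounded[1:]):
            b1, b2 = t1 + ov1, t2 + ov2
            frags.append(
                Fragment(
                    top=seq[t1:t2],
                    bottom=str(reverse_complement(seq[b1:b2])),
                    left_overhang=seq[t1:b1],
                    right_overhang=str(reverse_complement(seq[t2:b2])),
                )
            )
    return frags


def _contains_recognition(seq: str, enzymes: Iterable[TypeIIsEnzyme]) -> bool:
    return any(
        str(e.recognition) in seq or str(e.recognition_rc) in seq for e in enzymes
    )


def _oligo_fragment(pair: OligoPair, label: str) -> Fragment:
    return Fragment(
        top=str(pair.top),
        bottom=str(pair.bottom),
        left_overhang=str(pair.left_overhang),
        right_overhang=str(pair.right_overhang),
        label=label,
    )


def assemble_donor(
    vector: VectorSpec,
    oligos5: OligoPair,
    oligos3: OligoPair,
    allow_internal_sites: bool = False,
) -> AssembledDonor:
    """One-pot Golden Gate: digest the vector with both cloning enzymes,
    discard the stuffers (which carry the recognition sites), and ligate the
    two annealed arm duplexes between backbone and cargo.

    Ligation requires exact overhang complementarity at all four junctions;
    a mismatch raises :class:`AssemblyError` naming the side and the two
    sticky ends.  An arm containing an internal cloning-enzyme site would be
    re-digested in the one-pot reaction and is an error unless
    ``allow_internal_sites`` is set.
    """
    enzymes = [vector.cloning_junctions[FIVE_PRIME].enzyme,
               vector.cloning_junctions[THREE_PRIME].enzyme]

    for pair in (oligos5, oligos3):
        for enz in enzymes:
            if not allow_internal_sites and _motif_hits(str(pair.arm.sequence), enz):
                raise AssemblyError(
                    f"{pair.arm.side} arm contains an internal {enz.name} site "
                    "and would be re-digested during one-pot assembly "
                    "(pass allow_internal_sites=True to override)"
                )

    frags = digest_type_iis(vector.sequence, enzymes, circular=True)
    keep = [f for f in frags if not _contains_recognition(f.top, enzymes)]
    if len(keep) != 2:
        raise AssemblyError(
            f"vector digestion yielded {len(keep)} site-free fragments "
            "(expected backbone + cargo); vector layout is malformed"
        )
    usite = str(vector.ugRNA_spacer + vector.ugRNA_pam)
    backbones = [f for f in keep if str(vector.ugRNA_spacer) in f.top
                 or str(reverse_complement(usite)) in f.top]
    if len(backbones) != 1:
        raise AssemblyError("could not identify the backbone fragment by its "
                            "UgRNA sites")
    backbone = backbones[0]
    cargo_frag = keep[0] if keep[1] is backbone else keep[1]

    f5 = _oligo_fragment(oligos5, "arm5")
    f3 = _oligo_fragment(oligos3, "arm3")

    order = [(backbone, f5, FIVE_PRIME), (f5, cargo_frag, FIVE_PRIME),
             (cargo_frag, f3, THREE_PRIME), (f3, backbone, THREE_PRIME)]
    for left, right, side in order:
        if not right.compatible_after(left):
            raise AssemblyError(
                f"overhang mismatch at the {side} junction: fragment end "
                f"{reverse_complement(left.right_overhang)!s} cannot ligate to "
                f"{right.left_overhang!s}"
            )

    product = backbone.top + f5.top + cargo_frag.top + f3.top
    n = len(product)

    b0 = len(backbone.top)
    arm5_start = b0 + len(f5.left_overhang)
    arm5_end = b0 + len(f5.top)
    cargo_start = arm5_end
    b2 = cargo_start + len(cargo_frag.top)
    arm3_start = b2 + len(f3.left_overhang)
    arm3_end = b2 + len(f3.top)
    cargo_end = arm3_start  # cargo's trailing bases ride in on the arm3 oligo

    if not allow_internal_sites and _contains_recognition(product + product[:16], enzymes):
        raise AssemblyError(
            "assembly would recreate a cloning-enzyme recognition site at a "
            "ligation junction; redesign the arm or override"
        )

    u5_hits = [i for i in _find_all(product * 2, usite) if i < n]
    u3_hits = [i for i in _find_all(product * 2, str(reverse_complement(usite))) if i < n]
    if len(u5_hits) != 1 or len(u3_hits) != 1:
        raise AssemblyError("assembled donor does not carry exactly one UgRNA "
                            "site per orientation")

    feats = [
        Feature("backbone", 0, b0),
        Feature("arm5", arm5_start, arm5_end),
        Feature("cargo", cargo_start, cargo_end),
        Feature("arm3", arm3_start, arm3_end),
        Feature("buffer5", arm5_start - len(vector.buffer5), arm5_start),
        Feature("buffer3", (arm3_end % n), (arm3_end % n) + len(vector.buffer3)),
        Feature("ugRNA_site_5", u5_hits[0], u5_hits[0] + len(usite), 1),
        Feature("ugRNA_site_3", u3_hits[0], u3_hits[0] + len(usite), -1),
    ]
    # The U5 site straddles the backbone/arm-oligo boundary (its final PAM
    # base arrives on the arm5 oligo); keep features within [0, n).
    feats = [f for f in feats if f.end <= n] + [
        Feature(f.label, f.start, n, f.strand) for f in feats if f.end > n
    ]
    feats.sort(key=lambda f: (f.start, f.label))
    return AssembledDonor(
        name=f"{vector.name}__{oligos5.arm.cut.contig}",
        sequence=NucSequence(product),
        features=tuple(feats),
    )


def liberate_cargo(
    donor: AssembledDonor,
    spacer: str | NucSequence = UGRNA_SPACER,
    pam: str | NucSequence = UGRNA_PAM,
) -> LiberatedCargo:
    """Apply the blunt Cas9 cut at each UgRNA site of a circular donor and
    return the cargo-bearing fragment.

    Under the default orientation (PAM facing the cargo on each side) the
    fragment carries, outside each arm, a residual of 3 protospacer bases +
    PAM + buffer that lacks genomic homology.
    """
    seq = str(donor.sequence)
    n = len(seq)
    d = seq + seq
    usite = str(NucSequence(spacer)) + str(NucSequence(pam))
    plus = [i for i in _find_all(d, usite) if i < n]
    minus = [i for i in _find_all(d, str(reverse_complement(usite))) if i < n]
    if len(plus) != 1:
        raise LiberationError(
            f"5' UgRNA site missing or damaged ({len(plus)} plus-strand matches)"
        )
    if len(minus) != 1:
        raise LiberationError(
            f"3' UgRNA site missing or damaged ({len(minus)} minus-strand matches)"
        )
    # Blunt cut between protospacer bases 17|18 (3 bp 5' of the PAM).
    cut5 = (plus[0] + len(spacer) - 3) % n
    cut3 = (minus[0] + len(pam) + 3) % n

    frag_a = d[cut5 : cut5 + ((cut3 - cut5) % n)]
    frag_b = d[cut3 : cut3 + ((cut5 - cut3) % n)]

    arm5 = donor.feature("arm5")
    arm3 = donor.feature("arm3")
    cargo = donor.feature("cargo")
    off5 = (arm5.start - cut5) % n
    if off5 + (arm5.end - arm5.start) > len(frag_a):
        raise LiberationError("cargo-side fragment does not contain the 5' arm")
    arm5_iv = (off5, off5 + (arm5.end - arm5.start))
    off3 = (arm3.start - cut5) % n
    arm3_iv = (off3, off3 + (arm3.end - arm3.start))
    cargo_iv = ((cargo.start - cut5) % n, (cargo.start - cut5) % n + (cargo.end - cargo.start))

    feats = (
        Feature("arm5", *arm5_iv),
        Feature("cargo", *cargo_iv),
        Feature("arm3", *arm3_iv),
    )
    return LiberatedCargo(
        name=f"{donor.name}__cargo",
        sequence=NucSequence(frag_a),
        arm5_interval=arm5_iv,
        arm3_interval=arm3_iv,
        residual_ends={
            FIVE_PRIME: frag_a[: arm5_iv[0]],
            THREE_PRIME: frag_a[arm3_iv[1] :],
        },
        features=feats,
        backbone=NucSequence(frag_b),
    )


def ugRNA_offtarget_scan(
    genome: str | NucSequence,
    spacer: str | NucSequence = UGRNA_SPACER,
    pam_pattern: str = "NGG",
    max_mismatches: int = 3,
    contig: str = "genome",
) -> list[OffTargetHit]:
    """Scan both strands for protospacer matches within a Hamming-distance
    budget, holding the PAM pattern exact.

    Default budget 3, a conservative operationalization of "no predicted
    target" for the universal guide on a given genome.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    import re

    g = str(NucSequence(genome))
    sp = str(NucSequence(spacer).require_unambiguous("protospacer"))
    plen, pam_len = len(sp), len(pam_pattern)
    hits: list[OffTargetHit] = []

    pam_re = re.compile(f"(?=({iupac_to_regex(pam_pattern)}))")
    for m in pam_re.finditer(g):
        q = m.start()
        if q < plen:
            continue
        window = g[q - plen : q]
        mm = sum(a != b for a, b in zip(window, sp))
        if mm <= max_mismatches:
            hits.append(
                OffTargetHit(
                    interval=GenomicInterval(contig, q - plen, q),
                    strand="+",
                    mismatches=mm,
                    protospacer_found=NucSequence(window),
                )
            )
    rc_pam_re = re.compile(f"(?=({iupac_to_regex(str(reverse_complement(pam_pattern)))}))")
    sp_rc = str(reverse_complement(sp))
    for m in rc_pam_re.finditer(g):
        q = m.start()
        if q + pam_len + plen > len(g):
            continue
        window = g[q + pam_len : q + pam_len + plen]
        mm = sum(a != b for a, b in zip(window, sp_rc))
        if mm <= max_mismatches:
            hits.append(
                OffTargetHit(
                    interval=GenomicInterval(contig, q + pam_len, q + pam_len + plen),
                    strand="-",
                    mismatches=mm,
                    protospacer_found=reverse_complement(window),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def build_vector(
    cargo: str | NucSequence,
    name: str = "synthetic-donor",
    buffer5: str | NucSequence = "AAA",
    buffer3: str | NucSequence = "AAA",
    cargo_junction_phase: int | None = 0,
    backbone_length: int = 400,
    stuffer_length: int = 40,
    rng: np.random.Generator | int | None = 0,
    spacer: NucSequence = UGRNA_SPACER,
    pam: NucSequence = UGRNA_PAM,
) -> VectorSpec:
    """Construct a pGTag-style circular vector around a cargo.

    Layout (plus strand, origin at the 5' UgRNA protospacer)::

        [U5: protospacer+PAM][buffer5][BfuAI stuffer][cargo][BspQI stuffer]
        [buffer3][rc(PAM+protospacer): U3][backbone]

    The cut geometry places the sticky ends so that, after arm insertion,
    each homology arm directly abuts its buffer on the UgRNA side and the
    cargo on the other -- the 5' arm's left overhang is the last PAM base
    plus the buffer, its right overhang the first four cargo bases; the 3'
    arm's left overhang is the last three cargo bases, its right overhang
    the buffer.  Stuffers and backbone are seeded random sequence free of
    cloning-site and UgRNA motifs.
    """
    cargo = NucSequence(cargo).require_unambiguous("cargo")
    buffer5 = NucSequence(buffer5)
    buffer3 = NucSequence(buffer3)
    if len(buffer5) != BFUAI.overhang_length - 1:
        raise ValueError(
            f"buffer5 must be {BFUAI.overhang_length - 1} nt: the 5' sticky end "
            "is the final PAM base plus the buffer"
        )
    if len(buffer3) != BSPQI.overhang_length:
        raise ValueError(
            f"buffer3 must be {BSPQI.overhang_length} nt: it is itself the 3' "
            "sticky end"
        )
    if len(cargo) < 8:
        raise ValueError("cargo must be at least 8 bp to define both sticky ends")
    usite = str(spacer + pam)
    forbidden = both_strand_motifs(
        [str(BFUAI.recognition), str(BSPQI.recognition), usite]
    )
    for motif in forbidden:
        if motif in cargo:
            raise AssemblyError(
                f"cargo contains forbidden motif {motif}; it would be cut "
                "during cloning or liberation"
            )
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))

    for _ in range(100):
        filler_a = random_dna(rng, 4, forbidden)
        filler_b = random_dna(rng, 4, forbidden)
        filler_c = random_dna(rng, 1, forbidden)
        filler_d = random_dna(rng, 1, forbidden)
        stuffer_a = random_dna(rng, stuffer_length, forbidden)
        stuffer_b = random_dna(rng, stuffer_length, forbidden)
        backbone = random_dna(rng, backbone_length, forbidden)
        seq = NucSequence(
            usite
            + buffer5
            + filler_a
            + BFUAI.recognition_rc
            + stuffer_a
            + BFUAI.recognition
            + filler_b
            + cargo
            + filler_c
            + BSPQI.recognition_rc
            + stuffer_b
            + BSPQI.recognition
            + filler_d
            + buffer3
            + reverse_complement(usite)
            + backbone
        )
        d = str(seq) * 2
        n = len(seq)
        counts = {
            m: sum(1 for i in _find_all(d, m) if i < n) for m in forbidden
        }
        want = {
            str(BFUAI.recognition): 1,
            str(BFUAI.recognition_rc): 1,
            str(BSPQI.recognition): 1,
            str(BSPQI.recognition_rc): 1,
            usite: 1,
            str(reverse_complement(usite)): 1,
        }
        if counts == want:
            break
    else:  # pragma: no cover - motif collision 100 times in a row
        raise RuntimeError("could not build a clean vector scaffold")

    junctions = {
        FIVE_PRIME: CloningJunction(
            enzyme=BFUAI,
            left_overhang=NucSequence(pam[-1] + buffer5),
            right_overhang=reverse_complement(cargo[:4]),
        ),
        THREE_PRIME: CloningJunction(
            enzyme=BSPQI,
            left_overhang=NucSequence(cargo[-3:]),
            right_overhang=reverse_complement(buffer3),
        ),
    }
    return VectorSpec(
        name=name,
        sequence=seq,
        cargo=cargo,
        buffer5=buffer5,
        buffer3=buffer3,
        cloning_junctions=junctions,
        ugRNA_spacer=spacer,
        ugRNA_pam=pam,
        cargo_junction_phase=cargo_junction_phase,
    )


def to_seq_record(obj: AssembledDonor | LiberatedCargo):
    """Render a donor or liberated fragment as an annotated Bio.SeqRecord."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    circular = isinstance(obj, AssembledDonor) and obj.circular
    name = "".join(c if c.isalnum() or c in "-_." else "_" for c in obj.name)[:16]
    record = SeqRecord(
        Seq(str(obj.sequence)),
        id=name or "record",
        name=name or "record",
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if circular else "linear",
        },
    )
    for f in sorted(obj.features, key=lambda f: (f.start, f.label)):
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=f.strand),
                type="misc_feature",
                qualifiers={"label": [f.label]},
            )
        )
    return record


def emit_record(obj: AssembledDonor | LiberatedCargo, path) -> str:
    """Write an annotated GenBank flat file; returns the path written."""
    from Bio import SeqIO

    record = to_seq_record(obj)
    try:
        with open(path, "w") as fh:
            SeqIO.write([record], fh, "genbank")
    except OSError as exc:
        raise OSError(f"could not write GenBank record to {path}: {exc}") from exc
    return str(path)


def read_record(path) -> tuple[NucSequence, tuple[Feature, ...], str]:
    """Read back a GenBank record as (sequence, features, topology)."""
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    feats = tuple(
        Feature(
            label=f.qualifiers.get("label", ["?"])[0],
            start=int(f.location.start),
            end=int(f.location.end),
            strand=f.location.strand or 1,
        )
        for f in record.features
    )
    topology = record.annotations.get("topology", "linear")
    return NucSequence(str(record.seq)), feats, topology
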
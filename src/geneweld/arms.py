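"""Homology-arm extraction, annealing-oligo rendering, and design validation.

A homology arm is the genomic sequence directly flanking a double-strand
break: the 5' arm is ``genome[cut - L5 : cut)`` and the 3' arm is
``genome[cut : cut + L3)``, always stored on the plus strand.  Arms are
ordered as a pair of complementary oligonucleotides that anneal into a duplex
whose core is exactly the arm and whose single-stranded 5' protrusions are
the vector's cloning overhangs, ready for directional Golden Gate insertion.

Validation covers the pitfalls that break one-pot cloning or silently change
the design: internal BfuAI/BspQI recognition sites (the assembled arm would be
re-digested), a copy of the universal guide site inside the arm, and genomic
flanks that happen to match the vector scaffold just outside the arm (which
would extend the effective homology beyond the programmed length).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .enzymes import BFUAI, BSPQI, TypeIIsEnzyme
from .seqcore import (
    AmbiguousBaseError,
    CutSite,
    GenomicInterval,
    NucSequence,
    reverse_complement,
)

if TYPE_CHECKING:  # pragma: no cover
    from .donor import VectorSpec

__all__ = [
    "FIVE_PRIME",
    "THREE_PRIME",
    "ArmSpec",
    "HomologyArm",
    "OligoPair",
    "ArmValidationReport",
    "FrameCheck",
    "ArmBoundsError",
    "MissingOverhangError",
    "extract_arms",
    "make_arm_oligos",
    "validate_arm",
    "frame_check",
    "write_oligo_sheet",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
DEFAULT_ARM_LENGTHS = (12, 24, 48)


class ArmBoundsError(ValueError):
    """Requested arm extends past the contig boundary."""


class MissingOverhangError(KeyError):
    """The vector does not declare cloning overhangs for the requested side."""


@dataclass(frozen=True)
class ArmSpec:
    side: str
    length: int

    def __post_init__(self) -> None:
        if self.side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"side must be five_prime or three_prime, got {self.side!r}")
        if self.length < 1:
            raise ValueError(f"arm length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class HomologyArm:
    side: str
    sequence: NucSequence
    interval: GenomicInterval
    cut: CutSite

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError("arm sequence length disagrees with its interval")
        if self.side == FIVE_PRIME and self.interval.end != self.cut.position:
            raise ValueError("five_prime arm must end at the cut position")
        if self.side == THREE_PRIME and self.interval.start != self.cut.position:
            raise ValueError("three_prime arm must start at the cut position")


@dataclass(frozen=True)
class OligoPair:
    """Two oligos (each written 5'->3') that anneal into the arm duplex.

    ``top = left_overhang + arm`` and ``bottom = right_overhang +
    revcomp(arm)``, so the annealed duplex carries the left overhang as a
    5' protrusion on the top strand and the right overhang as a 5' protrusion
    on the bottom strand.
    """

    name: str
    top: NucSequence
    bottom: NucSequence
    arm: HomologyArm
    left_overhang: NucSequence
    right_overhang: NucSequence


@dataclass
class ArmValidationReport:
    internal_type_iis_hits: list[tuple[str, int, str]] = field(default_factory=list)
    ugRNA_match_in_arm: bool = False
    effective_homology_extension: int = 0
    frame_ok: bool | str = "not_applicable"
    warnings: list[str] = field(default_factory=list)

    @property
    def all_clear(self) -> bool:
        return (
            not self.internal_type_iis_hits
            and not self.ugRNA_match_in_arm
            and self.effective_homology_extension == 0
            and not self.warnings
        )


@dataclass(frozen=True)
class FrameCheck:
    applicable: bool
    frame_ok: bool | None
    required_phase: int | None


def extract_arms(
    genome: str | NucSequence,
    cut: CutSite,
    spec5: ArmSpec,
    spec3: ArmSpec,
) -> tuple[HomologyArm, HomologyArm]:
    """Slice the 5' and 3' homology arms flanking ``cut`` out of ``genome``.

    Concatenating the two arm sequences reproduces
    ``genome[cut - L5 : cut + L3)``.  Out-of-bounds requests and ambiguous
    bases (N) inside either slice are hard errors.
    """
    g = NucSequence(genome)
    if spec5.side != FIVE_PRIME or spec3.side != THREE_PRIME:
        raise ValueError("extract_arms expects (five_prime spec, three_prime spec)")
    pos = cut.position
    if pos - spec5.length < 0:
        raise ArmBoundsError(
            f"5' arm of {spec5.length} bp extends {spec5.length - pos} bp past "
            f"the contig start (cut at {pos})"
        )
    if pos + spec3.length > len(g):
        raise ArmBoundsError(
            f"3' arm of {spec3.length} bp extends "
            f"{pos + spec3.length - len(g)} bp past the contig end "
            f"(cut at {pos}, contig length {len(g)})"
        )
    seq5 = NucSequence(g[pos - spec5.length : pos]).require_unambiguous("5' arm")
    seq3 = NucSequence(g[pos : pos + spec3.length]).require_unambiguous("3' arm")
    arm5 = HomologyArm(
        side=FIVE_PRIME,
        sequence=seq5,
        interval=GenomicInterval(cut.contig, pos - spec5.length, pos),
        cut=cut,
    )
    arm3 = HomologyArm(
        side=THREE_PRIME,
        sequence=seq3,
        interval=GenomicInterval(cut.contig, pos, pos + spec3.length),
        cut=cut,
    )
    return arm5, arm3


def make_arm_oligos(arm: HomologyArm, vector: "VectorSpec") -> OligoPair:
    """Render an arm as its annealing-oligo pair with the vector's sticky ends.

    The vector declares, per side, the top-strand left overhang and the
    bottom-strand right overhang (both 5'->3' as synthesized).
    """
    junctions = getattr(vector, "cloning_junctions", None) or {}
    if arm.side not in junctions:
        raise MissingOverhangError(
            f"vector {getattr(vector, 'name', '?')!r} declares no cloning "
            f"overhangs for the {arm.side} arm"
        )
    jx = junctions[arm.side]
    left = NucSequence(jx.left_overhang)
    right = NucSequence(jx.right_overhang)
    if not left or not right:
        raise MissingOverhangError(
            f"empty overhang configured for the {arm.side} arm"
        )
    side_tag = "5p" if arm.side == FIVE_PRIME else "3p"
    name = f"{arm.cut.contig}_{side_tag}_{len(arm.sequence)}"
    return OligoPair(
        name=name,
        top=NucSequence(left + arm.sequence),
        bottom=NucSequence(right + reverse_complement(arm.sequence)),
        arm=arm,
        left_overhang=left,
        right_overhang=right,
    )


def _motif_hits(seq: str, enzyme: TypeIIsEnzyme) -> list[tuple[str, int, str]]:
    hits = []
    for strand, motif in (("+", str(enzyme.recognition)), ("-", str(enzyme.recognition_rc))):
        start = 0
        while (idx := seq.find(motif, start)) != -1:
            hits.append((enzyme.name, idx, strand))
            start = idx + 1
    return hits


def validate_arm(
    arm: HomologyArm,
    vector: "VectorSpec",
    genome: str | NucSequence,
    cut_phase: int | None = None,
) -> ArmValidationReport:
    """Report-only design checks for one homology arm.

    Flags (a) BfuAI/BspQI recognition sequences inside the arm on either
    strand, (b) a copy of the universal guide protospacer+PAM inside the arm,
    and (c) *effective homology extension*: consecutive vector scaffold bases
    immediately flanking the arm on its cargo-distal side (buffer, then PAM,
    then protospacer remnant, in liberated-cargo order) that happen to match
    the genome continuing beyond the programmed arm, which would lengthen the
    homology beyond the requested 12/24/48 bp.
    """
    g = NucSequence(genome)
    report = ArmValidationReport()

    for enz in (BFUAI, BSPQI):
        for hit in _motif_hits(str(arm.sequence), enz):
            report.internal_type_iis_hits.append(hit)
            report.warnings.append(
                f"{hit[0]} recognition site inside {arm.side} arm at offset "
                f"{hit[1]} ({hit[2]} strand); the cloned arm would be re-digested"
            )

    usite = str(vector.ugRNA_spacer) + str(vector.ugRNA_pam)
    if usite in arm.sequence or str(reverse_complement(usite)) in arm.sequence:
        report.ugRNA_match_in_arm = True
        report.warnings.append(
            f"universal guide site occurs inside the {arm.side} arm; "
            "liberation would also cut the arm"
        )

    # Cargo-distal vector flank, read outward from the arm boundary.  In the
    # liberated fragment the residual outside each arm is
    # (protospacer remnant)(PAM)(buffer) 5' of the 5' arm and its mirror
    # 3' of the 3' arm.
    spacer = NucSequence(vector.ugRNA_spacer)
    pam = NucSequence(vector.ugRNA_pam)
    remnant = spacer[-3:]  # 3 bases left of the protospacer after the blunt cut
    if arm.side == FIVE_PRIME:
        inward = str(remnant) + str(pam) + str(vector.buffer5)
        vector_outward = inward[::-1]
        genomic_outward = str(g[max(0, arm.interval.start - len(inward)) : arm.interval.start])[::-1]
    else:
        vector_outward = (
            str(vector.buffer3)
            + str(reverse_complement(pam))
            + str(reverse_complement(spacer))[:3]
        )
        genomic_outward = str(g[arm.interval.end : arm.interval.end + len(vector_outward)])
    ext = 0
    for vb, gb in zip(vector_outward, genomic_outward):
        if vb != gb:
            break
        ext += 1
    report.effective_homology_extension = ext
    if ext:
        report.warnings.append(
            f"genomic flank matches {ext} vector base(s) beyond the {arm.side} "
            f"arm; effective homology is {len(arm.sequence) + ext} bp"
        )

    if cut_phase is not None:
        fc = frame_check(cut_phase, vector)
        report.frame_ok = fc.frame_ok if fc.applicable else "not_applicable"
        if fc.applicable and not fc.frame_ok:
            report.warnings.append(
                f"cut phase {cut_phase} is out of frame with the cargo "
                f"(vector requires phase {fc.required_phase})"
            )
    return report


def frame_check(cut_phase: int, vector: "VectorSpec") -> FrameCheck:
    """Compare the genomic cut phase against the vector's declared cargo
    junction phase.  Promoter-driven cargos (no coding junction) are
    not applicable."""
    if cut_phase not in (0, 1, 2):
        raise ValueError(f"cut_phase must be 0, 1 or 2, got {cut_phase!r}")
    required = getattr(vector, "cargo_junction_phase", None)
    if required is None:
        return FrameCheck(applicable=False, frame_ok=None, required_phase=None)
    return FrameCheck(
        applicable=True,
        frame_ok=(cut_phase == required),
        required_phase=required,
    )


def write_oligo_sheet(path, pairs: list[OligoPair]) -> None:
    """Order sheet: one TSV row per oligo strand."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "sequence_5to3", "length", "side", "overhang"])
        for pair in pairs:
            writer.writerow(
                [f"{pair.name}_top", pair.top, len(pair.top), pair.arm.side,
                 pair.left_overhang]
            )
            writer.writerow(
                [f"{pair.name}_bottom", pair.bottom, len(pair.bottom),
                 pair.arm.side, pair.right_overhang]
            )
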
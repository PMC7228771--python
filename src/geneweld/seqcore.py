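"""Nucleotide sequence primitives, target-site location, and cut-site arithmetic.

All coordinates are 0-based, half-open, on the plus strand of the named
contig.  1-based inclusive coordinates appear only in human-facing reports
(see :mod:`geneweld.io`).  Double-strand breaks are modeled as blunt: a
:class:`CutSite` stores the plus-strand index of the first base 3' of the
break, so the left fragment is ``seq[:position]`` and the right fragment is
``seq[position:]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "NucSequence",
    "GenomicInterval",
    "GuideTarget",
    "TalenPair",
    "CutSite",
    "CodingContext",
    "InvalidSequenceError",
    "AmbiguousBaseError",
    "CutOutsideCdsError",
    "IntronicCutError",
    "OutsideGeneError",
    "reverse_complement",
    "find_guide_sites",
    "cas9_cut_site",
    "talen_cut_site",
    "coding_phase",
    "iupac_to_regex",
    "CAS9_CUT_OFFSET",
]

# SpCas9 cleaves 3 bp 5' of the PAM, between protospacer bases 17 and 18.
CAS9_CUT_OFFSET = 3

_IUPAC = "ACGTNRYSWKMBDHV"

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

# IUPAC ambiguity code -> character class for motif matching.
_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


class InvalidSequenceError(ValueError):
    """Raised when a string is not valid IUPAC DNA after normalization."""


class AmbiguousBaseError(InvalidSequenceError):
    """Raised when an operation requiring unambiguous sequence sees N (or
    another ambiguity code)."""


class NucSequence(str):
    """An uppercase IUPAC DNA string.

    Input is normalized: lowercase is upcased and U becomes T.  Any other
    non-IUPAC character is rejected.  ``NucSequence`` subclasses :class:`str`,
    so slicing and concatenation work as usual (and return plain ``str``;
    re-wrap when the invariant matters).
    """

    __slots__ = ()

    def __new__(cls, bases: str) -> "NucSequence":
        s = str(bases).upper().replace("U", "T")
        bad = set(s) - set(_IUPAC)
        if bad:
            raise InvalidSequenceError(
                f"non-IUPAC DNA character(s) {sorted(bad)!r} in sequence"
            )
        return super().__new__(cls, s)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.translate(_COMPLEMENT)[::-1])

    def require_unambiguous(self, what: str = "sequence") -> "NucSequence":
        """Raise :class:`AmbiguousBaseError` unless the sequence is pure ACGT."""
        extra = set(self) - set("ACGT")
        if extra:
            raise AmbiguousBaseError(
                f"{what} contains ambiguous base(s) {sorted(extra)!r}; "
                "an unambiguous sequence is required here"
            )
        return self


def reverse_complement(seq: str | NucSequence) -> NucSequence:
    """Watson-Crick complement, reversed.  N maps to N; ambiguity codes map to
    their complementary code (R<->Y etc.)."""
    return NucSequence(seq).reverse_complement()


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on the plus strand of *contig*."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class GuideTarget:
    """A Cas9 target: 20-nt protospacer with its PAM immediately 3' on the
    target strand.  ``protospacer_interval`` is always in plus-strand
    coordinates; ``protospacer`` and ``pam`` are given 5'->3' on the target
    strand."""

    protospacer: NucSequence
    pam: NucSequence
    protospacer_interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.protospacer) != len(self.protospacer_interval):
            raise ValueError("protospacer length disagrees with its interval")


@dataclass(frozen=True)
class TalenPair:
    """A TALEN pair: left and right binding sites separated by a spacer in
    which the FokI domains dimerize and cut."""

    left_site: GenomicInterval
    right_site: GenomicInterval
    spacer: GenomicInterval

    def __post_init__(self) -> None:
        contigs = {self.left_site.contig, self.right_site.contig, self.spacer.contig}
        if len(contigs) != 1:
            raise ValueError("TALEN half-sites and spacer must share one contig")
        if not (self.left_site.end <= self.spacer.start
                and self.spacer.end <= self.right_site.start):
            raise ValueError("TALEN layout must be left_site .. spacer .. right_site")


@dataclass(frozen=True)
class CutSite:
    """A blunt double-strand break.  ``position`` is the plus-strand index of
    the first base 3' of the break."""

    contig: str
    position: int
    source: str = "cas9"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"cut position must be >= 0, got {self.position}")
        if self.source not in ("cas9", "talen"):
            raise ValueError(f"unknown nuclease source {self.source!r}")


class CutOutsideCdsError(ValueError):
    """Base class for cut positions that do not fall in annotated CDS."""


class IntronicCutError(CutOutsideCdsError):
    """Cut lies between CDS intervals of the gene (intronic)."""


class OutsideGeneError(CutOutsideCdsError):
    """Cut lies outside the annotated gene span entirely."""


@dataclass(frozen=True)
class CodingContext:
    """Ordered CDS intervals of one coding sequence.

    ``cds_intervals`` must be listed in transcription direction: ascending
    plus-strand coordinates for a '+' CDS, descending for a '-' CDS.  A total
    CDS length that is not a multiple of 3 is allowed (partial annotation)
    but flagged via :attr:`partial`.
    """

    cds_intervals: tuple[GenomicInterval, ...]
    cds_strand: str

    def __post_init__(self) -> None:
        if self.cds_strand not in ("+", "-"):
            raise ValueError("cds_strand must be '+' or '-'")
        if not self.cds_intervals:
            raise ValueError("CodingContext requires at least one CDS interval")
        ivals = self.cds_intervals
        if len({iv.contig for iv in ivals}) != 1:
            raise ValueError("CDS intervals must share one contig")
        # non-overlap + transcription-direction ordering
        for a, b in zip(ivals, ivals[1:]):
            if self.cds_strand == "+" and a.end > b.start:
                raise ValueError("CDS intervals must be ordered 5'->3' (+ strand)")
            if self.cds_strand == "-" and b.end > a.start:
                raise ValueError("CDS intervals must be ordered 5'->3' (- strand)")

    @property
    def partial(self) -> bool:
        return sum(len(iv) for iv in self.cds_intervals) % 3 != 0

    @property
    def span(self) -> GenomicInterval:
        starts = [iv.start for iv in self.cds_intervals]
        ends = [iv.end for iv in self.cds_intervals]
        return GenomicInterval(self.cds_intervals[0].contig, min(starts), max(ends))


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC motif (e.g. ``NGG``) into a regex character-class
    pattern."""
    pat = NucSequence(pattern)
    return "".join(_IUPAC_CLASS[b] for b in pat)


def _overlapping_matches(haystack: str, regex: str) -> Iterable[int]:
    """Start positions of all (possibly overlapping) matches."""
    for m in re.finditer(f"(?=({regex}))", haystack):
        yield m.start()


def find_guide_sites(
    genome: str | NucSequence,
    protospacer: str | NucSequence,
    pam_pattern: str = "NGG",
    contig: str = "genome",
) -> list[GuideTarget]:
    """Locate every exact occurrence of ``protospacer`` followed by a PAM
    matching ``pam_pattern``, on both strands.

    Returns :class:`GuideTarget` records with plus-strand protospacer
    intervals.  The protospacer must be unambiguous (N is rejected); the PAM
    pattern may use any IUPAC code.  Zero hits yield an empty list.
    """
    g = NucSequence(genome)
    proto = NucSequence(protospacer).require_unambiguous("protospacer")
    pam_len = len(pam_pattern)
    plen = len(proto)
    hits: list[GuideTarget] = []

    fwd = re.escape(str(proto)) + iupac_to_regex(pam_pattern)
    for start in _overlapping_matches(g, fwd):
        hits.append(
            GuideTarget(
                protospacer=proto,
                pam=NucSequence(g[start + plen : start + plen + pam_len]),
                protospacer_interval=GenomicInterval(contig, start, start + plen),
                strand="+",
            )
        )

    # Minus strand: the site's plus-strand footprint is
    # revcomp(pam_pattern) + revcomp(protospacer).
    rev = iupac_to_regex(reverse_complement(pam_pattern)) + re.escape(
        str(proto.reverse_complement())
    )
    for start in _overlapping_matches(g, rev):
        ps, pe = start + pam_len, start + pam_len + plen
        hits.append(
            GuideTarget(
                protospacer=proto,
                pam=reverse_complement(g[start : start + pam_len]),
                protospacer_interval=GenomicInterval(contig, ps, pe),
                strand="-",
            )
        )
    hits.sort(key=lambda t: (t.protospacer_interval.start, t.strand))
    return hits


def cas9_cut_site(target: GuideTarget) -> CutSite:
    """Blunt Cas9 cut 3 bp 5' of the PAM on the target strand, i.e. between
    protospacer bases 17 and 18, reported in plus-strand convention."""
    iv = target.protospacer_interval
    if target.strand == "+":
        position = iv.end - CAS9_CUT_OFFSET
    else:
        position = iv.start + CAS9_CUT_OFFSET
    return CutSite(contig=iv.contig, position=position, source="cas9")


def talen_cut_site(pair: TalenPair, offset: int = 0) -> CutSite:
    """Blunt cut at the floor of the TALEN spacer midpoint, plus a signed
    ``offset`` in bp (positive = rightward on the plus strand)."""
    spacer = pair.spacer
    if len(spacer) == 0:
        raise ValueError("TALEN spacer has zero length; no cut position defined")
    midpoint = (spacer.start + spacer.end) // 2
    return CutSite(contig=spacer.contig, position=midpoint + offset, source="talen")


def coding_phase(cut: CutSite, ctx: CodingContext) -> int:
    """Reading-frame phase of a cut inside a CDS.

    Counts coding bases, in transcription direction, from the CDS start to the
    break, modulo 3.  A cut at the very first coding base is phase 0.  Raises
    :class:`IntronicCutError` or :class:`OutsideGeneError` when the break does
    not fall in coding sequence.
    """
    pos = cut.position
    preceding = 0
    for iv in ctx.cds_intervals:
        if ctx.cds_strand == "+":
            if iv.start <= pos < iv.end:
                return (preceding + (pos - iv.start)) % 3
        else:
            if iv.start < pos <= iv.end:
                return (preceding + (iv.end - pos)) % 3
        preceding += len(iv)
    span = ctx.span
    if span.start <= pos <= span.end:
        raise IntronicCutError(
            f"cut at {cut.contig}:{pos} falls between CDS intervals (intronic)"
        )
    raise OutsideGeneError(
        f"cut at {cut.contig}:{pos} lies outside the annotated gene span "
        f"[{span.start}, {span.end})"
    )
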
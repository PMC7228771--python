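"""Type IIS restriction enzyme geometry.

A Type IIS enzyme cuts at a fixed distance downstream of its (asymmetric)
recognition sequence, leaving a 5' overhang whose sequence is user-defined by
context -- the basis of Golden Gate cloning.  Geometry is written the standard
way, e.g. BfuAI = ACCTGC(4/8): top-strand cut 4 nt past the 3' end of the
recognition site, bottom-strand cut 8 nt past, leaving a 4-nt 5' overhang.

The shipped constants are the standard REBASE definitions for the two
cloning enzymes used by pGTag-style donors; both are editable data, not
hard-wired behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import NucSequence

__all__ = ["TypeIIsEnzyme", "BFUAI", "BSPQI", "CLONING_ENZYMES"]


@dataclass(frozen=True)
class TypeIIsEnzyme:
    name: str
    recognition: NucSequence
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if self.overhang_length == 0:
            raise ValueError(
                f"{self.name}: top and bottom cut offsets are equal (blunt); "
                "a Type IIS cloning enzyme must leave an overhang"
            )

    @property
    def overhang_length(self) -> int:
        """Positive for 5' overhangs (the only kind modeled here)."""
        return self.cut_offset_bottom - self.cut_offset_top

    @property
    def recognition_rc(self) -> NucSequence:
        return NucSequence(self.recognition).reverse_complement()


BFUAI = TypeIIsEnzyme("BfuAI", NucSequence("ACCTGC"), 4, 8)
BSPQI = TypeIIsEnzyme("BspQI", NucSequence("GCTCTTC"), 1, 4)

CLONING_ENZYMES = {"BfuAI": BFUAI, "BspQI": BSPQI}
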
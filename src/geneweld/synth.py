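"""Seeded random DNA with motif exclusion.

Used wherever the package fabricates sequence -- synthetic vector backbones,
stuffer fragments, and simulated genomes.  Excluding a motif set keeps
fabricated scaffolds free of cloning-enzyme recognition sites and of the
universal guide site, which real donor backbones are engineered to avoid as
well.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .seqcore import NucSequence, reverse_complement

__all__ = ["random_dna", "both_strand_motifs"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def both_strand_motifs(motifs: Iterable[str]) -> tuple[str, ...]:
    """Expand a motif list with reverse complements, deduplicated."""
    out: list[str] = []
    for m in motifs:
        for s in (str(NucSequence(m)), str(reverse_complement(m))):
            if s not in out:
                out.append(s)
    return tuple(out)


def random_dna(
    rng: np.random.Generator,
    length: int,
    forbid: Sequence[str] = (),
    max_rounds: int = 1000,
) -> NucSequence:
    """Uniform random ACGT sequence of ``length`` containing none of the
    ``forbid`` motifs (checked as given; pass both strands explicitly via
    :func:`both_strand_motifs` if needed).

    Offending windows are redrawn in place until the sequence is clean, so
    the result is only negligibly non-uniform for short motif lists.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    chars = _BASES[rng.integers(0, 4, size=length)]
    seq = bytearray(chars.tobytes())
    motifs = [m.encode() for m in forbid if m]
    for _ in range(max_rounds):
        dirty = False
        for m in motifs:
            idx = bytes(seq).find(m)
            while idx != -1:
                dirty = True
                repl = _BASES[rng.integers(0, 4, size=len(m))].tobytes()
                seq[idx : idx + len(m)] = repl
                idx = bytes(seq).find(m, idx)
        if not dirty:
            return NucSequence(seq.decode())
    raise RuntimeError("could not generate motif-free sequence; motif set too dense")
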
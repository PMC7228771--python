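"""Targeting plans, expected integrated alleles, and junction precision calls.

A targeting plan pairs a donor vector with one genomic cut site (single-site
knock-in) or two (deletion tagging, where the 5' arm flanks the upstream cut
and the 3' arm flanks the downstream cut so the intervening genomic DNA is
excised and replaced by the cargo).  From a plan the expected precisely
integrated allele is a pure splice: genome up to the (upstream) cut, then the
cargo payload, then genome from the (downstream) cut -- homology arms
coincide with the genome, so precise junctions are seamless.

An observed junction read is called *precise* when the homology arm carries
no mismatch and there is no insertion or deletion anywhere in the scored
window around the programmed junction; otherwise it is *imprecise*, with the
responsible events reported.  Mismatches outside the arm do not break
precision (the rule constrains mismatches only within the arm) and are
surfaced as warnings.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .arms import (
    FIVE_PRIME,
    THREE_PRIME,
    ArmSpec,
    HomologyArm,
    extract_arms,
    make_arm_oligos,
)
from .donor import (
    AssembledDonor,
    LiberatedCargo,
    VectorSpec,
    assemble_donor,
    build_vector,
    liberate_cargo,
)
from .enzymes import BFUAI, BSPQI
from .seqcore import (
    CutSite,
    GuideTarget,
    NucSequence,
    cas9_cut_site,
    find_guide_sites,
    reverse_complement,
)
from .synth import both_strand_motifs, random_dna

logger = logging.getLogger(__name__)

__all__ = [
    "SINGLE_SITE",
    "DELETION_TAG",
    "TargetingPlan",
    "ExpectedAllele",
    "JunctionReference",
    "JunctionEvent",
    "JunctionCall",
    "ClassifyParams",
    "PrecisionSummary",
    "Fixture",
    "SimRead",
    "build_expected_allele",
    "expected_junction",
    "classify_junction",
    "dominant_event",
    "summarize_precision",
    "simulate_fixture",
    "single_site_plan",
    "deletion_plan",
]

SINGLE_SITE = "single_site"
DELETION_TAG = "deletion_tag"


@dataclass(frozen=True)
class TargetingPlan:
    mode: str
    genome: NucSequence
    cut_a: CutSite
    arm5: HomologyArm
    arm3: HomologyArm
    vector: VectorSpec
    cut_b: CutSite | None = None

    def __post_init__(self) -> None:
        if self.mode not in (SINGLE_SITE, DELETION_TAG):
            raise ValueError(f"unknown targeting mode {self.mode!r}")
        if self.arm5.side != FIVE_PRIME or self.arm3.side != THREE_PRIME:
            raise ValueError("plan arms must be (five_prime, three_prime)")
        if self.mode == SINGLE_SITE:
            if self.cut_b is not None:
                raise ValueError("single_site plans take exactly one cut site")
            if (self.arm5.cut.position != self.cut_a.position
                    or self.arm3.cut.position != self.cut_a.position):
                raise ValueError("single_site arms must both flank cut_a")
        else:
            if self.cut_b is None:
                raise ValueError("deletion_tag plans require cut_b")
            if self.cut_b.contig != self.cut_a.contig:
                raise ValueError("deletion_tag cuts must share a contig")
            if self.cut_b.position <= self.cut_a.position:
                raise ValueError(
                    "deletion_tag requires cut_a upstream of cut_b "
                    f"(got {self.cut_a.position} >= {self.cut_b.position})"
                )
            if self.arm5.cut.position != self.cut_a.position:
                raise ValueError("deletion_tag 5' arm must flank the upstream cut")
            if self.arm3.cut.position != self.cut_b.position:
                raise ValueError("deletion_tag 3' arm must flank the downstream cut")

    @property
    def downstream_cut(self) -> CutSite:
        return self.cut_b if self.mode == DELETION_TAG else self.cut_a


@dataclass(frozen=True)
class ExpectedAllele:
    """The precisely integrated locus predicted from a plan."""

    sequence: NucSequence
    payload_interval: tuple[int, int]
    junction5_pos: int
    junction3_pos: int
    deleted_span: int
    arm5_len: int
    arm3_len: int
    contig: str


@dataclass(frozen=True)
class JunctionReference:
    """Amplicon-style reference window around one programmed junction."""

    side: str
    sequence: NucSequence
    arm_interval: tuple[int, int]
    junction_offset: int
    window: int


@dataclass(frozen=True)
class JunctionEvent:
    kind: str  # mismatch_in_arm | insertion | deletion | arm_duplication | unalignable
    ref_pos: int
    length: int
    detail: str = ""


@dataclass(frozen=True)
class JunctionCall:
    verdict: str  # precise | imprecise
    events: tuple[JunctionEvent, ...]
    side: str
    orientation: str = "+"
    identity: float = 1.0
    warnings: tuple[str, ...] = ()

    @property
    def precise(self) -> bool:
        return self.verdict == "precise"


@dataclass(frozen=True)
class ClassifyParams:
    """Alignment and calling parameters.

    The scoring scheme (match +1, mismatch -1, gap open -2, gap extend -1,
    first-reported-alignment tie break) operationalizes a rule originally
    applied by eye to Sanger traces; all values are overridable.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_overlap: int = 30
    identity_floor: float = 0.6
    duplication_fraction: float = 0.8


def build_expected_allele(plan: TargetingPlan, payload: str | NucSequence) -> ExpectedAllele:
    """Splice the payload into the genome at the plan's cut(s).

    single_site: ``genome[:cut_a) + payload + genome[cut_a:)``.
    deletion_tag: ``genome[:cut_a) + payload + genome[cut_b:)``; the span
    between the cuts is excised.
    """
    payload = NucSequence(payload)
    g = plan.genome
    a = plan.cut_a.position
    b = plan.downstream_cut.position
    seq = NucSequence(g[:a] + payload + g[b:])
    deleted = b - a
    allele = ExpectedAllele(
        sequence=seq,
        payload_interval=(a, a + len(payload)),
        junction5_pos=a,
        junction3_pos=a + len(payload),
        deleted_span=deleted,
        arm5_len=len(plan.arm5.sequence),
        arm3_len=len(plan.arm3.sequence),
        contig=plan.cut_a.contig,
    )
    assert len(seq) == len(g) - deleted + len(payload)
    return allele


def expected_junction(
    allele: ExpectedAllele, side: str, window: int = 40
) -> JunctionReference:
    """Symmetric reference window around the 5' or 3' junction, annotated
    with the arm sub-interval (the genomic homology within the window)."""
    if side == FIVE_PRIME:
        j, arm_len = allele.junction5_pos, allele.arm5_len
    elif side == THREE_PRIME:
        j, arm_len = allele.junction3_pos, allele.arm3_len
    else:
        raise ValueError(f"side must be five_prime or three_prime, got {side!r}")
    start, end = j - window, j + window
    if start < 0 or end > len(allele.sequence):
        logger.warning(
            "junction window [%d, %d) clipped to allele bounds [0, %d)",
            start, end, len(allele.sequence),
        )
        start, end = max(start, 0), min(end, len(allele.sequence))
    if side == FIVE_PRIME:
        arm_iv = (max(j - arm_len, start) - start, j - start)
    else:
        arm_iv = (j - start, min(j + arm_len, end) - start)
    return JunctionReference(
        side=side,
        sequence=NucSequence(allele.sequence[start:end]),
        arm_interval=arm_iv,
        junction_offset=j - start,
        window=window,
    )


def _make_aligner(params: ClassifyParams):
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _walk_alignment(alignment, ref: str, obs: str):
    """Yield (mismatches, insertions, deletions) from an alignment's aligned
    blocks, with positions on the reference."""
    mismatches: list[tuple[int, str, str]] = []
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    ref_blocks, obs_blocks = alignment.aligned
    prev_r = prev_q = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, obs_blocks):
        if rs > prev_r:
            deletions.append((prev_r, rs - prev_r))
        if qs > prev_q:
            insertions.append((rs, obs[prev_q:qs]))
        for k in range(re_ - rs):
            if ref[rs + k] != obs[qs + k]:
                mismatches.append((rs + k, ref[rs + k], obs[qs + k]))
        prev_r, prev_q = re_, qe
    if prev_r < len(ref):
        deletions.append((prev_r, len(ref) - prev_r))
    if prev_q < len(obs):
        insertions.append((len(ref), obs[prev_q:]))
    return mismatches, insertions, deletions


def classify_junction(
    observed: str | NucSequence,
    reference: JunctionReference,
    params: ClassifyParams | None = None,
) -> JunctionCall:
    """Call an observed junction read precise or imprecise.

    The read is oriented (forward vs. reverse complement, better global
    alignment wins), globally aligned to the reference window, and judged by
    the rule: precise iff the homology arm contains no mismatch and no
    insertion or deletion occurs anywhere in the window.  An insertion of at
    least ``duplication_fraction`` of the arm, tandem-adjacent to the
    programmed arm copy, is reported as ``arm_duplication``.  Reads aligning
    below ``identity_floor`` are imprecise with a single ``unalignable``
    event.
    """
    params = params or ClassifyParams()
    obs_fwd = str(NucSequence(observed))
    if len(obs_fwd) < params.min_overlap:
        raise ValueError(
            f"read of {len(obs_fwd)} nt is below the minimum overlap "
            f"({params.min_overlap} nt)"
        )
    ref = str(reference.sequence)
    aligner = _make_aligner(params)
    obs_rc = str(reverse_complement(obs_fwd))
    score_fwd = aligner.score(ref, obs_fwd)
    score_rc = aligner.score(ref, obs_rc)
    if score_rc > score_fwd:
        obs, orientation = obs_rc, "-"
    else:
        obs, orientation = obs_fwd, "+"
    alignment = aligner.align(ref, obs)[0]

    mismatches, insertions, deletions = _walk_alignment(alignment, ref, obs)
    n_match = sum(
        1
        for (rs, re_), (qs, _) in zip(*alignment.aligned)
        for k in range(re_ - rs)
        if ref[rs + k] == obs[qs + k]
    )
    identity = n_match / alignment.length  # matches per alignment column
    if identity < params.identity_floor:
        return JunctionCall(
            verdict="imprecise",
            events=(JunctionEvent("unalignable", 0, len(obs)),),
            side=reference.side,
            orientation=orientation,
            identity=identity,
        )

    arm_s, arm_e = reference.arm_interval
    arm_seq = ref[arm_s:arm_e]
    arm_len = arm_e - arm_s
    dup_min = math.ceil(params.duplication_fraction * arm_len) if arm_len else 0

    events: list[JunctionEvent] = []
    warnings: list[str] = []
    for pos, rbase, obase in mismatches:
        if arm_s <= pos < arm_e:
            events.append(
                JunctionEvent("mismatch_in_arm", pos, 1, f"{rbase}>{obase}")
            )
        else:
            warnings.append(
                f"mismatch {rbase}>{obase} at window position {pos}, outside "
                "the homology arm (does not break precision)"
            )
    for pos, inserted in insertions:
        kind = "insertion"
        if (
            arm_len
            and len(inserted) >= dup_min
            and inserted in (arm_seq + arm_seq)
            and arm_s - 1 <= pos <= arm_e + 1
        ):
            kind = "arm_duplication"
        events.append(JunctionEvent(kind, pos, len(inserted), inserted))
    for pos, length in deletions:
        events.append(JunctionEvent("deletion", pos, length))

    verdict = "precise" if not events else "imprecise"
    return JunctionCall(
        verdict=verdict,
        events=tuple(events),
        side=reference.side,
        orientation=orientation,
        identity=identity,
        warnings=tuple(warnings),
    )


def dominant_event(call: JunctionCall) -> str:
    """Single-label view of a call, for tallies against simulated truth."""
    if call.precise:
        return "precise"
    kinds = [e.kind for e in call.events]
    for kind in ("unalignable", "arm_duplication", "insertion", "deletion",
                 "mismatch_in_arm"):
        if kind in kinds:
            return "mismatch" if kind == "mismatch_in_arm" else kind
    return "imprecise"


@dataclass(frozen=True)
class PrecisionSummary:
    per_side: dict[str, tuple[int, int]]

    def fraction(self, side: str) -> float:
        precise, total = self.per_side[side]
        return precise / total

    def display(self, side: str) -> str:
        precise, total = self.per_side[side]
        return f"{precise}/{total}"

    def as_dict(self) -> dict:
        return {
            side: {
                "precise": p,
                "total": t,
                "fraction": p / t,
                "display": f"{p}/{t}",
            }
            for side, (p, t) in sorted(self.per_side.items())
        }


def summarize_precision(calls: Sequence[JunctionCall]) -> PrecisionSummary:
    """Per-side precise/total tallies in the field's "n/m" display form."""
    if not calls:
        raise ValueError("summarize_precision requires at least one call")
    per_side: dict[str, list[int]] = {}
    for call in calls:
        tally = per_side.setdefault(call.side, [0, 0])
        tally[0] += call.precise
        tally[1] += 1
    return PrecisionSummary(
        per_side={side: (p, t) for side, (p, t) in per_side.items()}
    )


# ---------------------------------------------------------------------------
# Plan builders


def single_site_plan(
    genome: str | NucSequence,
    cut: CutSite,
    vector: VectorSpec,
    arm5_len: int = 24,
    arm3_len: int = 24,
) -> TargetingPlan:
    g = NucSequence(genome)
    arm5, arm3 = extract_arms(
        g, cut, ArmSpec(FIVE_PRIME, arm5_len), ArmSpec(THREE_PRIME, arm3_len)
    )
    return TargetingPlan(
        mode=SINGLE_SITE, genome=g, cut_a=cut, arm5=arm5, arm3=arm3, vector=vector
    )


def deletion_plan(
    genome: str | NucSequence,
    cut_a: CutSite,
    cut_b: CutSite,
    vector: VectorSpec,
    arm5_len: int = 48,
    arm3_len: int = 48,
) -> TargetingPlan:
    """Deletion tagging: 5' arm flanks the upstream cut, 3' arm flanks the
    downstream cut, so integration excises the intervening span."""
    g = NucSequence(genome)
    arm5, _ = extract_arms(
        g, cut_a, ArmSpec(FIVE_PRIME, arm5_len), ArmSpec(THREE_PRIME, 1)
    )
    _, arm3 = extract_arms(
        g, cut_b, ArmSpec(FIVE_PRIME, 1), ArmSpec(THREE_PRIME, arm3_len)
    )
    return TargetingPlan(
        mode=DELETION_TAG,
        genome=g,
        cut_a=cut_a,
        cut_b=cut_b,
        arm5=arm5,
        arm3=arm3,
        vector=vector,
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures


@dataclass(frozen=True)
class SimRead:
    name: str
    sequence: NucSequence
    truth_kind: str
    orientation: str


@dataclass(frozen=True)
class Fixture:
    """A complete, reproducible synthetic test case: genome with one planted
    guide site, a designed plan, the assembled/liberated donor model, and
    junction reads drawn from a labeled event mix."""

    seed: int
    genome: NucSequence
    guide: GuideTarget
    cut: CutSite
    vector: VectorSpec
    plan: TargetingPlan
    donor: AssembledDonor
    liberated: LiberatedCargo
    allele: ExpectedAllele
    reference5: JunctionReference
    reads: tuple[SimRead, ...]
    event_mix: dict[str, float]
    per_base_error: float

    def manifest(self) -> dict:
        """Deterministic, JSON-serializable digest of the fixture."""
        return {
            "seed": self.seed,
            "genome": str(self.genome),
            "protospacer": str(self.guide.protospacer),
            "cut_position": self.cut.position,
            "vector_sequence": str(self.vector.sequence),
            "donor_sequence": str(self.donor.sequence),
            "liberated_sequence": str(self.liberated.sequence),
            "allele_sequence": str(self.allele.sequence),
            "reference5": str(self.reference5.sequence),
            "event_mix": {k: float(v) for k, v in self.event_mix.items()},
            "per_base_error": self.per_base_error,
            "reads": [
                {
                    "name": r.name,
                    "sequence": str(r.sequence),
                    "truth": r.truth_kind,
                    "orientation": r.orientation,
                }
                for r in self.reads
            ],
        }


DEFAULT_EVENT_MIX = {"precise": 0.95, "arm_duplication": 0.05}

_FORBIDDEN = both_strand_motifs(
    [str(BFUAI.recognition), str(BSPQI.recognition),
     "GGGAGGCGTTCGGGCCACAGCGG"]
)


def _mutate_read(
    rng: np.random.Generator,
    ref: JunctionReference,
    kind: str,
) -> str:
    seq = str(ref.sequence)
    j = ref.junction_offset
    arm_s, arm_e = ref.arm_interval
    bases = "ACGT"
    if kind == "precise":
        return seq
    if kind == "insertion":
        # single-base insertion at the arm/cargo boundary, the classic
        # NHEJ-derived imprecise allele
        ins = bases[rng.integers(0, 4)]
        return seq[:j] + ins + seq[j:]
    if kind == "deletion":
        k = int(rng.integers(1, 6))
        return seq[:j] + seq[j + k :]
    if kind == "mismatch":
        pos = int(rng.integers(arm_s, arm_e))
        old = seq[pos]
        new = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
        return seq[:pos] + new + seq[pos + 1 :]
    if kind == "arm_duplication":
        arm = seq[arm_s:arm_e]
        if ref.side == FIVE_PRIME:
            return seq[:arm_e] + arm + seq[arm_e:]
        return seq[:arm_s] + arm + seq[arm_s:]
    raise ValueError(f"unknown event kind {kind!r}")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    bases = "ACGT"
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = bases[(bases.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def simulate_fixture(
    seed: int,
    genome_len: int = 10_000,
    cargo_len: int = 1_500,
    arm_len: int = 24,
    n_reads: int = 20,
    event_mix: dict[str, float] | None = None,
    per_base_error: float = 0.0,
    window: int = 40,
    contig: str = "sim_locus",
) -> Fixture:
    """Build a reproducible synthetic targeting experiment.

    One guide site is planted at the genome midpoint; arms, oligos, donor,
    liberated cargo, expected allele, and 5'-junction reads with truth labels
    follow from it.  All randomness derives from ``seed``.  Defaults emulate
    the short-arm study conditions: a 24-bp arm, a ~1.5-kb reporter cargo,
    and an event mix dominated by precise junctions with occasional
    homology-domain duplication.
    """
    event_mix = dict(event_mix) if event_mix else dict(DEFAULT_EVENT_MIX)
    total = sum(event_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"event_mix must sum to 1, got {total}")
    rng = np.random.default_rng(seed)

    g0 = genome_len // 2
    cut_pos = g0 + 17
    if arm_len > cut_pos or cut_pos + arm_len > genome_len:
        raise ValueError(
            f"arm_len {arm_len} does not fit around a cut at {cut_pos} in a "
            f"{genome_len}-bp genome"
        )
    if g0 + 23 > genome_len:
        raise ValueError("genome too short to plant a guide site at its midpoint")

    genome = None
    for _ in range(50):
        backdrop = str(random_dna(rng, genome_len, _FORBIDDEN))
        proto = str(random_dna(rng, 20, _FORBIDDEN))
        candidate = backdrop[:g0] + proto + "AGG" + backdrop[g0 + 23 :]
        if candidate.count(proto) == 1 and str(
            reverse_complement(proto)
        ) not in candidate and not any(m in candidate for m in _FORBIDDEN):
            genome = NucSequence(candidate)
            break
    if genome is None:  # pragma: no cover
        raise RuntimeError("could not plant a unique guide site")

    hits = find_guide_sites(genome, proto, "NGG", contig)
    (hit,) = [h for h in hits if h.protospacer_interval.start == g0]
    cut = cas9_cut_site(hit)
    assert cut.position == cut_pos

    cargo = random_dna(rng, cargo_len, _FORBIDDEN)
    vector = build_vector(cargo, name="sim-donor", rng=rng)
    plan = single_site_plan(genome, cut, vector, arm_len, arm_len)
    oligos5 = make_arm_oligos(plan.arm5, vector)
    oligos3 = make_arm_oligos(plan.arm3, vector)
    donor = assemble_donor(vector, oligos5, oligos3)
    liberated = liberate_cargo(donor)
    allele = build_expected_allele(plan, vector.cargo)
    ref5 = expected_junction(allele, FIVE_PRIME, window)

    kinds = list(event_mix)
    probs = np.array([event_mix[k] for k in kinds], dtype=float)
    reads: list[SimRead] = []
    for i in range(n_reads):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        seq = _mutate_read(rng, ref5, kind)
        seq = _apply_errors(rng, seq, per_base_error)
        if rng.random() < 0.5:
            reads.append(
                SimRead(f"read_{i:04d}", reverse_complement(seq), kind, "-")
            )
        else:
            reads.append(SimRead(f"read_{i:04d}", NucSequence(seq), kind, "+"))

    return Fixture(
        seed=seed,
        genome=genome,
        guide=hit,
        cut=cut,
        vector=vector,
        plan=plan,
        donor=donor,
        liberated=liberated,
        allele=allele,
        reference5=ref5,
        reads=tuple(reads),
        event_mix=event_mix,
        per_base_error=per_base_error,
    )
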
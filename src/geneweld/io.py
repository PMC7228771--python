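"""File-format adapters and report writers.

Everything user-facing lives here: FASTA and GFF3 input, GenBank output
(delegated to :mod:`geneweld.donor`), TSV/JSON reports, the bundled vector
registry, and the 0-based/1-based coordinate conversion applied at I/O
boundaries (internally everything is 0-based half-open).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .donor import VectorSpec, build_vector
from .junctions import JunctionCall, JunctionReference, PrecisionSummary
from .seqcore import CodingContext, GenomicInterval, NucSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3_cds",
    "to_one_based",
    "from_one_based",
    "load_vector_spec",
    "registry_names",
    "write_calls_tsv",
    "write_reference_json",
    "read_reference_json",
    "write_provenance",
]


def read_fasta(path) -> dict[str, NucSequence]:
    """Multi-record FASTA -> {id: sequence}."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = NucSequence(str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records: Mapping[str, str], width: int = 70) -> str:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            s = str(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
    return str(path)


def read_gff3_cds(path, transcript_id: str | None = None) -> CodingContext:
    """Build a :class:`CodingContext` from the CDS features of a GFF3 file.

    When the file annotates several parents, ``transcript_id`` selects one
    (matched against the CDS Parent attribute); otherwise all CDS features
    must belong to a single parent.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="merge",
    )
    by_parent: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [feat.id or "?"])
        for parent in parents:
            by_parent.setdefault(parent, []).append(feat)
    if not by_parent:
        raise ValueError(f"no CDS features in {path}")
    if transcript_id is None:
        if len(by_parent) > 1:
            raise ValueError(
                f"multiple CDS parents in {path}: {sorted(by_parent)}; "
                "pass transcript_id"
            )
        (feats,) = by_parent.values()
    else:
        if transcript_id not in by_parent:
            raise ValueError(f"no CDS features with Parent={transcript_id!r}")
        feats = by_parent[transcript_id]
    strand = feats[0].strand
    if strand not in ("+", "-"):
        raise ValueError("CDS features must be stranded")
    feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
    intervals = tuple(
        GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in feats
    )
    return CodingContext(cds_intervals=intervals, cds_strand=strand)


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (human-facing reports)."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if first < 1 or last < first - 1:
        raise ValueError(f"invalid 1-based inclusive range {first}..{last}")
    return first - 1, last


# ---------------------------------------------------------------------------
# Vector registry

def registry_names() -> list[str]:
    """Names of the bundled vector-spec files."""
    pkg = resources.files("geneweld") / "vectors"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_vector_spec(name_or_path: str | Path) -> VectorSpec:
    """Load a vector spec from the bundled registry (by name) or from a YAML
    file path.

    The YAML declares the cargo sequence, buffers, cargo junction phase and a
    scaffold seed; the full circular vector is reconstructed deterministically
    around it.
    """
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        pkg = resources.files("geneweld") / "vectors" / f"{name_or_path}.yaml"
        try:
            text = pkg.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no vector spec {name_or_path!r}; bundled specs: "
                f"{', '.join(registry_names())}"
            ) from None
    data = yaml.safe_load(text)
    phase = data.get("cargo_junction_phase", 0)
    return build_vector(
        cargo=NucSequence("".join(str(data["cargo"]).split())),
        name=data["name"],
        buffer5=data.get("buffer5", "AAA"),
        buffer3=data.get("buffer3", "AAA"),
        cargo_junction_phase=None if phase in (None, "none") else int(phase),
        backbone_length=int(data.get("backbone_length", 400)),
        rng=np.random.default_rng(int(data.get("scaffold_seed", 0))),
    )


# ---------------------------------------------------------------------------
# Reports

def write_calls_tsv(path, names: Iterable[str], calls: Iterable[JunctionCall]) -> str:
    """One row per read: verdict, events, identity, orientation.

    Event positions are reported 1-based."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["read", "side", "verdict", "orientation", "identity", "events",
             "warnings"]
        )
        for name, call in zip(names, calls):
            events = ";".join(
                f"{e.kind}@{e.ref_pos + 1}(len={e.length})" for e in call.events
            )
            writer.writerow(
                [name, call.side, call.verdict, call.orientation,
                 f"{call.identity:.4f}", events or ".",
                 " | ".join(call.warnings) or "."]
            )
    return str(path)


def write_reference_json(path, reference: JunctionReference) -> str:
    payload = {
        "side": reference.side,
        "sequence": str(reference.sequence),
        "arm_interval": list(reference.arm_interval),
        "junction_offset": reference.junction_offset,
        "window": reference.window,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return str(path)


def read_reference_json(path) -> JunctionReference:
    data = json.loads(Path(path).read_text())
    return JunctionReference(
        side=data["side"],
        sequence=NucSequence(data["sequence"]),
        arm_interval=tuple(data["arm_interval"]),
        junction_offset=data["junction_offset"],
        window=data["window"],
    )


def write_provenance(path, subcommand: str, inputs: Mapping, params: Mapping,
                     seed: int | None = None) -> str:
    """Machine-readable run record: enough to rerun the command and
    reproduce every output byte-identically."""
    from . import __version__

    record = {
        "tool": "geneweld",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": dict(params),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return str(path)
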
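# geneweld

A design toolkit for **short-homology knock-in** experiments: targeted
integration of reporter cassettes at CRISPR/Cas9 (or TALEN) cut sites via
homology-mediated end joining (HMEJ), in the style of the pGTag /
universal-guide donor architecture used for gene tagging in zebrafish and
mammalian cells.

It is written for researchers designing knock-in constructs: you provide a
genome sequence and a guide, and the toolkit designs the homology-arm oligos,
simulates the Golden Gate cloning and the in-vivo cargo liberation, predicts
the precisely integrated allele, and classifies sequenced junction reads as
precise or imprecise.

## The method in brief

- **Cut-site arithmetic.** SpCas9 makes a blunt double-strand break 3 bp 5′
  of the PAM, between protospacer bases 17 and 18. All coordinates are
  0-based half-open on the plus strand internally; reports are 1-based.
- **Homology arms.** The 5′ arm is `genome[cut − L₅ .. cut)` and the 3′ arm
  `genome[cut .. cut + L₃)` — typically L = 12, 24 or 48 bp, directly
  flanking the break. Arms are ordered as two complementary oligos whose
  annealed duplex carries Type IIS sticky ends (BfuAI `ACCTGC(4/8)` for the
  5′ arm, BspQI `GCTCTTC(1/4)` for the 3′ arm) for one-pot directional
  Golden Gate cloning; a correct assembly retains no intact recognition
  site of either enzyme.
- **Universal guide (UgRNA).** The donor carries the engineered spacer
  `GGGAGGCGTTCGGGCCACAG` with a `CGG` PAM on each side of the cargo, PAM
  facing inward. Cas9 cuts both sites in vivo, liberating the cargo and
  exposing both homology arms. A 3-nt buffer (`aaa`) without genomic
  homology sits between each UgRNA PAM and the arm so that the effective
  homology stays exactly at the programmed length.
- **Deletion tagging.** With two genomic cuts, a donor whose 5′ arm flanks
  the upstream site and whose 3′ arm flanks the downstream site excises the
  intervening span and bridges it with the cargo.
- **Junction calls.** A read spanning a genome–cargo junction is *precise*
  iff the homology arm contains no mismatch and there is no insertion or
  deletion anywhere in the scored window; homology-domain duplications and
  single-base junction insertions are reported as their own event classes.
  Tallies use the field's `n/m` display (e.g. `19/20`).

## Worked example

Everything below runs on a self-contained synthetic fixture — no downloads.

```sh
# 1. make a seeded synthetic experiment: genome with one planted guide site,
#    donor, and 20 junction reads with known truth labels
geneweld simulate --seed 42 --genome-len 6000 --cargo-len 600 --n-reads 20 \
    --event-mix '{"precise":0.8,"insertion":0.1,"arm_duplication":0.1}' --out sim

# 2. design homology-arm oligos for that guide (24/24 bp arms)
geneweld design --genome sim/genome.fasta --protospacer CTCGGCTGTTAAGCCACCCG \
    --vector pGTag-2A-eGFP-SV40 --arm5 24 --arm3 24 --out design
head -3 design/oligos.tsv
```

```
name                    sequence_5to3                 length  side        overhang
sim_locus_5p_24_top     GAAATTGCCCGCTCGGCTGTTAAGCCAC  28      five_prime  GAAA
sim_locus_5p_24_bottom  CATAGTGGCTTAACAGCCGAGCGGGCAA  28      five_prime  CATA
```

Each arm is two 28-mers: a 4-nt sticky end (for the 5′ arm, the final UgRNA
PAM base plus the 3-nt buffer, here `GAAA`) followed by the 24-bp genomic
arm, and its complement with the cargo-side overhang.

```sh
# 3. assemble the donor in silico and liberate the cargo
geneweld assemble --genome sim/genome.fasta --protospacer CTCGGCTGTTAAGCCACCCG --out asm
geneweld liberate --donor asm/donor.gb --out lib

# 4. classify the simulated junction reads
geneweld classify --reads sim/reads.fasta --reference sim/reference.json --out calls
```

```
15/20 precise (0.75)
```

`calls/summary.json` holds the same tally (`"display": "15/20"`), and
`calls/calls.tsv` lists each read's verdict and events — here the 5
imprecise reads are the planted single-base insertions and homology-domain
duplications, recovered exactly. `asm/donor.gb` is an annotated circular
GenBank map (arms, buffers, UgRNA sites, cargo, backbone) that any plasmid
editor can open.

The same operations are available as a library (`geneweld.seqcore`,
`.arms`, `.donor`, `.junctions`); the CLI is a thin wrapper.

## Layout

```
src/geneweld/
  seqcore.py    sequence primitives, guide/TALEN targets, cut-site arithmetic
  arms.py       homology-arm extraction, oligo rendering, design validation
  enzymes.py    Type IIS enzyme geometry (BfuAI, BspQI)
  donor.py      vector model, digestion, Golden Gate assembly, liberation,
                off-target scan, GenBank output
  junctions.py  targeting plans, expected alleles, junction classification,
                fixture simulator
  io.py         FASTA/GFF3/TSV/JSON adapters, vector registry, coordinates
  cli.py        command-line surface
  vectors/      bundled vector specs (synthetic placeholder payloads)
docs/methods.md detailed model, parameter and limitation notes
```
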
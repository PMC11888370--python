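"""Selection simulator: FASTQ reads with complete ground truth.

Real selection data is a pool of amplicons whose barcodes encode which
compound each molecule was, corrupted by sequencer noise.  The simulator
reproduces that shape: it samples compounds from per-compound weights,
renders each one's barcode through the library's schema (constants
verbatim, per-cycle tags, a uniformly random UMI), adds 0-10 random flank
bases on each side, injects i.i.d. substitutions and single-base indels,
and reverse-complements about half the reads (long-read amplicons arrive
in both orientations).  Every read's provenance is recorded so decoding
accuracy can be measured exactly.

The error model is deliberately simple — uniform substitutions and
single-base indels, no homopolymer or quality structure — and is documented
as such; it exercises the decoding machinery, not a particular sequencer.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import barcodes
from .config import (BarcodeSchema, BuildingBlock, BuildingBlockSet,
                     LibrarySpec, SchemaSection)

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

DEFAULT_FLANK_MAX = 10


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadTruth:
    read_id: str
    library_id: str
    compound_id: str
    umi: str
    n_substitutions: int
    n_indels: int
    reverse: bool


@dataclass
class SimulationTruth:
    """Ground truth for one simulated condition."""

    seed: int
    condition: str
    weights: np.ndarray  # per-compound sampling distribution, lex order
    compound_ids: list[str]
    reads: list[ReadTruth] = field(default_factory=list)

    @property
    def sampled_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reads:
            counts[r.compound_id] = counts.get(r.compound_id, 0) + 1
        return counts

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "condition": self.condition,
            "compound_ids": self.compound_ids,
            "weights": self.weights.tolist(),
            "reads": [vars(r) for r in self.reads],
        }
        Path(path).write_text(json.dumps(payload) + "\n")


# ---------------------------------------------------------------------------
# synthetic library factory


def make_synthetic_library(
    n_cycles: int = 3,
    blocks_per_cycle: int = 24,
    tag_length: int = 8,
    umi_length: int = 10,
    seed: int = 0,
    library_id: str = "SYN001",
    parity: bool = False,
    with_smiles: bool = False,
    error_correction_mode: str = "hamming",
) -> LibrarySpec:
    """Build a fully in-memory synthetic library.

    Tags come from one Hamming codebook, drawn without replacement across
    all cycles so even cross-cycle tags keep the code's distance.  The
    schema is primer / library tag / per-cycle tag + 3-bp spacer / UMI /
    closing primer.  With ``with_smiles`` each block gets a simple alkyl
    carboxylic-acid or amine SMILES so enumeration tests have real
    chemistry to chew on.
    """
    rng = np.random.default_rng(seed)
    tags = barcodes.generate_barcode_set(
        tag_length, n_cycles * blocks_per_cycle, parity=parity,
        seed=int(rng.integers(2 ** 31)))

    def rand_seq(n: int) -> str:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=n))

    cycle_labels = [chr(ord("A") + i) for i in range(n_cycles)]
    bb_sets = []
    for ci, label in enumerate(cycle_labels):
        blocks = []
        for bi in range(blocks_per_cycle):
            smiles = None
            if with_smiles:
                # cycle A: carboxylic acids of varying chain length;
                # later cycles: primary amines
                chain = "C" * (bi + 1)
                smiles = f"{chain}C(=O)O" if ci == 0 else f"N{chain}"
            blocks.append(BuildingBlock(
                bb_id=f"{label}{bi + 1:03d}",
                dna_tag=tags[ci * blocks_per_cycle + bi],
                smiles=smiles))
        bb_sets.append(BuildingBlockSet(cycle_label=label, blocks=blocks,
                                        tag_length=tag_length))

    sections = [
        SchemaSection("primer", "constant", 8, sequence=rand_seq(8)),
        SchemaSection("library_tag", "constant", 10, sequence=rand_seq(10)),
    ]
    for label in cycle_labels:
        sections.append(SchemaSection(f"bb_{label}", "bb_tag", tag_length,
                                      cycle=label))
        sections.append(SchemaSection(f"spacer_{label}", "constant", 3,
                                      sequence=rand_seq(3)))
    if umi_length > 0:
        sections.append(SchemaSection("umi", "umi", umi_length))
    sections.append(SchemaSection("closing", "constant", 8,
                                  sequence=rand_seq(8)))

    reaction_scheme = []
    if with_smiles and n_cycles >= 2:
        amide = "[C:1](=[O:2])[OX2H1].[NX3;H2,H1:3]>>[C:1](=[O:2])[N:3]"
        reaction_scheme = [amide] * (n_cycles - 1)

    return LibrarySpec(
        library_id=library_id,
        library_tag=sections[1].sequence,
        schema=BarcodeSchema(sections=sections),
        bb_sets=bb_sets,
        reaction_scheme=reaction_scheme,
        error_correction_mode=error_correction_mode,
        hamming_parity=parity,
    )


# ---------------------------------------------------------------------------
# weights


def uniform_weights(library: LibrarySpec) -> np.ndarray:
    return np.full(library.size, 1.0 / library.size)


def planted_enrichment_weights(
    library: LibrarySpec, hit_fraction: float, fold: float, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampling weights with a planted hit set.

    A ``hit_fraction`` of compounds (chosen by ``seed``) is sampled at
    ``fold`` times the background weight, then the whole vector is
    renormalised.  Returns (weights, hit index array).
    """
    if not 0 < hit_fraction < 1:
        raise ValueError("hit_fraction must be in (0, 1)")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    n = library.size
    n_hits = max(1, round(hit_fraction * n))
    hits = rng.choice(n, size=n_hits, replace=False)
    w = np.ones(n)
    w[hits] = fold
    return w / w.sum(), np.sort(hits)


# ---------------------------------------------------------------------------
# read rendering


def compound_id_from_indices(library: LibrarySpec, indices: Sequence[int]) -> str:
    parts = [library.library_id]
    for bs, i in zip(library.bb_sets, indices):
        parts.append(bs.blocks[i].bb_id)
    return "-".join(parts)


def _indices_from_flat(library: LibrarySpec, flat: int) -> list[int]:
    sizes = [len(bs) for bs in library.bb_sets]
    out = []
    for size in reversed(sizes):
        out.append(flat % size)
        flat //= size
    return out[::-1]


def render_barcode(library: LibrarySpec, bb_indices: Sequence[int],
                   umi: str) -> str:
    """The error-free barcode sequence for one molecule."""
    parts = []
    it = iter(bb_indices)
    for sec in library.schema.sections:
        if sec.kind in ("constant", "index"):
            parts.append(sec.sequence)
        elif sec.kind == "bb_tag":
            cyc = library.bb_set(sec.cycle)
            parts.append(cyc.blocks[next(it)].dna_tag)
        elif sec.kind == "umi":
            parts.append(umi)
    return "".join(parts)


def _corrupt(seq: str, sub_rate: float, indel_rate: float,
             rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply i.i.d. substitutions and single-base indels; returns
    (corrupted sequence, n_substitutions, n_indels)."""
    out = []
    n_sub = n_indel = 0
    for base in seq:
        r = rng.random()
        if indel_rate and r < indel_rate:
            n_indel += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(BASES[rng.integers(4)])  # insertion before the base
            out.append(base)
            continue
        if sub_rate and r < indel_rate + sub_rate:
            n_sub += 1
            choices = [b for b in BASES if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out), n_sub, n_indel


def simulate_selection(
    library: LibrarySpec,
    weights: Optional[np.ndarray],
    n_reads: int,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    out_fastq: Optional[Path | str] = None,
    condition: str = "target",
    flank_max: int = DEFAULT_FLANK_MAX,
    rc_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Simulate one condition's reads from one library.

    Returns the reads as (read_id, sequence) pairs plus the full truth; if
    ``out_fastq`` is given the reads are also written there (gzipped when
    the name ends in .gz, with a fixed mtime so identical seeds give
    byte-identical files).  Weights default to uniform.
    """
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate <= 0.2:
            raise ValueError(f"{name} must be in [0, 0.2], got {rate}")
    if weights is None:
        weights = uniform_weights(library)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (library.size,):
        raise ValueError(
            f"weights length {weights.shape} does not match library size "
            f"{library.size}")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")

    rng = np.random.default_rng(seed)
    umi_sec = library.schema.umi_section()
    umi_len = umi_sec.length if umi_sec else 0
    compound_ids = [compound_id_from_indices(library,
                                             _indices_from_flat(library, f))
                    for f in range(library.size)]

    flat_draws = rng.choice(library.size, size=n_reads, p=weights)
    truth = SimulationTruth(seed=seed, condition=condition, weights=weights,
                            compound_ids=compound_ids)
    reads: list[tuple[str, str]] = []
    for ri, flat in enumerate(flat_draws):
        indices = _indices_from_flat(library, int(flat))
        umi = "".join(BASES[i] for i in rng.integers(0, 4, size=umi_len))
        barcode = render_barcode(library, indices, umi)
        left = "".join(BASES[i]
                       for i in rng.integers(0, 4, size=rng.integers(0, flank_max + 1)))
        right = "".join(BASES[i]
                        for i in rng.integers(0, 4, size=rng.integers(0, flank_max + 1)))
        seq, n_sub, n_indel = _corrupt(left + barcode + right, sub_rate,
                                       indel_rate, rng)
        reverse = bool(rng.random() < rc_fraction)
        if reverse:
            seq = reverse_complement(seq)
        read_id = f"sim_{condition}_{ri}"
        reads.append((read_id, seq))
        truth.reads.append(ReadTruth(
            read_id=read_id, library_id=library.library_id,
            compound_id=compound_id_from_indices(library, indices),
            umi=umi, n_substitutions=n_sub, n_indels=n_indel,
            reverse=reverse))

    if out_fastq is not None:
        write_fastq(reads, out_fastq)
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTQ with placeholder qualities.

    Gzip output (for .gz paths) pins mtime=0 so output bytes depend only on
    the reads.
    """
    path = Path(path)
    text = "".join(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n"
                   for rid, seq in reads)
    data = text.encode("ascii")
    if path.suffix == ".gz":
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb",
                               mtime=0) as gz:
                gz.write(data)
    else:
        path.write_bytes(data)
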
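"""Combinatorial enumeration of library chemical structures.

A combinatorial library's chemical space is the Cartesian product of its
building-block sets pushed through the synthesis scheme.  The scheme is a
linear, ordered list of two-reactant SMIRKS transforms: step *i* couples
the running intermediate (seeded with the first cycle's block) to cycle
*i+1*'s block.  The literal scheme entry ``"identity"`` keeps the
intermediate unchanged (useful for tag-only libraries and tests).
Enumeration can run in batch over the whole library — a deterministic
lexicographic stream whose length is always the product of the cycle
sizes, with chemistry failures carried inside the stream rather than
dropped — or on demand for single compound ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors

from .config import LibrarySpec

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # RDKit is chatty; we report failures ourselves

IDENTITY = "identity"

#: physicochemical descriptors available to compute_properties
DESCRIPTORS = {
    "mol_weight": Descriptors.MolWt,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
    "ring_count": rdMolDescriptors.CalcNumRings,
    "logp": Descriptors.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "hbd": rdMolDescriptors.CalcNumHBD,
    "hba": rdMolDescriptors.CalcNumHBA,
    "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds,
}


@dataclass(frozen=True)
class CompoundID:
    """Library id plus one building-block id per cycle, in cycle order."""

    library_id: str
    bb_ids: tuple[str, ...]

    def render(self) -> str:
        return "-".join((self.library_id,) + self.bb_ids)

    @classmethod
    def parse(cls, text: str, library: LibrarySpec) -> "CompoundID":
        n = len(library.bb_sets)
        parts = text.rsplit("-", n)
        if len(parts) != n + 1 or parts[0] != library.library_id:
            raise ValueError(
                f"compound id {text!r} does not match library "
                f"{library.library_id!r} with {n} cycles")
        cid = cls(library_id=parts[0], bb_ids=tuple(parts[1:]))
        cid.validate(library)
        return cid

    def validate(self, library: LibrarySpec) -> None:
        if len(self.bb_ids) != len(library.bb_sets):
            raise ValueError(
                f"compound id has {len(self.bb_ids)} blocks but library "
                f"{library.library_id} has {len(library.bb_sets)} cycles")
        for bb_id, bs in zip(self.bb_ids, library.bb_sets):
            if bs.by_id(bb_id) is None:
                raise ValueError(
                    f"unknown building block {bb_id!r} in cycle "
                    f"{bs.cycle_label!r} of library {library.library_id}")


@dataclass
class EnumeratedCompound:
    compound_id: CompoundID
    smiles: Optional[str] = None
    failure: Optional[str] = None
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if (self.smiles is None) == (self.failure is None):
            raise ValueError("exactly one of smiles/failure must be set")


def _parse_scheme(scheme: Sequence[str]):
    """Validate and compile the reaction scheme.

    Only linear two-reactant schemes are supported; anything else is
    rejected up front with a clear message.
    """
    compiled = []
    for i, entry in enumerate(scheme):
        if entry == IDENTITY:
            compiled.append(None)
            continue
        rxn = AllChem.ReactionFromSmarts(entry)
        if rxn is None:
            raise ValueError(f"reaction scheme step {i}: unparsable SMIRKS "
                             f"{entry!r}")
        if rxn.GetNumReactantTemplates() != 2:
            raise ValueError(
                f"reaction scheme step {i}: expected a linear two-reactant "
                f"transform (intermediate + next block), got "
                f"{rxn.GetNumReactantTemplates()} reactant templates; "
                "nonlinear/conditional schemes are not supported")
        compiled.append(rxn)
    return compiled


def _run_step(rxn, intermediate: Chem.Mol, block: Chem.Mol,
              step: int) -> tuple[Optional[Chem.Mol], Optional[str]]:
    products = rxn.RunReactants((intermediate, block))
    smiles_set = set()
    for tup in products:
        mol = tup[0]
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        smiles_set.add(Chem.MolToSmiles(mol))
    if not smiles_set:
        return None, (f"step {step}: reactants do not match the transform "
                      "(no product)")
    first = sorted(smiles_set)[0]  # first by canonical rank: deterministic
    if len(smiles_set) > 1:
        log.warning("reaction step %d produced %d distinct products; "
                    "keeping %s", step, len(smiles_set), first)
    return Chem.MolFromSmiles(first), None


def enumerate_compound(library: LibrarySpec, compound_id: CompoundID,
                       _compiled=None) -> EnumeratedCompound:
    """Assemble one compound through the library's reaction scheme.

    A block whose functional groups do not match a transform yields a
    failure marker (not an exception); a block with no SMILES at all is a
    configuration error and raises.
    """
    compound_id.validate(library)
    scheme = _compiled if _compiled is not None \
        else _parse_scheme(library.reaction_scheme)
    n_steps = len(library.bb_sets) - 1
    if len(scheme) != n_steps:
        raise ValueError(
            f"library {library.library_id}: reaction scheme has "
            f"{len(scheme)} steps but {len(library.bb_sets)} cycles need "
            f"{n_steps}")

    blocks = []
    for bb_id, bs in zip(compound_id.bb_ids, library.bb_sets):
        block = bs.by_id(bb_id)
        if block.smiles is None:
            raise ValueError(
                f"building block {bb_id!r} (cycle {bs.cycle_label!r}) has no "
                "SMILES; enumeration needs structures for every block")
        mol = Chem.MolFromSmiles(block.smiles)
        if mol is None:
            raise ValueError(
                f"building block {bb_id!r}: unparsable SMILES "
                f"{block.smiles!r}")
        blocks.append(mol)

    intermediate = blocks[0]
    for step, rxn in enumerate(scheme):
        if rxn is None:  # identity transform
            continue
        intermediate, failure = _run_step(rxn, intermediate, blocks[step + 1],
                                          step)
        if failure is not None:
            return EnumeratedCompound(compound_id=compound_id, failure=failure)
    return EnumeratedCompound(compound_id=compound_id,
                              smiles=Chem.MolToSmiles(intermediate))


def enumerate_library(library: LibrarySpec) -> Iterator[EnumeratedCompound]:
    """Stream every compound of the library.

    Yields exactly the Cartesian product of the cycles' blocks in
    lexicographic cycle-index order; per-compound chemistry failures appear
    in the stream as failure markers, so the stream length is always the
    product of the cycle sizes.
    """
    compiled = _parse_scheme(library.reaction_scheme)
    sizes = [len(bs) for bs in library.bb_sets]
    indices = [0] * len(sizes)
    total = library.size
    for _ in range(total):
        cid = CompoundID(
            library_id=library.library_id,
            bb_ids=tuple(bs.blocks[i].bb_id
                         for bs, i in zip(library.bb_sets, indices)))
        yield enumerate_compound(library, cid, _compiled=compiled)
        for pos in range(len(sizes) - 1, -1, -1):
            indices[pos] += 1
            if indices[pos] < sizes[pos]:
                break
            indices[pos] = 0


def compute_properties(compound: EnumeratedCompound,
                       descriptors: Sequence[str]) -> EnumeratedCompound:
    """Populate physicochemical descriptors for an enumerated compound."""
    if compound.smiles is None:
        raise ValueError("cannot compute properties of a failed enumeration")
    unknown = [d for d in descriptors if d not in DESCRIPTORS]
    if unknown:
        raise ValueError(
            f"unknown descriptors {unknown}; available: "
            f"{sorted(DESCRIPTORS)}")
    if descriptors:
        mol = Chem.MolFromSmiles(compound.smiles)
        for name in descriptors:
            compound.properties[name] = float(DESCRIPTORS[name](mol))
    return compound
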
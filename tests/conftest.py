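import json

import pytest

from delkit.config import Condition, SelectionSpec, load_library
from delkit.simulate import make_synthetic_library

TOY_BLOCKS_A = [("A01", "AAAAAAA", "CC(=O)O"), ("A02", "AACCTAC", "CCC(=O)O"),
                ("A03", "CCAACCA", "CCCC(=O)O"), ("A04", "GGAAGGT", "CC(C)C(=O)O")]
TOY_BLOCKS_B = [("B01", "AAAACCT", "NCC"), ("B02", "CCAAAAG", "NCCC"),
                ("B03", "GGAATTA", "NCCCC"), ("B04", "TTAAGGC", "NC1CC1")]

AMIDE = "[C:1](=[O:2])[OX2H1].[NX3;H2,H1:3]>>[C:1](=[O:2])[N:3]"


def write_toy_library(tmp_path, *, mode="none", scheme=(AMIDE,)):
    """A 2-cycle, 4-block toy library on disk (JSON + two CSVs)."""
    for name, blocks in (("bb_a.csv", TOY_BLOCKS_A), ("bb_b.csv", TOY_BLOCKS_B)):
        lines = ["id,tag,smiles"]
        lines += [f"{i},{t},{s}" for i, t, s in blocks]
        (tmp_path / name).write_text("\n".join(lines) + "\n")
    lib = {
        "library_id": "TOY1",
        "library_tag": "ACGTACGTAC",
        "barcode_schema": [
            {"name": "primer", "kind": "constant", "sequence": "TTGGCCAA"},
            {"name": "library_tag", "kind": "constant", "sequence": "ACGTACGTAC"},
            {"name": "bb_A", "kind": "bb_tag", "cycle": "A", "length": 7},
            {"name": "bb_B", "kind": "bb_tag", "cycle": "B", "length": 7},
            {"name": "umi", "kind": "umi", "length": 6},
            {"name": "closing", "kind": "constant", "sequence": "GGTTAACC"},
        ],
        "building_blocks": {"A": "bb_a.csv", "B": "bb_b.csv"},
        "reaction_scheme": list(scheme),
        "error_correction": {"mode": mode},
    }
    path = tmp_path / "toy.json"
    path.write_text(json.dumps(lib))
    return path


@pytest.fixture
def toy_library_path(tmp_path):
    return write_toy_library(tmp_path)


@pytest.fixture
def toy_library(toy_library_path):
    return load_library(toy_library_path)


@pytest.fixture(scope="session")
def small_synthetic_library():
    """3-cycle, 8 blocks/cycle, 8-bp Hamming tags, 10-bp UMI."""
    return make_synthetic_library(n_cycles=3, blocks_per_cycle=8, seed=11)


def selection_for(library, conditions=("target/1",)):
    conds = []
    for key in conditions:
        name, _, rep = key.partition("/")
        conds.append(Condition(name=name, replicate=rep, read_files=[]))
    return SelectionSpec(selection_id="TEST_SEL", libraries=[library],
                         conditions=conds)


@pytest.fixture
def small_selection(small_synthetic_library):
    return selection_for(small_synthetic_library)
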
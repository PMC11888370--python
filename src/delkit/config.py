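"""Library, building-block, and selection configuration.

A DNA-encoded library is described by three kinds of files:

* building-block tables (CSV/TSV; columns ``id``, ``tag``, optional
  ``smiles``) — one file per combinatorial cycle;
* a library JSON defining the barcode schema (the ordered layout of
  constant regions, per-cycle tag sections, UMI and optional index), the
  building-block files, the reaction scheme and the error-correction mode;
* a selection YAML naming the libraries screened, the FASTQ read files per
  condition/replicate, and the decoding settings.

Everything is cross-validated at load time, and every error message names
the file and offending field/row and, for misspelled keys or unknown
library ids, suggests the nearest valid name.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import barcodes

NUCLEOTIDES = set("ACGT")

SECTION_KINDS = ("constant", "bb_tag", "umi", "index")
ERROR_CORRECTION_MODES = ("hamming", "lookup", "none")
UMI_MODES = ("exact", "cluster1")

_LIBRARY_KEYS = [
    "library_id", "library_tag", "barcode_schema", "building_blocks",
    "reaction_scheme", "error_correction",
]
_SECTION_KEYS = ["name", "kind", "length", "sequence", "cycle"]
_SELECTION_KEYS = ["selection_id", "libraries", "conditions", "decode"]
_CONDITION_KEYS = ["name", "replicate", "read_files"]
_DECODE_KEYS = ["library_error_rate", "schema_error_rate", "umi_mode"]


class ConfigError(ValueError):
    """A configuration problem, with enough context to fix it."""

    def __init__(self, message: str, *, path=None, location: str | None = None,
                 suggestion: str | None = None):
        parts = []
        if path is not None:
            parts.append(f"{path}")
        if location:
            parts.append(location)
        prefix = ": ".join(parts)
        full = f"{prefix}: {message}" if prefix else message
        if suggestion:
            full += f" (did you mean {suggestion!r}?)"
        super().__init__(full)
        self.path = path
        self.location = location
        self.suggestion = suggestion


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit costs) by the standard DP."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def suggest_key(bad_key: str, valid_keys: Sequence[str],
                max_distance: int = 2) -> Optional[str]:
    """Nearest valid key by edit distance, if within ``max_distance``.

    Ties are broken lexicographically so suggestions are deterministic.
    """
    if not valid_keys:
        raise ValueError("valid_keys must be non-empty")
    best = min(sorted(valid_keys), key=lambda k: (edit_distance(bad_key, k), k))
    return best if edit_distance(bad_key, best) <= max_distance else None


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BuildingBlock:
    bb_id: str
    dna_tag: str
    smiles: Optional[str] = None


@dataclass
class BuildingBlockSet:
    cycle_label: str
    blocks: list[BuildingBlock]
    tag_length: int

    def __post_init__(self):
        self._by_tag = {b.dna_tag: b for b in self.blocks}
        self._by_id = {b.bb_id: b for b in self.blocks}

    def __len__(self):
        return len(self.blocks)

    def by_tag(self, tag: str) -> Optional[BuildingBlock]:
        return self._by_tag.get(tag)

    def by_id(self, bb_id: str) -> Optional[BuildingBlock]:
        return self._by_id.get(bb_id)

    @property
    def tags(self) -> list[str]:
        return [b.dna_tag for b in self.blocks]


@dataclass(frozen=True)
class SchemaSection:
    name: str
    kind: str  # constant | bb_tag | umi | index
    length: int
    sequence: Optional[str] = None  # constant / index sections
    cycle: Optional[str] = None  # bb_tag sections


@dataclass
class BarcodeSchema:
    """Ordered layout of one library's DNA barcode."""

    sections: list[SchemaSection]

    def __post_init__(self):
        self._offsets = {}
        off = 0
        for s in self.sections:
            self._offsets[s.name] = (off, off + s.length)
            off += s.length
        self.total_length = off

    def reference(self, wildcard: str = "N") -> str:
        """Reference string: constants verbatim, variable sections as
        wildcards; this is the pattern the read aligner anchors on."""
        parts = []
        for s in self.sections:
            if s.sequence is not None:
                parts.append(s.sequence)
            else:
                parts.append(wildcard * s.length)
        return "".join(parts)

    def section_offsets(self) -> Mapping[str, tuple[int, int]]:
        return dict(self._offsets)

    def bb_tag_sections(self) -> list[SchemaSection]:
        return [s for s in self.sections if s.kind == "bb_tag"]

    def umi_section(self) -> Optional[SchemaSection]:
        for s in self.sections:
            if s.kind == "umi":
                return s
        return None


@dataclass
class LibrarySpec:
    library_id: str
    library_tag: str
    schema: BarcodeSchema
    bb_sets: list[BuildingBlockSet]
    reaction_scheme: list[str] = field(default_factory=list)
    error_correction_mode: str = "none"
    hamming_parity: bool = False
    source_path: Optional[Path] = None

    @property
    def cycles(self) -> list[str]:
        return [s.cycle_label for s in self.bb_sets]

    @property
    def size(self) -> int:
        out = 1
        for s in self.bb_sets:
            out *= len(s)
        return out

    def bb_set(self, cycle: str) -> BuildingBlockSet:
        for s in self.bb_sets:
            if s.cycle_label == cycle:
                return s
        raise KeyError(f"library {self.library_id} has no cycle {cycle!r}")

    def to_dict(self) -> dict:
        """JSON-serialisable form with building blocks inlined."""
        return {
            "library_id": self.library_id,
            "library_tag": self.library_tag,
            "barcode_schema": [
                {k: v for k, v in {
                    "name": s.name, "kind": s.kind, "length": s.length,
                    "sequence": s.sequence, "cycle": s.cycle,
                }.items() if v is not None}
                for s in self.schema.sections
            ],
            "building_blocks": {
                bs.cycle_label: [
                    {k: v for k, v in {
                        "id": b.bb_id, "tag": b.dna_tag, "smiles": b.smiles,
                    }.items() if v is not None}
                    for b in bs.blocks
                ]
                for bs in self.bb_sets
            },
            "reaction_scheme": list(self.reaction_scheme),
            "error_correction": {
                "mode": self.error_correction_mode,
                "parity": self.hamming_parity,
            },
        }


@dataclass(frozen=True)
class Condition:
    name: str
    replicate: str
    read_files: list[Path]

    @property
    def key(self) -> str:
        return f"{self.name}/{self.replicate}" if self.replicate else self.name


@dataclass
class DecodeSettings:
    library_error_rate: float = 0.1
    schema_error_rate: float = 0.1
    umi_mode: str = "exact"

    def __post_init__(self):
        for name in ("library_error_rate", "schema_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ConfigError(f"{name} must be in [0, 0.5), got {v}")
        if self.umi_mode not in UMI_MODES:
            raise ConfigError(
                f"umi_mode must be one of {UMI_MODES}, got {self.umi_mode!r}")


@dataclass
class SelectionSpec:
    selection_id: str
    libraries: list[LibrarySpec]
    conditions: list[Condition]
    decode_settings: DecodeSettings = field(default_factory=DecodeSettings)

    @property
    def read_files(self) -> list[Path]:
        out = []
        for c in self.conditions:
            out.extend(c.read_files)
        return out


# ---------------------------------------------------------------------------
# validation helpers


def _check_keys(mapping: Mapping, valid: Sequence[str], required: Sequence[str],
                *, path, location: str):
    for key in mapping:
        if key not in valid:
            raise ConfigError(f"unknown key {key!r}", path=path,
                              location=location,
                              suggestion=suggest_key(str(key), list(valid)))
    for key in required:
        if key not in mapping:
            raise ConfigError(f"missing required key {key!r}", path=path,
                              location=location)


def _check_nucleotides(seq: str, *, path, location: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in NUCLEOTIDES:
            raise ConfigError(
                f"invalid nucleotide {ch!r} at position {i} in {seq!r} "
                "(allowed: A, C, G, T, uppercase)",
                path=path, location=location)


# ---------------------------------------------------------------------------
# building-block tables


def load_building_blocks(path, cycle_label: str) -> BuildingBlockSet:
    """Read one cycle's building blocks from a CSV (or TSV) table.

    The first row is a header; required columns ``id`` and ``tag``,
    optional ``smiles``.  The delimiter is inferred from the extension.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError("building-block file not found", path=path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigError("file is empty", path=path) from None
        header = [h.strip() for h in header]
        for col in ("id", "tag"):
            if col not in header:
                raise ConfigError(
                    f"missing required column {col!r} (found {header})",
                    path=path, location="header",
                    suggestion=suggest_key(col, header) if header else None)
        idx = {name: header.index(name) for name in header}
        blocks: list[BuildingBlock] = []
        seen_ids: set[str] = set()
        seen_tags: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            loc = f"row {rownum}"
            bb_id = row[idx["id"]].strip()
            tag = row[idx["tag"]].strip()
            smiles = None
            if "smiles" in idx and idx["smiles"] < len(row):
                smiles = row[idx["smiles"]].strip() or None
            if not bb_id:
                raise ConfigError("empty building-block id", path=path, location=loc)
            if "-" in bb_id:
                raise ConfigError(
                    f"building-block id {bb_id!r} may not contain '-' "
                    "(reserved as the compound-id separator)",
                    path=path, location=loc)
            if not tag:
                raise ConfigError("empty DNA tag", path=path, location=loc)
            _check_nucleotides(tag, path=path, location=loc)
            if bb_id in seen_ids:
                raise ConfigError(f"duplicate building-block id {bb_id!r}",
                                  path=path, location=loc)
            if tag in seen_tags:
                raise ConfigError(f"duplicate DNA tag {tag!r}", path=path,
                                  location=loc)
            seen_ids.add(bb_id)
            seen_tags.add(tag)
            blocks.append(BuildingBlock(bb_id=bb_id, dna_tag=tag, smiles=smiles))
    if not blocks:
        raise ConfigError("no building blocks in file", path=path)
    lengths = {len(b.dna_tag) for b in blocks}
    if len(lengths) > 1:
        raise ConfigError(
            f"DNA tags have inconsistent lengths {sorted(lengths)}", path=path)
    return BuildingBlockSet(cycle_label=cycle_label, blocks=blocks,
                            tag_length=lengths.pop())


# ---------------------------------------------------------------------------
# library JSON


def _parse_section(raw: Mapping, *, path, index: int) -> SchemaSection:
    loc = f"barcode_schema[{index}]"
    _check_keys(raw, _SECTION_KEYS, ["name", "kind"], path=path, location=loc)
    name = str(raw["name"])
    kind = str(raw["kind"])
    if kind not in SECTION_KINDS:
        raise ConfigError(f"unknown section kind {kind!r}", path=path,
                          location=loc,
                          suggestion=suggest_key(kind, list(SECTION_KINDS)))
    sequence = raw.get("sequence")
    cycle = raw.get("cycle")
    if kind in ("constant", "index"):
        if sequence is None:
            raise ConfigError(f"{kind} section {name!r} needs a 'sequence'",
                              path=path, location=loc)
        sequence = str(sequence)
        _check_nucleotides(sequence, path=path, location=loc)
        length = raw.get("length", len(sequence))
        if length != len(sequence):
            raise ConfigError(
                f"section {name!r}: length {length} != len(sequence) "
                f"{len(sequence)}", path=path, location=loc)
    else:
        if sequence is not None:
            raise ConfigError(f"{kind} section {name!r} may not carry a "
                              "'sequence'", path=path, location=loc)
        if "length" not in raw:
            raise ConfigError(f"{kind} section {name!r} needs a 'length'",
                              path=path, location=loc)
        length = raw["length"]
    if kind == "bb_tag" and cycle is None:
        raise ConfigError(f"bb_tag section {name!r} needs a 'cycle' label",
                          path=path, location=loc)
    if not isinstance(length, int) or length <= 0:
        raise ConfigError(f"section {name!r}: length must be a positive "
                          f"integer, got {length!r}", path=path, location=loc)
    return SchemaSection(name=name, kind=kind, length=length,
                         sequence=sequence,
                         cycle=str(cycle) if cycle is not None else None)


def load_library(path) -> LibrarySpec:
    """Load and fully cross-validate a library definition JSON.

    Building-block file paths are resolved relative to the JSON file.
    Building blocks may alternatively be inlined as lists of
    ``{"id":…, "tag":…, "smiles":…}`` objects (the serialisation format).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError("library file not found", path=path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON: {exc}", path=path) from None
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a JSON object", path=path)
    _check_keys(raw, _LIBRARY_KEYS,
                ["library_id", "library_tag", "barcode_schema",
                 "building_blocks"],
                path=path, location="top level")

    library_id = str(raw["library_id"])
    library_tag = str(raw["library_tag"])
    _check_nucleotides(library_tag, path=path, location="library_tag")

    schema_raw = raw["barcode_schema"]
    if not isinstance(schema_raw, list) or not schema_raw:
        raise ConfigError("barcode_schema must be a non-empty list of "
                          "sections", path=path)
    sections = [_parse_section(s, path=path, index=i)
                for i, s in enumerate(schema_raw)]
    names = [s.name for s in sections]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate section names in barcode_schema",
                          path=path)
    schema = BarcodeSchema(sections=sections)

    bb_raw = raw["building_blocks"]
    if not isinstance(bb_raw, dict) or not bb_raw:
        raise ConfigError("building_blocks must map cycle labels to CSV/TSV "
                          "paths or inline block lists", path=path)
    bb_sets = []
    for cycle_label, value in bb_raw.items():
        if isinstance(value, str):
            bb_path = (path.parent / value).resolve()
            bb_sets.append(load_building_blocks(bb_path, str(cycle_label)))
        elif isinstance(value, list):
            blocks = []
            for i, b in enumerate(value):
                loc = f"building_blocks[{cycle_label}][{i}]"
                _check_keys(b, ["id", "tag", "smiles"], ["id", "tag"],
                            path=path, location=loc)
                _check_nucleotides(str(b["tag"]), path=path, location=loc)
                blocks.append(BuildingBlock(bb_id=str(b["id"]),
                                            dna_tag=str(b["tag"]),
                                            smiles=b.get("smiles")))
            lengths = {len(b.dna_tag) for b in blocks}
            if len(lengths) != 1:
                raise ConfigError(
                    f"cycle {cycle_label!r}: inconsistent tag lengths",
                    path=path)
            tags = [b.dna_tag for b in blocks]
            ids = [b.bb_id for b in blocks]
            if len(set(tags)) != len(tags) or len(set(ids)) != len(ids):
                raise ConfigError(f"cycle {cycle_label!r}: duplicate id or tag",
                                  path=path)
            bb_sets.append(BuildingBlockSet(cycle_label=str(cycle_label),
                                            blocks=blocks,
                                            tag_length=lengths.pop()))
        else:
            raise ConfigError(
                f"cycle {cycle_label!r}: expected a file path or inline list",
                path=path)

    # cross-checks: one bb_tag section per cycle, matching tag lengths
    tag_sections = {s.cycle: s for s in schema.bb_tag_sections()}
    if len(tag_sections) != len(schema.bb_tag_sections()):
        raise ConfigError("two bb_tag sections share a cycle label", path=path)
    for bs in bb_sets:
        sec = tag_sections.get(bs.cycle_label)
        if sec is None:
            raise ConfigError(
                f"cycle {bs.cycle_label!r} has building blocks but no bb_tag "
                "section in barcode_schema", path=path,
                suggestion=suggest_key(bs.cycle_label,
                                       [c for c in tag_sections]))
        if sec.length != bs.tag_length:
            raise ConfigError(
                f"cycle {bs.cycle_label!r}: schema section {sec.name!r} "
                f"expects {sec.length}-bp tags but building blocks carry "
                f"{bs.tag_length}-bp tags", path=path)
    for cyc in tag_sections:
        if not any(bs.cycle_label == cyc for bs in bb_sets):
            raise ConfigError(
                f"bb_tag section for cycle {cyc!r} has no building-block set",
                path=path)
    # keep bb_sets in schema order
    order = [s.cycle for s in schema.bb_tag_sections()]
    bb_sets.sort(key=lambda bs: order.index(bs.cycle_label))

    ec_raw = raw.get("error_correction", {"mode": "none"})
    _check_keys(ec_raw, ["mode", "parity"], ["mode"], path=path,
                location="error_correction")
    mode = str(ec_raw["mode"])
    if mode not in ERROR_CORRECTION_MODES:
        raise ConfigError(
            f"unknown error-correction mode {mode!r}", path=path,
            location="error_correction",
            suggestion=suggest_key(mode, list(ERROR_CORRECTION_MODES)))
    parity = bool(ec_raw.get("parity", False))

    spec = LibrarySpec(
        library_id=library_id,
        library_tag=library_tag,
        schema=schema,
        bb_sets=bb_sets,
        reaction_scheme=[str(r) for r in raw.get("reaction_scheme", [])],
        error_correction_mode=mode,
        hamming_parity=parity,
        source_path=path,
    )
    if mode == "hamming":
        for bs in spec.bb_sets:
            code = barcodes.build_code(bs.tag_length, parity=parity)
            for b in bs.blocks:
                if any(code.syndrome(b.dna_tag)):
                    raise ConfigError(
                        f"cycle {bs.cycle_label!r}: tag {b.dna_tag!r} of "
                        f"block {b.bb_id!r} is not a codeword of the "
                        f"length-{bs.tag_length} "
                        f"{'parity ' if parity else ''}Hamming code; use "
                        "'lookup' mode for unstructured tag sets",
                        path=path)
    return spec


def save_library(spec: LibrarySpec, path) -> None:
    """Serialise a LibrarySpec (building blocks inlined) to JSON."""
    Path(path).write_text(json.dumps(spec.to_dict(), indent=1) + "\n")


# ---------------------------------------------------------------------------
# selection YAML


def load_selection(path, library_registry: Mapping[str, LibrarySpec] | None = None,
                   ) -> SelectionSpec:
    """Load a selection-experiment YAML and resolve its libraries.

    ``libraries`` entries ending in ``.json`` are loaded as files (relative
    to the YAML); other entries are looked up in ``library_registry`` by id,
    with a nearest-id suggestion on a miss.  Library tags that collide
    within the configured error tolerance raise an ambiguity error.
    """
    path = Path(path)
    registry = dict(library_registry or {})
    if not path.exists():
        raise ConfigError("selection file not found", path=path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}", path=path) from None
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a YAML mapping", path=path)
    _check_keys(raw, _SELECTION_KEYS, ["selection_id", "libraries",
                                       "conditions"],
                path=path, location="top level")

    libs: list[LibrarySpec] = []
    lib_entries = raw["libraries"]
    if not isinstance(lib_entries, list) or not lib_entries:
        raise ConfigError("'libraries' must be a non-empty list", path=path)
    for entry in lib_entries:
        entry = str(entry)
        if entry.endswith(".json"):
            libs.append(load_library(path.parent / entry))
        elif entry in registry:
            libs.append(registry[entry])
        else:
            raise ConfigError(
                f"unknown library id {entry!r}", path=path,
                location="libraries",
                suggestion=suggest_key(entry, list(registry))
                if registry else None)
    ids = [l.library_id for l in libs]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate library ids in selection", path=path)

    decode_raw = raw.get("decode", {})
    _check_keys(decode_raw, _DECODE_KEYS, [], path=path, location="decode")
    settings = DecodeSettings(**{k: decode_raw[k] for k in _DECODE_KEYS
                                 if k in decode_raw})

    # library-tag ambiguity: two tags closer than the per-tag error budget
    # cannot be told apart at that tolerance
    for i in range(len(libs)):
        for j in range(i + 1, len(libs)):
            a, b = libs[i], libs[j]
            budget = int(settings.library_error_rate *
                         max(len(a.library_tag), len(b.library_tag)))
            if edit_distance(a.library_tag, b.library_tag) <= budget:
                raise ConfigError(
                    f"library tags of {a.library_id!r} and {b.library_id!r} "
                    f"are within the error tolerance "
                    f"(distance <= {budget}); demultiplexing would be "
                    "ambiguous", path=path)

    cond_raw = raw["conditions"]
    if not isinstance(cond_raw, list) or not cond_raw:
        raise ConfigError("'conditions' must be a non-empty list", path=path)
    conditions = []
    for i, c in enumerate(cond_raw):
        loc = f"conditions[{i}]"
        _check_keys(c, _CONDITION_KEYS, ["name", "read_files"], path=path,
                    location=loc)
        files = c["read_files"]
        if not isinstance(files, list) or not files:
            raise ConfigError("read_files must be a non-empty list",
                              path=path, location=loc)
        conditions.append(Condition(
            name=str(c["name"]),
            replicate=str(c.get("replicate", "")),
            read_files=[(path.parent / f).resolve() for f in files]))
    keys = [c.key for c in conditions]
    if len(set(keys)) != len(keys):
        raise ConfigError("duplicate condition name/replicate pairs", path=path)

    return SelectionSpec(selection_id=str(raw["selection_id"]),
                         libraries=libs, conditions=conditions,
                         decode_settings=settings)
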
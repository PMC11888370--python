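"""FASTQ -> per-compound counts: the decoding pipeline.

Each read is processed in stages, and the first stage that fails determines
a categorical outcome, so every input read is accounted for exactly once:

1. *library match* — semi-global alignment of each candidate library's
   demultiplexing tag against the read (both orientations; exact substring
   and full-schema regex fast paths first), best within the configured
   error tolerance;
2. *schema alignment* — semi-global alignment of the library's full
   barcode reference (wildcards at tag/UMI positions) to recover a read
   span for every schema section;
3. *tag calling* — each cycle's extracted tag is decoded by the library's
   error-correction mode: syndrome decoding for Hamming codebooks, the
   hash-map lookup decoder for unstructured sets, or exact match;
4. *UMI extraction* — the molecular identifier that deduplicates PCR
   copies of the same molecule.

Counts are accumulated in a mergeable :class:`UMIState` (raw tallies plus
per-compound UMI multisets); shards decoded independently merge to exactly
the single-pass result, which is what makes decoding embarrassingly
parallel.  The final products are the "cube" CSV of raw and UMI-corrected
counts per compound and condition, and a failure report (JSON + HTML).
"""

from __future__ import annotations

import gzip
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import AlignmentHit, semi_global_align
from .barcodes import build_code, build_lookup_decoder
from .config import LibrarySpec, SelectionSpec
from .simulate import reverse_complement

STATUSES = ("decoded", "no_library_match", "schema_align_failed",
            "bb_tag_invalid", "umi_missing")


@dataclass
class DecodeOutcome:
    read_id: str
    status: str
    library_id: Optional[str] = None
    compound_id: Optional[str] = None
    umi: Optional[str] = None
    failed_cycle: Optional[str] = None
    corrected_tags: int = 0


class _TagCaller:
    """Per-cycle tag decoder for one library, per its correction mode."""

    def __init__(self, library: LibrarySpec):
        self.mode = library.error_correction_mode
        self._by_cycle = {}
        for bs in library.bb_sets:
            tag_to_id = {b.dna_tag: b.bb_id for b in bs.blocks}
            if self.mode == "hamming":
                code = build_code(bs.tag_length, parity=library.hamming_parity)
                self._by_cycle[bs.cycle_label] = ("hamming", code, tag_to_id,
                                                  bs.tag_length)
            elif self.mode == "lookup":
                dec = build_lookup_decoder(list(tag_to_id))
                self._by_cycle[bs.cycle_label] = ("lookup", dec, tag_to_id,
                                                  bs.tag_length)
            else:
                self._by_cycle[bs.cycle_label] = ("none", None, tag_to_id,
                                                  bs.tag_length)

    def call(self, cycle: str, observed: str) -> tuple[Optional[str], bool]:
        """Returns (bb_id or None, was_corrected)."""
        kind, engine, tag_to_id, length = self._by_cycle[cycle]
        if len(observed) != length or any(c not in "ACGT" for c in observed):
            return None, False
        if kind == "none":
            return tag_to_id.get(observed), False
        res = engine.decode_tag(observed)
        if res.status not in ("valid", "corrected"):
            return None, False
        bb = tag_to_id.get(res.codeword)
        if bb is None:
            # corrected onto a codeword this library does not use
            return None, False
        return bb, res.status == "corrected"


class LibraryDecoder:
    """Precomputed matching machinery for one library."""

    def __init__(self, library: LibrarySpec):
        self.library = library
        self.reference = library.schema.reference()
        self.offsets = library.schema.section_offsets()
        self.tag_caller = _TagCaller(library)
        # exact-match regex: constants literal, variable sections any base;
        # one group per section so spans come straight from the match
        parts = []
        self._group_names = []
        for i, sec in enumerate(library.schema.sections):
            gname = f"s{i}"
            self._group_names.append(sec.name)
            if sec.sequence is not None:
                parts.append(f"(?P<{gname}>{re.escape(sec.sequence)})")
            else:
                parts.append(f"(?P<{gname}>[ACGT]{{{sec.length}}})")
        self._regex = re.compile("".join(parts))

    def exact_schema_match(self, read: str) -> Optional[dict[str, tuple[int, int]]]:
        m = self._regex.search(read)
        if m is None:
            return None
        return {name: m.span(i + 1)
                for i, name in enumerate(self._group_names)}

    def schema_spans(self, read: str, max_error_rate: float,
                     ) -> Optional[dict[str, tuple[int, int]]]:
        hit = align_schema(read, self.library.schema, max_error_rate,
                           reference=self.reference, offsets=self.offsets)
        return hit.section_spans if hit else None


# ---------------------------------------------------------------------------
# stage operations (exposed individually; decode_read composes them)


def match_library(read: str, libraries: Sequence[LibrarySpec],
                  max_error_rate: float) -> Optional[str]:
    """Library whose demultiplexing tag aligns with fewest errors, or None.

    Orientation handling lives in :func:`decode_read`; this operation
    matches against the read as given.
    """
    best: tuple[int, int, str] | None = None
    for lib in libraries:
        if lib.library_tag in read:
            hit_errors, score = 0, len(lib.library_tag)
        else:
            hit = semi_global_align(read, lib.library_tag,
                                    max_error_rate=max_error_rate)
            if hit is None:
                continue
            hit_errors, score = hit.errors, hit.score
        cand = (hit_errors, -score, lib.library_id)
        if best is None or cand < best:
            best = cand
    return best[2] if best else None


def align_schema(read: str, schema, max_error_rate: float,
                 reference: Optional[str] = None,
                 offsets=None) -> Optional[AlignmentHit]:
    """Align the full barcode reference and recover per-section read spans."""
    if reference is None:
        reference = schema.reference()
    if offsets is None:
        offsets = schema.section_offsets()
    hit = semi_global_align(read, reference, max_error_rate=max_error_rate)
    if hit is None:
        return None
    hit.section_spans = {name: hit.span_for(a, b)
                         for name, (a, b) in offsets.items()}
    return hit


def _decode_with_spans(read: str, decoder: LibraryDecoder,
                       spans: dict[str, tuple[int, int]],
                       read_id: str) -> DecodeOutcome:
    lib = decoder.library
    bb_ids = []
    corrected = 0
    for sec in lib.schema.bb_tag_sections():
        a, b = spans[sec.name]
        bb, was_corrected = decoder.tag_caller.call(sec.cycle, read[a:b])
        if bb is None:
            return DecodeOutcome(read_id=read_id, status="bb_tag_invalid",
                                 library_id=lib.library_id,
                                 failed_cycle=sec.cycle,
                                 corrected_tags=corrected)
        corrected += was_corrected
        bb_ids.append(bb)
    umi = None
    umi_sec = lib.schema.umi_section()
    if umi_sec is not None:
        a, b = spans[umi_sec.name]
        if b <= a:
            return DecodeOutcome(read_id=read_id, status="umi_missing",
                                 library_id=lib.library_id,
                                 corrected_tags=corrected)
        umi = read[a:b]
    compound_id = "-".join([lib.library_id] + bb_ids)
    return DecodeOutcome(read_id=read_id, status="decoded",
                         library_id=lib.library_id, compound_id=compound_id,
                         umi=umi, corrected_tags=corrected)


def decode_read(read: str, selection: SelectionSpec,
                decoders: Optional[dict[str, LibraryDecoder]] = None,
                read_id: str = "") -> DecodeOutcome:
    """Decode one read against every library of the selection.

    Both the read and its reverse complement are considered; the
    orientation with the better library-tag alignment wins.  An exact
    full-schema match (regex) short-circuits the alignment stages.
    """
    if decoders is None:
        decoders = build_decoders(selection)
    settings = selection.decode_settings
    strands = (read, reverse_complement(read))

    # fast path: exact schema match on either strand for any library
    for oriented in strands:
        for dec in decoders.values():
            spans = dec.exact_schema_match(oriented)
            if spans is not None:
                return _decode_with_spans(oriented, dec, spans, read_id)

    # stage 1: library match, best over strands
    best: tuple[int, int, str, str] | None = None  # errors, -score, lib, strand
    for oriented in strands:
        for lib in selection.libraries:
            if lib.library_tag in oriented:
                cand = (0, -len(lib.library_tag), lib.library_id, oriented)
            else:
                hit = semi_global_align(oriented, lib.library_tag,
                                        max_error_rate=settings.library_error_rate)
                if hit is None:
                    continue
                cand = (hit.errors, -hit.score, lib.library_id, oriented)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        return DecodeOutcome(read_id=read_id, status="no_library_match")
    _, _, library_id, oriented = best
    dec = decoders[library_id]

    # stage 2: schema alignment
    spans = dec.schema_spans(oriented, settings.schema_error_rate)
    if spans is None:
        return DecodeOutcome(read_id=read_id, status="schema_align_failed",
                             library_id=library_id)

    # stages 3-4: tag calling and UMI extraction
    return _decode_with_spans(oriented, dec, spans, read_id)


def build_decoders(selection: SelectionSpec) -> dict[str, LibraryDecoder]:
    return {lib.library_id: LibraryDecoder(lib)
            for lib in selection.libraries}


# ---------------------------------------------------------------------------
# UMI state and cube


class UMIState:
    """Mergeable per-(condition, compound) counting state.

    Holds raw tallies and the multiset of observed UMIs per compound.  The
    UMI-corrected count is the number of distinct UMIs (``exact`` mode) or
    of greedy Hamming-distance-1 clusters (``cluster1`` mode).  Merging two
    states sums tallies and adds UMI multisets, which is associative and
    commutative, so any sharding of the read stream reproduces the
    single-pass state.
    """

    def __init__(self, selection_id: str, umi_mode: str = "exact"):
        self.selection_id = selection_id
        self.umi_mode = umi_mode
        # condition -> compound_id -> [raw_count, Counter(umi)]
        self.data: dict[str, dict[str, list]] = {}
        self.libraries: dict[str, str] = {}  # compound_id -> library_id

    def observe(self, condition: str, outcome: DecodeOutcome) -> None:
        if outcome.status != "decoded":
            return
        per_cond = self.data.setdefault(condition, {})
        entry = per_cond.setdefault(outcome.compound_id, [0, Counter()])
        entry[0] += 1
        if outcome.umi is not None:
            entry[1][outcome.umi] += 1
        self.libraries[outcome.compound_id] = outcome.library_id

    def raw_count(self, condition: str, compound_id: str) -> int:
        return self.data.get(condition, {}).get(compound_id, [0, Counter()])[0]

    def umi_count(self, condition: str, compound_id: str) -> int:
        entry = self.data.get(condition, {}).get(compound_id)
        if entry is None:
            return 0
        raw, umis = entry
        if not umis:
            return raw  # library without a UMI section: no deduplication
        if self.umi_mode == "cluster1":
            return _cluster1_count(umis)
        return len(umis)

    def merge_in(self, other: "UMIState") -> None:
        if other.selection_id != self.selection_id:
            raise ValueError(
                f"cannot merge UMI states from different selections "
                f"({self.selection_id!r} vs {other.selection_id!r})")
        for cond, per_cond in other.data.items():
            mine = self.data.setdefault(cond, {})
            for compound, (raw, umis) in per_cond.items():
                entry = mine.setdefault(compound, [0, Counter()])
                entry[0] += raw
                entry[1].update(umis)
        self.libraries.update(other.libraries)

    def to_dict(self) -> dict:
        return {
            "selection_id": self.selection_id,
            "umi_mode": self.umi_mode,
            "libraries": self.libraries,
            "conditions": {
                cond: {compound: {"raw": raw, "umis": dict(umis)}
                       for compound, (raw, umis) in per_cond.items()}
                for cond, per_cond in self.data.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "UMIState":
        state = cls(payload["selection_id"], payload.get("umi_mode", "exact"))
        state.libraries = dict(payload.get("libraries", {}))
        for cond, per_cond in payload["conditions"].items():
            state.data[cond] = {
                compound: [entry["raw"], Counter(entry["umis"])]
                for compound, entry in per_cond.items()
            }
        return state


def _cluster1_count(umis: Counter) -> int:
    """Greedy UMI clustering: descending count, join to an existing cluster
    representative within Hamming distance 1, ties broken lexicographically."""
    reps: list[str] = []
    for umi in sorted(umis, key=lambda u: (-umis[u], u)):
        for rep in reps:
            if len(rep) == len(umi) and \
                    sum(a != b for a, b in zip(rep, umi)) <= 1:
                break
        else:
            reps.append(umi)
    return len(reps)


def save_umi_state(state: UMIState, path) -> None:
    Path(path).write_text(json.dumps(state.to_dict(), sort_keys=True) + "\n")


def load_umi_state(path) -> UMIState:
    return UMIState.from_dict(json.loads(Path(path).read_text()))


def merge_umi_states(paths_or_states: Sequence) -> UMIState:
    """Merge shard states (paths or UMIState objects) into one."""
    if not paths_or_states:
        raise ValueError("nothing to merge")
    states = [s if isinstance(s, UMIState) else load_umi_state(s)
              for s in paths_or_states]
    merged = UMIState(states[0].selection_id, states[0].umi_mode)
    for s in states:
        merged.merge_in(s)
    return merged


# ---------------------------------------------------------------------------
# report tallies


@dataclass
class DecodeReport:
    selection_id: str
    total_reads: int = 0
    status_counts: Counter = field(default_factory=Counter)
    per_condition: dict[str, Counter] = field(default_factory=dict)

    def observe(self, condition: str, outcome: DecodeOutcome) -> None:
        self.total_reads += 1
        self.status_counts[outcome.status] += 1
        self.per_condition.setdefault(condition, Counter())[outcome.status] += 1

    @property
    def decoded_fraction(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.status_counts.get("decoded", 0) / self.total_reads


# ---------------------------------------------------------------------------
# FASTQ streaming and the full run


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from FASTQ or FASTQ.gz, with file and
    record index in any parse error."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    index = 0
    try:
        with opener(path, "rt") as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper()
                index += 1
    except FileNotFoundError:
        raise
    except (ValueError, EOFError, OSError) as exc:
        raise ValueError(
            f"{path}: malformed FASTQ at record {index}: {exc}") from exc


def run_decoding(selection: SelectionSpec,
                 reads_by_condition: Optional[dict[str, Iterable[tuple[str, str]]]] = None,
                 ) -> tuple[pd.DataFrame, DecodeReport, UMIState]:
    """Decode every read of a selection; returns (cube, report, UMI state).

    By default reads stream from the selection's FASTQ files; tests and the
    shard/merge machinery may inject ``reads_by_condition`` directly
    (condition key -> iterable of (read_id, sequence)).
    """
    decoders = build_decoders(selection)
    state = UMIState(selection.selection_id,
                     selection.decode_settings.umi_mode)
    report = DecodeReport(selection_id=selection.selection_id)
    for cond in selection.conditions:
        if reads_by_condition is not None:
            stream: Iterable[tuple[str, str]] = reads_by_condition.get(cond.key, [])
        else:
            def _chain(files=cond.read_files):
                for f in files:
                    yield from iter_fastq(f)
            stream = _chain()
        for read_id, seq in stream:
            outcome = decode_read(seq, selection, decoders, read_id=read_id)
            report.observe(cond.key, outcome)
            state.observe(cond.key, outcome)
    cube = build_cube(selection, state)
    return cube, report, state


# ---------------------------------------------------------------------------
# cube table


def build_cube(selection: SelectionSpec, state: UMIState) -> pd.DataFrame:
    """Assemble the per-compound count table from a UMI state.

    Columns: compound_id, library_id, one ``bb_i`` column per cycle (in
    cycle order; ragged libraries pad with empty strings), then
    ``<condition>_raw_count`` and ``<condition>_umi_count`` per condition.
    Compounds observed in any condition appear; unobserved conditions get
    zero counts.  Rows are sorted by compound_id.
    """
    n_cycles = {lib.library_id: len(lib.bb_sets)
                for lib in selection.libraries}
    max_cycles = max(n_cycles.values(), default=0)
    cond_keys = [c.key for c in selection.conditions]
    compounds = sorted({compound
                        for per_cond in state.data.values()
                        for compound in per_cond})
    rows = []
    for compound in compounds:
        library_id = state.libraries[compound]
        bb_ids = compound.rsplit("-", n_cycles[library_id])[1:]
        row = {"compound_id": compound, "library_id": library_id}
        for i in range(max_cycles):
            row[f"bb_{i + 1}"] = bb_ids[i] if i < len(bb_ids) else ""
        for key in cond_keys:
            row[f"{key}_raw_count"] = state.raw_count(key, compound)
            row[f"{key}_umi_count"] = state.umi_count(key, compound)
        rows.append(row)
    columns = (["compound_id", "library_id"]
               + [f"bb_{i + 1}" for i in range(max_cycles)]
               + [c for key in cond_keys
                  for c in (f"{key}_raw_count", f"{key}_umi_count")])
    return pd.DataFrame(rows, columns=columns)


def write_cube(cube: pd.DataFrame, path) -> None:
    """Deterministic CSV: rows sorted by compound_id, LF line endings."""
    out = cube.sort_values("compound_id", kind="mergesort")
    out.to_csv(path, index=False, lineterminator="\n")


def read_cube(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in df.columns:
        if col.endswith("_count"):
            df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# report rendering


def build_report(report: DecodeReport, state: UMIState,
                 library_share_cutoff: float = 0.01) -> tuple[dict, str]:
    """Summarise a decoding run as (JSON-ready dict, HTML string).

    Failure-cause proportions are over *all* input reads (decoded included)
    and sum to 1.  Per-library shares of UMI-corrected counts pool every
    library below the cutoff (default 1%) into "other".
    """
    total = report.total_reads
    proportions = {status: (report.status_counts.get(status, 0) / total
                            if total else 0.0)
                   for status in STATUSES}

    lib_umi: Counter = Counter()
    for cond, per_cond in state.data.items():
        for compound in per_cond:
            lib_umi[state.libraries[compound]] += state.umi_count(cond, compound)
    lib_total = sum(lib_umi.values())
    shares: dict[str, float] = {}
    other = 0.0
    for lib, count in sorted(lib_umi.items()):
        share = count / lib_total if lib_total else 0.0
        if share >= library_share_cutoff:
            shares[lib] = share
        else:
            other += share
    if other > 0:
        shares["other"] = other

    summary = {
        "selection_id": report.selection_id,
        "total_reads": total,
        "status_counts": dict(report.status_counts),
        "status_proportions": proportions,
        "per_condition": {c: dict(v) for c, v in report.per_condition.items()},
        "decoded_fraction": report.decoded_fraction,
        "library_umi_shares": shares,
    }

    def table(d: dict, fmt=lambda v: f"{v}") -> str:
        rows = "".join(f"<tr><td>{k}</td><td>{fmt(v)}</td></tr>"
                       for k, v in d.items())
        return f"<table>{rows}</table>"

    html = (
        "<html><head><title>Decoding report: "
        f"{report.selection_id}</title></head><body>"
        f"<h1>Decoding report: {report.selection_id}</h1>"
        f"<p>Total reads: {total}; decoded fraction: "
        f"{report.decoded_fraction:.4f}</p>"
        "<h2>Read outcomes</h2>"
        + table(proportions, fmt=lambda v: f"{100 * v:.2f}%")
        + "<h2>Library shares of UMI-corrected counts</h2>"
        + table(shares, fmt=lambda v: f"{100 * v:.2f}%")
        + "</body></html>"
    )
    return summary, html
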
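"""Decoding pipeline: stage behaviour, conservation, shard/merge, cube I/O."""

import json
from collections import Counter

import numpy as np
import pytest

from delkit.config import Condition, SelectionSpec
from delkit.decode import (UMIState, build_cube, build_decoders, build_report,
                           decode_read, iter_fastq, load_umi_state,
                           match_library, merge_umi_states, read_cube,
                           run_decoding, save_umi_state, write_cube)
from delkit.simulate import (make_synthetic_library, render_barcode,
                             reverse_complement, simulate_selection,
                             write_fastq)
from tests.conftest import selection_for


@pytest.fixture(scope="module")
def lib():
    return make_synthetic_library(n_cycles=3, blocks_per_cycle=8, seed=11)


@pytest.fixture(scope="module")
def selection(lib):
    return selection_for(lib)


@pytest.fixture(scope="module")
def decoders(selection):
    return build_decoders(selection)


def clean_read(lib, indices=(0, 0, 0), umi="ACGTACGTAC", flanks=("", "")):
    return flanks[0] + render_barcode(lib, indices, umi) + flanks[1]


class TestMatchLibrary:
    def test_exact_tag(self, lib):
        read = "T" * 5 + lib.library_tag + "G" * 5
        assert match_library(read, [lib], 0.1) == lib.library_id

    def test_one_substitution_within_tolerance(self, lib):
        tag = list(lib.library_tag)
        tag[4] = "A" if tag[4] != "A" else "C"
        read = "T" * 5 + "".join(tag) + "G" * 5
        assert match_library(read, [lib], 0.1) == lib.library_id

    def test_random_read_no_match(self, lib):
        rng = np.random.default_rng(0)
        misses = 0
        for _ in range(20):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            misses += match_library(read, [lib], 0.1) is None
        assert misses >= 18  # 10-bp tag at <=1 error almost never by chance


class TestDecodeRead:
    def test_clean_read_decodes_to_truth(self, lib, selection, decoders):
        out = decode_read(clean_read(lib, (1, 2, 3), flanks=("TTT", "AA")),
                          selection, decoders)
        assert out.status == "decoded"
        assert out.compound_id == f"{lib.library_id}-A002-B003-C004"
        assert out.umi == "ACGTACGTAC"
        assert out.corrected_tags == 0

    def test_reverse_complement_read_decodes(self, lib, selection, decoders):
        read = reverse_complement(clean_read(lib, (1, 2, 3)))
        out = decode_read(read, selection, decoders)
        assert out.status == "decoded"
        assert out.compound_id == f"{lib.library_id}-A002-B003-C004"

    def test_single_tag_substitution_corrected(self, lib, selection, decoders):
        read = clean_read(lib, (0, 5, 0))
        # cycle-B tag occupies schema offsets: locate and mutate one base
        off = lib.schema.section_offsets()["bb_B"]
        pos = off[0] + 3
        mutated = read[:pos] + ("A" if read[pos] != "A" else "C") + read[pos + 1:]
        out = decode_read(mutated, selection, decoders)
        assert out.status == "decoded"
        assert out.corrected_tags == 1
        assert out.compound_id == f"{lib.library_id}-A001-B006-C001"

    def test_double_tag_substitution_flagged_or_miscalled(self, lib, selection,
                                                          decoders):
        """Distance-3 tags: two substitutions are either flagged with the
        failing cycle or (rarely) silently miscalled; never crash."""
        read = clean_read(lib, (0, 5, 0))
        a, _ = lib.schema.section_offsets()["bb_B"]
        flagged = miscalled = correct = 0
        for i, j in [(0, 1), (2, 4), (3, 6), (1, 7), (5, 6)]:
            m = list(read)
            for p in (a + i, a + j):
                m[p] = "A" if m[p] != "A" else "C"
            out = decode_read("".join(m), selection, decoders)
            if out.status == "bb_tag_invalid":
                assert out.failed_cycle == "B"
                flagged += 1
            elif out.status == "decoded":
                if out.compound_id == f"{lib.library_id}-A001-B006-C001":
                    correct += 1
                else:
                    miscalled += 1
        assert flagged + miscalled + correct == 5
        assert flagged >= 1

    def test_garbage_read_is_no_library_match(self, selection, decoders):
        out = decode_read("ACGT" * 10, selection, decoders)
        assert out.status == "no_library_match"

    def test_truncated_read_fails_schema_alignment(self, lib, selection,
                                                   decoders):
        read = clean_read(lib)[:30]  # library tag present, barcode cut short
        out = decode_read(read, selection, decoders)
        assert out.status in ("schema_align_failed", "bb_tag_invalid",
                              "umi_missing")
        assert out.status != "decoded"


class TestRunDecoding:
    def test_zero_error_run_is_lossless(self, lib, selection):
        reads, truth = simulate_selection(lib, None, 1500, 0, 0, seed=21)
        cube, report, state = run_decoding(
            selection, reads_by_condition={"target/1": reads})
        assert report.decoded_fraction == 1.0
        # raw counts equal the simulator's multinomial draw exactly
        sampled = truth.sampled_counts
        got = dict(zip(cube["compound_id"], cube["target/1_raw_count"]))
        assert got == sampled
        # unique-per-molecule UMIs: corrected == raw
        assert (cube["target/1_umi_count"] <= cube["target/1_raw_count"]).all()

    def test_read_conservation_with_errors(self, lib, selection):
        reads, _ = simulate_selection(lib, None, 1200, 0.02, 0.005, seed=22)
        _, report, _ = run_decoding(selection,
                                    reads_by_condition={"target/1": reads})
        assert sum(report.status_counts.values()) == 1200
        assert report.total_reads == 1200

    def test_decode_rate_monotone_in_substitution_rate(self, lib, selection):
        fractions = []
        for rate in (0.0, 0.005, 0.02, 0.05):
            reads, _ = simulate_selection(lib, None, 600, rate, 0.0, seed=23)
            _, report, _ = run_decoding(selection,
                                        reads_by_condition={"target/1": reads})
            fractions.append(report.decoded_fraction)
        assert fractions == sorted(fractions, reverse=True)

    def test_empty_input_gives_empty_cube(self, selection):
        cube, report, _ = run_decoding(selection,
                                       reads_by_condition={"target/1": []})
        assert len(cube) == 0 and report.total_reads == 0

    def test_fastq_file_roundtrip(self, tmp_path, lib):
        reads, _ = simulate_selection(lib, None, 300, 0.005, 0.001, seed=24)
        fq = tmp_path / "cond.fastq.gz"
        write_fastq(reads, fq)
        sel = SelectionSpec(
            selection_id="TEST_SEL", libraries=[lib],
            conditions=[Condition("target", "1", [fq])])
        cube_f, report_f, _ = run_decoding(sel)
        _, report_m, _ = run_decoding(sel,
                                      reads_by_condition={"target/1": reads})
        assert report_f.status_counts == report_m.status_counts

    def test_malformed_fastq_names_file_and_record(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n")  # truncated record
        with pytest.raises(ValueError, match=r"bad\.fastq.*record 1"):
            list(iter_fastq(bad))


class TestShardMerge:
    def test_any_partition_merges_to_single_pass(self, tmp_path, lib,
                                                 selection):
        reads, _ = simulate_selection(lib, None, 2000, 0.005, 0.001, seed=25)
        cube_single, _, state_single = run_decoding(
            selection, reads_by_condition={"target/1": reads})
        shard_states = []
        for k in range(4):
            shard = reads[k::4]  # interleaved 4-way split
            _, _, st = run_decoding(selection,
                                    reads_by_condition={"target/1": shard})
            p = tmp_path / f"shard{k}.json"
            save_umi_state(st, p)
            shard_states.append(p)
        merged = merge_umi_states(shard_states)
        cube_merged = build_cube(selection, merged)
        single_csv, merged_csv = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cube(cube_single, single_csv)
        write_cube(cube_merged, merged_csv)
        assert single_csv.read_bytes() == merged_csv.read_bytes()

    def test_merge_identity_and_commutativity(self, lib, selection):
        reads, _ = simulate_selection(lib, None, 400, 0.0, 0.0, seed=26)
        _, _, a = run_decoding(selection,
                               reads_by_condition={"target/1": reads[:200]})
        _, _, b = run_decoding(selection,
                               reads_by_condition={"target/1": reads[200:]})
        assert merge_umi_states([a]).to_dict() == a.to_dict()
        assert merge_umi_states([a, b]).to_dict() == \
            merge_umi_states([b, a]).to_dict()

    def test_selection_mismatch_rejected(self):
        a, b = UMIState("S1"), UMIState("S2")
        with pytest.raises(ValueError, match="different selections"):
            a.merge_in(b)

    def test_state_json_roundtrip(self, tmp_path, lib, selection):
        reads, _ = simulate_selection(lib, None, 150, 0.0, 0.0, seed=27)
        _, _, state = run_decoding(selection,
                                   reads_by_condition={"target/1": reads})
        p = tmp_path / "state.json"
        save_umi_state(state, p)
        assert load_umi_state(p).to_dict() == state.to_dict()


class TestUMIModes:
    def test_umi_count_bounded_by_raw(self):
        state = UMIState("S", "exact")
        from delkit.decode import DecodeOutcome
        for umi in ["AAAA", "AAAA", "CCCC"]:
            state.observe("c", DecodeOutcome("r", "decoded", "L", "L-A1-B1",
                                             umi))
        assert state.raw_count("c", "L-A1-B1") == 3
        assert state.umi_count("c", "L-A1-B1") == 2

    def test_cluster1_merges_near_duplicates(self):
        state = UMIState("S", "cluster1")
        from delkit.decode import DecodeOutcome
        # AAAA (x3), AAAT (1 error of AAAA), GGGG -> 2 clusters
        for umi in ["AAAA", "AAAA", "AAAA", "AAAT", "GGGG"]:
            state.observe("c", DecodeOutcome("r", "decoded", "L", "L-A1-B1",
                                             umi))
        assert state.umi_count("c", "L-A1-B1") == 2


class TestCubeAndReport:
    def _tiny_state(self):
        from delkit.decode import DecodeOutcome
        state = UMIState("TEST_SEL")
        rows = [("c1/1", "L1-A001-B001-C001", "AAAA"),
                ("c1/1", "L1-A001-B001-C001", "CCCC"),
                ("c1/1", "L1-A002-B001-C001", "AAAA"),
                ("c2/1", "L1-A003-B002-C002", "GGGG")]
        for cond, cid, umi in rows:
            out = DecodeOutcome("r", "decoded", "L1", cid, umi)
            state.observe(cond, out)
        return state

    def _two_cond_selection(self, lib):
        sel = selection_for(lib, conditions=("c1/1", "c2/1"))
        sel.libraries[0].library_id = lib.library_id
        return sel

    def test_cube_layout_and_sparsity(self, lib):
        state = self._tiny_state()
        state.libraries = {c: "L1" for c in state.libraries}
        lib2 = make_synthetic_library(n_cycles=3, blocks_per_cycle=8, seed=11,
                                      library_id="L1")
        sel = selection_for(lib2, conditions=("c1/1", "c2/1"))
        cube = build_cube(sel, state)
        assert list(cube.columns) == [
            "compound_id", "library_id", "bb_1", "bb_2", "bb_3",
            "c1/1_raw_count", "c1/1_umi_count",
            "c2/1_raw_count", "c2/1_umi_count"]
        assert len(cube) == 3
        row = cube.set_index("compound_id").loc["L1-A003-B002-C002"]
        assert row["c1/1_raw_count"] == 0 and row["c2/1_raw_count"] == 1
        assert row["bb_1"] == "A003"

    def test_cube_csv_roundtrip(self, tmp_path, lib):
        lib2 = make_synthetic_library(n_cycles=3, blocks_per_cycle=8, seed=11,
                                      library_id="L1")
        sel = selection_for(lib2, conditions=("c1/1", "c2/1"))
        cube = build_cube(sel, self._tiny_state())
        path = tmp_path / "cube.csv"
        write_cube(cube, path)
        back = read_cube(path)
        assert back.equals(cube.sort_values("compound_id")
                           .reset_index(drop=True))

    def test_report_proportions_sum_to_one(self, lib, selection):
        reads, _ = simulate_selection(lib, None, 500, 0.02, 0.005, seed=28)
        _, report, state = run_decoding(selection,
                                        reads_by_condition={"target/1": reads})
        summary, html = build_report(report, state)
        assert sum(summary["status_proportions"].values()) == \
            pytest.approx(1.0, abs=1e-9)
        assert "Decoding report" in html

    def test_small_library_share_pooled_into_other(self):
        state = UMIState("S")
        from delkit.decode import DecodeOutcome
        for i in range(199):
            state.observe("c", DecodeOutcome(f"r{i}", "decoded", "BIG",
                                             f"BIG-A{i}-B1", f"U{i}"))
        state.observe("c", DecodeOutcome("rx", "decoded", "TINY",
                                         "TINY-A1-B1", "U"))
        from delkit.decode import DecodeReport
        report = DecodeReport("S", total_reads=200,
                              status_counts=Counter(decoded=200))
        summary, _ = build_report(report, state)
        shares = summary["library_umi_shares"]
        assert "TINY" not in shares and shares["other"] == pytest.approx(0.005)
        assert shares["BIG"] == pytest.approx(0.995)
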
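"""Chromosome assignment, ordering, pseudomolecule assembly, accounting."""

import pandas as pd
import pytest

from optscaf.core import SequenceRecord
from optscaf.pseudomolecule import (
    CHRUN,
    ChromAssignment,
    assign_chromosomes,
    build_pseudomolecules,
    compare_layouts,
    emit_pseudomolecule_fasta,
    gene_accounting,
    ledger_summary,
    merge_marker_maps,
    order_and_orient,
    read_markers,
    remap_markers,
    report_tables,
    write_markers,
)


def mk_markers(rows):
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "cm", "scaffold_id", "pos"])


class TestAssignment:
    def test_single_marker_not_anchored(self):
        markers = mk_markers([("m1", "2A", 10.0, "s", 100)])
        assignments, _ = assign_chromosomes(markers, ["s"])
        assert assignments == []

    def test_majority_wins_minority_logged(self):
        rows = [(f"m{i}", "2A", float(i), "s", 100 * i) for i in range(5)]
        rows.append(("mX", "3B", 50.0, "s", 900))
        assignments, discordant = assign_chromosomes(mk_markers(rows), ["s"])
        assert len(assignments) == 1
        a = assignments[0]
        assert (a.chrom, a.n_markers) == ("2A", 5)
        assert list(discordant["marker_id"]) == ["mX"]

    def test_majority_tie_goes_unassigned(self):
        rows = [("m1", "2A", 1.0, "s", 10), ("m2", "2A", 2.0, "s", 20),
                ("m3", "3B", 1.0, "s", 30), ("m4", "3B", 2.0, "s", 40)]
        assignments, _ = assign_chromosomes(mk_markers(rows), ["s"])
        assert assignments == []

    def test_simulated_assignments_fully_correct(self, rng):
        # 20 scaffolds, >= 2 concordant markers each, no noise
        rows = []
        truth = {}
        chroms = ["1A", "1B", "2A", "2B"]
        for i in range(20):
            chrom = chroms[i % 4]
            truth[f"s{i}"] = chrom
            for j in range(int(rng.integers(2, 6))):
                rows.append((f"m{i}_{j}", chrom, float(i * 10 + j), f"s{i}", 1000 * (j + 1)))
        assignments, discordant = assign_chromosomes(mk_markers(rows), truth)
        assert len(assignments) == 20
        assert discordant.empty
        assert all(a.chrom == truth[a.scaffold_id] for a in assignments)


class TestOrderAndOrient:
    def test_cm_increasing_with_bp_is_plus(self):
        markers = mk_markers([("m1", "1A", 5.0, "s", 100), ("m2", "1A", 9.0, "s", 900)])
        assignments, _ = assign_chromosomes(markers, ["s"])
        ordered = order_and_orient(assignments, markers, {"s": 1000})
        a = ordered["1A"][0]
        assert (a.orientation, a.orientation_determined) == ("+", True)

    def test_cm_decreasing_with_bp_is_minus(self):
        markers = mk_markers([("m1", "1A", 9.0, "s", 100), ("m2", "1A", 5.0, "s", 900)])
        assignments, _ = assign_chromosomes(markers, ["s"])
        a = order_and_orient(assignments, markers, {"s": 1000})["1A"][0]
        assert (a.orientation, a.orientation_determined) == ("-", True)

    def test_single_cm_value_undetermined_flagged_plus(self):
        markers = mk_markers([("m1", "1A", 5.0, "s", 100), ("m2", "1A", 5.0, "s", 900)])
        assignments, _ = assign_chromosomes(markers, ["s"])
        a = order_and_orient(assignments, markers, {"s": 1000})["1A"][0]
        assert (a.orientation, a.orientation_determined) == ("+", False)

    def test_order_by_mean_cm_with_length_tiebreak(self):
        rows = [("m1", "1A", 10.0, "a", 1), ("m2", "1A", 10.0, "a", 2),
                ("m3", "1A", 10.0, "b", 1), ("m4", "1A", 10.0, "b", 2),
                ("m5", "1A", 2.0, "c", 1), ("m6", "1A", 3.0, "c", 2)]
        markers = mk_markers(rows)
        assignments, _ = assign_chromosomes(markers, ["a", "b", "c"])
        ordered = order_and_orient(assignments, markers, {"a": 100, "b": 500, "c": 50})
        assert [x.scaffold_id for x in ordered["1A"]] == ["c", "b", "a"]

    def test_zero_noise_simulation_recovers_order_and_orientation(self, rng):
        # 4 chromosomes x 10 scaffolds laid end to end; cM strictly
        # increasing along each chromosome
        rows = []
        truth = []
        for chrom in ["1A", "1B", "2A", "2B"]:
            pos_cm = 0.0
            for i in range(10):
                sid = f"{chrom}_s{i}"
                orient = "+" if rng.random() < 0.5 else "-"
                truth.append((chrom, sid, orient))
                for j in range(4):
                    bp = 1000 + j * 2500
                    cm = pos_cm + (j if orient == "+" else 3 - j) * 0.05
                    rows.append((f"{sid}_m{j}", chrom, cm, sid, bp))
                pos_cm += 1.0
        markers = mk_markers(rows)
        ids = [t[1] for t in truth]
        assignments, _ = assign_chromosomes(markers, ids)
        ordered = order_and_orient(assignments, markers, {i: 10_000 for i in ids})
        for chrom in ["1A", "1B", "2A", "2B"]:
            expect = [(sid, o) for c, sid, o in truth if c == chrom]
            got = [(a.scaffold_id, a.orientation) for a in ordered[chrom]]
            assert got == expect


class TestBuildPseudomolecules:
    def test_join_arithmetic_single_member_chromosomes(self):
        ordered = {c: [ChromAssignment(f"s{c}", c, 2, 1.0)] for c in ["1A", "1B"]}
        lengths = {"s1A": 1000, "s1B": 2000}
        pset = build_pseudomolecules(ordered, lengths, lengths.keys())
        assert pset.chromosomes == {"1A": 1000, "1B": 2000}
        assert pset.total_unknown_gaps == 0
        assert pset.chrun == []

    def test_join_arithmetic_general(self):
        # 485 anchored scaffolds over 14 chromosomes with 1000-N joins
        lengths = {}
        ordered = {}
        chroms = [f"{i}{g}" for i in range(1, 8) for g in "AB"]
        total_member_bp = 10_330_081_199
        counts = [35] * 13 + [30]  # 485 members
        base = total_member_bp // 485
        k = 0
        members_made = []
        for chrom, cnt in zip(chroms, counts):
            ordered[chrom] = []
            for i in range(cnt):
                sid = f"scf{k}"
                L = base + (total_member_bp - base * 485 if k == 484 else 0)
                lengths[sid] = L
                ordered[chrom].append(ChromAssignment(sid, chrom, 2, float(i)))
                members_made.append(sid)
                k += 1
        pset = build_pseudomolecules(ordered, lengths, members_made)
        assert sum(lengths.values()) == total_member_bp
        assert sum(pset.chromosomes.values()) == 10_330_552_199
        assert pset.total_unknown_gaps == 485 - 14 == 471

    def test_agp_reconstruction_bit_identical(self, rng):
        recs = {}
        ordered = {"1A": [], "1B": []}
        for i in range(6):
            bases = "".join(rng.choice(list("ACGT"), int(rng.integers(100, 500))))
            sid = f"s{i}"
            recs[sid] = SequenceRecord(sid, bases)
            chrom = "1A" if i < 3 else "1B"
            ordered[chrom].append(
                ChromAssignment(sid, chrom, 2, float(i), "-" if i % 2 else "+")
            )
        lengths = {k: v.length_bp for k, v in recs.items()}
        pset = build_pseudomolecules(ordered, lengths, lengths.keys())
        chrom_seqs = emit_pseudomolecule_fasta(pset, recs)
        for rec in chrom_seqs:
            assert rec.length_bp == pset.chromosomes[rec.seq_id]
            assert rec.bases.count("N") == 1000 * (len(pset.members_of(rec.seq_id)) - 1)

    def test_partition_anchored_plus_chrun(self):
        ordered = {"1A": [ChromAssignment("a", "1A", 2, 1.0)]}
        pset = build_pseudomolecules(ordered, {"a": 100, "b": 50, "c": 70}, ["a", "b", "c"])
        assert set(pset.anchored) | set(pset.chrun) == {"a", "b", "c"}
        assert set(pset.anchored) & set(pset.chrun) == set()


class TestGeneAccounting:
    def _pset(self):
        ordered = {
            "1A": [ChromAssignment("s1", "1A", 2, 1.0)],
            "1B": [ChromAssignment("s2", "1B", 2, 1.0), ChromAssignment("s3", "1B", 2, 2.0)],
        }
        return build_pseudomolecules(ordered, {"s1": 10, "s2": 10, "s3": 10, "un": 10},
                                     ["s1", "s2", "s3", "un"])

    def test_rescued_genes_add_to_pseudomolecule_total(self):
        # 62,813 genes on previously placed scaffolds + 2,179 on rescued
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(65_012)],
             "scaffold_id": ["s1"] * 40_000 + ["s2"] * 22_813 + ["s3"] * 2_179 + ["un"] * 20}
        )
        table = gene_accounting(genes, self._pset())
        total = int(table[table["chrom"] == "Total_pseudomolecules"]["genes"].iloc[0])
        assert total == 62_813 + 2_179 == 64_992
        assert int(table[table["chrom"] == CHRUN]["genes"].iloc[0]) == 20

    def test_empty_gene_table_all_zero(self):
        table = gene_accounting(pd.DataFrame(columns=["gene_id", "scaffold_id"]), self._pset())
        assert (table["genes"] == 0).all()

    def test_duplicate_gene_rejected(self):
        genes = pd.DataFrame({"gene_id": ["g", "g"], "scaffold_id": ["s1", "s2"]})
        with pytest.raises(ValueError, match="duplicate"):
            gene_accounting(genes, self._pset())

    def test_per_chromosome_sum_equals_total(self, rng):
        hosts = ["s1", "s2", "s3", "un"]
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(500)],
             "scaffold_id": rng.choice(hosts, 500)}
        )
        table = gene_accounting(genes, self._pset()).set_index("chrom")
        assert (
            table.loc[["1A", "1B"], "genes"].sum()
            == table.loc["Total_pseudomolecules", "genes"]
        )
        assert table["genes"].iloc[:-1].sum() == 500  # incl. ChrUn


class TestCompareAssemblies:
    def _layout(self, rows):
        return pd.DataFrame(rows, columns=["scaffold_id", "chrom", "position", "orientation"])

    def test_identical_layouts_all_unchanged(self):
        layout = self._layout(
            [("a", "1A", 0, "+"), ("b", "1A", 1, "-"), ("c", "1B", 0, "+")]
        )
        ledger = compare_layouts(layout, layout)
        assert set(ledger["class"]) == {"unchanged"}

    def test_single_flip_is_exactly_one_reoriented(self):
        old = self._layout([("a", "1A", 0, "+"), ("b", "1A", 1, "-")])
        new = self._layout([("a", "1A", 0, "+"), ("b", "1A", 1, "+")])
        ledger = compare_layouts(new, old).set_index("scaffold_id")
        assert ledger.loc["a", "class"] == "unchanged"
        assert ledger.loc["b", "class"] == "reoriented"

    def test_moved_scaffold_does_not_drag_neighbours(self):
        old = self._layout(
            [("a", "1A", 0, "+"), ("b", "1A", 1, "+"), ("c", "1A", 2, "+"), ("d", "1A", 3, "+")]
        )
        new = self._layout(
            [("b", "1A", 0, "+"), ("c", "1A", 1, "+"), ("a", "1A", 2, "+"), ("d", "1A", 3, "+")]
        )
        ledger = compare_layouts(new, old).set_index("scaffold_id")
        assert ledger.loc["a", "class"] == "relocated"
        assert set(ledger.loc[["b", "c", "d"], "class"]) == {"unchanged"}

    def test_chrun_rescue(self):
        old = self._layout([("a", "1A", 0, "+"), ("b", CHRUN, 0, "+")])
        new = self._layout([("a", "1A", 0, "+"), ("b", "1A", 1, "+")])
        ledger = compare_layouts(new, old).set_index("scaffold_id")
        assert ledger.loc["b", "class"] == "rescued"

    def test_summary_counts_and_bp(self):
        old = self._layout([("a", "1A", 0, "+"), ("b", CHRUN, 0, "+")])
        new = self._layout([("a", "1A", 0, "-"), ("b", "1A", 1, "+")])
        ledger = compare_layouts(new, old, {"a": 100, "b": 250})
        summary = ledger_summary(ledger).set_index("class")
        assert summary.loc["rescued", "total_bp"] == 250
        assert summary.loc["reoriented", "total_bp"] == 100


class TestReports:
    def test_totals_row_reproduces_headline_n_pct(self):
        lengths = {"all": 10_330_552_199}
        effective = {"all": 9_995_175_477}
        table = report_tables(lengths, effective)
        total = table[table["chrom"] == "Total"].iloc[0]
        assert total["n_pct"] == 3.25

    def test_zero_n_assembly(self):
        table = report_tables({"1A": 100}, {"1A": 100})
        assert (table["n_pct"] == 0.0).all()

    def test_random_fixture_recount(self, rng):
        recs = {
            f"c{i}": "".join(rng.choice(list("ACGTN"), 500, p=[0.23] * 4 + [0.08]))
            for i in range(4)
        }
        lengths = {k: len(v) for k, v in recs.items()}
        eff = {k: len(v) - v.count("N") for k, v in recs.items()}
        table = report_tables(lengths, eff).set_index("chrom")
        for k, v in recs.items():
            assert table.loc[k, "n_pct"] == round(100.0 * v.count("N") / len(v), 2)
        assert table.loc["Total", "length_bp"] == sum(lengths.values())


class TestMarkerPlumbing:
    def test_marker_tsv_round_trip(self, tmp_path):
        df = mk_markers([("m1", "1A", 1.5, "s", 100), ("m2", "2B", 0.0, "t", 5)])
        path = tmp_path / "markers.tsv"
        write_markers(df, path)
        back = read_markers(path)
        pd.testing.assert_frame_equal(back, df)

    def test_conflicting_marker_claims_dropped_on_merge(self):
        a = mk_markers([("m1", "1A", 1.0, "s", 10), ("m2", "1A", 2.0, "s", 20)])
        b = mk_markers([("m1", "3B", 9.0, "t", 10), ("m3", "1A", 3.0, "s", 30)])
        merged = merge_marker_maps([a, b])
        assert sorted(merged["marker_id"]) == ["m2", "m3"]

    def test_split_remap_moves_hits_into_pieces(self):
        prov = pd.DataFrame(
            [{"piece_id": "s_1", "parent_id": "s", "parent_start": 0, "parent_end": 500},
             {"piece_id": "s_2", "parent_id": "s", "parent_start": 500, "parent_end": 900}]
        )
        markers = mk_markers([("m1", "1A", 1.0, "s", 100), ("m2", "1A", 2.0, "s", 700),
                              ("m3", "2B", 3.0, "t", 50)])
        out = remap_markers(markers, prov).set_index("marker_id")
        assert (out.loc["m1", "scaffold_id"], out.loc["m1", "pos"]) == ("s_1", 100)
        assert (out.loc["m2", "scaffold_id"], out.loc["m2", "pos"]) == ("s_2", 200)
        assert out.loc["m3", "scaffold_id"] == "t"
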
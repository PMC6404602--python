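"""The synthetic-data generator: determinism, truth consistency, noise model."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from optscaf.core import BSPQI, DLE1, digest_sequence, revcomp
from optscaf.simulate import (
    SimConfig,
    chromosome_names,
    fragment_genome,
    inject_errors,
    simulate_all,
    simulate_genetic_map,
    simulate_genome,
    simulate_optical_map,
    _apply_noise,
)

TINY = replace(
    SimConfig.zero_noise(3),
    n_chromosomes=2,
    chromosome_length_bp=1_500_000,
    n_chimeras=1,
    n_misplacements=1,
    n_misorientations=1,
    n_old_unplaced=1,
)


class TestGenome:
    def test_deterministic_under_seed(self):
        a, _ = simulate_genome(TINY)
        b, _ = simulate_genome(TINY)
        assert [(r.seq_id, r.bases) for r in a] == [(r.seq_id, r.bases) for r in b]

    def test_different_seed_differs(self):
        a, _ = simulate_genome(TINY)
        b, _ = simulate_genome(replace(TINY, seed=4))
        assert a[0].bases != b[0].bases

    def test_chromosome_naming(self):
        assert chromosome_names(4) == ["1A", "1B", "2A", "2B"]
        assert chromosome_names(14)[-1] == "7B"

    def test_label_density_near_target(self):
        chroms, truth = simulate_genome(TINY)
        for chrom in ("1A", "1B"):
            pos, _ = truth.label_positions[(chrom, "DLE-1")]
            per_100kb = len(pos) / (TINY.chromosome_length_bp / 1e5)
            assert abs(per_100kb - TINY.label_density) < 3.0

    def test_planted_repeat_arrays_match_annotation(self):
        cfg = replace(TINY, repeat_families=((2000, 3, 2),))
        chroms, truth = simulate_genome(cfg)
        ann = truth.repeat_annotation
        assert len(ann) == 2 * cfg.n_chromosomes
        by_id = {r.seq_id: r.bases for r in chroms}
        for _, row in ann.iterrows():
            seg = by_id[row["chrom"]][row["start"]:row["end"]]
            unit = seg[: row["unit_bp"]]
            expected = unit * row["copies"]
            # motif scrubbing/planting may touch a few bases of the array
            diffs = sum(a != b for a, b in zip(seg, expected))
            assert diffs < 0.02 * len(seg)

    def test_no_repeat_families_no_annotation(self):
        _, truth = simulate_genome(TINY)
        assert truth.repeat_annotation.empty

    def test_oversized_repeat_array_rejected(self):
        cfg = replace(TINY, repeat_families=((TINY.chromosome_length_bp, 2, 1),))
        with pytest.raises(ValueError):
            simulate_genome(cfg)


class TestFragmentation:
    def test_scaffolds_reconstruct_chromosome_slices(self):
        chroms, truth = simulate_genome(TINY)
        scaffolds, truth = fragment_genome(chroms, truth, TINY)
        by_id = {r.seq_id: r.bases for r in chroms}
        assert len(scaffolds) > 2
        for rec in scaffolds:
            row = truth.placements.set_index("scaffold_id").loc[rec.seq_id]
            seg = by_id[row["chrom"]][row["start"]:row["end"]]
            if row["orientation"] == "-":
                seg = revcomp(seg)
            assert rec.bases.replace("N", "") == seg

    def test_zero_break_rate_one_scaffold_per_chromosome(self):
        cfg = replace(TINY, scaffold_break_rate=0.0, nrun_rate_per_bp=0.0)
        chroms, truth = simulate_genome(cfg)
        scaffolds, truth = fragment_genome(chroms, truth, cfg)
        assert len(scaffolds) == cfg.n_chromosomes

    def test_break_counts_follow_poisson_rate(self):
        # mean segment count over seeds within 3 sd of the Poisson expectation
        counts = []
        for seed in range(30):
            cfg = replace(TINY, seed=100 + seed, n_chromosomes=1,
                          chromosome_length_bp=2_000_000)
            chroms, truth = simulate_genome(cfg)
            scaffolds, _ = fragment_genome(chroms, truth, cfg)
            counts.append(len(scaffolds) - 1)
        lam = 2.0 * TINY.scaffold_break_rate  # breaks per 2-Mb chromosome
        mean = np.mean(counts)
        # min-spacing rejection can only remove breaks, never add
        assert mean <= lam + 3 * np.sqrt(lam / 30)
        assert mean >= 0.5 * lam

    def test_truth_gap_table_matches_junction_count(self, small_sim):
        pl = small_sim.truth.placements
        junctions = len(pl) - pl["chrom"].nunique()
        assert len(small_sim.truth.gaps) == junctions
        assert (small_sim.truth.gaps["gap_bp"] >= TINY.intergap_range[0]).all()
        assert (small_sim.truth.gaps["gap_bp"] <= TINY.intergap_range[1]).all()


class TestErrorInjection:
    def test_zero_chimeras_is_identity(self):
        cfg = replace(TINY, n_chimeras=0)
        chroms, truth = simulate_genome(cfg)
        scaffolds, truth = fragment_genome(chroms, truth, cfg)
        out, truth = inject_errors(scaffolds, truth, cfg)
        assert {r.seq_id for r in out} == {r.seq_id for r in scaffolds}
        assert truth.chimeras.empty

    def test_junction_lies_inside_spacer_n_run(self, small_sim):
        recs = {r.seq_id: r for r in small_sim.scaffolds}
        for _, row in small_sim.truth.chimeras.iterrows():
            rec = recs[row["chimera_id"]]
            junction = rec.bases[row["junction_start"]:row["junction_end"]]
            assert set(junction) == {"N"}
            assert len(junction) == small_sim.config.chimera_spacer_n

    def test_chimera_count_matches_config(self, small_sim):
        assert len(small_sim.truth.chimeras) == small_sim.config.n_chimeras

    def test_chimera_partners_from_different_chromosomes(self, small_sim):
        chim = small_sim.truth.chimeras
        assert (chim["left_chrom"] != chim["right_chrom"]).all()

    def test_old_assembly_corruptions_match_config(self, small_sim):
        classes = small_sim.truth.old_classes["true_class"].value_counts()
        cfg = small_sim.config
        assert classes.get("relocated", 0) == cfg.n_misplacements
        assert classes.get("reoriented", 0) == cfg.n_misorientations
        assert classes.get("rescued", 0) == cfg.n_old_unplaced


class TestOpticalMap:
    def test_zero_noise_direct_map_equals_digest(self):
        chroms, truth = simulate_genome(TINY)
        maps, map_truth = simulate_optical_map(chroms, TINY, DLE1, truth)
        assert len(maps) == len(chroms)
        for m, rec in zip(maps, chroms):
            digest = digest_sequence(rec, DLE1, 0)
            assert m.positions == digest.positions
            assert m.length_bp == rec.length_bp

    def test_certain_fragile_breaks_fragment_every_pair(self):
        from optscaf.core import digest_with_strands, fragile_pairs

        cfg = replace(TINY, fragile_break_prob=1.0, min_molecule_kb=0)
        chroms, truth = simulate_genome(cfg)
        maps, _ = simulate_optical_map(chroms, cfg, BSPQI, truth)
        n_pairs = 0
        for rec in chroms:
            pos, strands = truth.label_positions[(rec.seq_id, BSPQI.name)]
            n_pairs += len(fragile_pairs(pos, strands, BSPQI.fragile_distance_bp))
        assert len(maps) == n_pairs + len(chroms)

    def test_nick_maps_less_contiguous_than_direct(self):
        # qualitative chemistry contrast on a handful of seeds (full
        # 20-seed comparison runs in the acceptance suite)
        from optscaf.core import n50

        wins = 0
        for seed in range(5):
            cfg = replace(SimConfig.default(50 + seed), n_chromosomes=1,
                          chromosome_length_bp=4_000_000)
            chroms, truth = simulate_genome(cfg)
            direct, _ = simulate_optical_map(chroms, cfg, DLE1, truth)
            nick, _ = simulate_optical_map(chroms, cfg, BSPQI, truth)
            if nick and direct:
                wins += n50([m.length_bp for m in direct]) >= n50(
                    [m.length_bp for m in nick]
                )
        assert wins >= 4

    def test_short_contigs_dropped(self):
        cfg = replace(TINY, fragile_break_prob=1.0, min_molecule_kb=150)
        chroms, truth = simulate_genome(cfg)
        maps, _ = simulate_optical_map(chroms, cfg, BSPQI, truth)
        assert all(m.length_bp >= 150_000 for m in maps)

    def test_sizing_noise_is_the_declared_gaussian(self):
        # standardised residuals of 10,000 perturbed intervals vs N(0,1)
        rng = np.random.default_rng(11)
        cfg = replace(SimConfig.default(1), miss_rate=0.0, false_rate=0.0)
        true_pos = list(np.cumsum(rng.integers(3000, 9000, size=10_001)))
        length = int(true_pos[-1] + 5000)
        noisy, _ = _apply_noise(list(true_pos), length, cfg, rng)
        assert len(noisy) == len(true_pos)
        ti = np.diff(np.concatenate([[0], true_pos]))
        ni = np.diff(np.concatenate([[0], noisy]))
        z = (ni - ti) / (cfg.sizing_sd_coeff * np.sqrt(ti))
        # rounding to integer positions adds sub-bp jitter; KS on the
        # standardised residuals must still accept the declared model
        p = stats.kstest(z, "norm").pvalue
        assert p > 0.01


class TestGeneticMap:
    def test_cm_values_non_negative(self, small_sim):
        assert (small_sim.markers["cm"] >= 0).all()

    def test_marker_positions_hit_real_scaffold_bases(self, small_sim):
        recs = {r.seq_id: r for r in small_sim.scaffolds}
        for _, m in small_sim.markers.iterrows():
            rec = recs[m["scaffold_id"]]
            assert 1 <= m["pos"] <= rec.length_bp

    def test_zero_density_empty_map(self):
        cfg = replace(TINY, marker_density=0.0)
        chroms, truth = simulate_genome(cfg)
        scaffolds, truth = fragment_genome(chroms, truth, cfg)
        scaffolds, truth = inject_errors(scaffolds, truth, cfg)
        markers = simulate_genetic_map(chroms, truth, cfg)
        assert markers.empty

    def test_marker_count_scales_with_density(self):
        chroms, truth = simulate_genome(TINY)
        scaffolds, truth = fragment_genome(chroms, truth, TINY)
        scaffolds, truth = inject_errors(scaffolds, truth, TINY)
        markers = simulate_genetic_map(chroms, truth, TINY)
        expected = TINY.n_chromosomes * TINY.chromosome_length_bp / 1e6 * TINY.marker_density
        assert 0.5 * expected < len(markers) < 1.5 * expected

    def test_marker_cm_monotone_in_chromosome_position(self):
        # markers on the same chromosome, ordered by true chromosome
        # coordinate, must have non-decreasing cM
        cfg = TINY
        chroms, truth = simulate_genome(cfg)
        scaffolds, truth = fragment_genome(chroms, truth, cfg)
        scaffolds, truth = inject_errors(scaffolds, truth, cfg)
        markers = simulate_genetic_map(chroms, truth, cfg)
        pl = truth.placements.set_index("scaffold_id")
        rm = truth.record_map
        rec_members = rm.groupby("record_id")

        def chrom_pos(row):
            # invert the record mapping for single-member records
            members = rec_members.get_group(row["scaffold_id"])
            if len(members) != 1:
                return None
            member = members.iloc[0]["member_id"]
            p = pl.loc[member]
            ins = truth.insertions.get(member, [])
            local = row["pos"] - 1
            for u, ln in sorted(ins):
                if local >= u + ln:
                    local -= ln
                elif local >= u:
                    return None
            if p["orientation"] == "+":
                return p["start"] + local
            return p["end"] - 1 - local

        for chrom, grp in markers.groupby("chrom"):
            pts = []
            for _, row in grp.iterrows():
                cp = chrom_pos(row)
                if cp is not None:
                    pts.append((cp, row["cm"]))
            pts.sort()
            cms = [c for _, c in pts]
            assert all(b >= a - 1e-9 for a, b in zip(cms, cms[1:]))


class TestDeterminism:
    def test_full_generator_deterministic(self):
        a = simulate_all(TINY)
        b = simulate_all(TINY)
        assert [(r.seq_id, r.bases) for r in a.scaffolds] == [
            (r.seq_id, r.bases) for r in b.scaffolds
        ]
        for enz in a.maps:
            assert [(m.map_id, m.positions) for m in a.maps[enz]] == [
                (m.map_id, m.positions) for m in b.maps[enz]
            ]
        pd.testing.assert_frame_equal(a.markers, b.markers)
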
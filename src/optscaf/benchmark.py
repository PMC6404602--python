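"""Benchmark experiments: run the toolkit against simulator ground truth.

Each experiment builds synthetic inputs with :mod:`optscaf.simulate`, runs
the relevant part of the pipeline, and scores the result against the
generator's truth. They power both the test suite and the reproduction
script, and are useful for parameter studies (e.g. how recall degrades
with labelling noise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .align import AlignParams, align_all
from .config import PipelineConfig
from .conflicts import MAP_ERROR, SEQUENCE_ERROR, arbitrate, detect_conflicts
from .core import BSPQI, DLE1, LabelMap, digest_sequence, n50
from .pipeline import PipelineResult, run_all
from .scaffold import estimate_gap, place_sequences
from .simulate import GroundTruth, SimConfig, SimResult, simulate_all, simulate_genome, simulate_optical_map


# ---------------------------------------------------------------------------
# member-level truth bookkeeping


def _pre_insertion(x: int, insertions) -> int:
    """Map a member-record coordinate back to the uninserted segment frame."""
    shift = 0
    for u, ln in sorted(insertions):
        if x >= u + shift + ln:
            shift += ln
        elif x > u + shift:
            return u  # inside an inserted N block
        else:
            break
    return x - shift


def piece_truth(truth: GroundTruth, provenance: pd.DataFrame) -> pd.DataFrame:
    """True chromosome footprint of every final pipeline record.

    Split pieces are mapped through the cut provenance: each piece inherits
    the member whose bases dominate it, and its chromosome interval is the
    member content actually inside the piece (a cut next to — rather than
    inside — a chimera spacer leaves a short residue, which this accounts
    for exactly). Columns: record_id, member_id, chrom, start, end,
    orientation.
    """
    pl = truth.placements.set_index("scaffold_id")
    rows = []
    split_parents = set(provenance["parent_id"]) if not provenance.empty else set()

    def content_interval(member_id: str, llo: int, lhi: int):
        m = pl.loc[member_id]
        ins = truth.insertions.get(member_id, [])
        seg_lo = _pre_insertion(llo, ins)
        seg_hi = _pre_insertion(lhi, ins)
        if m["orientation"] == "+":
            return int(m["start"]) + seg_lo, int(m["start"]) + seg_hi
        return int(m["end"]) - seg_hi, int(m["end"]) - seg_lo

    for record_id, grp in truth.record_map.groupby("record_id"):
        spans = []  # (member_id, rec_lo, rec_hi)
        for _, r in grp.sort_values("offset").iterrows():
            member = r["member_id"]
            m = pl.loc[member]
            rec_len = (int(m["end"]) - int(m["start"])) + sum(
                ln for _, ln in truth.insertions.get(member, [])
            )
            spans.append((member, int(r["offset"]), int(r["offset"]) + rec_len))

        if record_id not in split_parents:
            if len(spans) == 1:
                member, off, _ = spans[0]
                m = pl.loc[member]
                rows.append(
                    {"record_id": record_id, "member_id": member,
                     "chrom": m["chrom"], "start": int(m["start"]),
                     "end": int(m["end"]), "orientation": m["orientation"]}
                )
            continue
        for _, piece in provenance[provenance["parent_id"] == record_id].iterrows():
            ps, pe = int(piece["parent_start"]), int(piece["parent_end"])
            best = None
            for member, mlo, mhi in spans:
                llo, lhi = max(0, ps - mlo), min(mhi - mlo, pe - mlo)
                if lhi - llo > (0 if best is None else best[0]):
                    best = (lhi - llo, member, llo, lhi)
            if best is None:
                continue
            _, member, llo, lhi = best
            lo, hi = content_interval(member, llo, lhi)
            m = pl.loc[member]
            rows.append(
                {"record_id": piece["piece_id"], "member_id": member,
                 "chrom": m["chrom"], "start": lo, "end": hi,
                 "orientation": m["orientation"]}
            )
    return pd.DataFrame(
        rows, columns=["record_id", "member_id", "chrom", "start", "end", "orientation"]
    )


# ---------------------------------------------------------------------------
# end-to-end zero-noise recovery


@dataclass
class RecoveryReport:
    chimera_recall_pct: float
    false_splits: int
    false_conflicts: int
    order_accuracy_pct: float
    orientation_accuracy_pct: float
    gap_exact_pct: float
    assignment_accuracy_pct: float
    n50_before_bp: int
    n50_round1_bp: int
    n50_round2_bp: int
    ledger_agreement_pct: float


def evaluate_recovery(sim: SimResult, result: PipelineResult) -> RecoveryReport:
    """Score an end-to-end run against simulator truth."""
    truth = sim.truth
    pl = truth.placements.set_index("scaffold_id")
    chim = truth.chimeras

    # --- chimera detection: a chimera counts as recalled when its record
    # was cut inside (or within one junction pad of) the injected spacer
    prov = result.split_provenance
    recalled = 0
    for _, row in chim.iterrows():
        pieces = prov[prov["parent_id"] == row["chimera_id"]]
        cuts = [p for p in pieces["parent_start"] if p > 0]
        ok = any(
            row["junction_start"] - 50_000 <= c <= row["junction_end"] + 50_000
            for c in cuts
        )
        recalled += ok
    chimera_recall = 100.0 * recalled / len(chim) if len(chim) else 100.0

    chim_ids = set(chim["chimera_id"])
    false_splits = len(set(prov["parent_id"]) - chim_ids) if not prov.empty else 0
    false_conflicts = sum(
        1
        for c in result.conflicts
        if c.verdict == SEQUENCE_ERROR and c.scaffold_id.split("_")[0] not in chim_ids
        and c.scaffold_id not in chim_ids
    )

    # --- super-scaffold layout vs truth (piece-level chromosome footprints)
    pt = piece_truth(truth, prov).set_index("record_id")
    pairs_total = pairs_correct = 0
    orient_total = orient_correct = 0
    gaps_total = gaps_exact = 0
    for ss in result.supers_round2:
        members = [(m, m.seq_id) for m in ss.members if m.seq_id in pt.index]
        if len(members) < 2:
            continue
        rows = [pt.loc[rid] for _, rid in members]
        starts = [int(r["start"]) for r in rows]
        reversed_super = starts[0] > starts[-1]
        if reversed_super:
            members = members[::-1]
            rows = rows[::-1]
            starts = starts[::-1]
        same_chrom = len({r["chrom"] for r in rows}) == 1
        for a, b in zip(starts, starts[1:]):
            pairs_total += 1
            pairs_correct += same_chrom and (a < b)
        flip = {"+": "-", "-": "+"}
        for (m, _), r in zip(members, rows):
            want = r["orientation"] if not reversed_super else flip[r["orientation"]]
            orient_total += 1
            orient_correct += m.orientation == want
        for (m, _), (m2, _), r, r2 in zip(members, members[1:], rows, rows[1:]):
            if not same_chrom:
                continue
            gaps_total += 1
            true_gap = int(r2["start"]) - int(r["end"])
            got = m.gap_after if not reversed_super else m2.gap_after
            gaps_exact += got == true_gap

    # --- chromosome assignment of anchored super-scaffolds
    assign_total = assign_correct = 0
    if result.pset is not None:
        super_members = {
            ss.super_id: [m.seq_id for m in ss.members] for ss in result.supers_round2
        }
        for chrom in result.pset.chromosomes:
            for sid, _ in result.pset.members_of(chrom):
                truth_chroms = {
                    pt.loc[rid, "chrom"]
                    for rid in super_members.get(sid, [])
                    if rid in pt.index
                }
                if not truth_chroms:
                    continue
                assign_total += 1
                assign_correct += truth_chroms == {chrom}

    # --- provenance ledger vs injected old-assembly corruption
    ledger_total = ledger_correct = 0
    if result.ledger is not None and truth.old_classes is not None:
        led = result.ledger.set_index("scaffold_id")
        led.index = [
            pt.loc[i, "member_id"] if i in pt.index else i for i in led.index
        ]
        for _, row in truth.old_classes.iterrows():
            sid = row["scaffold_id"]
            if sid not in led.index:
                continue  # not anchored (e.g. too few markers)
            ledger_total += 1
            ledger_correct += led.loc[sid, "class"] == row["true_class"]

    lengths = {r.seq_id: r.length_bp for r in result.resolved_scaffolds}
    n50_before = n50([r.length_bp for r in sim.scaffolds])
    n50_r1 = n50([s.length_bp(lengths) for s in result.supers_round1])
    n50_r2 = n50([s.length_bp(lengths) for s in result.supers_round2])

    def pct(c, t):
        return 100.0 * c / t if t else 100.0

    return RecoveryReport(
        chimera_recall_pct=chimera_recall,
        false_splits=false_splits,
        false_conflicts=false_conflicts,
        order_accuracy_pct=pct(pairs_correct, pairs_total),
        orientation_accuracy_pct=pct(orient_correct, orient_total),
        gap_exact_pct=pct(gaps_exact, gaps_total),
        assignment_accuracy_pct=pct(assign_correct, assign_total),
        n50_before_bp=n50_before,
        n50_round1_bp=n50_r1,
        n50_round2_bp=n50_r2,
        ledger_agreement_pct=pct(ledger_correct, ledger_total),
    )


def run_recovery_benchmark(seed: int, config: SimConfig | None = None):
    """Simulate the zero-noise desk-scale benchmark and run the pipeline."""
    import tempfile

    sim_cfg = config or SimConfig.zero_noise(seed)
    sim = simulate_all(sim_cfg)
    with tempfile.TemporaryDirectory() as tmp:
        result = run_all(
            sim.scaffolds, sim.maps[DLE1.name], sim.maps[BSPQI.name], sim.markers,
            PipelineConfig(), tmp, old_assembly=sim.truth.old_assembly,
        )
    return sim, result, evaluate_recovery(sim, result)


# ---------------------------------------------------------------------------
# arbitration accuracy under noise


def splice_maps(a: LabelMap, b: LabelMap) -> list[LabelMap]:
    """Cross-join two map contigs at their midpoints (injected map error)."""
    mid_a, mid_b = a.length_bp // 2, b.length_bp // 2
    head_a = [p for p in a.positions if p <= mid_a]
    tail_b = [mid_a + (p - mid_b) for p in b.positions if p > mid_b]
    head_b = [p for p in b.positions if p <= mid_b]
    tail_a = [mid_b + (p - mid_a) for p in a.positions if p > mid_a]
    return [
        LabelMap("splice_ab", mid_a + (b.length_bp - mid_b), head_a + tail_b, "optical"),
        LabelMap("splice_ba", mid_b + (a.length_bp - mid_a), head_b + tail_a, "optical"),
    ]


def arbitration_experiment(
    seed: int, n_replicates: int = 25, noise: bool = True
) -> dict:
    """Arbitrate injected chimeras and injected map errors; score verdicts.

    Each replicate simulates a small two-chromosome genome with two
    chimeric scaffolds (truth: sequence_error) and splices the first-map
    contigs to fabricate a chimeric map (truth: map_error for conflicts it
    induces on clean scaffolds).
    """
    params = AlignParams()
    correct = total = detected_chimeras = unassessable = 0
    W = 100_000  # second-map coverage window required around the junction

    def covered(map_truth: pd.DataFrame, chrom: str, lo: int, hi: int) -> bool:
        here = map_truth[map_truth["chrom"] == chrom]
        return bool(
            ((here["start_bp"] <= lo) & (here["end_bp"] >= hi)).any()
        )

    for rep in range(n_replicates):
        base = SimConfig.default(seed + rep) if noise else SimConfig.zero_noise(seed + rep)
        cfg = replace(
            base, n_chromosomes=2, chromosome_length_bp=2_500_000,
            n_chimeras=2, n_misplacements=0, n_misorientations=0, n_old_unplaced=0,
        )
        sim = simulate_all(cfg)
        recs = {r.seq_id: r for r in sim.scaffolds}
        maps1, maps2 = sim.maps[DLE1.name], sim.maps[BSPQI.name]

        maps2_dict = {m.map_id: m for m in maps2}
        pad = 100_000  # a conflict this close to the injected event is scored
        chim = sim.truth.chimeras.set_index("chimera_id")
        aln1 = align_all(
            [digest_sequence(recs[c], DLE1, 0) for c in chim.index], maps1, params
        )
        aln2 = align_all(
            [digest_sequence(recs[c], BSPQI, 0) for c in chim.index], maps2, params
        )
        map2_truth = sim.truth.map_truth[BSPQI.name]
        pl = sim.truth.placements.set_index("scaffold_id")

        def junction_windows(row) -> list[tuple[str, int, int]]:
            # junction-adjacent chromosome windows of the two joined pieces
            out = []
            for sid, side in ((row["left_id"], "end"), (row["right_id"], "start")):
                p = pl.loc[sid]
                at_end = (side == "end") == (p["orientation"] == "+")
                if at_end:
                    out.append((p["chrom"], int(p["end"]) - W, int(p["end"])))
                else:
                    out.append((p["chrom"], int(p["start"]), int(p["start"]) + W))
            return out

        for c in detect_conflicts(aln1, None, {m.map_id: m for m in maps1}):
            row = chim.loc[c.scaffold_id]
            near = c.overlaps(
                (row["junction_start"] - pad, row["junction_end"] + pad)
            )
            if not near:
                continue  # a detection false positive, not an arbitration case
            if not all(
                covered(map2_truth, ch, lo, hi)
                for ch, lo, hi in junction_windows(row)
            ):
                unassessable += 1  # second map cannot testify here
                continue
            total += 1
            detected_chimeras += 1
            correct += arbitrate(c, aln2, second_maps=maps2_dict).verdict == SEQUENCE_ERROR

        if len(maps1) >= 2:
            spliced = splice_maps(maps1[0], maps1[1])
            cut = maps1[0].length_bp // 2  # splice point, chromosome coords
            span = pl[
                (pl["chrom"] == "1A")
                & (pl["end"] > cut + W)
                & (pl["start"] < cut - W)
            ]
            victims = [
                s for s in span.index if s in recs and recs[s].length_bp > 150_000
            ][:2]
            if not covered(map2_truth, "1A", cut - W, cut + W):
                unassessable += len(victims)
                victims = []
            q1 = [digest_sequence(recs[s], DLE1, 0) for s in victims]
            q2 = [digest_sequence(recs[s], BSPQI, 0) for s in victims]
            a1 = align_all(q1, spliced, params)
            a2 = align_all(q2, maps2, params)
            for c in detect_conflicts(a1, None, {m.map_id: m for m in spliced}):
                row = pl.loc[c.scaffold_id]
                if row["orientation"] == "+":
                    cut_local = cut - int(row["start"])
                else:
                    cut_local = int(row["end"]) - cut
                if not c.overlaps((cut_local - pad, cut_local + pad)):
                    continue
                total += 1
                correct += arbitrate(c, a2, second_maps=maps2_dict).verdict == MAP_ERROR
    return {
        "n_verdicts": total,
        "accuracy_pct": 100.0 * correct / total if total else 0.0,
        "detected_chimeras": detected_chimeras,
        "unassessable": unassessable,
    }


# ---------------------------------------------------------------------------
# gap estimation under noise


def gap_band_experiment(seed: int, n_sims: int = 3) -> dict:
    """Fraction of noisy gap estimates within 3 sd of the truth.

    The sd of an estimate is dominated by the accumulated sizing error of
    the map interval D between the flanking aligned labels:
    sd = sizing_sd_coeff * sqrt(D).
    """
    params = AlignParams()
    within = total = 0
    for rep in range(n_sims):
        cfg = replace(
            SimConfig.default(seed + rep), n_chromosomes=2,
            chromosome_length_bp=10_000_000, scaffold_break_rate=5.0,
            n_chimeras=0, n_misplacements=0, n_misorientations=0, n_old_unplaced=0,
        )
        sim = simulate_all(cfg)
        recs = {r.seq_id: r for r in sim.scaffolds}
        queries = [digest_sequence(r, DLE1, 0) for r in sim.scaffolds]
        aln = align_all(queries, sim.maps[DLE1.name], params)
        placements = place_sequences(aln, recs, {m.map_id: m for m in sim.maps[DLE1.name]})
        pl = sim.truth.placements.set_index("scaffold_id")
        by_map: dict[str, list] = {}
        for p in placements:
            by_map.setdefault(p.map_id, []).append(p)
        for group in by_map.values():
            group.sort(key=lambda p: p.map_start)
            for left, right in zip(group, group[1:]):
                if left.seq_id not in pl.index or right.seq_id not in pl.index:
                    continue
                est = estimate_gap(left, right, recs[left.seq_id], recs[right.seq_id])
                bounds = sorted(
                    [pl.loc[left.seq_id, "start"], pl.loc[left.seq_id, "end"],
                     pl.loc[right.seq_id, "start"], pl.loc[right.seq_id, "end"]]
                )
                true_gap = bounds[2] - bounds[1]
                D = right.alignment.ref_bp[0] - left.alignment.ref_bp[-1]
                band = 3.0 * cfg.sizing_sd_coeff * np.sqrt(max(D, 1))
                total += 1
                within += abs(est - true_gap) <= band
    return {
        "n_gaps": total,
        "within_band_pct": 100.0 * within / total if total else 0.0,
    }


# ---------------------------------------------------------------------------
# chemistry contrast


def chemistry_contrast(seed: int, n_seeds: int = 20) -> dict:
    """Direct-label vs nicking map contiguity at matched parameters."""
    direct_n50s, nick_n50s = [], []
    for rep in range(n_seeds):
        cfg = replace(
            SimConfig.default(seed + rep), n_chromosomes=1,
            chromosome_length_bp=4_000_000,
        )
        chroms, truth = simulate_genome(cfg)
        direct, _ = simulate_optical_map(chroms, cfg, DLE1, truth)
        nick, _ = simulate_optical_map(chroms, cfg, BSPQI, truth)
        if direct:
            direct_n50s.append(n50([m.length_bp for m in direct]))
        nick_n50s.append(n50([m.length_bp for m in nick]) if nick else 0)
    return {
        "median_direct_n50_bp": float(np.median(direct_n50s)),
        "median_nick_n50_bp": float(np.median(nick_n50s)),
        "n50_ratio_direct_over_nick": float(
            np.median(direct_n50s) / max(np.median(nick_n50s), 1.0)
        ),
    }


# ---------------------------------------------------------------------------
# DP vs exhaustive search


def dp_oracle_experiment(seed: int, n_instances: int = 100) -> dict:
    """Fraction of tiny instances where the DP equals exhaustive search."""
    from .align import _best_chain, best_chain_bruteforce

    rng = np.random.default_rng(seed)
    params = AlignParams(max_lookback=8, min_confidence=0.0)
    agree = 0
    for _ in range(n_instances):
        n, m = rng.integers(3, 9, size=2)
        q = LabelMap("q", 200_000, sorted(
            int(p) for p in np.cumsum(rng.integers(2000, 12_000, size=int(n)))))
        r = LabelMap("r", 200_000, sorted(
            int(p) for p in np.cumsum(rng.integers(2000, 12_000, size=int(m)))))
        _, oracle_score = best_chain_bruteforce(q, r, params)
        _, dp_score = _best_chain(
            np.asarray(q.positions, float), np.asarray(r.positions, float), params
        )
        agree += abs(dp_score - oracle_score) <= 1e-9
    return {"n_instances": n_instances, "agreement_pct": 100.0 * agree / n_instances}
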
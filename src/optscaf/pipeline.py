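"""End-to-end driver: chimera resolution → hybrid scaffolding → anchoring.

The flow mirrors the assembly-improvement strategy the package implements:

1. digest scaffolds in silico and align them to the first (direct-label)
   optical map;
2. detect conflicts, arbitrate each against the second (nicking) map, and
   split confirmed sequence errors at N runs;
3. place the resolved scaffolds on the first map and join them into
   super-scaffolds with optically sized gaps;
4. validate and further merge the super-scaffolds with the second map
   (new conflicts are arbitrated with the map roles swapped and reported);
5. anchor super-scaffolds to chromosomes with genetic-map markers and
   emit pseudomolecules, AGP and the accounting reports.

Every stage output is written under the run directory together with a
manifest of input/output hashes and the full configuration, making a run
a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .align import align_all, flatten_alignments, write_xmap
from .config import PipelineConfig
from .conflicts import (
    SEQUENCE_ERROR,
    arbitrate,
    apply_splits,
    conflict_report,
    detect_conflicts,
    plan_splits,
)
from .core import (
    LabelMap,
    SequenceRecord,
    compute_stats,
    digest_sequence,
    find_n_runs,
    write_fasta,
)
from .pseudomolecule import (
    PseudomoleculeSet,
    assign_chromosomes,
    build_pseudomolecules,
    compare_layouts,
    emit_pseudomolecule_fasta,
    order_and_orient,
    remap_markers,
    report_tables,
)
from .scaffold import (
    SuperScaffold,
    build_superscaffolds,
    emit_sequences,
    place_sequences,
    second_round,
    write_agp,
)

logger = logging.getLogger(__name__)

STAGES = ["digest", "align", "resolve", "scaffold", "second_round", "anchor"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    out_dir: Path
    resolved_scaffolds: list[SequenceRecord]
    split_provenance: pd.DataFrame
    conflicts: list
    supers_round1: list[SuperScaffold]
    supers_round2: list[SuperScaffold]
    super_records: list[SequenceRecord]
    super_agp: pd.DataFrame
    pset: PseudomoleculeSet | None
    ledger: pd.DataFrame | None
    manifest: dict


def lift_markers(markers: pd.DataFrame, super_agp: pd.DataFrame) -> pd.DataFrame:
    """Re-address marker hits from member scaffolds to super-scaffolds."""
    w = super_agp[super_agp["component_type"] == "W"]
    idx = w.set_index("component_id")
    rows = []
    for _, m in markers.iterrows():
        sid = m["scaffold_id"]
        if sid not in idx.index:
            continue
        row = idx.loc[sid]
        pos = int(m["pos"])
        if row["orientation"] == "+":
            new_pos = int(row["object_beg"]) + pos - 1
        else:
            new_pos = int(row["object_beg"]) + (int(row["component_end"]) - pos)
        rows.append(
            {"marker_id": m["marker_id"], "chrom": m["chrom"], "cm": m["cm"],
             "scaffold_id": row["object"], "pos": new_pos}
        )
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "cm", "scaffold_id", "pos"])


def member_layout(
    pset: PseudomoleculeSet, supers: Mapping[str, SuperScaffold]
) -> pd.DataFrame:
    """Member-scaffold-level layout of a pseudomolecule set.

    Super-scaffolds anchored '-' contribute their members reversed and
    flipped. ChrUn supers contribute members under chrom 'ChrUn'.
    """
    rows = []
    for chrom in pset.chromosomes:
        position = 0
        for sid, orient in pset.members_of(chrom):
            ss = supers[sid]
            oriented = ss if orient == "+" else ss.reversed()
            for m in oriented.members:
                rows.append(
                    {"scaffold_id": m.seq_id, "chrom": chrom,
                     "position": position, "orientation": m.orientation}
                )
                position += 1
    for sid in pset.chrun:
        for m in supers[sid].members:
            rows.append(
                {"scaffold_id": m.seq_id, "chrom": "ChrUn", "position": 0,
                 "orientation": m.orientation}
            )
    return pd.DataFrame(rows, columns=["scaffold_id", "chrom", "position", "orientation"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    scaffolds: Sequence[SequenceRecord],
    maps1: Sequence[LabelMap],
    maps2: Sequence[LabelMap] | None,
    markers: pd.DataFrame | None,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "optscaf_out",
    old_assembly: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory inputs; write outputs + manifest."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": [], "outputs": {}}
    manifest["config"] = config.to_yaml()
    stage = "digest"
    try:
        enz1 = config.enzyme_spec(1)
        enz2 = config.enzyme_spec(2)
        mind = config.digest_min_label_distance_bp
        queries1 = [digest_sequence(s, enz1, mind) for s in scaffolds]
        manifest["stages"].append(stage)

        stage = "align"
        params1 = replace(config.align, min_confidence=config.confidence_initial)
        aln1 = align_all(queries1, maps1, params1)
        manifest["stages"].append(stage)

        stage = "resolve"
        tol = config.tolerances
        maps1_dict = {m.map_id: m for m in maps1}
        maps2_dict = {m.map_id: m for m in maps2} if maps2 else {}
        conflicts = detect_conflicts(aln1, None, maps1_dict, tol)
        aln2: dict = {}
        if maps2:
            queries2 = [digest_sequence(s, enz2, mind) for s in scaffolds]
            aln2 = align_all(queries2, maps2, params1)
            for c in conflicts:
                arbitrate(c, aln2, tol, maps2_dict)
        elif conflicts:
            logger.warning("no second map: %d conflicts left unarbitrated", len(conflicts))
        affected = {c.scaffold_id for c in conflicts if c.verdict == SEQUENCE_ERROR}
        n_runs = {
            s.seq_id: find_n_runs(s) for s in scaffolds if s.seq_id in affected
        }
        plans = plan_splits(conflicts, n_runs, search_pad=tol.junction_bp)
        resolved, provenance = apply_splits(scaffolds, plans)
        manifest["stages"].append(stage)

        stage = "scaffold"
        scaffold_dict = {r.seq_id: r for r in resolved}
        params_ext = replace(params1, min_confidence=config.confidence_extension)
        piece_ids = set(provenance["piece_id"]) if not provenance.empty else set()
        parent_ids = set(provenance["parent_id"]) if not provenance.empty else set()
        aln1b = {k: v for k, v in aln1.items() if k not in parent_ids}
        if piece_ids:
            pieces = [digest_sequence(scaffold_dict[p], enz1, mind) for p in sorted(piece_ids)]
            aln1b.update(align_all(pieces, maps1, params_ext))
        placements = place_sequences(
            aln1b, scaffold_dict, maps1_dict,
            min_confidence=config.confidence_initial,
            margin=config.placement.margin,
            overlap_tol=config.placement.overlap_tol_bp,
        )
        supers1 = build_superscaffolds(placements, scaffold_dict, config.placement.min_gap_bp)
        manifest["stages"].append(stage)

        stage = "second_round"
        new_conflicts: list = []
        if maps2:
            supers2, new_conflicts = second_round(
                supers1, scaffold_dict, maps2, enz2, params1, tol,
                merge_confidence=config.confidence_merge,
                min_gap=config.placement.min_gap_bp,
                margin=config.placement.margin,
                overlap_tol=config.placement.overlap_tol_bp,
            )
            if new_conflicts:
                # arbitrate with map roles swapped: does the *first* map
                # confirm the break in the super-scaffold?
                confl_ids = {c.scaffold_id for c in new_conflicts}
                sup_records, _ = emit_sequences(
                    [s for s in supers1 if s.super_id in confl_ids], scaffold_dict
                )
                sup_digests = [digest_sequence(r, enz1, mind) for r in sup_records]
                aln_swap = align_all(sup_digests, maps1, params1)
                for c in new_conflicts:
                    arbitrate(c, aln_swap, tol, maps1_dict)
        else:
            logger.warning("no second map: skipping second scaffolding round")
            supers2 = supers1
        super_records, super_agp = emit_sequences(supers2, scaffold_dict)
        manifest["stages"].append(stage)

        stage = "anchor"
        pset = None
        ledger = None
        if markers is not None and not markers.empty:
            markers_resolved = remap_markers(markers, provenance)
            lifted = lift_markers(markers_resolved, super_agp)
            lengths = {r.seq_id: r.length_bp for r in super_records}
            assignments, discordant = assign_chromosomes(
                lifted, lengths, config.anchoring.min_markers
            )
            ordered = order_and_orient(assignments, lifted, lengths)
            pset = build_pseudomolecules(
                ordered, lengths, lengths.keys(), config.anchoring.join_gap_bp
            )
            if old_assembly is not None:
                supers_by_id = {s.super_id: s for s in supers2}
                new_layout = member_layout(pset, supers_by_id)
                member_lengths = {r.seq_id: r.length_bp for r in resolved}
                ledger = compare_layouts(new_layout, old_assembly, member_lengths)
                pset.ledger = ledger
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- write outputs
    write_fasta(resolved, out / "scaffolds.resolved.fasta")
    write_xmap(flatten_alignments(aln1), out / "alignments.round1.xmap")
    rep = conflict_report(conflicts + list(new_conflicts), plans)
    rep.to_csv(out / "conflicts.tsv", sep="\t", index=False)
    provenance.to_csv(out / "split_provenance.tsv", sep="\t", index=False)
    write_fasta(super_records, out / "superscaffolds.fasta")
    write_agp(super_agp, out / "superscaffolds.agp")
    stats = compute_stats(super_records)
    (out / "superscaffolds.stats.json").write_text(
        json.dumps(
            {"n_sequences": stats.n_sequences, "total_bp": stats.total_bp,
             "max_bp": stats.max_bp, "n50_bp": stats.n50_bp,
             "n_pct": round(stats.n_pct, 4)},
            indent=2,
        )
    )
    if pset is not None:
        write_agp(pset.agp, out / "pseudomolecules.agp")
        rec_by_id = {r.seq_id: r for r in super_records}
        pseudo = emit_pseudomolecule_fasta(pset, rec_by_id)
        write_fasta(pseudo, out / "pseudomolecules.fasta")
        chrun_records = [rec_by_id[s] for s in pset.chrun if s in rec_by_id]
        if chrun_records:
            write_fasta(chrun_records, out / "chrun.fasta")
        eff = {r.seq_id: r.length_bp - r.n_count for r in pseudo}
        lengths = {r.seq_id: r.length_bp for r in pseudo}
        table = report_tables(lengths, eff, pset.unknown_gap_counts)
        table.to_csv(out / "pseudomolecules.report.tsv", sep="\t", index=False)
        if ledger is not None:
            ledger.to_csv(out / "provenance_ledger.tsv", sep="\t", index=False)
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        out_dir=out,
        resolved_scaffolds=resolved,
        split_provenance=provenance,
        conflicts=conflicts + list(new_conflicts),
        supers_round1=supers1,
        supers_round2=supers2,
        super_records=super_records,
        super_agp=super_agp,
        pset=pset,
        ledger=ledger,
        manifest=manifest,
    )
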
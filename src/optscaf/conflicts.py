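"""Scaffold-versus-optical-map conflict detection, arbitration and splitting.

A scaffold that aligns in two pieces to incompatible optical loci (different
map contigs, or the same contig at a distance that disagrees with the
scaffold's own geometry) is a chimera candidate; a long stretch of
unalignable labels inside an otherwise good alignment (e.g. a tandem-repeat
copy-number disagreement) is an internal discordance. Because the optical
map itself can be wrong, every conflict is arbitrated against a second,
chemically independent map: if the second map also breaks over the same
scaffold interval the sequence is at fault; if it bridges the interval
concordantly the first map is at fault; otherwise the conflict stays
unresolved and nothing is cut.

Confirmed sequence errors are repaired the only safe way: by cutting inside
an existing N gap (never inside real sequence). Conflicts whose interval
contains no N run are reported but left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import LabelAlignment
from .core import NRun, SequenceRecord

logger = logging.getLogger(__name__)

SPLIT_ALIGNMENT = "split_alignment"
INTERNAL_DISCORDANCE = "internal_discordance"

SEQUENCE_ERROR = "sequence_error"
MAP_ERROR = "map_error"
UNRESOLVED = "unresolved"
PENDING = "pending"


@dataclass(frozen=True)
class ConflictTolerances:
    """Detection/arbitration tolerances (all in bp or label counts).

    The source procedure publishes none of these; defaults sit comfortably
    above the default sizing noise and are fully configurable.
    """

    junction_bp: int = 50_000  # max span overlap still treated as one junction
    distance_bp: int = 100_000  # max map-vs-scaffold distance disagreement
    min_unaligned: int = 5  # labels: internal-discordance run threshold
    span_bp: int = 100_000  # bp: internal-discordance span threshold
    min_confirm: int = 5  # labels needed on each side to confirm a bridge


@dataclass
class Conflict:
    scaffold_id: str
    map_id: str
    kind: str  # split_alignment | internal_discordance
    scaffold_interval: tuple[int, int]  # 0-based half-open, brackets the breakpoint
    map_interval: tuple[int, int]
    verdict: str = PENDING
    partner_map_id: str | None = None
    conflict_id: int = -1

    def overlaps(self, interval: tuple[int, int], pad: int = 0) -> bool:
        lo, hi = self.scaffold_interval
        return min(hi + pad, interval[1] + pad) > max(lo - pad, interval[0] - pad)


@dataclass
class SplitPlan:
    scaffold_id: str
    cut_positions: list[int]  # each inside an N run, strictly increasing
    provenance: list[int] = field(default_factory=list)  # conflict ids

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.cut_positions, self.cut_positions[1:])):
            raise ValueError("cut positions must be strictly increasing")


# ---------------------------------------------------------------------------
# detection


def _ref_tail_beyond(a: LabelAlignment, maps) -> int | None:
    """Reference bases past the alignment in the scaffold's travel direction."""
    if maps is None or a.ref_id not in maps:
        return None
    length = maps[a.ref_id].length_bp
    return length - a.ref_span_bp()[1] if a.orientation == "+" else a.ref_span_bp()[0]


def _ref_head_before(b: LabelAlignment, maps) -> int | None:
    """Reference bases before the alignment against the travel direction."""
    if maps is None or b.ref_id not in maps:
        return None
    length = maps[b.ref_id].length_bp
    return b.ref_span_bp()[0] if b.orientation == "+" else length - b.ref_span_bp()[1]


def _map_incompatible(
    a: LabelAlignment, b: LabelAlignment, tol: ConflictTolerances, maps=None
) -> bool:
    """Could alignments a and b (a left of b on the scaffold) not coexist?"""
    if a.ref_id != b.ref_id:
        # Two different contigs can host one scaffold legitimately: the map
        # itself may simply be fragmented there. It is a chimera signal only
        # when the scaffold jumps out of a contig *interior*: were the
        # sequence past the junction a real continuation of the contig, the
        # local aligner would have kept extending the chain, so an alignment
        # ending more than a junction-scale distance from the contig edge
        # means the sequence and the map part company there.
        tail = _ref_tail_beyond(a, maps)
        head = _ref_head_before(b, maps)
        if tail is None or head is None:
            return True  # no contig lengths available: conservative
        return max(tail, head) > tol.junction_bp
    if a.orientation != b.orientation:
        return True
    # scaffold distance between the two aligned spans vs map distance
    scaf_dist = b.query_span_bp()[0] - a.query_span_bp()[1]
    if a.orientation == "+":
        map_dist = b.ref_span_bp()[0] - a.ref_span_bp()[1]
    else:
        map_dist = a.ref_span_bp()[0] - b.ref_span_bp()[1]
    if map_dist < -tol.junction_bp:  # wrong relative order on the map
        return True
    return abs(map_dist - scaf_dist) > tol.distance_bp


def detect_conflicts(
    alignments: Mapping[str, Sequence[LabelAlignment]],
    scaffolds: Mapping[str, SequenceRecord] | None,
    maps: Mapping[str, "object"] | None,
    tol: ConflictTolerances | None = None,
) -> list[Conflict]:
    """Detect scaffold-vs-map discordances from retained alignments.

    Split-alignment conflicts: two alignments of one scaffold whose
    scaffold spans overlap by at most ``tol.junction_bp`` (i.e. describe
    two different pieces) but whose map placements are incompatible.
    Internal discordances: inside one alignment, a run of at least
    ``tol.min_unaligned`` consecutive unaligned labels on either side
    spanning more than ``tol.span_bp``.
    """
    tol = tol or ConflictTolerances()
    conflicts: list[Conflict] = []
    for scaffold_id in sorted(alignments):
        hits = _drop_nested(list(alignments[scaffold_id]))
        hits.sort(key=lambda a: a.query_span_bp())
        # --- split alignments: adjacent span pairs only, so the conflict
        # interval tightly brackets one junction
        for a, b in zip(hits, hits[1:]):
            a_span, b_span = a.query_span_bp(), b.query_span_bp()
            overlap = min(a_span[1], b_span[1]) - max(a_span[0], b_span[0])
            if overlap > tol.junction_bp:
                continue  # the two alignments cover the same scaffold piece
            if not _map_incompatible(a, b, tol, maps):
                continue
            lo = min(a_span[1], b_span[0])
            hi = max(a_span[1], b_span[0])
            if hi == lo:
                hi = lo + 1
            conflicts.append(
                Conflict(
                    scaffold_id=scaffold_id,
                    map_id=a.ref_id,
                    kind=SPLIT_ALIGNMENT,
                    scaffold_interval=(lo, hi),
                    map_interval=(a.ref_span_bp()[1], a.ref_span_bp()[1] + 1),
                    partner_map_id=b.ref_id,
                )
            )
        # --- internal discordances
        for a in hits:
            conflicts.extend(_internal_discordances(a, tol))
    for k, c in enumerate(conflicts):
        c.conflict_id = k
    return conflicts


def _drop_nested(hits: list[LabelAlignment]) -> list[LabelAlignment]:
    """Drop alignments mostly contained in a higher-confidence one.

    A short chance alignment nested inside the scaffold's real span is a
    repeat or coincidence signal, not evidence of a second piece.
    """
    keep: list[LabelAlignment] = []
    for a in sorted(hits, key=lambda a: -a.confidence):
        lo, hi = a.query_span_bp()
        size = max(1, hi - lo)
        contained = any(
            min(hi, k.query_span_bp()[1]) - max(lo, k.query_span_bp()[0]) >= 0.5 * size
            for k in keep
        )
        if not contained:
            keep.append(a)
    return keep


def _internal_discordances(a: LabelAlignment, tol: ConflictTolerances) -> list[Conflict]:
    out = []
    qbp_orig = a.query_bp_original()
    for step in range(len(a.pairs) - 1):
        (q0, r0), (q1, r1) = a.pairs[step], a.pairs[step + 1]
        skipped_ref = r1 - r0 - 1
        skipped_qry = q1 - q0 - 1
        ref_span = a.ref_bp[step + 1] - a.ref_bp[step]
        qry_span = abs(qbp_orig[step + 1] - qbp_orig[step])
        if (skipped_ref >= tol.min_unaligned and ref_span > tol.span_bp) or (
            skipped_qry >= tol.min_unaligned and qry_span > tol.span_bp
        ):
            lo = min(qbp_orig[step], qbp_orig[step + 1]) - 1
            hi = max(qbp_orig[step], qbp_orig[step + 1])
            out.append(
                Conflict(
                    scaffold_id=a.query_id,
                    map_id=a.ref_id,
                    kind=INTERNAL_DISCORDANCE,
                    scaffold_interval=(lo, hi),
                    map_interval=(a.ref_bp[step] - 1, a.ref_bp[step + 1]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# arbitration


def arbitrate(
    conflict: Conflict,
    second_map_alignments: Mapping[str, Sequence[LabelAlignment]],
    tol: ConflictTolerances | None = None,
    second_maps: Mapping[str, "object"] | None = None,
) -> Conflict:
    """Fill the verdict of a conflict using the second, independent map.

    sequence_error — the second map also conflicts with the scaffold over
    an overlapping interval; map_error — a single second-map alignment
    bridges the full conflict interval with >= ``tol.min_confirm`` aligned
    labels on each side; unresolved — no qualifying evidence. Passing the
    second map contigs (``second_maps``) lets cross-contig alignments that
    merely reflect second-map fragmentation be ignored.
    """
    tol = tol or ConflictTolerances()
    hits = list(second_map_alignments.get(conflict.scaffold_id, []))

    second_conflicts = detect_conflicts(
        {conflict.scaffold_id: hits}, None, second_maps, tol
    )
    # junction brackets from independent maps can each be off by about one
    # label interval; compare them with junction-scale slack
    if any(
        c.overlaps(conflict.scaffold_interval, pad=tol.junction_bp)
        for c in second_conflicts
    ):
        conflict.verdict = SEQUENCE_ERROR
        return conflict

    # concordant coverage across the junction: labels on both sides of the
    # interval from one second-map contig (its chains were just verified
    # mutually compatible, so split chains on one contig still testify to
    # contiguity; chains on different contigs do not)
    lo, hi = conflict.scaffold_interval
    before: dict[str, int] = {}
    after: dict[str, int] = {}
    for a in hits:
        for p in a.query_bp_original():
            if p - 1 < lo:
                before[a.ref_id] = before.get(a.ref_id, 0) + 1
            elif p - 1 >= hi:
                after[a.ref_id] = after.get(a.ref_id, 0) + 1
    for rid, n_before in before.items():
        if n_before >= tol.min_confirm and after.get(rid, 0) >= tol.min_confirm:
            conflict.verdict = MAP_ERROR
            return conflict
    conflict.verdict = UNRESOLVED
    return conflict


# ---------------------------------------------------------------------------
# split planning and application


def merge_conflicts(conflicts: Iterable[Conflict]) -> list[Conflict]:
    """Merge conflicts on one scaffold whose intervals overlap.

    Avoids planning two cuts for one physical event reported twice.
    """
    by_scaffold: dict[str, list[Conflict]] = {}
    for c in conflicts:
        by_scaffold.setdefault(c.scaffold_id, []).append(c)
    merged: list[Conflict] = []
    for sid in sorted(by_scaffold):
        group = sorted(by_scaffold[sid], key=lambda c: c.scaffold_interval)
        current = group[0]
        for c in group[1:]:
            if c.scaffold_interval[0] < current.scaffold_interval[1]:
                current = Conflict(
                    scaffold_id=sid,
                    map_id=current.map_id,
                    kind=current.kind,
                    scaffold_interval=(
                        current.scaffold_interval[0],
                        max(current.scaffold_interval[1], c.scaffold_interval[1]),
                    ),
                    map_interval=current.map_interval,
                    verdict=current.verdict,
                    partner_map_id=current.partner_map_id,
                    conflict_id=current.conflict_id,
                )
            else:
                merged.append(current)
                current = c
        merged.append(current)
    return merged


def plan_splits(
    conflicts: Iterable[Conflict],
    n_runs: Mapping[str, Sequence[NRun]],
    search_pad: int = 50_000,
) -> list[SplitPlan]:
    """Choose cut sites for confirmed sequence errors.

    Every N run intersecting the merged conflict interval is cut at its
    midpoint: the true junction can hide behind any of them, and cutting
    only the most central one would leave residual mis-joined sequence
    whenever a scaffold-internal N gap shares the bracket with the real
    junction. The interval brackets the junction only to about one label
    interval, so when it contains no N run at all the search widens by
    ``search_pad`` and takes the single run nearest the centre. A conflict
    with no N run even in the widened window is marked unresolved and
    logged — never a blind cut into real sequence.
    """
    plans: dict[str, SplitPlan] = {}
    for c in merge_conflicts(c for c in conflicts if c.verdict == SEQUENCE_ERROR):
        lo, hi = c.scaffold_interval
        centre = (lo + hi) / 2.0
        runs = [r for r in n_runs.get(c.scaffold_id, []) if r.end > lo and r.start < hi]
        if not runs:
            widened = [
                r for r in n_runs.get(c.scaffold_id, [])
                if r.end > lo - search_pad and r.start < hi + search_pad
            ]
            if widened:
                runs = [min(widened, key=lambda r: (abs(r.midpoint - centre), r.start))]
        if not runs:
            c.verdict = UNRESOLVED
            logger.warning(
                "conflict on %s [%d,%d): no N run in interval, leaving unsplit",
                c.scaffold_id, lo, hi,
            )
            continue
        plan = plans.get(c.scaffold_id)
        if plan is None:
            plan = plans[c.scaffold_id] = SplitPlan(c.scaffold_id, [], [])
        for run in runs:
            if run.midpoint not in plan.cut_positions:
                plan.cut_positions.append(run.midpoint)
        plan.cut_positions.sort()
        plan.provenance.append(c.conflict_id)
    return [plans[k] for k in sorted(plans)]


def apply_splits(
    scaffolds: Sequence[SequenceRecord],
    plans: Iterable[SplitPlan],
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Cut scaffolds at planned positions.

    k cuts in one record yield k+1 pieces named ``<id>_1`` ... ``<id>_k+1``
    in coordinate order; N bases up to a cut stay with the left piece. The
    record count grows by exactly the number of cuts and the multiset of
    non-N bases is conserved. Returns the new ledger and a provenance
    table (piece id, parent id, parent start/end).
    """
    by_id = {p.scaffold_id: p for p in plans}
    out: list[SequenceRecord] = []
    prov_rows = []
    for rec in scaffolds:
        plan = by_id.get(rec.seq_id)
        if plan is None:
            out.append(rec)
            continue
        if any(c <= 0 or c >= rec.length_bp for c in plan.cut_positions):
            raise ValueError(f"cut outside sequence {rec.seq_id}")
        bounds = [0, *plan.cut_positions, rec.length_bp]
        for k, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
            piece_id = f"{rec.seq_id}_{k}"
            out.append(SequenceRecord(piece_id, rec.bases[s:e]))
            prov_rows.append(
                {"piece_id": piece_id, "parent_id": rec.seq_id, "parent_start": s, "parent_end": e}
            )
    provenance = pd.DataFrame(prov_rows, columns=["piece_id", "parent_id", "parent_start", "parent_end"])
    return out, provenance


def conflict_report(conflicts: Iterable[Conflict], plans: Iterable[SplitPlan] | None = None) -> pd.DataFrame:
    """Tabular conflict report (one row per conflict, with any cut site)."""
    cuts: dict[str, list[int]] = {}
    for p in plans or []:
        cuts[p.scaffold_id] = p.cut_positions
    rows = []
    for c in conflicts:
        rows.append(
            {
                "scaffold_id": c.scaffold_id,
                "kind": c.kind,
                "scaffold_start": c.scaffold_interval[0],
                "scaffold_end": c.scaffold_interval[1],
                "map_id": c.map_id,
                "map_start": c.map_interval[0],
                "map_end": c.map_interval[1],
                "verdict": c.verdict,
                "cut_positions": ",".join(map(str, cuts.get(c.scaffold_id, []))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold_id", "kind", "scaffold_start", "scaffold_end",
            "map_id", "map_start", "map_end", "verdict", "cut_positions",
        ],
    )


def write_conflict_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
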
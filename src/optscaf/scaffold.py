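"""Hybrid scaffolding: order, orient and join scaffolds along optical maps.

Validated (chimera-free) scaffolds are placed on optical map contigs by
their best confident alignment, ordered by map coordinate, and joined into
super-scaffolds whose junction gaps are sized from the map distance between
the flanking aligned labels. A second round against an independent map of
the other chemistry can merge super-scaffolds the first map left apart.

Gap sizes come from label geometry: the map distance between the last
aligned label of the left scaffold and the first aligned label of the
right one, minus the unaligned (non-N) sequence overhangs of both. N bases
in an overhang are unsized placeholders and are not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignParams, LabelAlignment, align_all
from .conflicts import ConflictTolerances, detect_conflicts
from .core import LabelMap, RecognitionSpec, SequenceRecord, digest_sequence, n50, revcomp

UNKNOWN_GAP_BP = 100  # nominal length written for unknown-size gaps (AGP "U")


@dataclass
class Placement:
    """One scaffold placed on one map contig."""

    seq_id: str
    map_id: str
    map_start: int  # 0-based, extrapolated to the full scaffold
    map_end: int
    orientation: str
    confidence: float
    alignment: LabelAlignment

    def __post_init__(self):
        if self.map_end <= self.map_start:
            raise ValueError("empty placement interval")


@dataclass
class Member:
    seq_id: str
    orientation: str
    gap_after: int | None = None  # None for the last member
    gap_known: bool = True


@dataclass
class SuperScaffold:
    super_id: str
    members: list[Member]

    @property
    def member_ids(self) -> list[str]:
        return [m.seq_id for m in self.members]

    def length_bp(self, lengths: Mapping[str, int]) -> int:
        total = sum(lengths[m.seq_id] for m in self.members)
        for m in self.members[:-1]:
            total += m.gap_after if m.gap_known else UNKNOWN_GAP_BP
        return total

    def reversed(self) -> "SuperScaffold":
        flip = {"+": "-", "-": "+"}
        rev: list[Member] = []
        for i, m in enumerate(reversed(self.members)):
            prev_in_orig = self.members[len(self.members) - 1 - i - 1] if i < len(self.members) - 1 else None
            rev.append(
                Member(
                    m.seq_id,
                    flip[m.orientation],
                    None if prev_in_orig is None else prev_in_orig.gap_after,
                    True if prev_in_orig is None else prev_in_orig.gap_known,
                )
            )
        return SuperScaffold(self.super_id, rev)


# ---------------------------------------------------------------------------
# placement


def _extrapolated_span(a: LabelAlignment) -> tuple[int, int]:
    """Full-scaffold interval on the map implied by an alignment (0-based)."""
    start = (a.ref_bp[0] - 1) - (a.query_bp[0] - 1)
    return start, start + a.query_len_bp


def _same_locus(a: LabelAlignment, b: LabelAlignment) -> bool:
    if a.ref_id != b.ref_id:
        return False
    sa, sb = _extrapolated_span(a), _extrapolated_span(b)
    return min(sa[1], sb[1]) > max(sa[0], sb[0])


CHAIN_MERGE_TOL_BP = 50_000  # max offset disagreement when stitching chains


def _merge_sibling_chains(best: LabelAlignment, hits) -> LabelAlignment:
    """Stitch compatible chains of one scaffold on one contig into one.

    A mis-sized internal N gap can split a scaffold's alignment into
    several chains; placement and gap estimation must see the scaffold's
    full aligned extent, not just its best fragment. Chains are accepted
    in confidence order when they sit on the same contig and orientation,
    do not overlap the accepted set, and keep query and reference
    displacements consistent within ``CHAIN_MERGE_TOL_BP``.
    """
    group = [best]
    for h in sorted(hits, key=lambda a: -a.confidence):
        if h is best or h.ref_id != best.ref_id or h.orientation != best.orientation:
            continue
        ok = True
        for g in group:
            if h.query_bp[0] > g.query_bp[-1]:
                left, right = g, h
            elif h.query_bp[-1] < g.query_bp[0]:
                left, right = h, g
            else:
                ok = False  # overlapping chains: alternates, not pieces
                break
            dq = right.query_bp[0] - left.query_bp[-1]
            dr = right.ref_bp[0] - left.ref_bp[-1]
            # dr == 0: chains share a boundary ref label (only query labels
            # are masked during extraction); deduplicated below
            if dr < 0 or abs(dq - dr) > CHAIN_MERGE_TOL_BP:
                ok = False
                break
        if ok:
            group.append(h)
    if len(group) == 1:
        return best
    group.sort(key=lambda a: a.query_bp[0])
    pairs = []
    qbp = []
    rbp = []
    for g in group:
        for (qi, ri), qb, rb in zip(g.pairs, g.query_bp, g.ref_bp):
            if pairs and (qi <= pairs[-1][0] or ri <= pairs[-1][1]):
                continue  # shared boundary label
            pairs.append((qi, ri))
            qbp.append(qb)
            rbp.append(rb)
    return LabelAlignment(
        query_id=best.query_id,
        ref_id=best.ref_id,
        orientation=best.orientation,
        pairs=pairs,
        confidence=sum(g.confidence for g in group),
        score=sum(g.score for g in group),
        query_len_bp=best.query_len_bp,
        query_n_labels=best.query_n_labels,
        query_bp=qbp,
        ref_bp=rbp,
        query_site_width=best.query_site_width,
    )


def place_sequences(
    alignments: Mapping[str, Sequence[LabelAlignment]],
    scaffolds: Mapping[str, SequenceRecord],
    maps: Mapping[str, LabelMap],
    min_confidence: float = 10.0,
    margin: float = 3.0,
    overlap_tol: int = 20_000,
) -> list[Placement]:
    """Give each scaffold at most one placement: its best alignment.

    A scaffold whose runner-up alignment on a *different* locus comes
    within ``margin`` confidence units of the best is ambiguous and stays
    unplaced. Placements overlapping by more than ``overlap_tol`` bp on
    one map are resolved in favour of the higher confidence.
    """
    placements: list[Placement] = []
    for sid in sorted(alignments):
        hits = [a for a in alignments[sid] if a.confidence >= min_confidence]
        if not hits:
            continue
        hits.sort(key=lambda a: -a.confidence)
        best = hits[0]
        rival = next((h for h in hits[1:] if not _same_locus(best, h)), None)
        if rival is not None and best.confidence - rival.confidence < margin:
            continue  # ambiguous
        best = _merge_sibling_chains(best, hits)
        start, end = _extrapolated_span(best)
        map_len = maps[best.ref_id].length_bp if best.ref_id in maps else None
        if map_len is not None:
            start, end = max(0, start), min(map_len, end)
            if end <= start:
                continue
        placements.append(
            Placement(sid, best.ref_id, start, end, best.orientation, best.confidence, best)
        )
    # resolve overlaps per map, lower confidence demoted
    keep: dict[str, Placement] = {}
    by_map: dict[str, list[Placement]] = {}
    for p in placements:
        by_map.setdefault(p.map_id, []).append(p)
    for mid in sorted(by_map):
        group = sorted(by_map[mid], key=lambda p: -p.confidence)
        accepted: list[Placement] = []
        for p in group:
            clash = any(
                min(p.map_end, q.map_end) - max(p.map_start, q.map_start) > overlap_tol
                for q in accepted
            )
            if not clash:
                accepted.append(p)
        for p in accepted:
            keep[p.seq_id] = p
    return sorted(keep.values(), key=lambda p: (p.map_id, p.map_start, p.seq_id))


# ---------------------------------------------------------------------------
# gap estimation


def _flipped_interval_to_original(orientation: str, length: int, lo: int, hi: int) -> tuple[int, int]:
    """Map a 0-based half-open interval from the flipped frame to the original."""
    if orientation == "+":
        return lo, hi
    return length - hi, length - lo


def _overhang_non_n(a: LabelAlignment, seq: SequenceRecord, which: str) -> int:
    """Non-N bases of the unaligned scaffold overhang before/after the chain."""
    L = a.query_len_bp
    if which == "tail":
        lo_f, hi_f = a.query_bp[-1], L  # bases strictly after the last aligned label
    else:
        lo_f, hi_f = 0, a.query_bp[0] - 1  # strictly before the first aligned label
    lo, hi = _flipped_interval_to_original(a.orientation, L, lo_f, hi_f)
    segment = seq.bases[lo:hi]
    return len(segment) - segment.count("N")


def estimate_gap(
    left: Placement,
    right: Placement,
    left_seq: SequenceRecord,
    right_seq: SequenceRecord,
    min_gap: int = 13,
) -> int:
    """Estimate the gap between two adjacent placements on one map.

    gap = (bases strictly between the flanking aligned labels on the map)
          - (non-N overhang of the left scaffold past its last aligned label)
          - (non-N overhang of the right scaffold before its first aligned label),
    floored at ``min_gap``.
    """
    if left.map_id != right.map_id:
        raise ValueError("placements are not on the same map")
    if right.map_start < left.map_start:
        raise ValueError("placements are not in left-to-right order")
    between = right.alignment.ref_bp[0] - left.alignment.ref_bp[-1] - 1
    raw = between - _overhang_non_n(left.alignment, left_seq, "tail") - _overhang_non_n(
        right.alignment, right_seq, "head"
    )
    return max(int(raw), min_gap)


# ---------------------------------------------------------------------------
# super-scaffold construction


def build_superscaffolds(
    placements: Sequence[Placement],
    scaffolds: Mapping[str, SequenceRecord],
    min_gap: int = 13,
) -> list[SuperScaffold]:
    """Assemble per-map super-scaffolds plus pass-through singletons.

    Members are ordered by map coordinate; junction gaps come from
    :func:`estimate_gap`. Every scaffold without a placement becomes a
    singleton super-scaffold retaining its original id.
    """
    by_map: dict[str, list[Placement]] = {}
    placed = set()
    for p in placements:
        by_map.setdefault(p.map_id, []).append(p)
        placed.add(p.seq_id)
    supers: list[SuperScaffold] = []
    for mid in sorted(by_map):
        group = sorted(by_map[mid], key=lambda p: p.map_start)
        if len(group) == 1:
            p = group[0]
            supers.append(SuperScaffold(p.seq_id, [Member(p.seq_id, p.orientation)]))
            continue
        members: list[Member] = []
        for a, b in zip(group, group[1:]):
            gap = estimate_gap(a, b, scaffolds[a.seq_id], scaffolds[b.seq_id], min_gap)
            members.append(Member(a.seq_id, a.orientation, gap, True))
        members.append(Member(group[-1].seq_id, group[-1].orientation))
        supers.append(SuperScaffold(f"super_{mid}", members))
    for sid in sorted(scaffolds):
        if sid not in placed:
            supers.append(SuperScaffold(sid, [Member(sid, "+")]))
    return supers


# ---------------------------------------------------------------------------
# sequence emission and AGP

AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number",
    "component_type", "component_id", "component_beg", "component_end", "orientation",
]


def emit_sequences(
    supers: Sequence[SuperScaffold],
    scaffolds: Mapping[str, SequenceRecord],
    gap_evidence: str = "map",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Concatenate members (reverse-complemented for '-') with N gaps.

    Known gaps become AGP "N" rows of their estimated length; unknown gaps
    become "U 100" rows. Reconstructing from the AGP plus the member FASTA
    reproduces the emitted sequences exactly.
    """
    records: list[SequenceRecord] = []
    rows = []
    for ss in supers:
        parts: list[str] = []
        pos = 0
        part_no = 0
        for i, m in enumerate(ss.members):
            if m.seq_id not in scaffolds:
                raise KeyError(f"member {m.seq_id!r} missing from sequence collection")
            seq = scaffolds[m.seq_id]
            bases = seq.bases if m.orientation == "+" else revcomp(seq.bases)
            part_no += 1
            rows.append(
                {
                    "object": ss.super_id, "object_beg": pos + 1,
                    "object_end": pos + len(bases), "part_number": part_no,
                    "component_type": "W", "component_id": m.seq_id,
                    "component_beg": 1, "component_end": len(bases),
                    "orientation": m.orientation,
                }
            )
            parts.append(bases)
            pos += len(bases)
            if i < len(ss.members) - 1:
                gap = m.gap_after if m.gap_known else UNKNOWN_GAP_BP
                part_no += 1
                rows.append(
                    {
                        "object": ss.super_id, "object_beg": pos + 1,
                        "object_end": pos + gap, "part_number": part_no,
                        "component_type": "N" if m.gap_known else "U",
                        "component_id": gap, "component_beg": "scaffold",
                        "component_end": "yes", "orientation": gap_evidence,
                    }
                )
                parts.append("N" * gap)
                pos += gap
        records.append(SequenceRecord(ss.super_id, "".join(parts)))
    return records, pd.DataFrame(rows, columns=AGP_COLUMNS)


def reconstruct_from_agp(
    agp: pd.DataFrame, components: Mapping[str, SequenceRecord]
) -> list[SequenceRecord]:
    """Rebuild object sequences from AGP rows plus component sequences."""
    records = []
    for obj, group in agp.groupby("object", sort=False):
        parts = []
        for _, row in group.sort_values("part_number").iterrows():
            if row["component_type"] == "W":
                seq = components[row["component_id"]].bases
                seq = seq[int(row["component_beg"]) - 1 : int(row["component_end"])]
                parts.append(seq if row["orientation"] == "+" else revcomp(seq))
            else:
                parts.append("N" * int(row["component_id"]))
        records.append(SequenceRecord(str(obj), "".join(parts)))
    return records


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 AGP columns")
            rows.append(dict(zip(AGP_COLUMNS, parts)))
    df = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# second round against the independent map


def second_round(
    supers: Sequence[SuperScaffold],
    scaffolds: Mapping[str, SequenceRecord],
    second_maps: Sequence[LabelMap],
    enzyme: RecognitionSpec,
    params: AlignParams | None = None,
    tol: ConflictTolerances | None = None,
    merge_confidence: float = 15.0,
    min_gap: int = 13,
    margin: float = 3.0,
    overlap_tol: int = 20_000,
) -> tuple[list[SuperScaffold], list]:
    """Validate and further merge super-scaffolds with the second map.

    Super-scaffold sequences are re-digested (gap Ns carry no labels) and
    aligned to the second map; any super-scaffold now in conflict is left
    untouched and reported for re-arbitration with the map roles swapped.
    Concordantly placed super-scaffolds meeting ``merge_confidence`` are
    merged along each second-map contig, with junction gaps estimated from
    its labels. Merging never fragments, so N50 cannot decrease.
    """
    params = params or AlignParams()
    tol = tol or ConflictTolerances()
    records, _ = emit_sequences(supers, scaffolds)
    rec_by_id = {r.seq_id: r for r in records}
    digests = [digest_sequence(r, enzyme, min_label_distance_bp=0) for r in records]
    alignments = align_all(digests, second_maps, params)
    second_by_id = {m.map_id: m for m in second_maps}
    conflicts = detect_conflicts(alignments, None, second_by_id, tol)
    conflicted = {c.scaffold_id for c in conflicts}

    mergeable = {
        sid: [a for a in hits if a.confidence >= merge_confidence]
        for sid, hits in alignments.items()
        if sid not in conflicted
    }
    placements = place_sequences(
        mergeable, rec_by_id, {m.map_id: m for m in second_maps},
        min_confidence=merge_confidence, margin=margin, overlap_tol=overlap_tol,
    )
    by_super = {s.super_id: s for s in supers}
    by_map: dict[str, list[Placement]] = {}
    for p in placements:
        by_map.setdefault(p.map_id, []).append(p)

    merged_ids: set[str] = set()
    out: list[SuperScaffold] = []
    for mid in sorted(by_map):
        group = sorted(by_map[mid], key=lambda p: p.map_start)
        if len(group) < 2:
            continue
        members: list[Member] = []
        for i, p in enumerate(group):
            ss = by_super[p.seq_id]
            oriented = ss if p.orientation == "+" else ss.reversed()
            members.extend(
                Member(m.seq_id, m.orientation, m.gap_after, m.gap_known)
                for m in oriented.members
            )
            if i < len(group) - 1:
                nxt = group[i + 1]
                gap = estimate_gap(p, nxt, rec_by_id[p.seq_id], rec_by_id[nxt.seq_id], min_gap)
                members[-1] = replace(members[-1], gap_after=gap, gap_known=True)
            merged_ids.add(p.seq_id)
        out.append(SuperScaffold("+".join(p.seq_id for p in group), members))
    for ss in supers:
        if ss.super_id not in merged_ids:
            out.append(ss)
    return out, conflicts


def superscaffold_n50(supers: Sequence[SuperScaffold], lengths: Mapping[str, int]) -> int:
    return n50([ss.length_bp(lengths) for ss in supers])
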
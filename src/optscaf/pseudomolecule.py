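"""Chromosome assignment, ordering/orienting by genetic maps, and accounting.

Scaffolds (or super-scaffolds) carrying two or more concordant linkage-map
markers are assigned to the chromosome contributing the majority of their
markers, ordered along it by mean marker centimorgan, and oriented by the
sign of the rank correlation between marker cM and scaffold bp. Anchored
scaffolds are joined with fixed 1000-N spacers into pseudomolecules; the
rest stay in ChrUn as separate records. Accounting operations reproduce
the per-chromosome length / effective-length / N% / unknown-gap tables and
the rescued / relocated / reoriented provenance ledger against a prior
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SequenceRecord
from .scaffold import AGP_COLUMNS, reconstruct_from_agp

WHEAT_CHROMOSOMES = [f"{i}{g}" for i in range(1, 8) for g in "AB"]
CHRUN = "ChrUn"
JOIN_GAP_BP = 1000  # fixed unknown-size spacer between anchored scaffolds

MARKER_COLUMNS = ["marker_id", "chrom", "cm", "scaffold_id", "pos"]


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    chrom: str
    cm_pos: float
    scaffold_id: str
    scaffold_pos: int


@dataclass
class ChromAssignment:
    scaffold_id: str
    chrom: str
    n_markers: int
    mean_cm: float
    orientation: str = "+"  # '+' | '-'; undetermined recorded as '+' with flag
    orientation_determined: bool = True


@dataclass
class PseudomoleculeSet:
    """14 (or however many) chromosome objects + AGP + ChrUn leftovers."""

    chromosomes: dict[str, int]  # name -> length_bp
    agp: pd.DataFrame
    chrun: list[str]
    anchored: list[str]
    ledger: pd.DataFrame | None = None

    @property
    def unknown_gap_counts(self) -> dict[str, int]:
        gaps = self.agp[self.agp["component_type"].isin(["N", "U"])]
        counts = gaps.groupby("object").size().to_dict()
        return {c: int(counts.get(c, 0)) for c in self.chromosomes}

    @property
    def total_unknown_gaps(self) -> int:
        return sum(self.unknown_gap_counts.values())

    def members_of(self, chrom: str) -> list[tuple[str, str]]:
        rows = self.agp[(self.agp["object"] == chrom) & (self.agp["component_type"] == "W")]
        rows = rows.sort_values("part_number")
        return list(zip(rows["component_id"], rows["orientation"]))


# ---------------------------------------------------------------------------
# marker io


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing marker columns {sorted(missing)}")
    return df[MARKER_COLUMNS]


def write_markers(df: pd.DataFrame, path: str | Path) -> None:
    df[MARKER_COLUMNS].to_csv(path, sep="\t", index=False)


def merge_marker_maps(maps: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of several linkage maps; markers with conflicting chromosome
    claims across maps are dropped (conservative)."""
    df = pd.concat(maps, ignore_index=True)
    claims = df.groupby("marker_id")["chrom"].nunique()
    consistent = claims[claims == 1].index
    return df[df["marker_id"].isin(consistent)].drop_duplicates("marker_id")


def remap_markers(markers: pd.DataFrame, provenance: pd.DataFrame) -> pd.DataFrame:
    """Re-address marker hits from split parents to their pieces.

    ``provenance`` is the table from apply_splits (piece_id, parent_id,
    parent_start, parent_end).
    """
    if provenance.empty:
        return markers.copy()
    out = markers.copy()
    for parent_id, group in provenance.groupby("parent_id"):
        sel = out["scaffold_id"] == parent_id
        if not sel.any():
            continue
        for _, row in group.iterrows():
            inside = sel & (out["pos"] > row["parent_start"]) & (out["pos"] <= row["parent_end"])
            out.loc[inside, "scaffold_id"] = row["piece_id"]
            out.loc[inside, "pos"] = out.loc[inside, "pos"] - row["parent_start"]
    return out


# ---------------------------------------------------------------------------
# assignment, ordering, orientation


def assign_chromosomes(
    marker_hits: pd.DataFrame,
    scaffold_ids: Iterable[str],
    min_markers: int = 2,
) -> tuple[list[ChromAssignment], pd.DataFrame]:
    """Assign each scaffold to the majority chromosome of its markers.

    Requires at least ``min_markers`` markers from that chromosome (the
    two-or-more-SNP-markers anchoring rule); majority ties go unassigned.
    Returns assignments plus the table of discordant (minority) markers.
    """
    ids = set(scaffold_ids)
    assignments: list[ChromAssignment] = []
    discordant_frames = []
    for sid, group in marker_hits.groupby("scaffold_id"):
        if sid not in ids:
            continue
        counts = group["chrom"].value_counts()
        top = counts.max()
        winners = counts[counts == top].index
        if len(winners) > 1 or top < min_markers:
            continue
        chrom = winners[0]
        concordant = group[group["chrom"] == chrom]
        minority = group[group["chrom"] != chrom]
        if not minority.empty:
            discordant_frames.append(minority)
        assignments.append(
            ChromAssignment(
                scaffold_id=sid,
                chrom=chrom,
                n_markers=int(top),
                mean_cm=float(concordant["cm"].mean()),
            )
        )
    discordant = (
        pd.concat(discordant_frames, ignore_index=True)
        if discordant_frames
        else pd.DataFrame(columns=marker_hits.columns)
    )
    return assignments, discordant


def order_and_orient(
    assignments: Sequence[ChromAssignment],
    marker_hits: pd.DataFrame,
    lengths: Mapping[str, int],
) -> dict[str, list[ChromAssignment]]:
    """Per-chromosome ordered, oriented scaffold lists.

    Order: mean cM of concordant markers, ties broken by length (longer
    first) then lexicographic id. Orientation: sign of the Spearman rank
    correlation between marker cM and scaffold bp, computed only when at
    least two distinct cM values exist; degenerate cases are recorded as
    '+' with ``orientation_determined`` False.
    """
    out: dict[str, list[ChromAssignment]] = {}
    for a in assignments:
        hits = marker_hits[
            (marker_hits["scaffold_id"] == a.scaffold_id) & (marker_hits["chrom"] == a.chrom)
        ]
        cm = hits["cm"].to_numpy(float)
        bp = hits["pos"].to_numpy(float)
        if len(np.unique(cm)) >= 2:
            rho = stats.spearmanr(cm, bp).statistic
            if np.isnan(rho) or rho == 0:
                a.orientation, a.orientation_determined = "+", False
            else:
                a.orientation, a.orientation_determined = ("+" if rho > 0 else "-"), True
        else:
            a.orientation, a.orientation_determined = "+", False
        out.setdefault(a.chrom, []).append(a)
    for chrom in out:
        out[chrom].sort(key=lambda a: (a.mean_cm, -lengths[a.scaffold_id], a.scaffold_id))
    return {c: out[c] for c in sorted(out)}


# ---------------------------------------------------------------------------
# pseudomolecule construction


def build_pseudomolecules(
    ordered: Mapping[str, Sequence[ChromAssignment]],
    lengths: Mapping[str, int],
    all_scaffold_ids: Iterable[str] | None = None,
    join_gap: int = JOIN_GAP_BP,
) -> PseudomoleculeSet:
    """Join anchored scaffolds with fixed ``join_gap`` Ns per chromosome.

    Chromosome length = sum of member lengths + join_gap * (members - 1);
    with S anchored scaffolds over C chromosomes the set carries exactly
    S - C unknown-length joins. Works on lengths alone; sequence emission
    is a separate step so genome-scale accounting stays cheap.
    """
    chrom_lengths: dict[str, int] = {}
    rows = []
    anchored: list[str] = []
    for chrom in sorted(ordered):
        members = ordered[chrom]
        if not members:
            raise ValueError(f"chromosome {chrom} has no members")
        pos = 0
        part = 0
        for i, a in enumerate(members):
            L = lengths[a.scaffold_id]
            part += 1
            rows.append(
                {
                    "object": chrom, "object_beg": pos + 1, "object_end": pos + L,
                    "part_number": part, "component_type": "W",
                    "component_id": a.scaffold_id, "component_beg": 1,
                    "component_end": L, "orientation": a.orientation,
                }
            )
            pos += L
            anchored.append(a.scaffold_id)
            if i < len(members) - 1:
                part += 1
                rows.append(
                    {
                        "object": chrom, "object_beg": pos + 1, "object_end": pos + join_gap,
                        "part_number": part, "component_type": "U",
                        "component_id": join_gap, "component_beg": "contig",
                        "component_end": "yes", "orientation": "map",
                    }
                )
                pos += join_gap
        chrom_lengths[chrom] = pos
    anchored_set = set(anchored)
    chrun = (
        sorted(set(all_scaffold_ids) - anchored_set) if all_scaffold_ids is not None else []
    )
    return PseudomoleculeSet(
        chromosomes=chrom_lengths,
        agp=pd.DataFrame(rows, columns=AGP_COLUMNS),
        chrun=chrun,
        anchored=anchored,
    )


def emit_pseudomolecule_fasta(
    pset: PseudomoleculeSet, scaffolds: Mapping[str, SequenceRecord]
) -> list[SequenceRecord]:
    """Materialise chromosome sequences from the AGP (ChrUn never emitted
    as a concatenated record — unplaced scaffolds stay separate)."""
    return reconstruct_from_agp(pset.agp, scaffolds)


# ---------------------------------------------------------------------------
# accounting


def gene_accounting(
    gene_to_scaffold: pd.DataFrame, pset: PseudomoleculeSet
) -> pd.DataFrame:
    """Per-chromosome counts of genes hosted by anchored scaffolds.

    ``gene_to_scaffold`` needs columns gene_id, scaffold_id; duplicate
    gene ids are rejected. Genes on ChrUn scaffolds are counted under
    ChrUn; the totals are additive by construction.
    """
    if gene_to_scaffold["gene_id"].duplicated().any():
        dup = gene_to_scaffold.loc[gene_to_scaffold["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    host = {}
    for chrom in pset.chromosomes:
        for sid, _ in pset.members_of(chrom):
            host[sid] = chrom
    for sid in pset.chrun:
        host[sid] = CHRUN
    located = gene_to_scaffold["scaffold_id"].map(host)
    counts = located.value_counts()
    rows = [
        {"chrom": c, "genes": int(counts.get(c, 0))}
        for c in list(pset.chromosomes) + [CHRUN]
    ]
    df = pd.DataFrame(rows)
    on_pseudo = int(df[df["chrom"] != CHRUN]["genes"].sum())
    df = pd.concat(
        [df, pd.DataFrame([{"chrom": "Total_pseudomolecules", "genes": on_pseudo}])],
        ignore_index=True,
    )
    return df


def _lcs_keep(old: Sequence[str], new: Sequence[str]) -> set[str]:
    """Ids in a longest common subsequence of two orderings."""
    n, m = len(old), len(new)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if old[i] == new[j]:
                dp[i, j] = dp[i + 1, j + 1] + 1
            else:
                dp[i, j] = max(dp[i + 1, j], dp[i, j + 1])
    keep = set()
    i = j = 0
    while i < n and j < m:
        if old[i] == new[j]:
            keep.add(old[i])
            i += 1
            j += 1
        elif dp[i + 1, j] >= dp[i, j + 1]:
            i += 1
        else:
            j += 1
    return keep


def compare_assemblies(
    new: PseudomoleculeSet,
    old: pd.DataFrame,
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Classify each scaffold's fate relative to a prior assembly.

    ``old`` needs columns scaffold_id, chrom (CHRUN for unplaced),
    position (order index), orientation. Classes: rescued (old ChrUn, now
    anchored); relocated (chromosome changed, or order within the shared
    chromosome changed — judged by a longest-common-subsequence of the two
    orders so that a moved scaffold does not drag its unmoved neighbours
    with it); reoriented (same place, flipped); unchanged.
    """
    rows = []
    for chrom in new.chromosomes:
        for pos, (sid, orient) in enumerate(new.members_of(chrom)):
            rows.append(
                {"scaffold_id": sid, "chrom": chrom, "position": pos, "orientation": orient}
            )
    new_df = pd.DataFrame(rows, columns=["scaffold_id", "chrom", "position", "orientation"])
    return compare_layouts(new_df, old, lengths)


def compare_layouts(
    new: pd.DataFrame,
    old: pd.DataFrame,
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Layout-level core of :func:`compare_assemblies`.

    Both tables carry columns scaffold_id, chrom, position, orientation;
    rows of ``new`` with chrom CHRUN are ignored (unanchored scaffolds are
    not classified).
    """
    old = old.set_index("scaffold_id")
    rows = []
    new_layout: dict[str, tuple[str, str]] = {}
    new_orders: dict[str, list[str]] = {}
    anchored = new[new["chrom"] != CHRUN].sort_values(["chrom", "position"])
    for _, r in anchored.iterrows():
        new_layout[r["scaffold_id"]] = (r["chrom"], r["orientation"])
        new_orders.setdefault(r["chrom"], []).append(r["scaffold_id"])

    stable: dict[str, set[str]] = {}
    for chrom, new_order in new_orders.items():
        old_chrom = old[old["chrom"] == chrom].sort_values("position")
        shared_old = [s for s in old_chrom.index if s in new_layout and new_layout[s][0] == chrom]
        shared_new = [s for s in new_order if s in old.index and old.loc[s, "chrom"] == chrom]
        stable[chrom] = _lcs_keep(shared_old, shared_new)

    for sid, (chrom, orient) in new_layout.items():
        if sid not in old.index:
            cls = "rescued"
        elif old.loc[sid, "chrom"] == CHRUN:
            cls = "rescued"
        elif old.loc[sid, "chrom"] != chrom or sid not in stable[chrom]:
            cls = "relocated"
        elif old.loc[sid, "orientation"] != orient:
            cls = "reoriented"
        else:
            cls = "unchanged"
        rows.append(
            {
                "scaffold_id": sid, "class": cls, "chrom": chrom,
                "length_bp": int(lengths[sid]) if lengths else 0,
            }
        )
    return pd.DataFrame(rows, columns=["scaffold_id", "class", "chrom", "length_bp"])


def ledger_summary(ledger: pd.DataFrame) -> pd.DataFrame:
    return (
        ledger.groupby("class")
        .agg(n_scaffolds=("scaffold_id", "size"), total_bp=("length_bp", "sum"))
        .reset_index()
    )


def report_tables(
    lengths: Mapping[str, int],
    effective: Mapping[str, int],
    unknown_gaps: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-chromosome length / effective length / N% report with totals.

    N% = 100 * (length - effective) / length, rounded to 2 decimals; the
    totals row is the column sum with N% recomputed on the summed values.
    """
    rows = []
    for chrom in lengths:
        L, eff = int(lengths[chrom]), int(effective[chrom])
        row = {
            "chrom": chrom, "length_bp": L, "effective_bp": eff,
            "n_pct": round(100.0 * (L - eff) / L, 2) if L else 0.0,
        }
        if unknown_gaps is not None:
            row["unknown_gaps"] = int(unknown_gaps.get(chrom, 0))
        rows.append(row)
    tot_l = sum(r["length_bp"] for r in rows)
    tot_e = sum(r["effective_bp"] for r in rows)
    total = {
        "chrom": "Total", "length_bp": tot_l, "effective_bp": tot_e,
        "n_pct": round(100.0 * (tot_l - tot_e) / tot_l, 2) if tot_l else 0.0,
    }
    if unknown_gaps is not None:
        total["unknown_gaps"] = sum(r["unknown_gaps"] for r in rows)
    rows.append(total)
    return pd.DataFrame(rows)
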
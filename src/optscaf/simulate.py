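"""Synthetic genomes, scaffolds, optical maps and linkage maps with truth.

Every other module is testable against this generator: it emits a random
genome with controllable label density (motif sites are scrubbed from the
random background and re-planted as a Poisson process, so the expected
label spacing is a dial rather than an accident of base composition),
fragments it into scaffolds with internal N gaps, injects chimeras and
layout errors, images the chromosomes into noisy optical map contigs under
either labelling chemistry, and writes a genetic map — all alongside a
machine-readable ground truth.

Noise channels for the optical maps are the physically motivated ones:
per-label Bernoulli misses, Poisson false labels, Gaussian interval sizing
error with sd proportional to the square root of the interval, and — for
nicking chemistry only — double-strand breaks at fragile sites (close
opposite-strand nick pairs), which is what fragments nick-labelled maps
relative to direct-label maps of the same genome.

All randomness derives from one mandatory seed through independent,
operation-tagged child generators, so adding a new draw to one operation
never perturbs the streams of the others.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    BSPQI,
    DLE1,
    LabelMap,
    RecognitionSpec,
    SequenceRecord,
    digest_with_strands,
    fragile_pairs,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

# fixed stream tags: one child generator per operation
_TAGS = {
    "genome": 1, "repeats": 2, "plant": 3, "fragment": 4,
    "errors": 5, "map": 6, "markers": 7, "old": 8,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    The default preset is the desk-scale benchmark: a 50-Mb genome of 4
    chromosomes, about 15 labels per 100 kb for each chemistry, about 120
    scaffolds, 8 injected chimeras and 10 injected layout errors — small
    enough for a full pipeline run on one CPU in a few minutes while
    keeping hundreds of junctions and thousands of labels in play.
    """

    seed: int
    n_chromosomes: int = 4
    chromosome_length_bp: int = 12_500_000
    label_density: float = 15.0  # expected labels per 100 kb, per enzyme
    enzymes: tuple[RecognitionSpec, ...] = (DLE1, BSPQI)
    chemistry: RecognitionSpec = DLE1  # default imaging chemistry
    repeat_families: tuple[tuple[int, int, int], ...] = ()  # (unit_bp, copies, insertions)
    scaffold_break_rate: float = 2.3  # per Mb
    min_segment_bp: int = 50_000
    intergap_range: tuple[int, int] = (500, 5000)  # excised between neighbours
    nrun_rate_per_bp: float = 1.0 / 500_000
    nrun_length_range: tuple[int, int] = (100, 5000)
    n_chimeras: int = 8
    chimera_spacer_n: int = 100
    min_chimera_labels: int = 8  # labels each joined piece must carry
    # the junction-side end of each joined piece must lie this far inside
    # its chromosome, otherwise the chimera is indistinguishable from a
    # legitimate contig-terminal join and undetectable in principle
    min_chimera_interior_bp: int = 200_000
    n_misplacements: int = 10
    n_misorientations: int = 10
    n_old_unplaced: int = 5
    miss_rate: float = 0.10  # per label
    false_rate: float = 0.5  # per 100 kb
    sizing_sd_coeff: float = 1.0  # bp^(1/2)
    # at the default label density this yields nicking-map contigs about
    # one to two Mb long — the Mb-scale contiguity a real nicking map
    # shows — while direct-label maps stay chromosome-sized
    fragile_break_prob: float = 0.1
    marker_density: float = 12.0  # markers per Mb
    min_molecule_kb: int = 150  # map contigs shorter than this are dropped

    def __post_init__(self):
        for name in ("miss_rate", "fragile_break_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.label_density <= 0 or self.marker_density < 0:
            raise ValueError("densities must be positive")

    @classmethod
    def default(cls, seed: int) -> "SimConfig":
        return cls(seed=seed)

    @classmethod
    def zero_noise(cls, seed: int) -> "SimConfig":
        """All stochastic corruption channels off (layout errors stay)."""
        return cls(
            seed=seed, miss_rate=0.0, false_rate=0.0,
            sizing_sd_coeff=0.0, fragile_break_prob=0.0,
        )

    def rng(self, tag: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _TAGS[tag]])


def chromosome_names(n: int) -> list[str]:
    return [f"{i // 2 + 1}{'AB'[i % 2]}" for i in range(n)]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    chromosomes: list[str] = field(default_factory=list)
    label_positions: dict = field(default_factory=dict)  # (chrom, enzyme) -> (pos, strand)
    repeat_annotation: pd.DataFrame | None = None
    placements: pd.DataFrame | None = None  # scaffold_id, chrom, start, end, orientation
    insertions: dict = field(default_factory=dict)  # scaffold_id -> [(u, length)]
    gaps: pd.DataFrame | None = None  # chrom, left_id, right_id, gap_bp
    chimeras: pd.DataFrame | None = None
    record_map: pd.DataFrame | None = None  # record_id, member_id, offset
    old_assembly: pd.DataFrame | None = None
    old_classes: pd.DataFrame | None = None
    map_truth: dict = field(default_factory=dict)  # enzyme name -> DataFrame

    # -- coordinate helpers -------------------------------------------------
    def member_local_pos(self, member_id: str, chrom_pos: int) -> int:
        """0-based position inside the member record of a chromosome base."""
        row = self.placements.set_index("scaffold_id").loc[member_id]
        if row["orientation"] == "+":
            local = chrom_pos - int(row["start"])
        else:
            local = int(row["end"]) - 1 - chrom_pos
        shift = 0
        for u, length in self.insertions.get(member_id, []):
            if u <= local:
                shift += length
        return local + shift

    def record_pos(self, member_id: str, chrom_pos: int) -> tuple[str, int]:
        """Final record id and 0-based position of a chromosome base."""
        local = self.member_local_pos(member_id, chrom_pos)
        rm = self.record_map.set_index("member_id")
        rec = rm.loc[member_id]
        return str(rec["record_id"]), int(rec["offset"]) + local

    def member_label_count(self, member_id: str, enzyme_name: str) -> int:
        row = self.placements.set_index("scaffold_id").loc[member_id]
        pos, _ = self.label_positions[(row["chrom"], enzyme_name)]
        lo = bisect.bisect_right(pos, int(row["start"]))  # 1-based labels
        hi = bisect.bisect_right(pos, int(row["end"]))
        return hi - lo


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _scrub_motifs(seq: bytearray, enzymes: Sequence[RecognitionSpec]) -> None:
    """Destroy every motif occurrence (both strands) by mutating one base."""
    patterns = set()
    for e in enzymes:
        patterns.add(e.motif)
        patterns.add(revcomp(e.motif))
    changed = True
    while changed:
        changed = False
        text = seq.decode()
        for pat in patterns:
            start = 0
            while True:
                i = text.find(pat, start)
                if i < 0:
                    break
                mid = i + len(pat) // 2
                seq[mid] = ord(_NEXT_BASE[chr(seq[mid])])
                changed = True
                start = i + 1
        # loop again in case a mutation created a fresh occurrence


def simulate_genome(config: SimConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Random chromosomes with planted label motifs and tandem repeats.

    Bases are i.i.d. uniform outside planted features; each enzyme's motif
    is planted as a Poisson process at ``label_density`` (random strand
    for non-palindromic motifs). Deterministic under the seed.
    """
    rng_g = config.rng("genome")
    rng_r = config.rng("repeats")
    rng_p = config.rng("plant")
    names = chromosome_names(config.n_chromosomes)
    truth = GroundTruth(chromosomes=names)
    records = []
    repeat_rows = []
    L = config.chromosome_length_bp
    for chrom in names:
        seq = _random_bases(rng_g, L)
        # tandem repeat arrays (replacement, uniformly placed, no overlap)
        occupied: list[tuple[int, int]] = []
        for fam_idx, (unit_bp, copies, count) in enumerate(config.repeat_families):
            array_len = unit_bp * copies
            if array_len >= L:
                raise ValueError("repeat array exceeds chromosome length")
            unit = _BASES[rng_r.integers(0, 4, size=unit_bp)].tobytes()
            for _ in range(count):
                for _attempt in range(100):
                    pos = int(rng_r.integers(0, L - array_len))
                    if all(pos + array_len <= s or pos >= e for s, e in occupied):
                        break
                else:  # pragma: no cover - pathological packing
                    raise ValueError("cannot place repeat array without overlap")
                seq[pos : pos + array_len] = unit * copies
                occupied.append((pos, pos + array_len))
                repeat_rows.append(
                    {"chrom": chrom, "start": pos, "end": pos + array_len,
                     "family": fam_idx, "unit_bp": unit_bp, "copies": copies}
                )
        _scrub_motifs(seq, config.enzymes)
        # plant motifs as a Poisson process
        taken: list[tuple[int, int]] = list(occupied)
        for enz in config.enzymes:
            k = len(enz.motif)
            n = rng_p.poisson(L * config.label_density / 1e5)
            sites = np.sort(rng_p.integers(10, L - 10 - k, size=n))
            for p in sites:
                p = int(p)
                if any(p < e and p + k > s for s, e in taken[len(occupied):]):
                    continue  # avoid overwriting another planted motif
                strand = 1 if enz.palindromic else (1 if rng_p.random() < 0.5 else -1)
                motif = enz.motif if strand == 1 else revcomp(enz.motif)
                seq[p : p + k] = motif.encode()
                taken.append((p, p + k))
        rec = SequenceRecord(chrom, seq.decode())
        records.append(rec)
        for enz in config.enzymes:
            truth.label_positions[(chrom, enz.name)] = digest_with_strands(rec, enz)
    truth.repeat_annotation = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "family", "unit_bp", "copies"]
    )
    return records, truth


# ---------------------------------------------------------------------------
# fragmentation into scaffolds


def fragment_genome(
    chromosomes: Sequence[SequenceRecord], truth: GroundTruth, config: SimConfig
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Break chromosomes into scaffolds with known layout.

    Breakpoints follow a Poisson process at ``scaffold_break_rate`` per
    Mb; a short segment (``intergap_range``) is excised at each junction
    (the unsequenced gap the optical map will later size), each scaffold
    is flipped with probability 0.5, and internal N runs are inserted at
    ``nrun_rate_per_bp`` so that split sites exist. Truth records the
    chromosome interval, orientation and N-run registry of every scaffold
    and the true size of every junction gap.
    """
    rng = config.rng("fragment")
    placements = []
    gap_rows = []
    records = []
    counter = 0
    gmin, gmax = config.intergap_range
    for rec in chromosomes:
        L = rec.length_bp
        n_breaks = rng.poisson(L * config.scaffold_break_rate / 1e6)
        cuts = np.sort(rng.integers(gmax + config.min_segment_bp,
                                    L - config.min_segment_bp, size=n_breaks))
        # enforce minimum spacing so every segment is usable
        accepted: list[int] = []
        for c in cuts:
            if not accepted or c - accepted[-1] >= config.min_segment_bp + gmax:
                accepted.append(int(c))
        bounds = []
        start = 0
        for c in accepted:
            gap = int(rng.integers(gmin, gmax + 1))
            bounds.append((start, c - gap))
            gap_rows.append({"chrom": rec.seq_id, "gap_bp": gap, "junction": c})
            start = c
        bounds.append((start, L))
        prev_id = None
        for seg_idx, (s, e) in enumerate(bounds):
            counter += 1
            sid = f"scaffold{counter}"
            orientation = "+" if rng.random() < 0.5 else "-"
            segment = rec.bases[s:e]
            if orientation == "-":
                segment = revcomp(segment)
            # internal N runs (insertions; zero physical extent)
            n_runs = rng.poisson((e - s) * config.nrun_rate_per_bp)
            ins = []
            for _ in range(n_runs):
                u = int(rng.integers(500, max(501, e - s - 500)))
                length = int(rng.integers(*config.nrun_length_range))
                ins.append((u, length))
            ins.sort()
            if ins:
                parts = []
                prev = 0
                for u, length in ins:
                    parts.append(segment[prev:u])
                    parts.append("N" * length)
                    prev = u
                parts.append(segment[prev:])
                segment = "".join(parts)
            records.append(SequenceRecord(sid, segment))
            placements.append(
                {"scaffold_id": sid, "chrom": rec.seq_id, "start": s, "end": e,
                 "orientation": orientation}
            )
            truth.insertions[sid] = ins
            if prev_id is not None:
                # this chromosome contributed len(bounds)-1 rows, junction
                # between segments seg_idx-1 and seg_idx is row seg_idx-1
                gi = len(gap_rows) - len(bounds) + seg_idx
                gap_rows[gi]["left_id"] = prev_id
                gap_rows[gi]["right_id"] = sid
            prev_id = sid
    truth.placements = pd.DataFrame(
        placements, columns=["scaffold_id", "chrom", "start", "end", "orientation"]
    )
    gaps = pd.DataFrame(gap_rows)
    if not gaps.empty:
        gaps = gaps[["chrom", "left_id", "right_id", "gap_bp"]]
    truth.gaps = gaps
    return records, truth


# ---------------------------------------------------------------------------
# error injection


def inject_errors(
    scaffolds: Sequence[SequenceRecord], truth: GroundTruth, config: SimConfig
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Inject chimeras and build the corrupted 'prior assembly' table.

    Chimeras join two scaffolds from different chromosomes through a
    ``chimera_spacer_n``-N spacer, so a break-at-N repair exists; both
    pieces must carry at least ``min_chimera_labels`` labels per enzyme so
    that the junction is detectable in principle. Misplacements,
    misorientations and unplaced scaffolds are injected into the *old*
    assembly table (the pipeline's reconstruction should disagree with it
    in exactly those places).
    """
    rng = config.rng("errors")
    by_id = {r.seq_id: r for r in scaffolds}
    pl = truth.placements.set_index("scaffold_id")

    chrom_len = config.chromosome_length_bp

    def interior(sid: str, side: str) -> bool:
        # distance from the junction-side end of the piece to the end of
        # its chromosome; terminal joins are undetectable in principle
        row = pl.loc[sid]
        at_end = (side == "left") == (row["orientation"] == "+")
        dist = chrom_len - int(row["end"]) if at_end else int(row["start"])
        return dist >= config.min_chimera_interior_bp

    eligible = [
        sid for sid in pl.index
        if all(
            truth.member_label_count(sid, e.name) >= config.min_chimera_labels
            for e in config.enzymes
        )
    ]
    rng.shuffle(eligible)
    chim_rows = []
    used: set[str] = set()
    records: list[SequenceRecord] = []
    rm_rows = []
    k = 0
    for _ in range(config.n_chimeras):
        pair = None
        for i in range(len(eligible)):
            if eligible[i] in used or not interior(eligible[i], "left"):
                continue
            for j in range(len(eligible)):
                if j == i or eligible[j] in used or not interior(eligible[j], "right"):
                    continue
                if pl.loc[eligible[i], "chrom"] != pl.loc[eligible[j], "chrom"]:
                    pair = (eligible[i], eligible[j])
                    break
            if pair:
                break
        if pair is None:
            break
        left, right = pair
        used.update(pair)
        cid = f"chimera{k}"
        k += 1
        left_len = by_id[left].length_bp
        spacer = "N" * config.chimera_spacer_n
        records.append(SequenceRecord(cid, by_id[left].bases + spacer + by_id[right].bases))
        chim_rows.append(
            {"chimera_id": cid, "left_id": left, "right_id": right,
             "junction_start": left_len, "junction_end": left_len + config.chimera_spacer_n,
             "left_chrom": pl.loc[left, "chrom"], "right_chrom": pl.loc[right, "chrom"]}
        )
        rm_rows.append({"record_id": cid, "member_id": left, "offset": 0})
        rm_rows.append(
            {"record_id": cid, "member_id": right,
             "offset": left_len + config.chimera_spacer_n}
        )
    for r in scaffolds:
        if r.seq_id not in used:
            records.append(r)
            rm_rows.append({"record_id": r.seq_id, "member_id": r.seq_id, "offset": 0})
    truth.chimeras = pd.DataFrame(
        chim_rows,
        columns=["chimera_id", "left_id", "right_id", "junction_start",
                 "junction_end", "left_chrom", "right_chrom"],
    )
    truth.record_map = pd.DataFrame(rm_rows, columns=["record_id", "member_id", "offset"])

    # --- corrupted prior-assembly table (for compare_assemblies)
    rng_old = config.rng("old")
    order = truth.placements.sort_values(["chrom", "start"])
    old_rows = []
    for chrom, grp in order.groupby("chrom"):
        for pos, (_, row) in enumerate(grp.iterrows()):
            old_rows.append(
                {"scaffold_id": row["scaffold_id"], "chrom": chrom,
                 "position": pos, "orientation": row["orientation"]}
            )
    old = pd.DataFrame(old_rows)
    candidates = [s for s in old["scaffold_id"] if s not in used]
    rng_old.shuffle(candidates)
    need = config.n_misplacements + config.n_misorientations + config.n_old_unplaced
    chosen = candidates[:need]
    classes = []
    chroms = truth.chromosomes
    idx = old.set_index("scaffold_id")
    for sid in chosen[: config.n_misplacements]:
        here = idx.loc[sid, "chrom"]
        other = next(c for c in chroms if c != here)
        old.loc[old["scaffold_id"] == sid, "chrom"] = other
        old.loc[old["scaffold_id"] == sid, "position"] = 1000 + len(classes)
        classes.append({"scaffold_id": sid, "true_class": "relocated"})
    for sid in chosen[config.n_misplacements : config.n_misplacements + config.n_misorientations]:
        sel = old["scaffold_id"] == sid
        old.loc[sel, "orientation"] = old.loc[sel, "orientation"].map({"+": "-", "-": "+"})
        classes.append({"scaffold_id": sid, "true_class": "reoriented"})
    for sid in chosen[config.n_misplacements + config.n_misorientations :]:
        old.loc[old["scaffold_id"] == sid, "chrom"] = "ChrUn"
        classes.append({"scaffold_id": sid, "true_class": "rescued"})
    truth.old_assembly = old
    truth.old_classes = pd.DataFrame(classes, columns=["scaffold_id", "true_class"])
    return records, truth


# ---------------------------------------------------------------------------
# optical map simulation


def simulate_optical_map(
    chromosomes: Sequence[SequenceRecord],
    config: SimConfig,
    enzyme: RecognitionSpec | None = None,
    truth: GroundTruth | None = None,
) -> tuple[list[LabelMap], pd.DataFrame]:
    """Image the chromosomes into noisy consensus map contigs.

    True label positions come from in-silico digestion of the chromosome.
    Nicking chemistry breaks the molecule at each fragile pair (opposite
    strand sites within the enzyme's fragile distance) with probability
    ``fragile_break_prob`` — the mechanism that fragments nick-labelled
    maps. Then per contig: Bernoulli label misses, Poisson false labels,
    and Gaussian interval sizing noise with sd = sizing_sd_coeff *
    sqrt(interval). Contigs shorter than ``min_molecule_kb`` are dropped.
    """
    enzyme = enzyme or config.chemistry
    rng = config.rng("map")
    maps: list[LabelMap] = []
    truth_rows = []
    for rec in chromosomes:
        if truth is not None and (rec.seq_id, enzyme.name) in truth.label_positions:
            pos, strands = truth.label_positions[(rec.seq_id, enzyme.name)]
        else:
            pos, strands = digest_with_strands(rec, enzyme)
        pos = list(pos)
        breaks: list[int] = []
        if enzyme.chemistry == "nick" and config.fragile_break_prob > 0:
            for i, j in fragile_pairs(pos, strands, enzyme.fragile_distance_bp):
                if rng.random() < config.fragile_break_prob:
                    breaks.append((pos[i] + pos[j]) // 2)
        bounds = [0, *sorted(breaks), rec.length_bp]
        for k, (s, e) in enumerate(zip(bounds, bounds[1:])):
            if e <= s:
                continue
            local = [p - s for p in pos if s < p <= e]
            local, length = _apply_noise(local, e - s, config, rng)
            if length < config.min_molecule_kb * 1000:
                continue
            map_id = f"map_{rec.seq_id}_{k}"
            maps.append(LabelMap(map_id, length, local, source="optical"))
            truth_rows.append(
                {"map_id": map_id, "chrom": rec.seq_id, "start_bp": s, "end_bp": e}
            )
    truth_df = pd.DataFrame(truth_rows, columns=["map_id", "chrom", "start_bp", "end_bp"])
    if truth is not None:
        truth.map_truth[enzyme.name] = truth_df
    return maps, truth_df


def _apply_noise(
    positions: list[int], length: int, config: SimConfig, rng: np.random.Generator
) -> tuple[list[int], int]:
    keep = [p for p in positions if config.miss_rate == 0 or rng.random() >= config.miss_rate]
    n_false = rng.poisson(length * config.false_rate / 1e5) if config.false_rate > 0 else 0
    if n_false:
        keep.extend(int(p) for p in rng.integers(1, length + 1, size=n_false))
        keep = sorted(set(keep))
    if config.sizing_sd_coeff > 0 and keep:
        anchors = [0, *keep, length]
        intervals = np.diff(anchors).astype(float)
        sd = config.sizing_sd_coeff * np.sqrt(intervals)
        intervals = np.maximum(1.0, intervals + rng.normal(0.0, 1.0, len(intervals)) * sd)
        cum = np.cumsum(intervals)
        keep = [int(round(c)) for c in cum[:-1]]
        length = int(round(cum[-1]))
        keep = [p for p in keep if 1 <= p <= length]
        keep = sorted(set(keep))
    return keep, length


# ---------------------------------------------------------------------------
# genetic map simulation


def simulate_genetic_map(
    chromosomes: Sequence[SequenceRecord], truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Markers at Poisson positions with a monotone piecewise-linear cM map.

    Plateau segments (zero recombination) are included so that the
    distinct-cM scarcity cases the orientation logic must survive occur
    naturally. Marker scaffold hits are derived through the truth
    placements; markers falling in excised junction gaps are lost, as in
    real data.
    """
    rng = config.rng("markers")
    rows = []
    pl = truth.placements
    for rec in chromosomes:
        chrom = rec.seq_id
        L = rec.length_bp
        n_seg = 10
        edges = np.linspace(0, L, n_seg + 1)
        rates = np.where(rng.random(n_seg) < 0.3, 0.0, rng.exponential(1.5, n_seg))  # cM/Mb
        cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges) / 1e6)])

        def cm_of(p: float) -> float:
            i = min(int(np.searchsorted(edges, p, side="right")) - 1, n_seg - 1)
            return float(cum[i] + rates[i] * (p - edges[i]) / 1e6)

        n = rng.poisson(L * config.marker_density / 1e6)
        sites = np.sort(rng.integers(0, L, size=n))
        here = pl[pl["chrom"] == chrom].sort_values("start")
        starts = here["start"].to_list()
        for k, p in enumerate(sites):
            p = int(p)
            i = bisect.bisect_right(starts, p) - 1
            if i < 0:
                continue
            row = here.iloc[i]
            if p >= int(row["end"]):
                continue  # fell into an excised junction gap
            member = str(row["scaffold_id"])
            rec_id, rec_pos = truth.record_pos(member, p)
            rows.append(
                {"marker_id": f"m_{chrom}_{k}", "chrom": chrom,
                 "cm": round(cm_of(p), 4), "scaffold_id": rec_id, "pos": rec_pos + 1}
            )
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "cm", "scaffold_id", "pos"])


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class SimResult:
    config: SimConfig
    chromosomes: list[SequenceRecord]
    scaffolds: list[SequenceRecord]
    truth: GroundTruth
    maps: dict[str, list[LabelMap]]  # enzyme name -> contigs
    markers: pd.DataFrame


def simulate_all(config: SimConfig) -> SimResult:
    """Run the full generator: genome, scaffolds, errors, maps, markers."""
    chroms, truth = simulate_genome(config)
    scaffolds, truth = fragment_genome(chroms, truth, config)
    scaffolds, truth = inject_errors(scaffolds, truth, config)
    maps = {}
    for enz in config.enzymes:
        contigs, _ = simulate_optical_map(chroms, config, enz, truth)
        maps[enz.name] = contigs
    markers = simulate_genetic_map(chroms, truth, config)
    return SimResult(config, chroms, scaffolds, truth, maps, markers)
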
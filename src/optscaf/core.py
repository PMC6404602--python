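"""Core domain types for optical-map guided scaffolding.

This module houses the two physical abstractions everything else is built
on: sequence scaffolds (FASTA records with N-gap runs) and label maps (the
CMAP abstraction: an ordered list of label positions along a molecule,
whether measured optically or computed by in-silico digestion), together
with in-silico digestion, N-run indexing, standard assembly statistics and
FASTA/CMAP readers and writers.

Coordinate conventions
----------------------
CMAP label positions are 1-based basepairs (the Bionano convention); all
internal *intervals* are 0-based half-open. Conversions happen at the type
boundaries defined here and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(bases: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A scaffold or chromosome sequence."""

    seq_id: str
    bases: str

    @property
    def length_bp(self) -> int:
        return len(self.bases)

    @property
    def n_count(self) -> int:
        return self.bases.count("N")


@dataclass(frozen=True)
class NRun:
    """A maximal run of N bases, 0-based half-open."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty N run {self.start}:{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RecognitionSpec:
    """A labelling enzyme: its motif and chemistry.

    ``direct`` chemistry (e.g. DLE-1) marks the motif without cutting;
    ``nick`` chemistry (e.g. Nt.BspQI) nicks one strand, and two nicks on
    opposite strands within ``fragile_distance_bp`` form a fragile site
    prone to double-strand breakage (consumed by the simulator).
    """

    name: str
    motif: str
    chemistry: str = "direct"  # direct | nick
    fragile_distance_bp: int = 0

    def __post_init__(self):
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"invalid motif {self.motif!r}")
        if self.chemistry not in ("direct", "nick"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.chemistry == "nick" and self.fragile_distance_bp <= 0:
            raise ValueError("nick chemistry requires fragile_distance_bp > 0")

    @property
    def palindromic(self) -> bool:
        return self.motif == revcomp(self.motif)


# Motifs are not part of the source publication; shipped as overridable
# configuration defaults.
DLE1 = RecognitionSpec("DLE-1", "CTTAAG", "direct")
BSPQI = RecognitionSpec("Nt.BspQI", "GCTCTTC", "nick", fragile_distance_bp=1000)

ENZYMES = {"dle1": DLE1, "bspqi": BSPQI}


@dataclass
class LabelMap:
    """An ordered list of label positions on one molecule (CMAP record).

    Positions are 1-based bp, strictly increasing, within [1, length_bp].
    ``site_width`` is the footprint of one label: 1 for an optically
    imaged point label, the motif length for an in-silico digest (a site
    is the interval [p, p+w)). Mirroring a map sends a site start to
    ``length - (p + w - 1) + 1``, so reverse-complement digests line up
    exactly with forward digests — flipping bare starts would shift every
    site by w-1.
    """

    map_id: str
    length_bp: int
    positions: list[int] = field(default_factory=list)
    source: str = "insilico"  # optical | insilico
    site_width: int = 1

    def __post_init__(self):
        pos = list(self.positions)
        if any(b >= a for a, b in zip(pos[1:], pos)):
            raise ValueError(f"{self.map_id}: positions not strictly increasing")
        if pos and (pos[0] < 1 or pos[-1] > self.length_bp):
            raise ValueError(f"{self.map_id}: positions outside [1, {self.length_bp}]")

    @property
    def n_labels(self) -> int:
        return len(self.positions)

    def reversed(self) -> "LabelMap":
        """The same molecule read from the other end."""
        w = self.site_width
        flipped = [self.length_bp - p - w + 2 for p in reversed(self.positions)]
        return LabelMap(self.map_id, self.length_bp, flipped, self.source, w)


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bp: int
    max_bp: int
    n50_bp: int
    n_pct: float

    @property
    def effective_bp(self) -> int:
        """Total length excluding N bases."""
        return round(self.total_bp * (1.0 - self.n_pct / 100.0))


# ---------------------------------------------------------------------------
# in-silico digestion


def _motif_sites(bases: str, spec: RecognitionSpec) -> tuple[list[int], list[int]]:
    """1-based forward-strand start positions of motif matches.

    Returns (positions, strands) with strand +1 for a forward match and -1
    for a reverse-complement match; palindromic duplicates are collapsed
    (strand recorded as +1). Overlapping matches are all reported. Matches
    containing N cannot occur because motifs contain no N.
    """
    fwd = re.compile("(?=" + spec.motif + ")")
    hits: dict[int, int] = {}
    for m in fwd.finditer(bases):
        hits[m.start() + 1] = 1
    if not spec.palindromic:
        rev = re.compile("(?=" + revcomp(spec.motif) + ")")
        for m in rev.finditer(bases):
            hits.setdefault(m.start() + 1, -1)
    pos = sorted(hits)
    return pos, [hits[p] for p in pos]


def merge_close_labels(positions: Sequence[int], min_distance_bp: int) -> list[int]:
    """Collapse labels closer than ``min_distance_bp`` to their midpoint.

    Models finite imaging resolution. Clusters are chained transitively;
    the merged label sits at the rounded midpoint of the cluster extremes.
    """
    if min_distance_bp <= 0 or len(positions) < 2:
        return list(positions)
    merged: list[int] = []
    cluster = [positions[0]]
    for p in positions[1:]:
        if p - cluster[-1] < min_distance_bp:
            cluster.append(p)
        else:
            merged.append(round((cluster[0] + cluster[-1]) / 2))
            cluster = [p]
    merged.append(round((cluster[0] + cluster[-1]) / 2))
    # midpoints of chained clusters are strictly ordered by construction
    return merged


def digest_sequence(
    seq: SequenceRecord,
    spec: RecognitionSpec,
    min_label_distance_bp: int = 1000,
) -> LabelMap:
    """Compute the in-silico label map of a sequence.

    One label per motif occurrence on either strand, positioned at the
    1-based start of the match on the forward strand; palindromic motifs
    yield one label per site. Labels closer than ``min_label_distance_bp``
    are merged to their midpoint (optical-resolution model; pass 0 to keep
    every site). An empty sequence gives an empty map.
    """
    pos, _ = _motif_sites(seq.bases, spec)
    pos = merge_close_labels(pos, min_label_distance_bp)
    return LabelMap(
        seq.seq_id, seq.length_bp, pos, source="insilico", site_width=len(spec.motif)
    )


def digest_with_strands(
    seq: SequenceRecord, spec: RecognitionSpec
) -> tuple[list[int], list[int]]:
    """Unmerged label positions with strand signs (for fragile-site models)."""
    return _motif_sites(seq.bases, spec)


def fragile_pairs(
    positions: Sequence[int], strands: Sequence[int], fragile_distance_bp: int
) -> list[tuple[int, int]]:
    """Index pairs of adjacent opposite-strand sites within the fragile distance.

    Under nicking chemistry such a pair nicks both strands close together
    and tends to break the molecule.
    """
    out = []
    for i in range(len(positions) - 1):
        if (
            strands[i] != strands[i + 1]
            and positions[i + 1] - positions[i] <= fragile_distance_bp
        ):
            out.append((i, i + 1))
    return out


# ---------------------------------------------------------------------------
# N runs and assembly statistics

_N_RUN = re.compile("N+")


def find_n_runs(seq: SequenceRecord) -> list[NRun]:
    """Maximal N runs, sorted, non-overlapping (0-based half-open)."""
    return [NRun(seq.seq_id, m.start(), m.end()) for m in _N_RUN.finditer(seq.bases)]


def compute_stats(seqs: Iterable[SequenceRecord]) -> AssemblyStats:
    """Standard assembly statistics (count, total, max, N50, N%)."""
    lengths = []
    n_bases = 0
    for s in seqs:
        lengths.append(s.length_bp)
        n_bases += s.n_count
    if not lengths:
        raise ValueError("empty sequence collection")
    total = int(sum(lengths))
    return AssemblyStats(
        n_sequences=len(lengths),
        total_bp=total,
        max_bp=int(max(lengths)),
        n50_bp=n50(lengths),
        n_pct=100.0 * n_bases / total if total else 0.0,
    )


def n50(lengths: Sequence[int]) -> int:
    """Length L such that sequences of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("empty length multiset")
    arr = sorted(lengths, reverse=True)
    half = sum(arr) / 2.0
    acc = 0
    for L in arr:
        acc += L
        if acc >= half:
            return int(L)
    return int(arr[-1])  # pragma: no cover


# ---------------------------------------------------------------------------
# FASTA io (Biopython-backed, wrapped at 60 columns)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        if set(bases) - _VALID_BASES:
            bad = sorted(set(bases) - _VALID_BASES)
            raise ValueError(f"{path}: {rec.id}: invalid characters {bad}")
        records.append(SequenceRecord(rec.id, bases))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (_BioSeqRecord(Seq(r.bases), id=r.seq_id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# CMAP io (tab-separated Bionano-style dialect)

_CMAP_COLUMNS = ["CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel", "Position"]


def write_cmap(maps: Iterable[LabelMap], path: str | Path) -> None:
    """Write label maps as a CMAP-dialect TSV.

    One row per label (LabelChannel 1) plus the conventional trailing
    channel-0 row marking the contig end.
    """
    maps = list(maps)
    with open(path, "w") as fh:
        fh.write("# CMAP File\n")
        fh.write("#h " + "\t".join(_CMAP_COLUMNS) + "\n")
        fh.write("#f " + "\t".join(["str", "float", "int", "int", "int", "float"]) + "\n")
        for m in maps:
            if m.site_width != 1:
                fh.write(f"#w {m.map_id}\t{m.site_width}\n")
        for m in maps:
            n = m.n_labels
            for i, p in enumerate(m.positions, start=1):
                fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{i}\t1\t{p:.1f}\n")
            fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}\n")


def read_cmap(path: str | Path, source: str = "optical") -> list[LabelMap]:
    """Read a CMAP-dialect TSV, validating monotone positions.

    Malformed rows raise with file and line context.
    """
    path = Path(path)
    by_id: dict[str, dict] = {}
    order: list[str] = []
    widths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#w "):
                mid, w = line[3:].split("\t")
                widths[mid] = int(w)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns, got {len(parts)}")
            try:
                cmap_id = parts[0]
                length = int(float(parts[1]))
                channel = int(parts[4])
                pos = int(float(parts[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            entry = by_id.get(cmap_id)
            if entry is None:
                entry = by_id[cmap_id] = {"length": length, "positions": []}
                order.append(cmap_id)
            if channel == 0:
                continue  # contig-end marker row
            if entry["positions"] and pos <= entry["positions"][-1]:
                raise ValueError(
                    f"{path}:{lineno}: non-monotone position {pos} for map {cmap_id}"
                )
            entry["positions"].append(pos)
    return [
        LabelMap(
            mid, by_id[mid]["length"], by_id[mid]["positions"],
            source=source, site_width=widths.get(mid, 1),
        )
        for mid in order
    ]
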
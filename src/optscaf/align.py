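"""Dynamic-programming alignment of label maps with a sizing-error model.

A query label map (typically an in-silico digest of a scaffold) is aligned
against a reference map (an optical consensus contig). The aligner is
local: a chain of matched labels may start and end anywhere on either map,
so unaligned overhangs are free. Each chain step pairs one query label
with one reference label and is charged

* a sizing term  (dq - dr)^2 / (2 * sizing_sd_coeff^2 * dr), capped at
  ``sizing_max`` — the optical sizing error of an interval of true length
  dr is modelled as Gaussian with sd = sizing_sd_coeff * sqrt(dr);
* ``miss_penalty`` per reference label skipped inside the step (a label
  the query failed to show);
* ``false_penalty`` per query label skipped (a label the reference lacks);

and earns ``match_bonus`` per paired label. The best chain is extracted,
its query labels are masked, and extraction repeats — so a chimeric query
yields one alignment per constituent locus, which is exactly the signal
the conflict detector consumes.

Scores are converted to a log10-scale confidence; the default acceptance
threshold of 10 plays the role of a 1e-10 alignment P-value cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import LabelMap

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


LN10 = math.log(10.0)


@dataclass(frozen=True)
class AlignParams:
    """Scoring and acceptance parameters for label-map alignment.

    ``min_confidence`` is on a log10 scale: the default of 10 mirrors an
    initial alignment cutoff of P < 1e-10; 11 and 15 reproduce the
    stricter extension/merge rungs of the same ladder.
    """

    sizing_sd_coeff: float = 1.0  # bp^(1/2); sd ~ 300 bp on a 90-kb interval
    miss_penalty: float = 2.0
    false_penalty: float = 2.0
    match_bonus: float = 3.0
    min_confidence: float = 10.0
    max_lookback: int = 8  # labels skippable per chain step
    sizing_max: float = 50.0  # robust cap on the per-step sizing term

    def __post_init__(self):
        if min(self.miss_penalty, self.false_penalty, self.min_confidence) < 0:
            raise ValueError("penalties and min_confidence must be >= 0")
        if self.max_lookback < 1:
            raise ValueError("max_lookback must be >= 1")


@dataclass
class LabelAlignment:
    """A monotone pairing of query and reference labels (XMAP abstraction).

    ``pairs`` are (query_index, ref_index) tuples, 0-based, strictly
    increasing in both coordinates, with query indices taken in the
    orientation-flipped frame for '-' alignments (index i of the reversed
    map corresponds to original index n-1-i). ``query_bp``/``ref_bp`` give
    the corresponding label positions, in the flipped frame for the query.
    """

    query_id: str
    ref_id: str
    orientation: str  # '+' | '-'
    pairs: list[tuple[int, int]]
    confidence: float
    score: float
    query_len_bp: int
    query_n_labels: int
    query_bp: list[int]  # flipped frame, monotone increasing
    ref_bp: list[int]
    query_site_width: int = 1

    def __post_init__(self):
        if len(self.pairs) < 2:
            raise ValueError("an alignment needs >= 2 pairs")
        q = [p[0] for p in self.pairs]
        r = [p[1] for p in self.pairs]
        if any(b <= a for a, b in zip(q, q[1:])) or any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("pairs must be strictly increasing in both coordinates")
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")

    # -- coordinate helpers ------------------------------------------------
    def query_bp_original(self) -> list[int]:
        """Aligned query label positions in the original (unflipped) frame."""
        if self.orientation == "+":
            return list(self.query_bp)
        w = self.query_site_width
        return [self.query_len_bp - p - w + 2 for p in self.query_bp]

    def query_span_bp(self) -> tuple[int, int]:
        """0-based half-open interval of the aligned span on the original query."""
        bp = self.query_bp_original()
        lo, hi = min(bp[0], bp[-1]), max(bp[0], bp[-1])
        return lo - 1, hi

    def ref_span_bp(self) -> tuple[int, int]:
        return self.ref_bp[0] - 1, self.ref_bp[-1]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# scoring


def _step_cost(dq: float, dr: float, params: AlignParams) -> float:
    sizing = (dq - dr) ** 2 / (2.0 * params.sizing_sd_coeff**2 * dr)
    return min(sizing, params.sizing_max)


def score_alignment(
    pairs: Sequence[tuple[int, int]],
    query: LabelMap,
    ref: LabelMap,
    params: AlignParams,
) -> float:
    """Score a monotone chain of (query_index, ref_index) label pairs.

    Higher is better; a perfect all-label pairing of identical maps scores
    match_bonus * n_labels.
    """
    q = [p[0] for p in pairs]
    r = [p[1] for p in pairs]
    if any(b <= a for a, b in zip(q, q[1:])) or any(b <= a for a, b in zip(r, r[1:])):
        raise ValueError("pairs must be strictly increasing in both coordinates")
    score = params.match_bonus * len(pairs)
    for (q0, r0), (q1, r1) in zip(pairs, pairs[1:]):
        dq = query.positions[q1] - query.positions[q0]
        dr = ref.positions[r1] - ref.positions[r0]
        score -= _step_cost(dq, dr, params)
        score -= params.miss_penalty * (r1 - r0 - 1)
        score -= params.false_penalty * (q1 - q0 - 1)
    return score


def confidence_from_score(
    score: float,
    n_pairs: int,
    query: LabelMap,
    ref: LabelMap,
    params: AlignParams,
) -> float:
    """Transform a chain score into a non-negative log10-scale confidence.

    confidence = max(0, (score - null_mean) / ln 10), where null_mean is
    the expected best score of a chance chain of the same length: per step
    the best-of-lookback candidate has a near-zero sizing term by
    selection but must on average skip about one label on one side, so
    the expected per-step score under the null is
    -(miss_penalty + false_penalty) / 2. Deterministic given its inputs.
    """
    null_mean = -n_pairs * (params.miss_penalty + params.false_penalty) / 2.0
    return max(0.0, (score - null_mean) / LN10)


# ---------------------------------------------------------------------------
# DP kernel


def _dp_fill_py(q, r, lookback, c2, miss, false, bonus, cap):
    # S[i,j]: best chain ending at pair (i,j), singletons allowed (local
    # alignment start). E[i,j]: best chain ending at (i,j) with >= 2 pairs
    # (kept separately so a weak short chain is still representable).
    n, m = len(q), len(r)
    S = np.full((n, m), bonus)
    E = np.full((n, m), -1e18)
    bi = np.full((n, m), -1, np.int32)  # S-chain predecessor (-1: fresh start)
    bj = np.full((n, m), -1, np.int32)
    ei = np.full((n, m), -1, np.int32)  # E-chain predecessor
    ej = np.full((n, m), -1, np.int32)
    for i in range(n):
        for j in range(m):
            best_e = -1e18
            b0 = -1
            b1 = -1
            for di in range(1, min(i, lookback + 1) + 1):
                ip = i - di
                dq = q[i] - q[ip]
                for dj in range(1, min(j, lookback + 1) + 1):
                    jp = j - dj
                    dr = r[j] - r[jp]
                    siz = (dq - dr) * (dq - dr) / (2.0 * c2 * dr)
                    if siz > cap:
                        siz = cap
                    s = S[ip, jp] + bonus - siz - miss * (dj - 1) - false * (di - 1)
                    if s > best_e:
                        best_e = s
                        b0 = ip
                        b1 = jp
            E[i, j] = best_e
            ei[i, j] = b0
            ej[i, j] = b1
            if best_e > bonus:
                S[i, j] = best_e
                bi[i, j] = b0
                bj[i, j] = b1
    return S, E, bi, bj, ei, ej


if _HAVE_NUMBA:
    _dp_fill = _njit(cache=False)(_dp_fill_py)
else:  # pragma: no cover
    _dp_fill = _dp_fill_py


def _best_chain(qpos: np.ndarray, rpos: np.ndarray, params: AlignParams):
    """Best-scoring local chain between two position arrays.

    Returns (pairs as local index tuples, score) or (None, -inf).
    """
    if len(qpos) < 2 or len(rpos) < 2:
        return None, -math.inf
    S, E, bi, bj, ei, ej = _dp_fill(
        qpos.astype(np.float64),
        rpos.astype(np.float64),
        params.max_lookback,
        params.sizing_sd_coeff**2,
        params.miss_penalty,
        params.false_penalty,
        params.match_bonus,
        params.sizing_max,
    )
    i, j = np.unravel_index(int(np.argmax(E)), E.shape)
    if ei[i, j] < 0:
        return None, -math.inf
    score = float(E[i, j])
    chain = [(int(i), int(j))]
    i, j = int(ei[i, j]), int(ej[i, j])
    chain.append((i, j))
    while bi[i, j] >= 0:
        i, j = int(bi[i, j]), int(bj[i, j])
        chain.append((i, j))
    chain.reverse()
    return chain, score


# ---------------------------------------------------------------------------
# pairwise and batch alignment


def align_pair(query: LabelMap, ref: LabelMap, params: AlignParams | None = None) -> list[LabelAlignment]:
    """All alignments of ``query`` against ``ref`` with confidence >= threshold.

    Both orientations are tried; the best chain (by confidence) is
    extracted greedily, its query labels are masked, and the search
    repeats, so split alignments of a chimeric query are all reported.
    Maps with fewer than 2 labels yield an empty list.
    """
    params = params or AlignParams()
    nq = query.n_labels
    if nq < 2 or ref.n_labels < 2:
        return []
    qpos = np.asarray(query.positions, dtype=np.float64)
    qflip = (query.length_bp - qpos - query.site_width + 2)[::-1].copy()
    rpos = np.asarray(ref.positions, dtype=np.float64)

    active = np.ones(nq, dtype=bool)  # in original index space
    results: list[LabelAlignment] = []
    while int(active.sum()) >= 2:
        best = None  # (conf, orient, chain_in_full_flipped_idx, score)
        for orient in "+-":
            if orient == "+":
                idx_full = np.nonzero(active)[0]
                pos = qpos[idx_full]
            else:
                act_f = active[::-1]
                idx_full = np.nonzero(act_f)[0]  # indices in flipped frame
                pos = qflip[idx_full]
            chain, score = _best_chain(pos, rpos, params)
            if chain is None:
                continue
            conf = confidence_from_score(score, len(chain), query, ref, params)
            if best is None or conf > best[0]:
                best = (conf, orient, [(int(idx_full[qi]), rj) for qi, rj in chain], score)
        if best is None or best[0] < params.min_confidence:
            break
        conf, orient, chain, score = best
        if orient == "+":
            qbp = [int(qpos[qi]) for qi, _ in chain]
            orig_idx = [qi for qi, _ in chain]
        else:
            qbp = [int(qflip[qi]) for qi, _ in chain]
            orig_idx = [nq - 1 - qi for qi, _ in chain]
        results.append(
            LabelAlignment(
                query_id=query.map_id,
                ref_id=ref.map_id,
                orientation=orient,
                pairs=chain,
                confidence=conf,
                score=score,
                query_len_bp=query.length_bp,
                query_n_labels=nq,
                query_bp=qbp,
                ref_bp=[int(rpos[rj]) for _, rj in chain],
                query_site_width=query.site_width,
            )
        )
        active[orig_idx] = False
    results.sort(key=lambda a: -a.confidence)
    return results


def align_all(
    queries: Iterable[LabelMap],
    refs: Iterable[LabelMap],
    params: AlignParams | None = None,
) -> dict[str, list[LabelAlignment]]:
    """Align every query against every reference; keyed by query id.

    Retains every alignment above the confidence threshold — a query
    aligning to several reference contigs is the chimera signal, not an
    error.
    """
    params = params or AlignParams()
    refs = list(refs)
    out: dict[str, list[LabelAlignment]] = {}
    for q in queries:
        hits: list[LabelAlignment] = []
        for r in refs:
            hits.extend(align_pair(q, r, params))
        hits.sort(key=lambda a: -a.confidence)
        out[q.map_id] = hits
    return out


# ---------------------------------------------------------------------------
# brute-force reference scorer (test oracle; kept independent of the DP)


def best_chain_bruteforce(
    query: LabelMap, ref: LabelMap, params: AlignParams
) -> tuple[list[tuple[int, int]] | None, float]:
    """Exhaustive best monotone chain on tiny maps (<= ~8 labels a side).

    Enumerates every monotone pairing with >= 2 pairs and scores it with
    :func:`score_alignment`. Exponential; only for oracle use in tests.
    """
    n, m = query.n_labels, ref.n_labels
    best_pairs, best_score = None, -math.inf
    for k in range(2, min(n, m) + 1):
        for qs in combinations(range(n), k):
            for rs in combinations(range(m), k):
                pairs = list(zip(qs, rs))
                s = score_alignment(pairs, query, ref, params)
                if s > best_score:
                    best_score, best_pairs = s, pairs
    return best_pairs, best_score


# ---------------------------------------------------------------------------
# XMAP-style io

_XMAP_COLUMNS = [
    "XmapEntryID",
    "QryContigID",
    "RefContigID",
    "QryStartPos",
    "QryEndPos",
    "RefStartPos",
    "RefEndPos",
    "Orientation",
    "Confidence",
    "Alignment",
]


def write_xmap(alignments: Iterable[LabelAlignment], path: str | Path) -> None:
    """Write alignments as an XMAP-style TSV.

    Query start/end are in original query coordinates (start > end for '-'
    alignments, the XMAP convention); the Alignment column holds 1-based
    (query_site, ref_site) pairs in original site numbering.
    """
    with open(path, "w") as fh:
        fh.write("# XMAP File\n")
        fh.write("#h " + "\t".join(_XMAP_COLUMNS) + "\n")
        for k, a in enumerate(alignments, start=1):
            qbp = a.query_bp_original()
            pair_str = "".join(
                f"({_orig_site(a, qi)},{rj + 1})" for qi, rj in a.pairs
            )
            fh.write(
                f"{k}\t{a.query_id}\t{a.ref_id}\t{qbp[0]:.1f}\t{qbp[-1]:.1f}\t"
                f"{a.ref_bp[0]:.1f}\t{a.ref_bp[-1]:.1f}\t{a.orientation}\t"
                f"{a.confidence:.2f}\t{pair_str}\n"
            )


def _orig_site(a: LabelAlignment, flipped_idx: int) -> int:
    if a.orientation == "+":
        return flipped_idx + 1
    return a.query_n_labels - flipped_idx


def flatten_alignments(per_query: dict[str, list[LabelAlignment]]) -> list[LabelAlignment]:
    return [a for qid in sorted(per_query) for a in per_query[qid]]


def read_xmap(path: str | Path) -> list[dict]:
    """Read an XMAP-style TSV back into plain row dictionaries."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_XMAP_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(_XMAP_COLUMNS)} columns")
            row = dict(zip(_XMAP_COLUMNS, parts))
            for key in ("QryStartPos", "QryEndPos", "RefStartPos", "RefEndPos", "Confidence"):
                row[key] = float(row[key])
            rows.append(row)
    return rows
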
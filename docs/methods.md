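# Methods

`optscaf` improves a fragmented draft genome assembly with optical maps:
it validates sequence scaffolds against one or two independent Bionano-style
label maps, detects and splits chimeric scaffolds, orders and orients the
validated scaffolds along map contigs into super-scaffolds with optically
sized gaps, and anchors the result onto chromosomes with genetic-map
markers. A first-class simulator generates every input with machine-readable
ground truth, so the whole pipeline is testable without external data.

## The label-map abstraction

An optical map is an ordered list of fluorescent label positions along a
DNA molecule; an in-silico digest is the same object computed from sequence
by scanning for the labelling enzyme's recognition motif on both strands.
Both live in one type, `LabelMap` (1-based positions, the CMAP convention).
Two chemistries are modelled:

* **direct label** (DLE-1, motif `CTTAAG`, palindromic): marks the motif
  without cutting; maps stay chromosome-scale.
* **nicking** (Nt.BspQI, motif `GCTCTTC`, strand-specific): nicks one
  strand; two opposite-strand nicks within the fragile distance
  (default 1000 bp) form a fragile site where the molecule tends to break,
  fragmenting the map.

The motifs are configuration defaults, not hard-coded behaviour.

A digest label is an interval `[p, p+w)` (`w` = motif length), not a point:
mirroring a map for reverse-complement alignment sends a site start to
`L - (p + w - 1) + 1`. Flipping bare starts would bias every minus-strand
label by `w - 1` bp, which is large enough to corrupt gap estimates.
Optical maps carry `w = 1` (point labels). `digest_sequence` can also merge
labels closer than a resolution limit to their midpoint (default 1000 bp
for stand-alone use, modelling finite imaging resolution); the pipeline
digests with merging off because the simulated maps are not merged either,
keeping query and reference on the same footing.

## Alignment scoring

Alignment of a query digest to a reference map is a banded local DP over
label pairs. A chain step pairing query label `i` with reference label `j`
from predecessor `(i', j')` scores

```
match_bonus
  - min( (dq - dr)^2 / (2 * c^2 * dr), sizing_max )
  - miss_penalty  * (skipped reference labels)
  - false_penalty * (skipped query labels)
```

with `dq, dr` the inter-label distances and `c = sizing_sd_coeff` the
sizing-noise scale (sd of an interval of length `dr` is `c * sqrt(dr)`;
the default `c = 1 bp^1/2` gives sd ≈ 300 bp on a 90-kb interval). The cap
`sizing_max` (default 50) is a robust loss: a single badly mis-sized
stretch — typically an N gap of unknown true size inside a scaffold —
costs a bounded amount instead of shattering the chain, so alignments
bridge internal discordances when the flanks support them. Defaults:
`match_bonus 3`, `miss_penalty 2`, `false_penalty 2`, lookback 8 labels
per step (runs of unaligned labels above the internal-discordance
threshold of 5 must be representable inside one step). Runtime is
`O(n·m·k²)` per orientation; the kernel is compiled with numba when
available, with an identical pure-Python fallback.

The best chain is extracted, its query labels are masked, and extraction
repeats — a chimeric query therefore yields one alignment per constituent
locus. Scores map to a log10-scale confidence

```
confidence = max(0, (score - null_mean) / ln 10),
null_mean  = -n_pairs * (miss_penalty + false_penalty) / 2
```

The null model is the expected best-chain score under random label
placement: by selection the best-of-lookback candidate has a near-zero
sizing term, but on average one label per step must be skipped on one
side. With defaults, a perfect 5-label chain scores confidence 10.9 and a
perfect 4-label chain 8.7, so the default acceptance threshold of 10
(playing the role of a 1e-10 alignment P-value) admits 5-label scaffold
pieces while excluding near-perfect chance 4-chains. The threshold ladder
10 / 11 / 15 gates initial alignment, re-alignment of split pieces, and
second-round merges respectively, mirroring the 1e-10 / 1e-11 / 1e-15
significance rungs customary for consensus-map assembly.

## Conflict detection, arbitration, splitting

Within one scaffold's retained alignments (sorted by scaffold span, with
chance alignments nested inside a better span dropped), adjacent span
pairs are tested for compatibility:

* same contig: same orientation, consistent order, and map distance within
  `distance_bp` (default 100 kb) of the scaffold distance;
* different contigs: compatible only when both alignments reach within
  `junction_bp` (default 50 kb) of their contig edges. A fragmented map
  legitimately hosts one scaffold across several contigs; but an alignment
  that stops deep inside a contig interior means sequence and map part
  company there, because a local aligner would have kept extending had the
  sequence continued — that is the chimera signal.

Incompatible pairs raise a `split_alignment` conflict whose interval is
the scaffold stretch between the flanking aligned labels. A run of ≥ 5
consecutive unaligned labels spanning > 100 kb inside one alignment
(e.g. a tandem-repeat copy-number disagreement) raises an
`internal_discordance` conflict.

Because the map itself can be wrong, every conflict is arbitrated against
the second, chemically independent map: if that map also conflicts with
the scaffold over the same interval (padded by `junction_bp`, since each
map localises the junction only to about one label interval) the verdict
is `sequence_error`; if one second-map contig shows ≥ 5 concordant labels
on each side of the interval (counted across that contig's mutually
compatible chains) the verdict is `map_error`; otherwise `unresolved`,
and nothing is cut.

Confirmed sequence errors are repaired by cutting at the midpoint of
**every** N run intersecting the merged conflict interval — never inside
real sequence. The junction can hide behind any N gap in the bracket, and
cutting only the most central one would leave residual mis-joined
sequence whenever a scaffold-internal N gap shares the bracket with the
true junction. If the bracket contains no N run the search widens by
50 kb and takes the single nearest run; failing that the conflict is
reported unresolved. Cuts conserve the non-N base multiset exactly and
grow the record count by exactly the number of cuts.

## Hybrid scaffolding and gap sizes

Each validated scaffold receives at most one placement: its best
alignment, provided no rival on a different locus comes within 3
confidence units, and subject to a 20-kb overlap resolution in favour of
the higher confidence. Sibling chains of the placed scaffold on the same
contig (one physical alignment split by a mis-sized internal N gap) are
stitched back together before geometry is read off, so placement and gap
estimation see the scaffold's full aligned extent.

The gap between adjacent placements is

```
gap = (bases strictly between the flanking aligned labels on the map)
    - (non-N overhang of the left scaffold past its last aligned label)
    - (non-N overhang of the right scaffold before its first aligned label)
```

floored at 13 bp. N bases in an overhang are unsized placeholders and are
excluded — counting their nominal length would shrink the estimate by
exactly the amount the gap is supposed to absorb. At zero noise this
estimator is exact; under the default noise model its error is dominated
by the accumulated sizing noise of the flanking-label interval `D`, i.e.
sd ≈ `sizing_sd_coeff · sqrt(D)`.

Super-scaffolds are per-contig ordered member lists with per-junction gap
estimates; unplaced scaffolds pass through as singletons under their
original ids. Emission writes AGP v2.1 (`N` rows for estimated gaps, `U
100` rows for unknown ones) and reconstructing from AGP plus member FASTA
reproduces the emitted sequences bit-exactly. A second round re-digests
the super-scaffolds (gap Ns carry no labels), aligns them to the second
map, reports any new conflict for re-arbitration with the map roles
swapped (conservatively, without automatic re-cutting of super-scaffolds),
and merges super-scaffolds linked by concordant placements at confidence
≥ 15 — merging never fragments, so N50 cannot decrease.

## Anchoring and accounting

A super-scaffold is assigned to the chromosome contributing the majority
of its linkage-map markers, requiring at least 2 markers (majority ties
stay unassigned; minority markers are logged as discordant). Order along
the chromosome is by mean cM (ties: longer scaffold first, then id);
orientation is the sign of the Spearman rank correlation between marker
cM and scaffold bp, computed only when two distinct cM values exist —
degenerate cases are recorded as `+` with an explicit undetermined flag.
Anchored scaffolds are joined with fixed 1000-N spacers (AGP `U` rows,
linkage evidence `map`); with `S` anchored scaffolds over `C` chromosomes
the set carries exactly `S - C` unknown-length joins. Unanchored
scaffolds stay in ChrUn as separate records, never concatenated.

Accounting operations reproduce the standard report tables (length,
effective length = length minus N bases, N% to 2 decimals, unknown-gap
counts, per-chromosome gene counts) and classify each scaffold against a
prior assembly as rescued / relocated / reoriented / unchanged. Relocation
within a chromosome is judged by a longest-common-subsequence of the two
orders, so a moved scaffold does not drag its unmoved neighbours into the
relocated class.

## The simulator

`simulate` generates, from one mandatory seed (operation-tagged child
generators keep streams independent):

* **genomes** — i.i.d. uniform bases; all spontaneous motif occurrences
  are scrubbed and each enzyme's motif is re-planted as a Poisson process
  at the configured density (default 15 labels / 100 kb), making label
  spacing a dial; optional tandem-repeat arrays for copy-number test
  scenarios. Default preset: 4 chromosomes × 12.5 Mb.
* **scaffolds** — Poisson breakpoints (default 2.3 / Mb, ~120 scaffolds
  per 50-Mb genome) with a short excised segment (U[500, 5000] bp,
  recorded as the true junction gap) between neighbours, random
  orientation flips, and internal N-run insertions (1 per 500 kb,
  100–5000 Ns) so split sites exist. Insertions have zero physical
  extent, emulating gaps whose nominal N count is wrong.
* **injected errors** — chimeras joining two scaffolds from different
  chromosomes through a 100-N spacer; both pieces must carry ≥ 8 labels
  per enzyme and end ≥ 200 kb inside their chromosomes, since a junction
  at a contig terminus is indistinguishable from a legitimate join in
  principle. Misplacements, misorientations and unplaced scaffolds are
  injected into a corrupted "prior assembly" table with truth classes.
* **optical maps** — true label positions from digestion; fragile-site
  breaks (nick chemistry, probability 0.1 per fragile pair, which at the
  default density reproduces the ~0.7 breaks/Mb contiguity real nicking
  maps show while direct maps stay chromosome-sized); Bernoulli label
  misses (0.10), Poisson false labels (0.5 / 100 kb), Gaussian interval
  sizing noise (sd = sqrt(interval) bp), and a minimum-length filter
  (150 kb).
* **genetic maps** — Poisson markers (12 / Mb) with a monotone
  piecewise-linear cM transform including zero-recombination plateaus, so
  the distinct-cM scarcity cases the orientation logic must survive occur
  naturally.

What the simulator does **not** model: raw molecule (BNX) data,
per-molecule stretch, diploid haplotypes, fluorescence intensity, and
chimeric consensus-map contigs (benchmarks fabricate those by splicing
contigs). Passing tests therefore demonstrate correctness of the
algorithms under the declared noise channels, not performance on any
particular real dataset.

## Benchmarks and problem sizes

The `benchmark` module scores the pipeline against simulator truth.
Problem sizes are chosen so a full run fits comfortably on one CPU:

* zero-noise end-to-end recovery on the 50-Mb default preset (about
  90 scaffolds, 8 chimeras; a few minutes): chimera recall, false splits,
  member order / orientation / junction-gap exactness (measured at the
  level of emitted pieces' true chromosome footprints), chromosome
  assignment, and provenance-ledger agreement;
* arbitration accuracy at default noise on thirty small two-chromosome
  replicates (~100 verdicts), with injected chimeras (truth:
  sequence error) and spliced map contigs (truth: map error). Junctions
  the second map cannot physically cover (checked against truth before
  arbitration) are reported as unassessable rather than scored, because
  `unresolved` is the contract-correct output there; an `unresolved` on a
  covered junction still counts as an error;
* noisy gap estimation over ~230 junctions (three 20-Mb replicates),
  scored against the 3-sd sizing band;
* direct-vs-nicking map contiguity over 20 seeds (direction only — the
  magnitude of the contrast is scale-dependent);
* DP optimum vs exhaustive chain enumeration on 100 instances of ≤ 8
  labels a side.

## Known limitations

* Breakpoint localisation is limited to the flanking-label bracket; when
  several N runs share the bracket, all are cut, which can sever a short
  genuine fragment (it survives as its own record).
* Second-round conflicts are reported, not auto-repaired.
* Arbitration abstains (`unresolved`) where the second map has no
  qualifying coverage; at desk scale with a fragmented nicking map this
  affects a minority of junctions.
* The confidence transform is a calibrated surrogate, not a P-value; its
  absolute scale is only meaningful relative to the shipped thresholds.
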
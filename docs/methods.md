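# Methods

## Model and assumptions

### Fingerprints and overlap scores

A clone's HICF fingerprint is its sorted list of restriction-fragment
sizes digitized to integer size units (0.1 bp per unit over a 35–600 bp
sizing window, so G = 5650 resolvable units). Band matching is greedy
two-pointer pairing over the two sorted lists with tolerance t: each
band is used at most once. On this interval structure the greedy count
attains the maximum bipartite matching; the suite certifies this against
an exhaustive matcher on small instances.

The Sulston score treats the `nL = min(n1, n2)` bands of the smaller
fingerprint as independent Bernoulli trials with success probability
`p = 1 − (1 − (2t+1)/G)^nH` and reports the binomial upper tail
`P(X ≥ m)`. The independence assumption makes the score a slightly
conservative estimate of the true null probability (the Monte-Carlo
acceptance test bounds the discrepancy). Scores are computed and
compared exclusively in log10 space.

### Contig assembly

1. **Build** — single-linkage clustering: contigs are connected
   components of the pair graph at the stringent cutoff (1e-80).
2. **Layout** — each contig is laid out in consensus-band (CB)
   coordinates: clone order from spectral seriation (Fiedler vector of
   the Laplacian of the matched-band similarity matrix), offsets
   propagated over a maximum-weight spanning tree with the edge estimate
   `n_i − m_ij` CB, signed along the seriation order, normalized to
   minimum 0. A clone's CB span equals its band count. This replaces
   FPC's simulated-annealing CB map with a deterministic approximation
   adequate for coordinate-level uses (MTP spacing, marker placement).
3. **DQer** — a clone is questionable (Q) when more than half its bands
   have no band within tolerance in the pooled bands of its contig
   mates; contigs with Q fraction > 0.10 are re-clustered at stringency
   stepped up by 1e-10 per step, at most three steps.
4. **Relaxed merges** — Singles-to-Ends then Ends-to-Ends at 1e-50
   between end clones (clones within one median clone span of a contig
   extremity), then an evidence merge allowed down to 1e-25 but only
   between contigs carrying markers of the same linkage group within
   10 cM. Merges apply best score first via union-find; merged contigs
   are re-laid out at the relaxed cutoff.

### Anchoring, scaffolding, MTP, synteny

- 3-D pooling: probes on a 5×5×5 grid, 15 axis pools, row-major
  assignment. Deconvolution per clone from the positive pools on each
  axis: all empty → negative; exactly one per axis naming a designed
  probe → unique; an empty axis beside a positive one (or an undesigned
  coordinate) → inconsistent; otherwise ambiguous with candidates the
  designed probes in the axis product. Probes hitting more than 8
  distinct map locations are masked as repetitive.
- A marker's CB position in a contig is the median midpoint of its hit
  clones' spans. Contigs take the majority linkage group (conflicts
  flagged, never dropped); COSII markers inherit their contig's group.
- CB→bp: `bp_per_cb = average insert / average bands per clone`,
  reported rounded to the nearest 10 bp. Pseudomolecules concatenate
  each group's contigs in mean-cM order with fixed 0.25-Mbp gaps;
  orientation is the sign of Spearman(CB, cM) over a contig's markers
  (≥2 distinct markers required). Gap padding is excluded from size
  statistics unless explicitly requested; component Mbp values are
  rounded to one decimal before summing.
- MTP spacing `n = max(1, round(m·k/i))` CB; selection walks targets
  0, n, 2n, … per contig, skipping targets within n/2 CB of an existing
  BAC-end or a previously selected right end, and refusing candidates
  whose left end falls within n/2 CB of an already selected left end.
- Synteny: per (source, reference chromosome) the longest chain of
  anchors monotone on both genomes (forward or inverted) with
  consecutive gaps ≤ max_gap on both sides is extracted repeatedly;
  accepted blocks claim their reference span. Chains shorter than 3
  anchors are discarded. Coverage statistics use a sweep over block
  intervals. Unanchored contigs inherit the linkage group collecting
  votes from >50% of their anchors and strictly more than any rival.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| tolerance t | 3 | size units (0.1 bp) | capillary sizing reproducibility |
| gellen G | 5650 | size units | 35.0–600.0 bp window at 0.1 bp |
| build cutoff | 1e-80 | probability | stringent initial assembly |
| merge cutoff | 1e-50 | probability | relaxed end merges |
| evidence floor | 1e-25 | probability | marker-supported merges only |
| QC band window | 20–220 | bands | removes failed/chimeric digests |
| Q threshold | 0.10 | fraction | DQer trigger |
| DQer step | 1e-10, ≤3 steps | probability factor | stepwise re-clustering |
| pool dims | 5×5×5 | probes | 125 probes in 15 reactions |
| repeat screen | >8 | map locations | masks repetitive probes |
| gap | 250,000 | bp | fixed inter-contig spacer |
| MTP k | 8,000 | bp | desired BAC-end spacing |
| BES read | 600 | bp | end-read length |
| chain gap | 50,000 | bp (pipeline default) | see below |
| min anchors | 3 | anchors/block | noise floor for blocks |

`chain_anchors` itself defaults to a 500-kb gap (appropriate for
chromosome-scale comparisons); the simulation pipeline overrides this to
50 kb because a chain gap must sit between the anchor spacing (~8 kb)
and the size of the rearrangements to be resolved (~40–120 kb at the
2-Mbp study scale) — with a gap larger than an event, chains simply step
over it.

## Generator realism and limits

The simulator generates an i.i.d. random genome (default 2 Mbp,
GC 0.5), three BAC libraries with production-scale insert windows
(HindIII 90–185 kb, EcoRI 40–160 kb, MboI 80–180 kb; 10× nominal
coverage each), clones whose ends always coincide with cut sites of the
cloning enzyme and whose target length is drawn from a truncated normal
around the library mean, and a five-enzyme HICF digest (HindIII, BamHI,
XbaI, XhoI, HaeIII) in which only fragments whose left cut was made by
one of the four labelled six-cutters are detected — reproducing the
~107-band fingerprints of SNaPshot-style end-labelling. Sizing noise is
Gaussian with SD 0.5 size units. These defaults are study conditions
fixed a priori, not tuned quantities.

Limits: the genome has no repeat structure, so repeat-induced false
joins and genuinely repetitive probes never arise (the repeat screen and
DQer are exercised on constructed inputs instead); sizing noise is
homoscedastic, whereas real capillary error grows with fragment size;
partial digestion, cloning bias, well-tracking errors, and hybridization
noise are not modelled (the hit-matrix simulator accepts false-positive
and false-negative rates for targeted tests); linkage groups are exact
windows of the genome with cM strictly proportional to bp.

## Numerical choices

- All Sulston arithmetic in log10 via `gammaln`/`logsumexp`; scores are
  compared in log space because true-overlap probabilities underflow
  float64.
- A cheap upper bound on the matched count (each band of the smaller
  list vs any band of the larger, by binary search) yields an optimistic
  score bound that prunes most of the O(N²) exact matchings during
  assembly.
- Layout is deterministic: spectral seriation with lexicographic tie
  breaks, a fixed orientation rule (smaller clone id at the left end),
  BFS offset propagation from the leftmost clone.
- All randomness flows through seeded `numpy` generators; stage seeds
  are fixed offsets of the run seed, and a fixed configuration produces
  byte-identical artifacts.
- Problem sizes (2-Mbp genome, 448 clones, 12 markers) are this
  package's own desk-scale choices: large enough that assembly,
  deconvolution, and block recovery are non-trivial, small enough that
  the whole suite runs in minutes on one CPU.

## Limitations

The CB layout is an approximation: it reproduces clone order and
coordinate-level spacing (rank correlation with true coordinates ≥ 0.95
is an acceptance criterion) but not FPC's exact consensus-band map. The
minimal FPC-dialect project file is a documented subset sufficient for
round-tripping by this toolkit, not a full FPC implementation.
Deconvolution reports ambiguity rather than resolving it, so probe pairs
closer than a clone insert lose some placements by design. Statements in
this document describe what the code computes and what the test suite
verifies; no empirical claims beyond those are made.
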
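# bacmap

A desk-scale re-creation of the FPC-era BAC physical-mapping workflow:
simulated high-information-content fingerprinting (HICF), Sulston-score
contig assembly, pooled-overgo marker anchoring, pseudomolecule
scaffolding, dense minimum-tile-path (MTP) selection, and synteny-block
chaining — every stage testable end to end against planted simulation
truth.

## The science

Before cheap long-read sequencing, chromosome-scale maps of plant genomes
were built from libraries of bacterial artificial chromosomes (BACs,
~100–150 kb inserts). Each clone was *fingerprinted*: digested with a
panel of restriction enzymes and sized on a capillary sequencer, giving a
list of fragment sizes ("bands"). Two clones drawn from overlapping
genome intervals share the fragments of the shared interval, so band
matching measures physical overlap.

**Sulston score.** Let the sizing system resolve *G* distinct size units
and call two bands matched when they differ by at most *t* units. For
fingerprints with `nL ≤ nH` bands, the chance that one given band of the
smaller fingerprint matches *some* band of the larger is

    p = 1 − (1 − (2t+1)/G)^nH

and the probability of observing at least *m* matches between two
*unrelated* clones is the binomial upper tail

    S = Σ_{j=m}^{nL} C(nL, j) p^j (1 − p)^(nL−j).

Scores are evaluated in log space (`gammaln` + `logsumexp`), since a true
overlap between ~107-band fingerprints scores far below the 1e-308
floating-point underflow floor. Contigs are the connected components of
the pair graph at a stringent cutoff (1e-80), refined by a Q-clone/DQer
pass and by relaxed Ends-to-Ends, Singles-to-Ends, and marker-evidence
merges (1e-50, floor 1e-25).

**Anchoring.** Marker probes are arranged on a 5×5×5 grid and hybridized
as 15 axis pools, so each probe lies in exactly three pools; a clone
carrying one probe lights one pool per axis and its probe is recovered
directly (clones carrying several probes yield ambiguous candidate sets,
reported, never auto-resolved). Contigs inheriting linkage-group (LG)
markers are ordered by mean cM position, oriented by the sign of the
Spearman correlation between band-coordinate (CB) and cM positions, and
concatenated into pseudomolecules with fixed 0.25-Mbp gaps.

**MTP and synteny.** A dense tile path selects a clone left-end every
`n = m·k/i` CB units (m = median CB per clone, i = average insert bp,
k = desired end spacing bp). BAC-end reads from the selected clones are
mapped to a diverged reference; maximal runs of anchors collinear (or
consistently inverted) in both genomes become synteny blocks, and
unanchored contigs inherit an LG prediction from the blocks their
anchors fall in.

## Worked example

```bash
bacmap demo --seed 1 --out runs/demo
```

simulates a 2-Mbp genome, three BAC libraries (HindIII / EcoRI / MboI,
10× each, 448 clones averaging ~107 bands), assembles, anchors against a
12-marker panel, selects an MTP, and chains BAC-end anchors against a
reference carrying a planted inversion, translocation, and duplication.
It prints:

```
contigs: 1  singletons: 0
anchored contigs: 1
genome size estimate: 1.9 Mbp (100.0% anchored)
MTP: n=7 CB, 146 clones, 292 reactions
synteny blocks: 8
```

The single contig spans the genome; the 8 synteny blocks recover every
planted collinear segment — 7 forward blocks plus the 120-kb inversion
detected as an inverted block — at 94.8% reference coverage. All 12
markers place at a single map location, and the two COSII markers (no
genetic position of their own) inherit LG1 from the contig they land in.
All artifacts (band files, a minimal FPC-dialect project file, CMAP/AGP
exports, anchor and block tables, JSON reports) are written to the run
directory.

The two headline unit conversions are direct CLI calls:

```bash
$ bacmap mtp-spacing -m 120 -i 138000 -k 8000
7
$ bacmap cb-factor --insert-bp 138000 --bands 114.2
{"bp_per_cb": 1208.4, "bp_per_cb_rounded": 1210}
```

i.e. one selected clone end every 7 CB units, and ~1210 bp per consensus
band.

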
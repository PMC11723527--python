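# Methods

This note records the model, the parameter choices that matter, the
numerical conventions, and what the synthetic fixtures do and do not show.

## Problem and model

A predicted protein structure is to be segmented into domains — compact
evolutionary/structural units, possibly discontinuous in sequence. The
package casts this as per-residue-pair classification: estimate
P(i and j share a domain) from geometry (distances, PAE) and homology
evidence, then convert the L×L probability matrix to discrete domains by
agglomerative clustering plus rule-based masking and refinement.

Coordinates and residue identity conventions: residues are renumbered 1..L
in file order; residue sets and hit mappings use these 1-based numbers;
intervals (crop segments, secondary-structure spans) are half-open over
them; matrix entry (i, j) lives at `values[i-1, j-1]`. All I/O (range
strings, TSVs) is 1-based inclusive, ECOD-style.

## Input channels

24 channels of shape L×L: distance, PAE, two position channels, 10+10
evidence channels.

- *Distance* is the minimum over heavy-atom pairs; hydrogens are removed and
  only the first altloc kept.
- *PAE asymmetry.* AFDB PAE matrices are asymmetric and no convention is
  mandated by the source data; we symmetrize by elementwise minimum —
  min preserves the strongest "well-modeled" signal — and use that one view
  both as network input and in disorder detection. The choice is isolated
  in `structure.load_pae`.
- *Scaling.* The network sees bounded inputs: distances capped at 50 Å and
  divided by 50, PAE capped at 31.75 Å (the AFDB ceiling) and scaled,
  positions divided by 2000 and clipped at 1, sequence-hit probabilities
  divided by 100, structure-hit Z-scores squashed by z/(z+10) (bounded,
  monotone, keeps the two evidence sources on a comparable range). Without
  the distance/PAE scaling the raw Å values dominate early training;
  with it all channels live in [0, 1].
- *Evidence.* Hits below the acceptability thresholds are discarded. The
  exact published thresholds for "acceptable" hits live in an upstream
  pipeline and are not printed here; the defaults (sequence: probability
  ≥ 20 and ≥ 10 aligned residues; structure: Z ≥ 2 and ≥ 20 aligned
  residues) are deliberately permissive placeholders, exposed in
  `AcceptabilityConfig` and meant to be tuned per database. Grouping is
  greedy best-first with a 20% coverage-overlap admission rule; group rank
  is the best member's score (ties: reference domain id ascending; whether
  rank should instead use merged coverage was an open choice — best-member
  is simpler and stable).

## Crops

Networks operate on fixed 500×500 crops.

- Short proteins (L < 500) are padded: x positions on the left, the
  remainder on the right, x uniform in [0, 500−L] per epoch; padded pixels
  are zero in every channel, masked out of the loss, and the input is
  multiplied by the validity mask at the network entry so padding content
  can never influence a masked loss (verified by perturbation tests).
- Long proteins get n crops per epoch (n = 1/2/3/4/5 for L ≤ 750 / ≤ 1000 /
  ≤ 1500 / ≤ 2000 / > 2000), each a fair coin between one 500-residue
  window and two in-sequence windows totalling 500 (each ≥ 50 residues;
  bounds uniform). Crops are re-sampled every epoch from a per-epoch seed
  derived from the run seed.
- Inference tiling is deterministic: 500-wide windows at stride 250
  (last window clamped to end at L) plus two-segment crops pairing every
  ordered couple of non-overlapping 250-residue tiles. Only pair coverage
  is contractual; this scheme guarantees it with O((L/250)²) crops, and
  coverage is verified exhaustively for L ∈ {501, 700, 1300, 2100}.
  Per-pair outputs from overlapping crops are averaged, then the matrix is
  symmetrized by averaging with its transpose.

## Network

48 convolutional layers with residual blocks and 15 dropout layers
(ratio 0.15) with a per-pixel two-class softmax head; the class-1 map is
the same-domain probability. The exact schedule is configuration, not
constant: the default is a 1×1 projection to 64 filters, 23 residual blocks
of two 3×3 convolutions (projection + 46 + 1×1 head = 48 conv layers),
dilation 8/4/2/1 and filters 64/48/32/16 stepping down over block
quartiles, dropout after 15 evenly spaced blocks. Blocks adapt channel
count on the skip path by slicing (narrowing) or zero-padding (widening) so
channel changes cost no extra convolution. A `tiny` preset (8 conv,
2 dropout, 8 filters) exists for desk-scale training and tests.

The implementation is pure NumPy: stride-1 'same' convolutions computed as
k² shifted BLAS matmuls with hand-written backward passes, Adam
(lr 1e-3 — optimizer and rate are artifact choices), binary cross-entropy
on masked pixels with probabilities clipped to [1e-7, 1−1e-7]. Everything
is float32, CPU-only, and bit-deterministic given the run seed; per-epoch
crop/dropout seeds derive from `SeedSequence([run_seed, epoch])`.

Training holds out whole redundancy clusters (default 5% of clusters) for
validation; the epoch cap (default 30) is the primary stop, with optional
early-stopping patience that is off by default.

## Probability → domains

Stages run in fixed order: disorder → helical linkers → segments →
clustering → boundary refinement → size filter.

- *Disorder.* A residue's PAE neighbors are residues ≥ 20 apart in sequence
  with symmetrized PAE < 6 Å. Windows are tiled (non-overlapping, matching
  the 5-residue segment convention; whether windows slide or tile was an
  open choice — tiling is used, and the trailing remnant window is tested
  with the same ≤ 10 total-neighbor threshold). All residues of a
  qualifying window are flagged.
- *Helical linkers.* Same windowed test, with neighbor pairs inside one
  secondary-structure element not counted, windows with > 40% candidate
  intra-domain residues (those covered by acceptable hits) ineligible, and
  only windows intersecting a helix eligible (the literal reading of
  "helical" linkers; a config flag disables the helix restriction).
  Secondary structure comes from DSSP codes — runs of B/E ≥ 3 are strands,
  G/H/I ≥ 6 helices; the package consumes the code string or DSSP file
  rather than bundling an assigner, keeping the thresholding logic (which
  is the contribution) separate from the assignment backend.
- *Segments.* Tiled 5-residue segments, trailing remnant kept as a short
  segment (discarding termini would bias boundaries); segments with ≥ 3
  masked residues are dropped.
- *Clustering.* Segment pairs with mean block probability Psame > x are
  visited in descending order (ties: segment index ascending — ties are
  not expected in float data but the rule makes runs reproducible). Three
  scenarios: both ungrouped → found a group; one grouped → the free
  segment joins if (within-group mean)/(segment-to-group mean) < y, else
  founds its own group; two groups → merge if Psame1 < y·Psame12 or
  Psame2 < y·Psame12. A within-group mean over zero pairs (singleton
  group) is undefined; it is treated as equal to the between mean, which
  makes the merge test pass — a singleton carries no cohesion evidence
  against the merge. Defaults x = 0.89, y = 1.12; both sit in
  `ClusterConfig` and `grid_search_xy` re-optimizes them on a validation
  set by maximizing the fraction of correctly predicted domains
  (mutual overlap > 75%), ties toward smaller x then smaller y. Groups
  with one segment are left unassigned rather than force-merged;
  refinement may still recruit their residues.
- *Refinement.* Sweeps (N→C, removals before additions, ≤ 20 sweeps or to
  a fixed point — the order and cap are fixed for determinism): a
  contiguous-run terminus with strictly more contacts (< 6 Å, > 6 apart)
  outside its domain than inside is dropped; an unassigned residue
  sequence-adjacent to a domain with strictly more inside contacts is
  added (if adjacent to several domains, the one with most inside
  contacts wins). Domains with < 20 residues are then discarded.

## Evaluation

Detection uses "at least 50%" of reference residues assigned; split
counting uses the strictly-greater ">50%" per predicted domain — the two
thresholds differ by design and are carried exactly. IoU is
|∩|/|∪| of residue sets (undefined for two empty sets). Summary statistics
use linear-interpolation quantiles.

## Synthetic fixtures

`synthetic.make_protein` plants each domain as a compact confined random
walk (3.8 Å steps inside a radius ≈ 3·size^⅓ + 2 Å ball, 1–3 heavy atoms
per residue), domains ≥ 25 Å apart, extended linkers between them; PAE is
uniform 2–5 Å within domains and 15–30 Å elsewhere; pLDDT 90/40 for
domain/linker residues; secondary structure alternates 8-residue helices
and 4-residue strands inside domains. `make_hits` plants 1–5 high-scoring
hits per domain covering 60–100% of it, plus optional low-scoring decoys
straddling boundaries. `make_probability` draws same-domain pixels from
0.55 + 0.45·Beta(8, 2) and others from 0.45·Beta(2, 8) (so thresholding at
0.5 is exact at zero flip rate) with a configurable mode-flip rate.

The benchmark suite (`make_suite`) uses 30 proteins, domain counts 1/2/3
with weights 0.3/0.4/0.3 (multidomain-dominated, as in classified-structure
collections), sizes 60–140, 10-residue linkers, and a ~1/15 chance of a
discontinuous wrapped domain (such domains are rare in real training sets).
These sizes keep the full train-predict-parse-evaluate cycle within a few
minutes on one CPU while leaving every pipeline stage exercised.

What the fixtures do *not* emulate: real PAE error structure (smooth
gradients, partially disordered regions, inter-domain contacts with low
PAE), realistic fold geometry, or hit noise correlated with structure.
Passing the suite therefore demonstrates algorithmic correctness and
learnability of planted block structure, not benchmark-level accuracy on
real predicted models; the published-scale benchmarks require the real
classified-domain databases and trained weights and are out of scope.

## Known limitations

- Single chains only; no altloc handling beyond first-listed, no hydrogens.
- The CNN is NumPy/CPU; full-scale (48-layer) training is supported by the
  code but not practical without substantial compute — the full preset is
  used for architecture introspection and forward-pass work, the tiny
  preset for training studies.
- External search engines (HH-suite, Foldseek, Dali) are out of process:
  the package parses their outputs (`.hhr`, a documented simplified
  equivalence format, or a pre-digested TSV) and drives iterative masked
  re-alignment through a pluggable aligner callable.
- Discontinuous domains are supported throughout (two-segment crops,
  wrapped synthetic layouts, range-string I/O) but are the hardest case;
  the clustering admits discontinuous merges only through the group-merge
  scenario.
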
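# Methods

## Mutant library design

### Mutation naming and numbering

Mutations are written `<parent aa><position><mutant aa>` (e.g. `T6A`),
dash-joined for multiples (`S9G-R31L-R85L`). Positions are 1-based with the
initiator methionine as residue 1; the convention is fixed here because
mutant names are ambiguous without one, and counting the initiator keeps
positions aligned with codon indices in the CDS. Every parsed token is
validated against the parent protein, and identity substitutions are
rejected. `*` denotes a stop codon.

### Codon choice

Designed substitutions use exactly **one codon per amino acid** — the top
entry of an *E. coli* K-12 usage-ranked table (stop = TAA) — rather than
degenerate codons. This is the point of cassette mutagenesis over
error-prone PCR: the pool contains no synonymous duplicates and no
unintended stops, so library cardinality is exactly 20 × (codons in range)
for site saturation and C(k, 2) minus same-position pairs for paired
recombination. The ranked tail of the table is used only for synonymous
rescue (below). The table is a plain data structure and can be swapped for
another host's preferences.

### Cassette windows and overhangs

The CDS is tiled into windows of near-equal size whose variable regions fit
the synthesis limit (default ≤ 90 nt); remainder codons go to the trailing
windows. Each window's 4-nt assembly overhangs are read off the constant
sequence adjacent to it — the last 4 nt of the upstream constant region
(vector arm + CDS prefix) and the first 4 nt downstream — so a correct
ligation reconstitutes the parent sequence exactly, with no scars. All
overhangs in a design must be mutually distinct, non-palindromic, and not
reverse complements of one another; because junction overhangs are
sequence-derived, the tiler searches boundary shifts of up to ±3 codons for
a clean set and raises an error listing the colliding junctions when none
exists. Explicit window boundaries (whole-codon only) override the search.

### Oligo layout and forbidden-site rescue

```
adapter5 · flank5 · GGTCTC · N · overhang5 · variable · overhang3 · N · GAGACC · flank3 · adapter3
```

Two inward-facing BsaI sites (6-nt recognition, 1-nt spacer, 4-nt
overhang; the enzyme model is configurable) release the variable region
with the window's overhangs. The evSeq-style inner adapters default to
empty strings and are configurable. When a mutation writes a recognition
site into the variable region, the codon overlapping the site is rewritten
synonymously — codons scanned left to right, synonyms in table-rank order,
first rewrite that clears both strands wins — and every rewrite is reported
on the emitted oligo. Parents must be *domesticated* (recognition-site-free
constant regions); the synthetic parent generator only emits domesticated
sequences, and acceptor construction fails with an explicit message
otherwise.

### In-silico Golden Gate

Digestion is simulated literally: recognition sites are located on both
strands of the (linear) oligo and the (circular) acceptor, cuts are placed
with the enzyme's spacer/overhang geometry, and fragments carry their
terminal 4-mers. Ligation enumerates every distinct circular product over
fragment orientations; assembly succeeds only when exactly one full-length
product containing the vector backbone exists. Scrambled overhangs
therefore produce an explicit *no product* failure and promiscuous
overhangs an *ambiguity* failure, rather than silently wrong sequences.
The extracted CDS of every emitted member is required (and fuzz-tested) to
translate to the intended mutant protein; a wild-type cassette round-trips
to the parent CDS byte-for-byte.

### Pool QC

`qc_mutation_count` recounts amino-acid mutations of observed (sequenced)
members against the parent and partitions the pool into
{matching, fewer, more} relative to the designed count; the off-count
classes are the template-swap candidates. `check_library_coverage` passes
when transformants ≥ 100× the designed unique diversity (threshold
configurable).

## Phantom simulation

### Response model

Each well is four numbers: nonlinear amplitude `A` (arbitrary intensity
units), buckling threshold `p_buck` (default 150 kPa), collapse midpoint
`p_col` (default 300 kPa), and collapse width `w_col` (default 20 kPa).
The rendered mean signal at pressure `p` is
`A · 1[p ≥ p_buck] · S(max(p, q))` with survival
`S(q) = 1/(1 + exp((q − p_col)/w_col))` of the per-well running-maximum
pressure `q` — a logistic was chosen because collapse transitions are
empirically sigmoidal; no particular mechanistic form is implied. Signal is
zero below buckling and plateaus at `A` above it; no amplitude-vs-pressure
shape between the thresholds is modeled, and the linear-scattering channel
is not rendered at all (the pipeline consumes nonlinear-signal images
only). Far past the midpoint the survival term underflows to exact
floating-point zero, which is what makes noiseless closed-form tests exact.

Voltage maps to pressure linearly (default 50 kPa/V; only ratios matter
anywhere in the pipeline). The default pre/post protocol images at 4.4 V
(220 kPa, inside the nonlinear window) and collapses at 30 V (1.5 MPa,
75 widths past the midpoint, survival ~1e-26).

### Noise

Pixels are Rayleigh-distributed with the local mean (background `B = 2.0`
everywhere, plus the well response inside well disks) — the classical
amplitude statistics of envelope-detected ultrasound speckle. The Rayleigh
family is parameterized by its mean (`scale = mean·√(2/π)`), so ROI means
are unbiased estimates of the programmed means with relative SD
`√((4−π)/π)/√n ≈ 0.52/√n` per ROI. `speckle=False` renders exact means for
closed-form tests. A seeded generator makes every stack bit-reproducible.

What the simulator does **not** emulate: beamforming and pulse-sequence
physics, attenuation and point-spread blur, well-to-well crosstalk,
registration error, culture-density variation, and any coupling between
expression level and collapse pressure. Passing recovery tests therefore
demonstrates that the quantification pipeline is correct and statistically
efficient under speckle — not that it is robust to instrument artifacts.

### Geometry

A `WellGrid` maps wells (8 × 12 by default) and background regions to
pixel-disk ROIs: 0-based pixel centers at integer coordinates, membership
by Euclidean distance ≤ radius with boundary ties included. Background
ROIs sit on diagonal inter-well midpoints by default and must not overlap
sample ROIs (validated at construction). Grid placement is deterministic
from configuration; no image registration is attempted.

## Quantification

Difference SBR = (pre sample mean − post sample mean)/(post background
mean), computed only for frame pairs at the same transmit voltage (a
metadata-enforced precondition); plain SBR = sample mean / background
mean. Background disks are pooled (a single mean over their union, i.e.
pixel-count weighted), and negative difference values are retained so null
distributions stay symmetric around zero. On noiseless simulator stacks the
difference SBR equals `A_eff/B` exactly, where `A_eff` is the response at
the imaging pressure — the closed form used as an oracle in the tests.

Collapse-ramp curves are fit with
`f(x) = baseline + plateau/(1 + exp((x − midpoint)/width))` by
least squares (initialization: baseline = min, plateau = range, midpoint =
first half-decay crossing, width = span/10; width bounded positive). The
fitted midpoint is reported as the collapse pressure. A fit is flagged —
not raised — as unsuccessful when the curve is flat, the optimizer fails,
the midpoint leaves the scanned range, or the rms residual exceeds 20% of
the data range; fewer than 4 points is an error. `normalize=True` divides
the curve by its maximum first so midpoints can be compared across samples
with different contrast. Ramps intended for collapse fitting should start
above the buckling threshold; the sub-buckling step function otherwise
biases the logistic.

## Screening pipeline

Aggregation averages technical replicates within each biological replicate
first, then reports the mean of biological-replicate means with SEM =
sample SD (n−1) / √n_bio; a single biological replicate reports SEM 0 with
`n_bio = 1` as the flag. Fold-change is the ratio of grand means (not the
mean of per-replicate ratios — with shared collapse parameters the two
agree in expectation, and the ratio of means is the lower-variance
estimator here). Ranking sorts on the grand mean of the difference SBR,
deduplicates by amino-acid mutation signature (protein identity, not DNA),
breaks ties lexicographically on sample id, and returns up to N — all
deterministic and permutation-stable. Titration summaries use population
STD by default (configurable to sample SD) and report the argmax cell and
any missing cells of the factorial grid. Plate layouts place picks from A1
and one parent control in the last well of each plate (enabling per-plate
normalization); tray capacity is phantoms × wells per phantom, 12 × 96 =
1152 by default.

## Problem sizes in the test suite

Tests run the full paths at reduced scale chosen to exercise every regime:
ROI-oracle checks use ≤ ~40×40-px images with 1–4 wells; speckle-recovery
checks use ~10⁴-pixel ROIs (radius 57), 3 technical replicates, 12-point
collapse ramps, and 20 seeds; assembly fidelity is fuzzed over 1000+
members on 70-codon parents; the simulated screening round uses 8-well
plates over 20 seeded runs. Synthetic parents are random domesticated
CDSs of the real genes' lengths (70 and 87 codons); only codon counts, not
the specific sequences, enter any cardinality result.
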
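# gvscreen

A toolkit for high-throughput acoustic screening of **acoustic reporter
genes** (ARGs) — gene clusters whose expression produces gas vesicles (GVs),
air-filled protein nanostructures that scatter ultrasound and so make gene
expression visible *in vivo*. Directed evolution of the primary GV
structural protein (GvpA/GvpB homologues) requires (i) designed mutant
libraries, (ii) ultrasound scans of thousands of bacterial cultures arrayed
in 96-well agarose phantoms, and (iii) quantification and ranking of the
resulting signals. `gvscreen` implements the computational core of that
workflow, with a synthetic phantom-image simulator standing in for the
scanning hardware so every stage is testable end to end.

## What it does

**Library design** (`gvscreen.mutagenesis`, `gvscreen.cassette`)

* *Scanning site saturation*: every codon of a CDS is substituted with the
  19 non-parent amino acids plus a stop codon, one fixed codon per
  substitution from an *E. coli*-usage-ranked table — so a 70-codon gene
  gives exactly 20 × 70 = 1400 members and an 87-codon gene 1740, with no
  synonymous duplicates and no accidental premature stops.
* *Paired recombination*: beneficial single mutations combined two at a
  time, one member per unordered pair at distinct positions (C(10,2) = 45
  members from a top-10 list).
* Members are emitted as *cassette oligos*: a variable region (one tiling
  window of the gene) framed by constant primer flanks and inward-facing
  BsaI sites. An in-silico Golden Gate engine digests oligo and acceptor
  vector and verifies that the single circular product reconstitutes a CDS
  translating to the intended mutant protein.
* QC utilities flag *template-swap* artifacts (members with zero or three
  mutations in a two-mutation design, a known artifact of PCR-amplifying
  near-identical oligo pools) and check transformant fold-coverage
  (pass at ≥ 100× designed diversity by default).

**Phantom simulation** (`gvscreen.phantom`, `gvscreen.grid`)

GVs respond to ultrasound in three pressure regimes — linear scattering,
nonlinear scattering above a buckling threshold, and irreversible collapse.
The simulator renders the nonlinear-signal channel of a well plate: each
well's mean signal is

```
signal(p) = A · 1[p ≥ p_buck] · S(max pressure so far),
S(q) = 1 / (1 + exp((q − p_col) / w_col))
```

on a Rayleigh-speckle background of mean *B*, with collapse state carried
across frames (signal never recovers after a high-pressure pulse). Three
protocols mirror an acoustic plate reader: pre/post-collapse pairs, voltage
ramps (pre/post pairs at each voltage), and collapse ramps.

**Quantification** (`gvscreen.metrics`)

* nonlinear difference SBR = (precollapse sample mean − postcollapse sample
  mean) / postcollapse background mean, with the two frames of each pair
  required to share a transmit voltage;
* plain nonlinear SBR = sample mean / background mean for collapse ramps;
* four-parameter logistic fits of collapse-ramp curves, reporting the
  midpoint as the collapse pressure (optionally after normalizing for
  nonlinear contrast);
* decibel conversion for display images.

**Screening pipeline** (`gvscreen.pipeline`)

Two-level replicate aggregation (technical replicates averaged within each
biological replicate; mean ± SEM across biological replicates), fold-change
versus parent, deterministic top-N ranking with deduplication by amino-acid
mutation signature, glucose × arabinose autoinduction titration summaries,
screening-plate layouts (e.g. 380 picks + 4 parent controls → 4 full
96-well plates), and scan-tray capacity (12 phantoms × 96 wells = 1152
samples per automated scan).

## Worked example

```python
import gvscreen as gv

# --- design a site-saturation library on a 70-codon synthetic parent
parent  = gv.random_parent_cds(70, seed=7, id="gvpA-like")
members = gv.design_site_saturation(parent)          # 1400 members
windows = gv.tile_cds(parent, max_variable_len=90)   # codons 1-22, 23-46, 47-70
oligos  = gv.emit_oligos(members, windows, parent)
acceptor = gv.build_acceptor(parent, oligos[0].window)
assert gv.ECOLI_TABLE.translate(gv.simulate_assembly(oligos[0], acceptor))

# --- simulate a pre/post-collapse scan and quantify it
grid  = gv.WellGrid.standard(n_rows=1, n_cols=3, roi_radius=20, n_background=2)
wells = {"A1": gv.WellResponse(amplitude=10.0),   # bright mutant
         "A2": gv.WellResponse(amplitude=2.0),    # parent
         "A3": gv.WellResponse(amplitude=0.0)}    # empty well
noise = gv.NoiseModel(background_mean=2.0, speckle=True)
stack = gv.run_protocol(gv.pre_post_protocol(), grid, wells, noise, seed=1)
diff  = gv.pre_post_difference_sbr(stack, grid)
print({k: round(v, 3) for k, v in diff.items()})
print("fold vs parent:", round(diff["A1"] / diff["A2"], 2))
```

prints

```
{'A1': 4.969, 'A2': 0.982, 'A3': -0.0}
fold vs parent: 5.06
```

The mutant well reads a difference SBR near its programmed `A_eff/B`
(≈ 4.91 at the default imaging pressure), the empty well reads ≈ 0 (noise
only, negative values retained), and the recovered fold-change matches the
programmed 5× ratio of amplitudes to within speckle noise.

A `gvscreen` command-line interface wraps the same functions
(`gvscreen design saturate`, `design recombine`, `design qc`, `simulate`,
`quantify`, `rank`, `layout`, `titrate`, `capacity`); see `gvscreen --help`.

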
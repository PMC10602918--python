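# Methods

## Precursor model

A MIR390-family amiRNA precursor is modeled as nine ordered segments:

```
flank5 · bs5_arm · guide(21) · dsl5_arm · loop · dsl3_arm · star(21) · bs3_arm · flank3
```

The basal stem (BS) pairs `bs5_arm` against `bs3_arm`, the 21/21
guide/star duplex sits above it, and the distal stem-loop (DSL =
`dsl5_arm + loop + dsl3_arm`) caps the hairpin. All coordinates are
1-based inclusive (so the span 1004..1092 is 89 nt). Sequences are accepted
in DNA or RNA, case-insensitively; precursors are handled as RNA, cloning
oligos as DNA.

Registered backbones and their declared arithmetic
(`total = bs_region + 42 + dsl`):

| backbone | bs region (nt) | dsl (nt) | total (nt) |
|---|---|---|---|
| pri | 448 (33-bp-stem + 415 flanks) | 31 | 521 |
| AtDSL-Δ6/13/21/25 | 448 | 25/18/10/6 | 515/508/500/496 |
| OsDSL, OsDSL-Δ2/4/6 | 448 | 16, 14/12/10 | 506, 504/502/500 |
| OsDS-AtL | 448 | 12 | 502 |
| BS, BS-Δ7/17/23/31 | 33, 26/16/10/2 | 31 | 106, 99/89/83/75 |
| shc | 33 | 14 | 89 |

The Δ-series are derived at load time from their parent by deleting
symmetrically from the duplex-proximal ends of the affected stem (the odd
nucleotide from the longer arm), never stored redundantly. Every length in
the table is re-checked when the registry loads, so a mistyped bundle fails
immediately.

## Duplex geometry, star design, compensation nucleotides

The guide/star duplex carries 2-nt 3' overhangs, as released by Dicer-like
processing. In the hairpin this means:

- guide *i* pairs star (20 − *i*) for *i* = 1..19, except one declared
  mismatch facing guide position 11 (star position 9), mirroring the
  central mismatch of the natural miR390/miR390* duplex;
- guide 20/21 pair the two duplex-proximal `dsl3_arm` bases — these are
  the **two compensation nucleotides** rewritten for every amiRNA
  (Watson-Crick complements of guide 21/20), which is what keeps the
  backbone's drawn structure intact for an arbitrary guide;
- star 20/21 (the star's 3' overhang) face the two duplex-proximal
  `bs5_arm` bases; since those are backbone sequence, the star's last two
  bases are fixed template data, not a function of the guide.

`design_star` therefore returns, deterministically: complement at every
template-paired position, the guide base itself at mismatch positions (a
same-base apposition can never pair, including via G:U), and the fixed
overhang bases elsewhere. An all-paired blunt template
(`ALL_PAIRED_TEMPLATE`) is provided for which star design is exactly
reverse complementation (and hence an involution).

This geometry is also what makes the cloning-oligo arithmetic exact (next
section); it is the only assignment of the "two modified nucleotides per
construct" we found that does.

## Cloning oligos and in-silico ligation

A B/c acceptor vector is the backbone with the guide..star region replaced
by a stuffer between two inverted BsaI sites; digestion exposes two fixed
4-base 5' overhangs. The forward (sense) oligo spans

```
bs5_arm[-4:] + guide(21) + DSL + star[1..19]
```

— 4 + 21 + 31 + 19 = **75 bases** for `AtMIR390a-B/c` and
4 + 21 + 14 + 19 = **58 bases** for `BS-AtMIR390a-B/c`. The reverse oligo
is the reverse complement of `guide + DSL + star(21) + bs3_arm[1..2]`
(same length), so the annealed duplex has the two 4-base 5' overhangs and
the star's last two bases plus two bs3 bases come from the vector.
`ligate` checks overhang identity against the vector and internal
annealing of the two oligos, then reconstructs the sense strand; oligo
design refuses guides that introduce an internal BsaI site (GGTCTC/GAGACC)
and records whether ligation reproduced `build_precursor` bit-exactly.

## Structural validation

`pair_by_layout` verifies the declared pairs — basal stem (anchored at the
base), duplex per template, compensation and star-overhang pairs, DSL stem
(anchored at the loop) — against the assembled sequence. Watson-Crick and
G:U both count as paired (configurable); declared mismatches must *not*
pair. Violations are reported as (position, expected, found), never fixed
silently. With the bundled backbones the pri/shc basal helix is 16 bp
(14 arm pairs + 2 star-overhang pairs), inside the canonical 15–17 bp
band; the 17-nt bs3 arm carries 3 unpaired duplex-proximal bases, and stem
anchoring away from the duplex is what lets the Δ-deletions preserve the
parent register.

`fold_nussinov` is a classical base-pair-maximization DP (min loop 3 nt,
G:U allowed, deterministic leftmost-partner traceback) used only as an
independent cross-check that the declared hairpin's pair count is
attainable; it is not an MFE predictor, and no test asserts that the
declared pairing is contained in an optimal fold.

## Sequencing metrics

Reads are collapsed to unique sequences with counts (fastx_collapser
convention, `>rank-count` headers) and mapped exactly — no mismatches, no
gaps — against the forward strand of the reference (or both strands for
polarity). A read hitting *m* positions contributes its count at each
position but enters the mapped total once; RPM = count/total × 10⁶, so
ΣRPM = 10⁶ exactly whenever every mapped read is single-hit (always the
case for the simulated precursor libraries; the multi-hit caveat is
documented on `MappingProfile`). The RPM denominator is per-reference
(reads mapped to the reference under analysis), since profiles are built
per precursor.

Processing accuracy uses the 9-position window [g−4, g+4] on read 5' ends,
lengths 19–24 nt, (+) strand only; the window does not constrain read 3'
ends. The numerator is the count at (g, 21, +), which under exact mapping
is necessarily the authentic mature amiRNA (still asserted explicitly). A
zero denominator yields an explicitly flagged undefined accuracy, never
0/0. Counts (not unique sequences) are weighted throughout, matching how
counts are retained through collapsing; accuracy is invariant under count
rescaling.

The cleavage site for phasing is the canonical plant AGO1 cut between the
target bases opposite guide positions 10 and 11; `locate_cleavage_site`
requires exactly one perfectly complementary site and returns the last
base of the 5' fragment (site start + 10). Registers partition 21-nt (+)
reads strictly downstream of the cut into 21 cyclic classes, register 1
being perfectly phased.

## Simulator

`simgen` emulates the three library types the metrics are designed for:

- **Precursor reads**: a read is star-arm with probability
  1 − `guide_star_ratio` (default 0.9 → 10% star reads, exact 21-nt star),
  otherwise guide-arm: the exact mature guide with probability
  `exact_fraction` (default 0.95), else a mis-processed read with 5'
  offset drawn from a symmetric triangular distribution on ±1..4 and
  length from {19: .03, 20: .12, 21: .60, 22: .12, 23: .03, 24: .10}
  (the 24-nt class standing in for transgene-derived sRNAs). Because
  every offset/length combination lands inside the accuracy window and
  star reads land outside it, `processing_accuracy` recovers
  `exact_fraction` in expectation for any star share — the property the
  recovery tests rely on.
- **Viral siRNAs**: 19–24-nt windows uniform along a genome, strand (+)
  with probability `strand_bias` (0.5 ≈ dsRNA-derived, high bias ≈
  hairpin/subgenomic-derived).
- **Phased reads**: 21-mers starting at site+1+21k with probability
  `phased_fraction`, else uniform downstream; the register-1 expectation
  of a half-phased mixture is 0.5 + 0.5/21 because unphased reads also hit
  register 1.

Counts are multinomial allocations over the discrete outcome space, drawn
from a single `numpy.random.default_rng(seed)`; identical seed + config
give identical read sets on any platform. Out-of-bounds offset/length
cells are redrawn among feasible cells, failing after 100 rounds.
The offset and size spectra are plausible placeholders, not measured
Dicer-imprecision spectra: passing recovery tests shows the metrics invert
the generative model, not that real libraries look like this. The
simulator also omits sequencing errors, adapters and PCR duplication by
design.

## Synthetic backbone bundle

The natural AtMIR390a/OsMIR390 segment sequences are published only in
supplementary appendices, so `data/backbones_synthetic.yaml` ships
synthetic stand-ins (flagged as such in the file): segments of the correct
lengths, fully Watson-Crick stems under the layout above, free of BsaI
sites, with the real mature miR390a guide as the slot placeholder. The
pri flank split (415 nt of ssRNA around the 33-nt basal stem) is not
published; 207/208 was fixed once, near-even. Consequences: every length,
pairing, oligo and metric computation here is faithful to the
architecture, but the literal precursor strings differ from the natural
ones — users cloning real constructs should load the published sequences
via their own bundle, which the registry validates with the same length
checks.

## Numerical and interface choices

- Problem sizes: recovery tests use depth 10⁵ (accuracy), 10⁴ (polarity),
  2.1×10⁴ (phasing) — large enough for 3σ bounds of ±0.2–1.5 percentage
  points, and all fast.
- Ties in Nussinov traceback go to the leftmost admissible partner;
  outputs are byte-stable across runs.
- Degenerate inputs are flagged, not errored: empty read sets collapse to
  empty lists, unmapped profiles carry an `empty` flag with zero RPM,
  zero-denominator accuracy is `None`, zero-read phasing tables are
  all-zero with `n_reads = 0`.
- CLI exit codes: 0 success, 2 usage error, 1 runtime error; every file
  output gets a `.provenance.json` sidecar (tool version, config, hash,
  seed).
- MFE/thermodynamic folding and mismatch-tolerant mapping are deliberately
  out of scope; exactness of the mapper is a property of the method, and
  Gateway recombination beyond the BsaI insert step is not simulated.
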
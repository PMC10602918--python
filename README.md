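# amirnakit

Design and sRNA-seq evaluation of minimal *MIR390*-based artificial-microRNA
precursors.

Artificial microRNAs (amiRNAs) are 21-nt small RNAs that redirect the plant
miRNA machinery to silence a chosen transcript. They are produced *in vivo*
from an engineered miRNA precursor in which the native miRNA/miRNA* duplex
is replaced by the amiRNA/amiRNA* duplex. The widely used *AtMIR390a*
primary precursor is 521 nt long; most of that length is dispensable, and a
shortened chimeric ("*shc*") precursor of only 89 nt — the complete 33-nt
*AtMIR390a* basal stem, the 42-nt amiRNA/amiRNA* duplex, and the *OsMIR390*
distal stem-loop shortened to 14 nt — still yields accurately processed,
highly active amiRNAs, and is short enough to ride stably inside an RNA
virus vector for transgene-free silencing.

`amirnakit` is for researchers engineering such constructs and for
bioinformaticians evaluating how precisely they are processed:

- **Design** (`amirnakit.design`): a registry of precursor backbones
  (`pri`, the `AtDSL-Δ`/`OsDSL-Δ`/`BS-Δ` deletion series, `OsDS-AtL`,
  `shc`), star-strand design under a declared duplex template, precursor
  assembly with per-amiRNA compensation nucleotides, annealed cloning-oligo
  design for the BsaI-based B/c vectors (75-base oligos for
  `AtMIR390a-B/c`, 58-base for `BS-AtMIR390a-B/c`) with in-silico ligation
  verification, and 1-based coordinate fragment extraction.
- **Structure** (`amirnakit.structure`): layout-based hairpin validation
  (basal stem / duplex / distal stem-loop pairing, dot-bracket output) and a
  Nussinov base-pair-maximization folder as an independent cross-check.
- **Sequencing metrics** (`amirnakit.srnametrics`): read collapsing,
  exact-match ungapped mapping with per-position counts and RPM,
  the processing-accuracy statistic, strand polarity, cleavage-site
  location, and 21-register phasing tables.
- **Simulation** (`amirnakit.simgen`): seeded generators for precursor
  reads, viral siRNAs and phased reads with known parameters, so every
  metric can be tested for parameter recovery without sequencing data.

## Core quantities

For a precursor with guide 5' position *g*, mapped without mismatches or
gaps to its forward strand, the **processing accuracy** is

```
accuracy = N_exact / N_window
```

where `N_window` counts 19–24-nt (+) reads whose 5' ends fall in
[*g* − 4, *g* + 4] and `N_exact` counts reads at exactly (*g*, 21 nt, +) —
the authentic mature amiRNA. Per-position abundances are reported as
**RPM** = count / total mapped reads × 10⁶. The **phasing register** of a
21-nt (+) read starting at *p*, relative to a cleavage site *c* (the last
target base left of the cut, opposite guide positions 10/11), is
`((p − (c+1)) mod 21) + 1`; phased secondary siRNAs concentrate in
register 1. **Strand polarity** is the (+)/(−) split of mapped counts,
diagnostic of dsRNA-derived (≈50/50) versus hairpin-derived ((+)-skewed)
small RNAs.

Because the natural precursor sequences ship only in supplementary
appendices, the bundled backbone segments are synthetic stand-ins
(`data/backbones_synthetic.yaml`) that satisfy every published length and
pairing constraint; see `docs/methods.md`.

## Worked example

Design the 89-nt shc precursor and its 58-base cloning oligos for a guide:

```
$ amirnakit design precursor --guide UUCGAAUGCUUCGAUUGGCAA --backbone shc --name amiR-demo
>shc-amiR-demo guide_start=17 star_start=52 bs5_arm=1..16;guide_slot=17..37;dsl5_arm=38..40;loop=41..48;dsl3_arm=49..51;star_slot=52..72;bs3_arm=73..89
CUAUAACCUCCUGGCUUUCGAAUGCUUCGAUUGGCAAAUUACGAACAGAUUGCCAAUCGUAGCAUUCGAAAGUCACCAGGAGGUUAUAG

$ amirnakit design oligos --guide UUCGAAUGCUUCGAUUGGCAA --vector "BS-AtMIR390a-B/c" --name amiR-demo
name        vector            strand   sequence                                                    length  overhang
amiR-demo   BS-AtMIR390a-B/c  forward  GGCTTTCGAATGCTTCGATTGGCAAATTACGAACAGATTGCCAATCGTAGCATTCGAA  58      GGCT
amiR-demo   BS-AtMIR390a-B/c  reverse  GACTTTCGAATGCTACGATTGGCAATCTGTTCGTAATTTGCCAATCGAAGCATTCGAA  58      GACT
```

The precursor is 89 nt (guide at 17–37, star at 52–72); both oligos are 58
bases with the 4-base 5' overhangs (`GGCT`/`GACT`) that match the
BsaI-linearized vector, and the command fails if in-silico ligation does
not reconstruct the precursor bit-exactly.

Simulate a sequencing library with 95% accurate processing and recover the
statistic:

```
$ amirnakit design precursor --guide UUCGAAUGCUUCGAUUGGCAA --backbone shc --name amiR-demo --out prec.fa
$ amirnakit simulate precursor --guide UUCGAAUGCUUCGAUUGGCAA --backbone shc \
      --seed 4 --depth 100000 --exact-fraction 0.95 --out reads.fa
$ amirnakit accuracy --reads reads.fa --ref prec.fa --guide UUCGAAUGCUUCGAUUGGCAA
{
  "reference": "shc-amiR-demo",
  "guide_start": 17,
  "window_reads": 89912,
  "exact_guide_reads": 85483,
  "accuracy": 0.9507407242637246,
  ...
}
```

Of 100 000 simulated reads, 89 912 are 19–24-nt (+) reads in the ±4-nt
window around the guide 5' end (the rest are star-arm reads, outside the
window) and 85 483 are the authentic 21-nt amiRNA, recovering the
configured 0.95 within sampling error.

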
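# Synthetic backbone segment bundle.
#
# These segment sequences are SYNTHETIC stand-ins generated to satisfy the
# declared MIR390-architecture constraints (segment lengths, fully
# Watson-Crick stems, no BsaI sites); they are not the natural AtMIR390a /
# OsMIR390 genomic sequences.  The native mature miR390a guide is real.
native_guide: AAGCUCAGGAGGGAUAGCGCC
segments:
  at_flank5: AGUAAGGACUUGCCGAACAUUCCACACCCCAGCAGGCAAAUAUUAGGAGGGACGGACGCGGUAGUUGCGAUGUACACAAAUACACCUAAGCCGACGCAGCCUCUAGUCGCUAUCUGAGCGCGCCUGAAGCGCAUCCUGUACGUGAAGUAAGGCCAAGUAGUAAUAGGAUCAGCUCAGGACGUCGACAUAGCACGCAAUAGUGGUGGU
  at_bs5: CUAUAACCUCCUGGCU
  at_bs3: UCACCAGGAGGUUAUAG
  at_flank3: AUCAAAAUCGCACGCGACAUCCGUUGACCCUUGGUAUUACACAUUAGCAAGCUCCGCAUUGUCAGAUUAACCCCCGCUUCCGCGUCUCUUUGGGCCAUUUCCCUGGUUAUGUGUCCGCGAACAGCCUACUGAAAAACAGGGAAAUGGGGAGGCAAUGCGAGAGAACUAUAAAGGCGCAGACAUUGGACCAUUUAUAAUGAGAUCCUAU
  at_dsl5: GGCGGGGGGUCAC
  at_loop: CAUG
  at_dsl3: GUGACCCCCCGCGG
  os_dsl5: UAUU
  os_loop: ACGAACAG
  os_dsl3: AAGG
vectors:
  "AtMIR390a-B/c":
    backbone: pri
    oligo_length: 75
  "BS-AtMIR390a-B/c":
    backbone: shc
    oligo_length: 58
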
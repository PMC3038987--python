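# Synthetic reconstruction of the Arabidopsis thaliana plastome psbB operon
# cluster: plus-strand psbB, psbT, psbH, petB, petD against the long
# minus-strand ribosomal-protein operon rpoA..trnI, with psbN (minus) nested
# between psbT and psbH. Two 44-nt cross-hairpin terminators sit between
# psbT and psbN (T1) and between petD and rpoA (T2), each terminating a
# crossing polymerase with probability 0.25. Promoters: psbB-170 (P1),
# psbN-32 (P2) and rps11-12 (P3) are bacterial-type; trnI-20 (N) is
# phage-type. Intensity vectors per condition: wild type, sig3 knockout and
# sig4 knockout (phage-type N unaffected by sigma knockouts). Gene lengths
# and gaps are typical plastome values, NOT accession-exact coordinates:
# this file is a synthetic stand-in regenerated without access to the
# source annotation.
format: 1
name: locus3
length: 11000
genes:
  - {id: psbB, strand: "+", start: 300, end: 1830}
  - {id: psbT, strand: "+", start: 1900, end: 2002}
  - {id: psbN, strand: "-", start: 2150, end: 2282}
  - {id: psbH, strand: "+", start: 2600, end: 2822}
  - {id: petB, strand: "+", start: 2900, end: 3550}
  - {id: petD, strand: "+", start: 3650, end: 4130}
  - {id: rpoA, strand: "-", start: 4350, end: 5364}
  - {id: rps11, strand: "-", start: 5450, end: 5867}
  - {id: rpl36, strand: "-", start: 5950, end: 6064}
  - {id: rps8, strand: "-", start: 6150, end: 6555}
  - {id: rpl14, strand: "-", start: 6650, end: 7019}
  - {id: rpl16, strand: "-", start: 7100, end: 7600}
  - {id: rps3, strand: "-", start: 7700, end: 8357}
  - {id: rpl22, strand: "-", start: 8450, end: 8899}
  - {id: rps19, strand: "-", start: 9000, end: 9279}
  - {id: rpl2, strand: "-", start: 9350, end: 10250}
  - {id: rpl23, strand: "-", start: 10300, end: 10582}
  - {id: trnI, strand: "-", start: 10650, end: 10724}
promoters:
  - id: P1            # psbB-170
    strand: "+"
    tss: 130
    class: PEP
    intensity: {wt: 1.355, sig3ko: 0.555, sig4ko: 0.867}
  - id: P2            # psbN-32
    strand: "-"
    tss: 2313
    class: PEP
    intensity: {wt: 0.284, sig3ko: 0.075, sig4ko: 0.227}
  - id: P3            # rps11-12
    strand: "-"
    tss: 5878
    class: PEP
    intensity: {wt: 0.182, sig3ko: 0.116, sig4ko: 0.146}
  - id: N             # trnI-20, phage-type
    strand: "-"
    tss: 10743
    class: NEP
    intensity: {wt: 0.116, sig3ko: 0.116, sig4ko: 0.116}
terminators:
  - id: T1            # 44-nt palindrome between psbT and psbN
    arms: [[2050, 2070], [2074, 2094]]
    p: 0.25
  - id: T2            # 44-nt imperfect palindrome between petD and rpoA
    arms: [[4200, 4220], [4224, 4244]]
    p: 0.25
factor_sites: []
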
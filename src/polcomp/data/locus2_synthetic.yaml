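# Synthetic reconstruction of the Hordeum vulgare (barley) plastome region
# rps12..psbA studied in heat-shock experiments: plus-strand genes rps12,
# rps7, ndhB, trnL, trnI, rpl23, rpl2 and rps19; minus-strand trnH and psbA
# convergent against them. Promoters are all bacterial-type: rps12-261 (P0),
# trnI-56 (P1), trnH-36 (P2) and psbA-79 (P3); P3 stands at the locus
# boundary and carries the summed intensity of psbA's own promoter plus
# upstream minus-strand input (the locus is modeled as a closed system).
# rpl23 and rpl2 are pooled into one counting group because their
# transcription level is measured cumulatively. Gene lengths and gaps are
# typical plastome values, NOT accession-exact coordinates: this file is a
# synthetic stand-in regenerated without access to the source annotation.
format: 1
name: locus2
length: 9000
genes:
  - {id: rps12, strand: "+", start: 500, end: 900}
  - {id: rps7, strand: "+", start: 1000, end: 1470}
  - {id: ndhB, strand: "+", start: 1600, end: 3100}
  - {id: trnL, strand: "+", start: 3200, end: 3285}
  - {id: trnI, strand: "+", start: 3600, end: 3674}
  - {id: rpl23, strand: "+", start: 3750, end: 4032, group: rpl23-rpl2}
  - {id: rpl2, strand: "+", start: 4100, end: 5000, group: rpl23-rpl2}
  - {id: trnH, strand: "-", start: 5200, end: 5274}
  - {id: rps19, strand: "+", start: 5450, end: 5730}
  - {id: psbA, strand: "-", start: 6200, end: 7262}
promoters:
  - id: P0            # rps12-261
    strand: "+"
    tss: 239
    class: PEP
    intensity: {wt: 0.2}
  - id: P1            # trnI-56
    strand: "+"
    tss: 3544
    class: PEP
    intensity: {wt: 0.9}
  - id: P2            # trnH-36
    strand: "-"
    tss: 5309
    class: PEP
    intensity: {wt: 0.3}
  - id: P3            # psbA-79, boundary promoter with summed upstream input
    strand: "-"
    tss: 7340
    class: PEP
    intensity: {wt: 0.1}
terminators: []
factor_sites: []
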
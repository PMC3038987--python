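# Synthetic reconstruction of the Arabidopsis thaliana plastome neighborhood
# around the short ycf1 copy at the inverted-repeat / small-single-copy border:
# ycf1 (plus strand), ndhF (minus strand, convergent) and rpl32 downstream.
# Promoter offsets relative to start codons follow the described layout
# (ycf1-104 and ycf1-39 phage-type promoters, ycf1-33 and ndhF-320
# bacterial-type promoters). Absolute gene lengths and intergenic gaps are
# typical plastome values, NOT accession-exact coordinates: this file is a
# synthetic stand-in regenerated without access to the source annotation.
# Conditions: wt (all sigma subunits), sig4ko (Sig4 removed: lower intensity
# at the two bacterial-type promoters), rpotpko (RpoTp phage polymerase
# knockout: ycf1-39 silent, ycf1-33 relieved).
format: 1
name: locus1
length: 6000
genes:
  - {id: ycf1, strand: "+", start: 600, end: 1700}
  - {id: ndhF, strand: "-", start: 2100, end: 4300}
  - {id: rpl32, strand: "+", start: 4900, end: 5100}
promoters:
  - id: N1            # ycf1-104, phage-type
    strand: "+"
    tss: 496
    class: NEP
    intensity: {wt: 0.003, sig4ko: 0.003, rpotpko: 0.003}
  - id: N2            # ycf1-39, phage-type (RpoTp-dependent)
    strand: "+"
    tss: 561
    class: NEP
    intensity: {wt: 0.054, sig4ko: 0.054, rpotpko: 0.0}
  - id: P1            # ycf1-33, bacterial-type
    strand: "+"
    tss: 567
    class: PEP
    intensity: {wt: 0.037, sig4ko: 0.010, rpotpko: 0.12}
  - id: P2            # ndhF-320, bacterial-type
    strand: "-"
    tss: 4619
    class: PEP
    intensity: {wt: 0.093, sig4ko: 0.050, rpotpko: 0.093}
terminators: []
factor_sites: []
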
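"""Sig4 knockout on the Arabidopsis ycf1/ndhF/rpl32 locus (scaled down).

Removing the Sig4 sigma-subunit lowers the binding intensity of the two
bacterial-type promoters (ycf1-33: 0.037 -> 0.010, ndhF-320: 0.093 -> 0.050)
while the phage-type promoters are untouched. The knockout-to-wild-type
transcription ratio per gene emerges from the changed polymerase traffic:
ycf1 and ndhF drop with their promoters, while rpl32 RISES because the
weakened antisense traffic from ndhF-320 kills fewer of the sense-strand
polymerases that must read through to reach it.
"""

from polcomp import compare_conditions, toy_locus

locus = toy_locus("locus1_fixture")
est = compare_conditions(
    locus, "sig4ko", "wt",
    duration=3 * 3600.0, n=10, seed=17,
    temperature=23.0, warmup=1800.0, n_boot=200,
)
print(est.table.round(3))
print(
    "\nratio = ensemble-mean transcripts (knockout) / (wild type), bootstrap"
    "\nspread over trajectory pairs. Compare the directions: ycf1 and ndhF"
    "\nbelow 1, rpl32 above 1 — the read-through relief effect."
)
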
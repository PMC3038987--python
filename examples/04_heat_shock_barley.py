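"""Heat shock of isolated barley chloroplasts (scaled down).

Plants grown at 21 C are shocked at 40 C for 1.5 h and returned to 25 C for
15 min; controls stay at 21 C. Binding intensities do not change — only the
elongation rate responds to temperature (9.2 nt/s at 21 C, 36.8 nt/s at
40 C) — yet the rpl23-rpl2 pair gains transcripts while psbA loses them:
faster elongation clears the strong trnI-56 promoter sooner (more sense
traffic) and that extra traffic collides away the antisense polymerases
that would have completed psbA.
"""

from polcomp import heat_shock_protocol, toy_locus

locus = toy_locus("locus2_fixture")
est = heat_shock_protocol(locus, "wt", n=10, seed=17, t1=1.25 * 3600.0, n_boot=200)
print(est.table.round(3))
print(
    "\nratio = transcripts completed during shock+aftershock, shocked over"
    "\ncontrol. rpl23-rpl2 (measured cumulatively, hence one pooled row)"
    "\nrises well above 1; psbA falls below 1."
)
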
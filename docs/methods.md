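# Methods

## Model

A locus is a closed region of double-stranded DNA: every polymerase inside
it initiated at one of its promoters, and a polymerase leaving either end is
a completed run-off. Promoter binding attempts form independent Poisson
processes, one per promoter, with condition-dependent intensities λ (s⁻¹);
the justification is the classical superposition limit — the pooled arrivals
of many independent stationary sources are asymptotically Poisson — and the
package tests it directly (merging two attempt streams is statistically
indistinguishable from one stream at the summed rate). An attempt succeeds
only if the promoter's holoenzyme window is free of polymerase footprints
and bound factors, so λ is a *conditional* intensity: the rate of attempts,
not of initiations.

A successful PEP binding first runs an abortive-initiation phase: duration
t ~ Exp(t₀); the number of aborted attempts is the largest k with
−(ln ξ₁+…+ln ξₖ) ≤ t·ν/r₀, each attempt releasing an RNA of the integer
length nearest to −r₀·ln ξᵢ (half away from zero, floored at 1 nt). Given t
the count is a unit-rate Poisson count on [0, t·ν/r₀]; mixing over the
exponential t makes k geometric on {0, 1, …} with mean t₀·ν/r₀ — the
closed form used as the independent oracle in the test suite. NEP initiates
productively at once. Elongation is deterministic at ν(T), linearly
interpolated between tabulated temperatures (PEP: 9.2/12.1/15.0/36.8 nt/s at
21/23/25/40 °C; NEP: 45 nt/s, temperature-independent because only one
tabulated value exists); sequence- or RNA-structure-dependent rate variation
is deliberately out of scope. Temperature schedules are piecewise constant;
at a phase boundary every moving polymerase finishes its remaining path at
the new rate.

Exclusion and termination rules: same-strand polymerases neither overlap nor
overtake — a faster trailing enzyme advances until its footprints contact
the leader's and is then dragged at the leader's speed; head-on collision is
triggered by 3′-end coincidence of antiparallel polymerases and removes both
instantly; the first entry of a polymerase into the proximal shoulder of a
cross-hairpin terminator draws one Bernoulli trial with the terminator's p,
in either crossing direction; a moving polymerase displaces a bound protein
factor on contact without delay, while a bound factor blocks any promoter
window it overlaps. A transcript is counted for a gene when a same-strand
polymerase that initiated at or upstream of the gene's 5′ end moves its 3′
end past the gene's 3′ end; genes flagged with a common group id are pooled
into one reporting unit (used where an assay measures two genes cumulatively).

## Event-driven implementation

The engine processes one chronological priority queue (time, then an insert
sequence number; coincident times have probability zero under the continuous
clocks). Elongation is not stepped nucleotide by nucleotide: because motion
is piecewise linear, the time of a polymerase's next interaction — static
checkpoint (gene 3′ end, terminator shoulder, factor site, locus end),
contact with its leader, or collision with the nearest approaching
antiparallel polymerase — is computed in closed form, and only those events
enter the queue. Stale events are invalidated by per-polymerase version
counters; contact and collision events are re-validated geometrically
against the current neighbor when popped. This is the continuum limit of
the per-nucleotide walk with identical rules and runs orders of magnitude
faster; positions are continuous, and the minimal same-strand separation is
footprint contact (lead + trail between 3′ ends), the convention consistent
with the closed-interval occupancy test used for binding.

Two reproducibility guarantees are engineered in. First, every stochastic
element owns a named substream (promoter attempt clock, per-promoter abort
draws, per-terminator Bernoulli trials, factor clocks, the bootstrap) split
from one master seed by hashing the label, so a trajectory is bit-for-bit
reproducible and single elements can be replayed; trajectory *i* of an
ensemble uses seed entropy (master, i), which also gives common random
numbers across compared conditions and grid-search candidates. Second, all
static geometry enters event arithmetic as exact integer differences in
strand-local coordinates, and checkpoint times are anchored at the last
speed change rather than accumulated checkpoint to checkpoint; consequences:
a mirrored locus replays the exactly mirrored trajectory, and a terminator
with p = 0 is a bit-exact no-op.

## Ensembles, comparisons, heat shock

Transcription levels are per-hour completed-transcript rates averaged over
independently seeded trajectories, counted after a warm-up the traffic needs
to reach its stationary pattern (about 3 h of modeled time at full scale;
scaled runs use shorter warm-ups stated below). Between-condition changes
are ratios of ensemble means — per-trajectory count ratios are heavy-tailed
(Cauchy-like, without a finite mean) and are never averaged — with spread
from a seeded nonparametric bootstrap over trajectory pairs (default 1000
resamples). A zero denominator flags the ratio undefined rather than
raising. The heat-shock protocol grows the system at T₁, exposes it to T₂
for t₂ = 1.5 h, returns it to T₃ = 25 °C for t₃ = 0.25 h (control: T₁
throughout the shock phase), and reports shocked/control ratios of
transcripts completed during the shock-plus-aftershock window; counting only
the 15-min aftershock is supported (`count_window="aftershock"`) but yields
very few transcripts at desk scale, so the wider window is the default.

## Inverse mode

Unknown promoter intensities (and optionally terminator probabilities) are
estimated by exhaustive grid search (default step 0.01 s⁻¹ on [0, 1.113];
the ceiling is the rrn-operon calibration: 18 700 rRNA copies per 40-min
generation across 7 operons ≈ one initiation per 0.9 s). The grid is pruned
first by optional order constraints (a σ-subunit knockout cannot raise an
intensity: λ_ko ≤ λ_wt) and then by the strand-balance condition: for every
region bounded by a convergent promoter pair with no promoter in between,
the summed intensities entering on the two strands must differ by at most D
(default 0.8, chosen in [0.1, 0.8]) — otherwise one strand simply silences
the other and the measured genes could not all be expressed. Membership is
the minimal reading: all same-strand promoters upstream of the region on
each side; alternative rules for more promoters per strand would be
reasonable and the region enumeration is exposed (`competing_regions`) for
inspection. Candidates are scored per experiment by the worst-case symmetric
relative discrepancy (the averaged denominator makes a 3-vs-2 mismatch score
exactly like 1/3-vs-1/2), ranked per experiment with minimum-rank ties, and
ordered by weighted total rank, then weighted discrepancy sum, then
lexicographic parameters; weights are user-supplied (default 1). Structural
hypotheses (e.g. presence of candidate terminators) are compared by
re-fitting under each element set and comparing best discrepancies.

## Synthetic data and packaged loci

`make_toy_locus` generates validated toy configurations (single gene,
convergent pair, divergent pair, tandem gene pair behind a terminator), with
optional ±20 % seeded jitter of lengths and gaps for property tests. Three
reference loci ship as data files modeled on real plastome neighborhoods:
the *Arabidopsis* ycf1/ndhF/rpl32 region with two phage-type and two
bacterial-type promoters, the barley rps12…psbA region studied under heat
shock (rpl23+rpl2 pooled; the boundary psbA-79 promoter carries the summed
upstream antisense input, keeping the locus closed), and the *Arabidopsis*
psbB cluster with the long antisense ribosomal-protein operon, two 44-nt
cross-hairpin terminators (p = 0.25 each) and per-condition intensity
vectors for wild type and the Sig3/Sig4 knockouts. **The coordinates are
synthetic reconstructions**: gene order, strands, promoter offsets relative
to start codons, intensities and terminator probabilities follow the
published descriptions of these loci, but gene lengths and intergenic gaps
are typical plastome values, not accession-exact coordinates (the files are
named `*_synthetic.yaml`). Passing tests on them therefore demonstrate the
*mechanisms* — direction and rough size of knockout and heat-shock
responses, read-through relief, dominance flips — not a quantitative
reproduction of any specific genome; with accession-exact annotation
imported via `import_annotation`, the same machinery applies unchanged.
Balanced convergent regions (e.g. around ndhF) show winner-take-all
trajectories whose ensemble means converge slowly; direction estimates there
use larger ensembles.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: kernel laws at
10⁵–10⁶ draws; engine analytics at 200 trajectories × 2000 s; reference-locus
comparisons at 3–6 h of modeled time with 10–60 trajectories per condition
(60 for the ycf1 locus, whose ndhF estimate is fluctuation-dominated);
parameter recovery at 20 replicates of a 7-point grid with 20 trajectories
per evaluation. Statistical assertions use 3-standard-error bands or
chi-square/KS p-values at 10⁻³. Geometric tolerances: collision and contact
events re-validate within 10⁻⁷ nt; interarrival sampling redraws a uniform
of exactly 0 (probability 2⁻⁵³). Degenerate inputs: λ = 0 promoters and
factor sites never fire; a temperature outside a class's tabulated range is
an error rather than an extrapolation; an empty promoter set refuses to
simulate; an ensemble of one trajectory is rejected (no spread).

## Known limitations

Elongation ignores sequence, RNA secondary structure and ribosome coupling;
collided polymerases detach instantly and never rebind; the abortive phase
occupies the full holoenzyme window and its duration is insensitive to a
temperature change mid-phase; loci are closed systems, so transcription
entering from outside must be emulated by a boundary promoter; and the
packaged reference loci are synthetic-coordinate stand-ins as described
above. Inference is exhaustive-search only — no gradients, no posterior —
which is honest about the noisy, non-smooth objective but limits the number
of simultaneous unknowns in practice.
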
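"""Back-of-envelope calibration of the promoter binding-intensity scale.

The strongest known bacterial promoters (the rRNA operons of *E. coli*) set
a physical ceiling for how often a polymerase can productively engage a
promoter. From the standing rRNA copy number per cell, the generation time
and the number of rrn operon copies one obtains the mean interval between
productive initiations at a single optimal promoter, and hence an upper
bound for the Poisson binding intensity used throughout this package.
"""

from __future__ import annotations

__all__ = ["mean_initiation_interval", "intensity_upper_bound"]

#: rRNA copies per cell under good growth (37 C, 40 min generation time).
ECOLI_RRNA_COPIES = 18700
#: Generation time in seconds for the conditions above.
ECOLI_GENERATION_TIME_S = 40 * 60.0
#: rrn operon copies in the E. coli chromosome.
ECOLI_RRN_OPERONS = 7


def mean_initiation_interval(
    transcripts_per_generation: float = ECOLI_RRNA_COPIES,
    generation_time_s: float = ECOLI_GENERATION_TIME_S,
    gene_copies: int = ECOLI_RRN_OPERONS,
) -> float:
    """Mean seconds between productive initiations at one gene copy.

    With the defaults this evaluates to about 0.9 s: each of the 7 rrn
    operons must fire ~2671 times per 2400 s generation to sustain 18700
    rRNA copies.
    """
    if transcripts_per_generation <= 0 or generation_time_s <= 0 or gene_copies <= 0:
        raise ValueError("all calibration inputs must be positive")
    return generation_time_s * gene_copies / transcripts_per_generation


def intensity_upper_bound(
    transcripts_per_generation: float = ECOLI_RRNA_COPIES,
    generation_time_s: float = ECOLI_GENERATION_TIME_S,
    gene_copies: int = ECOLI_RRN_OPERONS,
) -> float:
    """Upper bound for a promoter binding intensity, 1/s (~1.113 s^-1).

    The reciprocal of :func:`mean_initiation_interval`: no promoter can be
    bound more often than the best promoter known.
    """
    return 1.0 / mean_initiation_interval(
        transcripts_per_generation, generation_time_s, gene_copies
    )
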
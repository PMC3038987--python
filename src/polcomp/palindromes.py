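"""Imperfect-palindrome scanning for candidate cross-hairpin terminators.

A DNA palindrome whose two arms reverse-complement each other can extrude a
cruciform ("cross-hairpin") that a moving polymerase may read as a terminator.
The scanner reports every fixed-length window whose arms pair with at most a
configured number of non-complementary positions; plastid terminator
candidates observed so far are 44 nt with arms of 20-22 nt around a short
loop, which are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = ["PalindromeHit", "scan_palindromes", "DEFAULT_TOTAL_LENGTH"]

DEFAULT_TOTAL_LENGTH = 44
DEFAULT_LOOP_RANGE = (0, 4)
DEFAULT_MAX_MISMATCHES = 3

# IUPAC ambiguity codes expand to base sets for complementarity; N is treated
# as never complementary (an unknown base cannot be credited with pairing).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PalindromeHit:
    """One candidate hairpin: ``[start, end)`` window, arm/loop split, mismatches."""

    start: int
    end: int
    arm_length: int
    loop_length: int
    mismatches: int

    def __post_init__(self):
        if self.end - self.start != 2 * self.arm_length + self.loop_length:
            raise ValueError("window length inconsistent with arm/loop split")

    @property
    def arms(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Half-open arm intervals, ready to use as terminator shoulders."""
        return (
            (self.start, self.start + self.arm_length),
            (self.end - self.arm_length, self.end),
        )


def _complementary(a: str, b: str) -> bool:
    if a == "N" or b == "N":
        return False
    return any(_COMPLEMENT[x] in _IUPAC[b] for x in _IUPAC[a])


def scan_palindromes(
    sequence: str,
    total_length: int = DEFAULT_TOTAL_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    loop_range: Sequence[int] | Iterable[int] = DEFAULT_LOOP_RANGE,
) -> list[PalindromeHit]:
    """Report every window whose arms reverse-complement with few mismatches.

    ``loop_range`` is an inclusive ``(min, max)`` pair of loop lengths; only
    loops with the same parity as ``total_length`` are geometrically possible
    and others are skipped. Hits are sorted by position, then mismatch count.
    Non-DNA characters other than N and IUPAC ambiguity codes raise
    ``ValueError``.
    """
    if total_length < 2:
        raise ValueError("total_length must be >= 2")
    seq = sequence.upper()
    bad = set(seq) - set(_IUPAC) - {"N"}
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")

    lo, hi = min(loop_range), max(loop_range)
    arm_options = [
        ((total_length - loop) // 2, loop)
        for loop in range(lo, hi + 1)
        if (total_length - loop) % 2 == 0 and (total_length - loop) // 2 >= 1
    ]
    if not arm_options:
        raise ValueError(
            f"no arm/loop split of total length {total_length} fits loops {loop_range}"
        )

    hits: list[PalindromeHit] = []
    for start in range(0, len(seq) - total_length + 1):
        window = seq[start : start + total_length]
        for arm, loop in arm_options:
            left = window[:arm]
            right = window[total_length - arm :]
            mism = sum(
                0 if _complementary(left[i], right[arm - 1 - i]) else 1
                for i in range(arm)
            )
            if mism <= max_mismatches:
                hits.append(
                    PalindromeHit(
                        start=start,
                        end=start + total_length,
                        arm_length=arm,
                        loop_length=loop,
                        mismatches=mism,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.mismatches, h.loop_length))
    return hits


def reverse_complement(sequence: str) -> str:
    """Reverse complement preserving IUPAC codes (via Biopython)."""
    return str(Seq(sequence).reverse_complement())
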
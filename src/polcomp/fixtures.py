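"""Toy and reference locus builders.

``make_toy_locus`` produces small, fully synthetic locus documents for tests
and examples, plus the three packaged reference loci modeled on real plastome
neighborhoods (Arabidopsis ycf1/ndhF/rpl32, the barley rpl23-rpl2/psbA
region, and the Arabidopsis psbB operon cluster). The reference documents
ship as data files with synthetic coordinates: gene order, strands, promoter
offsets, intensity vectors and terminator probabilities follow the published
descriptions of those loci, while absolute gene lengths and intergenic gaps
are typical plastome values rather than accession-exact coordinates (the
files are named ``*_synthetic.yaml`` accordingly).
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .locus import Locus, load_locus

__all__ = ["make_toy_locus", "toy_locus", "TOY_KINDS"]

TOY_KINDS = (
    "single_gene",
    "convergent_pair",
    "divergent_pair",
    "tandem_with_terminator",
    "locus1_fixture",
    "locus2_fixture",
    "locus3_fixture",
)

_FIXTURE_FILES = {
    "locus1_fixture": "locus1_synthetic.yaml",
    "locus2_fixture": "locus2_synthetic.yaml",
    "locus3_fixture": "locus3_synthetic.yaml",
}


def _jitter(rng: Optional[np.random.Generator], value: int, frac: float = 0.2) -> int:
    if rng is None:
        return value
    lo = max(1, int(value * (1 - frac)))
    hi = int(value * (1 + frac)) + 1
    return int(rng.integers(lo, hi))


def make_toy_locus(kind: str, seed: Optional[int] = None, **params) -> dict:
    """Emit a valid locus config document of the requested shape.

    Toy kinds accept ``lam`` (binding intensity, 1/s), ``gene_length`` and
    ``separation`` overrides; a ``seed`` randomizes lengths and gaps by
    +-20% for property tests. The three ``locus*_fixture`` kinds load the
    packaged synthetic reference documents (seed and params ignored).
    """
    if kind not in TOY_KINDS:
        raise ValueError(f"unknown toy locus kind {kind!r}; choose from {TOY_KINDS}")
    if kind in _FIXTURE_FILES:
        text = (
            resources.files("polcomp.data")
            .joinpath(_FIXTURE_FILES[kind])
            .read_text()
        )
        return yaml.safe_load(text)

    rng = np.random.default_rng(seed) if seed is not None else None
    lam = float(params.get("lam", 0.1))
    glen = _jitter(rng, int(params.get("gene_length", 1000)))
    pclass = params.get("pclass", "PEP")

    if kind == "single_gene":
        gap = _jitter(rng, 50)
        tss = 100
        start = tss + gap
        return {
            "format": 1,
            "name": "toy_single_gene",
            "length": start + glen + 200,
            "genes": [{"id": "gA", "strand": "+", "start": start, "end": start + glen}],
            "promoters": [
                {"id": "pA", "strand": "+", "tss": tss, "class": pclass, "intensity": {"wt": lam}}
            ],
        }

    if kind == "convergent_pair":
        sep = _jitter(rng, int(params.get("separation", 1000)))
        lam_b = float(params.get("lam_b", lam))
        a_start = 200
        a_end = a_start + glen
        b_start = a_end + sep
        b_end = b_start + glen
        return {
            "format": 1,
            "name": "toy_convergent_pair",
            "length": b_end + 200,
            "genes": [
                {"id": "gA", "strand": "+", "start": a_start, "end": a_end},
                {"id": "gB", "strand": "-", "start": b_start, "end": b_end},
            ],
            "promoters": [
                {"id": "pA", "strand": "+", "tss": a_start - 50, "class": pclass,
                 "intensity": {"wt": lam}},
                {"id": "pB", "strand": "-", "tss": b_end + 49, "class": pclass,
                 "intensity": {"wt": lam_b}},
            ],
        }

    if kind == "divergent_pair":
        gap = _jitter(rng, int(params.get("separation", 150)))
        a_end = 1000
        a_start = a_end - glen
        if a_start < 100:
            a_start, a_end = 100, 100 + glen
        pa_tss = a_end + 40
        pb_tss = pa_tss + gap
        b_start = pb_tss + 50
        b_end = b_start + glen
        return {
            "format": 1,
            "name": "toy_divergent_pair",
            "length": b_end + 200,
            "genes": [
                {"id": "gA", "strand": "-", "start": a_start, "end": a_end},
                {"id": "gB", "strand": "+", "start": b_start, "end": b_end},
            ],
            "promoters": [
                {"id": "pA", "strand": "-", "tss": pa_tss, "class": pclass,
                 "intensity": {"wt": lam}},
                {"id": "pB", "strand": "+", "tss": pb_tss, "class": pclass,
                 "intensity": {"wt": lam}},
            ],
        }

    if kind == "tandem_with_terminator":
        p_term = float(params.get("p_terminate", 0.5))
        g1_start = 150
        g1_end = g1_start + glen
        arm = 20
        t_start = g1_end + 50
        arms = [[t_start, t_start + arm], [t_start + arm + 4, t_start + 2 * arm + 4]]
        g2_start = arms[1][1] + 60
        g2_end = g2_start + glen
        return {
            "format": 1,
            "name": "toy_tandem_with_terminator",
            "length": g2_end + 200,
            "genes": [
                {"id": "g1", "strand": "+", "start": g1_start, "end": g1_end},
                {"id": "g2", "strand": "+", "start": g2_start, "end": g2_end},
            ],
            "promoters": [
                {"id": "p1", "strand": "+", "tss": 100, "class": pclass,
                 "intensity": {"wt": lam}}
            ],
            "terminators": [{"id": "t1", "arms": arms, "p": p_term}],
        }

    raise AssertionError("unreachable")


def toy_locus(kind: str, seed: Optional[int] = None, **params) -> Locus:
    """Validated :class:`Locus` for a toy kind (convenience wrapper)."""
    return load_locus(make_toy_locus(kind, seed=seed, **params))
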
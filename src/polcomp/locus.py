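"""Locus geometry: genes, promoters, terminators and factor sites on two strands.

Coordinates are 0-based. Gene intervals are half-open ``[start, end)``; a
promoter's ``tss`` is the first transcribed nucleotide. Polymerase footprints
are closed integer intervals stated in promoter-local orientation
``(upstream, downstream)`` with ``upstream <= 0 <= downstream`` and are
reflected for minus-strand elements, so the same footprint numbers serve both
strands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "Strand",
    "PolymeraseClass",
    "Promoter",
    "Gene",
    "Terminator",
    "FactorSite",
    "Locus",
    "LocusValidationError",
    "PEP",
    "NEP",
    "load_locus",
    "locus_to_document",
    "serialize_locus",
    "import_annotation",
    "mirror_locus",
]


class LocusValidationError(ValueError):
    """A locus document or object violates a structural invariant."""


class Strand(enum.Enum):
    """DNA strand; minus-strand transcription proceeds toward decreasing coordinates."""

    PLUS = "+"
    MINUS = "-"

    @property
    def direction(self) -> int:
        return 1 if self is Strand.PLUS else -1

    @classmethod
    def parse(cls, value) -> "Strand":
        if isinstance(value, Strand):
            return value
        if value in ("+", "plus", 1):
            return cls.PLUS
        if value in ("-", "minus", -1):
            return cls.MINUS
        raise LocusValidationError(f"unknown strand {value!r}")


@dataclass(frozen=True)
class PolymeraseClass:
    """A polymerase species: footprints, temperature-dependent rate, abort behaviour.

    ``holo_footprint`` is the DNA interval shielded while the enzyme sits on the
    promoter (for the bacterial-type enzyme this includes the sigma-subunit
    contacts); ``core_footprint`` is the interval around the active site while
    elongating. ``rate_table`` maps temperature in Celsius to elongation rate in
    nt/s; lookups interpolate linearly between tabulated temperatures, a
    single-entry table is temperature-independent, and extrapolation is an
    error. ``abort_params = (t0, r0)`` gives the mean abortive-initiation phase
    duration (s) and mean abortive RNA length (nt); ``None`` means the class
    initiates productively at once (phage-type enzymes).
    """

    name: str
    holo_footprint: tuple[int, int]
    core_footprint: tuple[int, int]
    rate_table: Mapping[float, float]
    abort_params: Optional[tuple[float, float]] = None

    def __post_init__(self):
        for fp in (self.holo_footprint, self.core_footprint):
            if not (fp[0] <= 0 <= fp[1]):
                raise LocusValidationError(
                    f"{self.name}: footprint {fp} must straddle position 0"
                )
        if not self.rate_table:
            raise LocusValidationError(f"{self.name}: empty rate table")
        for temp, rate in self.rate_table.items():
            if rate <= 0:
                raise LocusValidationError(
                    f"{self.name}: rate {rate} at {temp} C must be positive"
                )
        if self.abort_params is not None:
            t0, r0 = self.abort_params
            if t0 <= 0 or r0 <= 0:
                raise LocusValidationError(
                    f"{self.name}: abort parameters must be positive, got {self.abort_params}"
                )
        object.__setattr__(self, "rate_table", dict(self.rate_table))

    def rate_at(self, temperature: float) -> float:
        """Elongation rate (nt/s) at ``temperature`` by linear interpolation."""
        table = self.rate_table
        temps = sorted(table)
        if len(temps) == 1:
            return table[temps[0]]
        if temperature in table:
            return table[temperature]
        if temperature < temps[0] or temperature > temps[-1]:
            raise ValueError(
                f"{self.name}: temperature {temperature} C outside tabulated range "
                f"[{temps[0]}, {temps[-1]}]; extrapolation is not supported"
            )
        import bisect

        i = bisect.bisect_left(temps, temperature)
        t0, t1 = temps[i - 1], temps[i]
        r0, r1 = table[t0], table[t1]
        return r0 + (r1 - r0) * (temperature - t0) / (t1 - t0)


#: Plastid-encoded bacterial-type polymerase (requires a sigma-subunit).
PEP = PolymeraseClass(
    name="PEP",
    holo_footprint=(-44, 20),
    core_footprint=(-15, 20),
    rate_table={21.0: 9.2, 23.0: 12.1, 25.0: 15.0, 40.0: 36.8},
    abort_params=(0.4, 4.0),
)

#: Nuclear-encoded phage-type single-subunit polymerase.
NEP = PolymeraseClass(
    name="NEP",
    holo_footprint=(-15, 4),
    core_footprint=(-15, 4),
    rate_table={23.0: 45.0},
    abort_params=None,
)

_BUILTIN_CLASSES = {"PEP": PEP, "NEP": NEP}


@dataclass(frozen=True)
class Promoter:
    """A promoter: strand, transcription start site and per-condition binding intensity.

    ``intensity_by_condition`` maps a condition label (e.g. ``wt``, ``sig4ko``)
    to the Poisson intensity lambda (1/s) of polymerase binding attempts.
    """

    id: str
    strand: Strand
    tss: int
    pclass: PolymeraseClass
    intensity_by_condition: Mapping[str, float]

    def __post_init__(self):
        for cond, lam in self.intensity_by_condition.items():
            if lam < 0:
                raise LocusValidationError(
                    f"promoter {self.id}: intensity for condition {cond!r} is negative"
                )
        object.__setattr__(
            self, "intensity_by_condition", dict(self.intensity_by_condition)
        )

    def intensity(self, condition: str) -> float:
        try:
            return self.intensity_by_condition[condition]
        except KeyError:
            raise KeyError(
                f"promoter {self.id} has no intensity for condition {condition!r}; "
                f"known conditions: {sorted(self.intensity_by_condition)}"
            ) from None

    def occupancy_window(self) -> tuple[int, int]:
        """Closed absolute interval shielded by the bound holoenzyme."""
        u, d = self.pclass.holo_footprint
        if self.strand is Strand.PLUS:
            return (self.tss + u, self.tss + d)
        return (self.tss - d, self.tss - u)


@dataclass(frozen=True)
class Gene:
    """A gene interval ``[start, end)``; ``group`` pools genes counted cumulatively."""

    id: str
    strand: Strand
    start: int
    end: int
    group: Optional[str] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise LocusValidationError(
                f"gene {self.id}: start {self.start} must be < end {self.end}"
            )

    @property
    def five_prime(self) -> int:
        """First transcribed coordinate of the gene."""
        return self.start if self.strand is Strand.PLUS else self.end - 1

    @property
    def three_prime(self) -> int:
        """Last transcribed coordinate of the gene."""
        return self.end - 1 if self.strand is Strand.PLUS else self.start


@dataclass(frozen=True)
class Terminator:
    """A cross-hairpin terminator: two palindrome arms and a per-crossing probability."""

    id: str
    shoulder_intervals: tuple[tuple[int, int], tuple[int, int]]
    p_terminate: float

    def __post_init__(self):
        (a0, a1), (b0, b1) = self.shoulder_intervals
        if not (a0 < a1 <= b0 < b1):
            raise LocusValidationError(
                f"terminator {self.id}: arms must be disjoint, ordered intervals"
            )
        if not 0.0 <= self.p_terminate <= 1.0:
            raise LocusValidationError(
                f"terminator {self.id}: p={self.p_terminate} outside [0, 1]"
            )


@dataclass(frozen=True)
class FactorSite:
    """A DNA-binding protein factor site with binding-attempt intensity lambda_F."""

    id: str
    interval: tuple[int, int]
    lambda_f: float
    residence: Optional[float] = None

    def __post_init__(self):
        if self.lambda_f < 0:
            raise LocusValidationError(f"factor site {self.id}: lambda_F < 0")
        if self.interval[0] >= self.interval[1]:
            raise LocusValidationError(f"factor site {self.id}: empty interval")
        if self.residence is not None and self.residence <= 0:
            raise LocusValidationError(f"factor site {self.id}: residence must be > 0")


@dataclass(frozen=True)
class Locus:
    """Immutable two-strand locus geometry.

    The locus is a closed system: every polymerase moving inside it initiated
    at one of its promoters.
    """

    name: str
    length: int
    genes: tuple[Gene, ...] = ()
    promoters: tuple[Promoter, ...] = ()
    terminators: tuple[Terminator, ...] = ()
    factor_sites: tuple[FactorSite, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "promoters", tuple(self.promoters))
        object.__setattr__(self, "terminators", tuple(self.terminators))
        object.__setattr__(self, "factor_sites", tuple(self.factor_sites))
        if self.length <= 0:
            raise LocusValidationError("locus length must be positive")
        ids = [p.id for p in self.promoters]
        if len(set(ids)) != len(ids):
            raise LocusValidationError("promoter ids must be unique")
        gids = [g.id for g in self.genes]
        if len(set(gids)) != len(gids):
            raise LocusValidationError("gene ids must be unique")
        for g in self.genes:
            if not (0 <= g.start and g.end <= self.length):
                raise LocusValidationError(
                    f"gene {g.id} [{g.start}, {g.end}) outside locus [0, {self.length})"
                )
        for p in self.promoters:
            if not (0 <= p.tss < self.length):
                raise LocusValidationError(
                    f"promoter {p.id}: tss {p.tss} outside locus [0, {self.length})"
                )
            lo, hi = p.occupancy_window()
            if lo < 0 or hi >= self.length:
                raise LocusValidationError(
                    f"promoter {p.id}: occupancy window [{lo}, {hi}] extends "
                    f"outside locus [0, {self.length})"
                )
        for t in self.terminators:
            for s, e in t.shoulder_intervals:
                if s < 0 or e > self.length:
                    raise LocusValidationError(
                        f"terminator {t.id}: arm [{s}, {e}) outside locus"
                    )
        for f in self.factor_sites:
            if f.interval[0] < 0 or f.interval[1] > self.length:
                raise LocusValidationError(
                    f"factor site {f.id}: interval outside locus"
                )
        groups: dict[str, Strand] = {}
        for g in self.genes:
            if g.group is None:
                continue
            if g.group in groups and groups[g.group] is not g.strand:
                raise LocusValidationError(
                    f"group {g.group!r}: member genes must share a strand"
                )
            groups[g.group] = g.strand

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"no gene {gene_id!r} in locus {self.name!r}")

    def promoter(self, promoter_id: str) -> Promoter:
        for p in self.promoters:
            if p.id == promoter_id:
                return p
        raise KeyError(f"no promoter {promoter_id!r} in locus {self.name!r}")

    @property
    def conditions(self) -> set[str]:
        out: set[str] = set()
        for p in self.promoters:
            out.update(p.intensity_by_condition)
        return out

    def count_units(self) -> list[str]:
        """Reporting units: group ids replace their member genes, in locus order."""
        units: list[str] = []
        for g in self.genes:
            unit = g.group if g.group is not None else g.id
            if unit not in units:
                units.append(unit)
        return units


# ---------------------------------------------------------------------------
# Config document I/O (format: 1)
# ---------------------------------------------------------------------------


def _parse_pclass(spec, classes: Mapping[str, PolymeraseClass]) -> PolymeraseClass:
    if isinstance(spec, PolymeraseClass):
        return spec
    try:
        return classes[spec]
    except KeyError:
        raise LocusValidationError(
            f"unknown polymerase class {spec!r}; known: {sorted(classes)}"
        ) from None


def load_locus(document) -> Locus:
    """Build a validated :class:`Locus` from a config document.

    ``document`` may be a mapping, YAML text, or a path to a YAML file. The
    schema is versioned (``format: 1``) with sections ``genes``, ``promoters``,
    ``terminators`` and ``factor_sites``; promoter intensities are given per
    condition label. Custom polymerase classes may be declared under
    ``polymerases``; ``PEP`` and ``NEP`` are built in.
    """
    if isinstance(document, Path):
        document = yaml.safe_load(document.read_text())
    elif isinstance(document, str):
        if "\n" not in document and Path(document).exists():
            document = yaml.safe_load(Path(document).read_text())
        else:
            document = yaml.safe_load(document)
    if not isinstance(document, Mapping):
        raise LocusValidationError("locus document must be a mapping")
    fmt = document.get("format", 1)
    if fmt != 1:
        raise LocusValidationError(f"unsupported locus document format {fmt!r}")
    if "length" not in document:
        raise LocusValidationError("locus document missing required key 'length'")

    classes = dict(_BUILTIN_CLASSES)
    for name, spec in (document.get("polymerases") or {}).items():
        abort = spec.get("abort_params")
        classes[name] = PolymeraseClass(
            name=name,
            holo_footprint=tuple(spec["holo_footprint"]),
            core_footprint=tuple(spec["core_footprint"]),
            rate_table={float(k): float(v) for k, v in spec["rate_table"].items()},
            abort_params=tuple(abort) if abort is not None else None,
        )

    genes = tuple(
        Gene(
            id=g["id"],
            strand=Strand.parse(g["strand"]),
            start=int(g["start"]),
            end=int(g["end"]),
            group=g.get("group"),
        )
        for g in document.get("genes") or ()
    )
    promoters = tuple(
        Promoter(
            id=p["id"],
            strand=Strand.parse(p["strand"]),
            tss=int(p["tss"]),
            pclass=_parse_pclass(p.get("class", "PEP"), classes),
            intensity_by_condition={
                str(c): float(v) for c, v in (p.get("intensity") or {}).items()
            },
        )
        for p in document.get("promoters") or ()
    )
    terminators = tuple(
        Terminator(
            id=t["id"],
            shoulder_intervals=(tuple(t["arms"][0]), tuple(t["arms"][1])),
            p_terminate=float(t["p"]),
        )
        for t in document.get("terminators") or ()
    )
    factor_sites = tuple(
        FactorSite(
            id=f["id"],
            interval=tuple(f["interval"]),
            lambda_f=float(f["lambda_f"]),
            residence=f.get("residence"),
        )
        for f in document.get("factor_sites") or ()
    )
    return Locus(
        name=document.get("name", "locus"),
        length=int(document["length"]),
        genes=genes,
        promoters=promoters,
        terminators=terminators,
        factor_sites=factor_sites,
    )


def locus_to_document(locus: Locus) -> dict:
    """Serialize a locus back to the ``format: 1`` document shape."""
    doc: dict = {"format": 1, "name": locus.name, "length": locus.length}
    custom = {
        p.pclass.name: p.pclass
        for p in locus.promoters
        if _BUILTIN_CLASSES.get(p.pclass.name) != p.pclass
    }
    if custom:
        doc["polymerases"] = {
            name: {
                "holo_footprint": list(c.holo_footprint),
                "core_footprint": list(c.core_footprint),
                "rate_table": {float(k): float(v) for k, v in c.rate_table.items()},
                "abort_params": list(c.abort_params) if c.abort_params else None,
            }
            for name, c in custom.items()
        }
    doc["genes"] = [
        {
            "id": g.id,
            "strand": g.strand.value,
            "start": g.start,
            "end": g.end,
            **({"group": g.group} if g.group else {}),
        }
        for g in locus.genes
    ]
    doc["promoters"] = [
        {
            "id": p.id,
            "strand": p.strand.value,
            "tss": p.tss,
            "class": p.pclass.name,
            "intensity": dict(p.intensity_by_condition),
        }
        for p in locus.promoters
    ]
    doc["terminators"] = [
        {"id": t.id, "arms": [list(t.shoulder_intervals[0]), list(t.shoulder_intervals[1])], "p": t.p_terminate}
        for t in locus.terminators
    ]
    doc["factor_sites"] = [
        {
            "id": f.id,
            "interval": list(f.interval),
            "lambda_f": f.lambda_f,
            **({"residence": f.residence} if f.residence is not None else {}),
        }
        for f in locus.factor_sites
    ]
    return doc


def serialize_locus(locus: Locus) -> str:
    """YAML text for a locus document (round-trips through :func:`load_locus`)."""
    return yaml.safe_dump(locus_to_document(locus), sort_keys=False)


# ---------------------------------------------------------------------------
# Annotation import
# ---------------------------------------------------------------------------


def import_annotation(
    features,
    promoters: Sequence[Mapping],
    *,
    length: Optional[int] = None,
    name: str = "locus",
    genes: Optional[Sequence[str]] = None,
    terminators: Sequence[Terminator] = (),
) -> Locus:
    """Build a locus from a gene feature table plus promoter offsets.

    ``features`` is a pandas DataFrame (or path to a TSV) with columns
    ``id, strand, start, end`` (0-based half-open) and optionally ``group``.
    Each entry of ``promoters`` is a mapping with keys ``id``, ``gene``,
    ``offset`` (negative distance from the transcription start site to the
    gene's start codon, e.g. -320 for a promoter named like ``ndhF-320``),
    ``class`` (default PEP) and ``intensity`` (condition -> lambda). The tss
    is placed ``-offset`` nucleotides upstream of the named gene's start codon
    on the gene's strand.
    """
    import pandas as pd

    if not isinstance(features, pd.DataFrame):
        features = pd.read_csv(features, sep="\t", comment="#")
    table = {str(r.id): r for r in features.itertuples()}

    gene_objs = tuple(
        Gene(
            id=str(r.id),
            strand=Strand.parse(r.strand),
            start=int(r.start),
            end=int(r.end),
            group=(getattr(r, "group", None) or None),
        )
        for r in features.itertuples()
        if genes is None or str(r.id) in genes
    )
    prom_objs = []
    for spec in promoters:
        gene_id = spec["gene"]
        if gene_id not in table:
            raise LocusValidationError(
                f"promoter {spec['id']}: gene {gene_id!r} absent from feature table"
            )
        row = table[gene_id]
        strand = Strand.parse(row.strand)
        offset = int(spec["offset"])
        if strand is Strand.PLUS:
            tss = int(row.start) + offset
        else:
            tss = (int(row.end) - 1) - offset
        prom_objs.append(
            Promoter(
                id=spec["id"],
                strand=strand,
                tss=tss,
                pclass=_parse_pclass(spec.get("class", "PEP"), _BUILTIN_CLASSES),
                intensity_by_condition=spec.get("intensity", {}),
            )
        )
    if length is None:
        length = max(
            [g.end for g in gene_objs]
            + [p.occupancy_window()[1] + 1 for p in prom_objs]
        )
    return Locus(
        name=name,
        length=int(length),
        genes=gene_objs,
        promoters=tuple(prom_objs),
        terminators=tuple(terminators),
    )


def mirror_locus(locus: Locus) -> Locus:
    """Reflect a locus end-to-end: coordinates map via ``x -> length - 1 - x``
    and strands flip. Used for the engine's mirror-symmetry property."""
    L = locus.length

    def flip(strand: Strand) -> Strand:
        return Strand.MINUS if strand is Strand.PLUS else Strand.PLUS

    genes = tuple(
        replace(g, strand=flip(g.strand), start=L - g.end, end=L - g.start)
        for g in locus.genes
    )
    promoters = tuple(
        replace(p, strand=flip(p.strand), tss=L - 1 - p.tss) for p in locus.promoters
    )
    terminators = tuple(
        replace(
            t,
            shoulder_intervals=(
                (L - t.shoulder_intervals[1][1], L - t.shoulder_intervals[1][0]),
                (L - t.shoulder_intervals[0][1], L - t.shoulder_intervals[0][0]),
            ),
        )
        for t in locus.terminators
    )
    sites = tuple(
        replace(f, interval=(L - f.interval[1], L - f.interval[0]))
        for f in locus.factor_sites
    )
    return Locus(
        name=locus.name + "_mirror",
        length=L,
        genes=genes,
        promoters=promoters,
        terminators=terminators,
        factor_sites=sites,
    )
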
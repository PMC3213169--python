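"""Interval-level editing of the stripe 2 enhancer (S2E) annotation.

The full S2E is a 798 bp region bordered by two completely conserved blocks
(26 bp on the 5' side, 18 bp on the 3' side).  The minimal stripe element
(MSE) variant removes a 33 bp distal fragment and a 211 bp proximal
fragment (244 bp total), leaving a 509 bp minimal element (the classic
480 bp element plus a 29 bp distal extension that carries no mapped
transcription-factor binding site).  The inverted variant (INV_MSE)
reverse-complements the minimal element in place between identical flanking
sequences.

Coordinates are 1-based inclusive, the molecular-biology convention used
for the printed bp arithmetic; they are converted internally as needed.

The bundled reference annotation is a synthetic placeholder: the real S2E
sequence and exact fragment endpoints are not reproduced here, so a random
(seeded) sequence carries the printed interval lengths.  Supply a real
FASTA plus interval table for sequence-level work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "BindingSite",
    "EnhancerAnnotation",
    "VariantReport",
    "reference_s2e",
    "apply_deletions",
    "build_minimal_element",
    "invert_segment",
    "mse_variant",
    "inv_mse_variant",
]


@dataclass(frozen=True)
class BindingSite:
    """A footprinted transcription-factor binding site (1-based inclusive)."""

    id: str
    factor: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"malformed site interval for {self.id}: ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class EnhancerAnnotation:
    """Sequence plus named intervals and binding sites for one enhancer."""

    name: str
    length: int
    sequence: str | None = None
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    sites: list[BindingSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
        for name, (s, e) in self.intervals.items():
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"interval {name!r} ({s}, {e}) outside bounds [1, {self.length}]")
        ids = [s.id for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate binding-site ids")
        for s in self.sites:
            if s.end > self.length:
                raise ValueError(f"site {s.id} extends past sequence end")

    def interval_length(self, name: str) -> int:
        s, e = self.intervals[name]
        return e - s + 1

    def site_ids(self) -> set[str]:
        return {s.id for s in self.sites}


@dataclass
class VariantReport:
    """Audit record of an enhancer edit."""

    variant_name: str
    length: int
    removed_bases: int = 0
    absent_sites: tuple[str, ...] = ()
    inverted: bool = False
    notes: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, indent=2)


# placeholder layout: 26 + 1 + 33 + 29 + 480 + 211 + 18 = 798
_REF_INTERVALS = {
    "s2e": (1, 798),
    "border_5p": (1, 26),          # conserved block b, 26 bp
    "distal_deletion": (28, 60),   # 33 bp
    "extension": (61, 89),         # 29 bp, no mapped TFBS
    "classic_mse": (90, 569),      # 480 bp
    "minimal_element": (61, 569),  # 509 bp
    "proximal_deletion": (570, 780),  # 211 bp
    "border_3p": (781, 798),       # conserved block a, 18 bp
}

# Site inventory: 5 bcd, 3 hb, 6 kr, 3 gt, 1 slp1.  Positions inside the
# placeholder are invented; only their containment relations matter (hb-1 in
# the distal deletion; kr-1, kr-2 and hb-2 in the proximal deletion; the
# rest inside the classic element).
_REF_SITES = [
    ("hb-1", "hb", 34, 43),
    ("kr-3", "kr", 92, 101),
    ("bcd-1", "bcd", 110, 118),
    ("bcd-2", "bcd", 140, 148),
    ("hb-3", "hb", 180, 189),
    ("bcd-3", "bcd", 200, 208),
    ("kr-4", "kr", 230, 239),
    ("bcd-4", "bcd", 260, 268),
    ("kr-5", "kr", 290, 299),
    ("bcd-5", "bcd", 320, 328),
    ("gt-1", "gt", 360, 368),
    ("gt-2", "gt", 400, 408),
    ("gt-3", "gt", 440, 448),
    ("slp1-1", "slp1", 480, 489),
    ("kr-6", "kr", 540, 549),
    ("kr-1", "kr", 600, 609),
    ("kr-2", "kr", 630, 639),
    ("hb-2", "hb", 660, 669),
]


def reference_s2e(with_sequence: bool = True) -> EnhancerAnnotation:
    """Synthetic placeholder S2E annotation carrying the printed lengths.

    The sequence is a fixed-seed random 798-mer, clearly not the native
    enhancer; interval lengths (798/26/18/33/211/480/29/509 bp) match the
    published construct arithmetic.
    """
    seq = None
    if with_sequence:
        rng = np.random.default_rng(798)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=798)])
    return EnhancerAnnotation(
        name="S2E-placeholder-synthetic",
        length=798,
        sequence=seq,
        intervals=dict(_REF_INTERVALS),
        sites=[BindingSite(i, f, s, e) for i, f, s, e in _REF_SITES],
    )


def _check_deletions(annotation: EnhancerAnnotation, deletions: list[tuple[int, int]]):
    dels = sorted((int(s), int(e)) for s, e in deletions)
    for s, e in dels:
        if not (1 <= s <= e <= annotation.length):
            raise ValueError(f"deletion ({s}, {e}) outside bounds [1, {annotation.length}]")
    for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping deletions ({s1},{e1}) and ({s2},{e2})")
    return dels


def _shift(pos: int, dels: list[tuple[int, int]]) -> int:
    """Map a 1-based coordinate to the post-deletion coordinate system."""
    off = 0
    for s, e in dels:
        if e < pos:
            off += e - s + 1
    return pos - off


def apply_deletions(
    annotation: EnhancerAnnotation,
    deletions: list[tuple[int, int]] | list[str],
    variant_name: str = "variant",
) -> tuple[EnhancerAnnotation, VariantReport]:
    """Delete non-overlapping intervals and shift all coordinates.

    Deletions may be (start, end) pairs or names of intervals in the
    annotation.  Binding sites fully inside a deletion are reported absent;
    a site straddling a deletion edge is an error (the published deletions
    were designed around intact sites).  Named intervals partially
    overlapping a deletion are clipped; fully contained ones are dropped.
    """
    if deletions and isinstance(deletions[0], str):
        deletions = [annotation.intervals[n] for n in deletions]
    dels = _check_deletions(annotation, deletions)
    removed = sum(e - s + 1 for s, e in dels)

    absent: list[str] = []
    new_sites: list[BindingSite] = []
    for site in annotation.sites:
        inside = [(s, e) for s, e in dels if s <= site.start and site.end <= e]
        overlap = [(s, e) for s, e in dels if site.start <= e and s <= site.end]
        if inside:
            absent.append(site.id)
        elif overlap:
            raise ValueError(f"site {site.id} straddles a deletion edge {overlap[0]}")
        else:
            new_sites.append(replace(site, start=_shift(site.start, dels),
                                     end=_shift(site.end, dels)))

    new_intervals: dict[str, tuple[int, int]] = {}
    for name, (s, e) in annotation.intervals.items():
        # clip the interval against every deletion, then shift
        pieces = [(s, e)]
        for ds, de in dels:
            pieces = [
                p for seg in pieces
                for p in ((seg[0], min(seg[1], ds - 1)), (max(seg[0], de + 1), seg[1]))
                if p[0] <= p[1]
            ]
        if not pieces:
            continue
        ns, ne = pieces[0][0], pieces[-1][1]
        new_intervals[name] = (_shift(ns, dels), _shift(ne, dels))

    new_seq = None
    if annotation.sequence is not None:
        keep = np.ones(annotation.length, dtype=bool)
        for s, e in dels:
            keep[s - 1:e] = False
        new_seq = "".join(np.array(list(annotation.sequence))[keep])

    variant = EnhancerAnnotation(
        name=f"{annotation.name}:{variant_name}",
        length=annotation.length - removed,
        sequence=new_seq,
        intervals=new_intervals,
        sites=new_sites,
    )
    report = VariantReport(variant_name=variant_name, length=variant.length,
                           removed_bases=removed, absent_sites=tuple(absent))
    return variant, report


def build_minimal_element(annotation: EnhancerAnnotation) -> VariantReport:
    """Length audit of the minimal element: classic element plus extension."""
    for needed in ("classic_mse", "extension"):
        if needed not in annotation.intervals:
            raise ValueError(f"annotation lacks required interval {needed!r}")
    classic = annotation.interval_length("classic_mse")
    ext = annotation.interval_length("extension")
    es, ee = annotation.intervals["extension"]
    in_ext = tuple(s.id for s in annotation.sites if s.start <= ee and es <= s.end)
    notes = ("no mapped TFBS in extension",) if not in_ext else (
        f"extension overlaps sites: {', '.join(in_ext)}",)
    return VariantReport(variant_name="minimal_element", length=classic + ext,
                         notes=notes)


def invert_segment(
    annotation: EnhancerAnnotation,
    interval: tuple[int, int] | str,
    protected: tuple[str, ...] = ("border_5p", "border_3p"),
) -> EnhancerAnnotation:
    """Reverse-complement an interval in place; flanks stay untouched.

    Binding sites inside the interval are remapped end-for-end with their
    strand flipped; a site straddling the interval edge is an error, as is
    overlap with a protected border block.
    """
    if isinstance(interval, str):
        interval = annotation.intervals[interval]
    s, e = int(interval[0]), int(interval[1])
    if not (1 <= s <= e <= annotation.length):
        raise ValueError(f"interval ({s}, {e}) outside bounds")
    if annotation.sequence is None:
        raise ValueError("inversion requires a sequence")
    for name in protected:
        if name in annotation.intervals:
            ps, pe = annotation.intervals[name]
            if s <= pe and ps <= e:
                raise ValueError(f"interval overlaps protected border block {name!r}")

    seq = annotation.sequence
    segment = str(Seq(seq[s - 1:e]).reverse_complement())
    new_seq = seq[:s - 1] + segment + seq[e:]

    new_sites: list[BindingSite] = []
    flip = {"+": "-", "-": "+"}
    for site in annotation.sites:
        inside = s <= site.start and site.end <= e
        overlap = site.start <= e and s <= site.end
        if inside:
            new_sites.append(replace(site, start=s + e - site.end, end=s + e - site.start,
                                     strand=flip[site.strand]))
        elif overlap:
            raise ValueError(f"site {site.id} straddles the inversion edge")
        else:
            new_sites.append(site)
    new_sites.sort(key=lambda x: x.start)
    return replace(annotation, name=f"{annotation.name}:inv({s},{e})",
                   sequence=new_seq, sites=new_sites)


def mse_variant(annotation: EnhancerAnnotation | None = None):
    """The deletion variant: both flanking fragments removed (244 bp)."""
    if annotation is None:
        annotation = reference_s2e()
    return apply_deletions(annotation, ["distal_deletion", "proximal_deletion"],
                           variant_name="MSE")


def inv_mse_variant(annotation: EnhancerAnnotation | None = None):
    """The inversion variant: the 509 bp minimal element reverse-complemented."""
    variant, report = mse_variant(annotation)
    inv = invert_segment(variant, "minimal_element")
    report = replace(report, variant_name="INV_MSE", inverted=True)
    return inv, report
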
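"""Homozygosity mapping: ROH calling, shared regions, and STR haplotypes.

Runs of homozygosity (ROH) are the genomic signature of autozygosity: in
the offspring of consanguineous unions, the tract around a recessive
causal allele is homozygous by descent.  This module calls ROH tracts from
sparse (exome-density) genotypes, intersects them across patients with a
minimum shared-length rule (100 kb by default), and delineates the minimal
ancestral haplotype shared by patients at multi-allelic STR markers.

Coordinates are 1-based closed; region length uses the end - start
difference convention (so Chr16:4,057,603-7,657,432 renders as 3.6 Mb).
BED output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .variantstore import HET, HOM_ALT, HOM_REF, MISSING

__all__ = [
    "GenomicRegion",
    "RohParams",
    "STRGenotype",
    "PhasedMarker",
    "PhasedHaplotype",
    "MinimalHaplotype",
    "call_roh",
    "shared_regions",
    "region_length",
    "format_mb",
    "phase_str_trio",
    "minimal_shared_haplotype",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicRegion:
    """Chromosome interval (1-based closed) supported by >= 1 variant."""

    chrom: str
    start: int
    end: int
    n_variants: int = 1
    samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


@dataclass(frozen=True)
class RohParams:
    """ROH scan parameters.

    ``max_het = 0`` by default: at exome variant density a single
    heterozygous call is strong evidence against autozygosity.  The 100 kb
    length threshold matches the reporting rule used for shared regions.
    """

    min_variants: int = 10
    min_length_bp: int = 100_000
    max_het: int = 0


def region_length(region: GenomicRegion) -> int:
    """Length in bp by the difference convention (end - start)."""
    return region.end - region.start


def format_mb(length_bp: int, decimals: int = 1) -> str:
    """Render a bp length in Mb, rounding half-up (3,599,829 -> "3.6 Mb")."""
    mb = Decimal(length_bp) / Decimal(1_000_000)
    if decimals == 0:
        q = mb.quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        return f"∼{q} Mb"
    q = mb.quantize(Decimal("1." + "0" * decimals), rounding=ROUND_HALF_UP)
    return f"{q} Mb"


def call_roh(
    positions: Sequence[int],
    states: Sequence[int],
    params: RohParams = RohParams(),
    chrom: str = "?",
    sample: Optional[str] = None,
) -> list[GenomicRegion]:
    """Call runs of homozygosity on one chromosome of one sample.

    Input is position-sorted genotype states.  Missing calls are skipped
    without breaking a run.  A run is a maximal window of consecutive
    non-missing calls that starts and ends on a homozygous call and
    contains at most ``max_het`` heterozygous calls; it is reported when it
    holds at least ``min_variants`` homozygous calls and spans at least
    ``min_length_bp`` (end - start).  Region boundaries are the positions
    of the first and last homozygous call of the run.
    """
    positions = np.asarray(positions, dtype=np.int64)
    states = np.asarray(states, dtype=np.int64)
    if positions.shape != states.shape:
        raise ValueError("positions and states differ in length")
    if np.any(np.diff(positions) < 0):
        raise ValueError(f"positions not sorted on chromosome {chrom}")
    keep = states != MISSING
    pos = positions[keep]
    st = states[keep]
    is_hom = (st == HOM_REF) | (st == HOM_ALT)
    is_het = st == HET
    n = len(st)
    sample_set = frozenset([sample]) if sample else frozenset()

    regions: list[GenomicRegion] = []
    prev_end_idx = -1
    i = 0
    while i < n:
        if not is_hom[i]:
            i += 1
            continue
        # greedy extension: widest window starting at i with <= max_het hets
        hets = 0
        j = i
        last_hom = i
        k = i
        while k < n:
            if is_het[k]:
                if hets + 1 > params.max_het:
                    break
                hets += 1
            else:
                last_hom = k
            k += 1
        j = last_hom  # trim to end on a homozygous call
        if j > prev_end_idx:  # maximal under containment
            n_hom = int(is_hom[i : j + 1].sum())
            span = int(pos[j] - pos[i])
            if n_hom >= params.min_variants and span >= params.min_length_bp:
                regions.append(
                    GenomicRegion(
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j]),
                        n_variants=n_hom,
                        samples=sample_set,
                    )
                )
            prev_end_idx = j
        # with no het budget, every start inside [i..j] yields the same run
        i = j + 1 if params.max_het == 0 else i + 1
    return regions


def _intersect_two(
    a: list[GenomicRegion], b: list[GenomicRegion]
) -> list[GenomicRegion]:
    out = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            lo, hi = max(ra.start, rb.start), min(ra.end, rb.end)
            if lo <= hi:
                out.append(
                    GenomicRegion(
                        chrom=ra.chrom,
                        start=lo,
                        end=hi,
                        n_variants=min(ra.n_variants, rb.n_variants),
                        samples=ra.samples | rb.samples,
                    )
                )
    return out


def shared_regions(
    regions_by_sample: Mapping[str, list[GenomicRegion]],
    min_shared_length_bp: int = 100_000,
) -> list[GenomicRegion]:
    """Intervals homozygous in every sample, at least ``min_shared_length_bp`` long.

    Takes the k-wise intersection of each sample's ROH regions (tagging
    each sample's regions with its id), keeps intersections with
    end - start >= threshold, and sorts by (chromosome, start).
    """
    if len(regions_by_sample) < 2:
        raise ValueError("shared_regions requires regions from >= 2 samples")
    items = sorted(regions_by_sample.items())
    current = [
        GenomicRegion(r.chrom, r.start, r.end, r.n_variants, frozenset([items[0][0]]))
        for r in items[0][1]
    ]
    for sample, regs in items[1:]:
        tagged = [
            GenomicRegion(r.chrom, r.start, r.end, r.n_variants, frozenset([sample]))
            for r in regs
        ]
        current = _intersect_two(current, tagged)
    kept = [r for r in current if r.length >= min_shared_length_bp]
    return sorted(kept, key=lambda r: (r.chrom, r.start, r.end))


# -- STR phasing and the minimal ancestral haplotype ----------------


@dataclass(frozen=True)
class STRGenotype:
    """One microsatellite call: unordered pair of integer repeat labels."""

    marker: str
    chrom: str
    position: int
    sample: str
    alleles: Optional[tuple[int, int]] = None  # None = missing

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]


@dataclass(frozen=True)
class PhasedMarker:
    marker: str
    chrom: str
    position: int
    paternal: Optional[int]  # None when unresolved / inconsistent
    maternal: Optional[int]
    resolved: bool
    mendelian_consistent: bool
    alleles: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class PhasedHaplotype:
    sample: str
    markers: tuple[PhasedMarker, ...]


def phase_str_trio(
    child: Sequence[STRGenotype],
    father: Sequence[STRGenotype],
    mother: Sequence[STRGenotype],
) -> PhasedHaplotype:
    """Assign parental origin to each child STR allele from the trio.

    A child allele is paternal iff it occurs in the father's pair and the
    assignment is unique given the mother's pair; when both orientations
    are compatible the marker is left unresolved; Mendelian-inconsistent
    markers are flagged, never raised.
    """
    f_by = {g.marker: g for g in father}
    m_by = {g.marker: g for g in mother}
    out = []
    for cg in sorted(child, key=lambda g: (g.chrom, g.position, g.marker)):
        fg, mg = f_by.get(cg.marker), m_by.get(cg.marker)
        if cg.alleles is None or fg is None or mg is None or fg.alleles is None or mg.alleles is None:
            out.append(
                PhasedMarker(cg.marker, cg.chrom, cg.position, None, None, False, True,
                             cg.alleles or (0, 0))
            )
            continue
        a, b = cg.alleles
        options = []
        for pat, mat in {(a, b), (b, a)}:
            if pat in fg.alleles and mat in mg.alleles:
                options.append((pat, mat))
        if not options:
            out.append(
                PhasedMarker(cg.marker, cg.chrom, cg.position, None, None, False, False, (a, b))
            )
        elif len(options) == 1:
            pat, mat = options[0]
            out.append(
                PhasedMarker(cg.marker, cg.chrom, cg.position, pat, mat, True, True, (a, b))
            )
        else:
            out.append(
                PhasedMarker(cg.marker, cg.chrom, cg.position, None, None, False, True, (a, b))
            )
    return PhasedHaplotype(sample=child[0].sample if child else "?", markers=tuple(out))


@dataclass(frozen=True)
class MinimalHaplotype:
    """Minimal ancestral shared-homozygosity haplotype across patients."""

    region: Optional[GenomicRegion]
    core_markers: tuple[str, ...]
    left_boundary: Optional[str]  # first flanking discordant/het marker
    right_boundary: Optional[str]
    diagnostic: str = ""


def minimal_shared_haplotype(
    genotypes_by_patient: Mapping[str, Sequence[STRGenotype]],
    marker_map: Sequence[tuple[str, str, int]],
) -> MinimalHaplotype:
    """Maximal run of markers at which every patient is homozygous for one allele.

    ``marker_map`` is the ordered (marker, chromosome, position) panel.
    Boundaries are the first flanking marker on each side that is
    heterozygous or discordant in some patient; the span is computed
    between the boundary-marker positions (difference convention).  When
    the run touches the panel edge, the edge marker itself bounds the
    region.  Ties between equally long runs resolve to the leftmost.
    """
    if len(genotypes_by_patient) < 2:
        raise ValueError("minimal_shared_haplotype requires >= 2 patients")
    by_patient = {
        s: {g.marker: g for g in gs} for s, gs in genotypes_by_patient.items()
    }
    shared = []
    for marker, _chrom, _pos in marker_map:
        allele = None
        ok = True
        for s, gmap in by_patient.items():
            g = gmap.get(marker)
            if g is None or g.alleles is None or not g.is_hom:
                ok = False
                break
            if allele is None:
                allele = g.alleles[0]
            elif g.alleles[0] != allele:
                ok = False
                break
        shared.append(ok)
    # longest run of True, leftmost on ties
    best = (0, -1)  # (length, start)
    i = 0
    n = len(shared)
    while i < n:
        if shared[i]:
            j = i
            while j + 1 < n and shared[j + 1]:
                j += 1
            if j - i + 1 > best[0]:
                best = (j - i + 1, i)
            i = j + 1
        else:
            i += 1
    if best[0] == 0:
        return MinimalHaplotype(
            region=None,
            core_markers=(),
            left_boundary=None,
            right_boundary=None,
            diagnostic="no marker with shared homozygosity across all patients",
        )
    run_start = best[1]
    run_end = best[1] + best[0] - 1
    li = run_start - 1 if run_start > 0 else run_start
    ri = run_end + 1 if run_end < n - 1 else run_end
    left_name, chrom, left_pos = marker_map[li]
    right_name, _, right_pos = marker_map[ri]
    region = GenomicRegion(
        chrom=chrom,
        start=left_pos,
        end=right_pos,
        n_variants=best[0],
        samples=frozenset(genotypes_by_patient),
    )
    return MinimalHaplotype(
        region=region,
        core_markers=tuple(m for m, _, _ in marker_map[run_start : run_end + 1]),
        left_boundary=left_name,
        right_boundary=right_name,
    )


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open): start-1, end."""
    lines = []
    for r in regions:
        name = ",".join(sorted(r.samples)) or "."
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_variants}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
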
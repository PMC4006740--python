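"""Genotype, annotation and frequency data model, plus the exclusion database.

Variant identity is ``(chromosome, position, ref, alt)`` after multi-allelic
splitting and left-trim normalisation; coordinates are 1-based fully closed,
per VCF convention.  Genotype states are encoded as small integers
(:data:`HOM_REF`, :data:`HET`, :data:`HOM_ALT`, :data:`MISSING`).

The exclusion database reproduces the "common, non-pathogenic" construction
rule used for candidate filtering: a frequency record becomes a member iff
it is not flagged pathogenic, has frequency information, and that frequency
is at least 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "VariantKey",
    "GenotypeCall",
    "GenotypeMatrix",
    "AnnotatedVariant",
    "FrequencyRecord",
    "ExclusionDatabase",
    "read_vcf",
    "write_vcf",
    "build_exclusion_db",
    "build_control_panel",
    "read_annotations",
    "read_frequency_table",
    "read_panel",
]

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_STATE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

REGION_CLASSES = ("exonic", "splice", "intronic", "intergenic", "UTR", "other")
EFFECT_CLASSES = (
    "nonsynonymous_SNV",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "synonymous",
    "other",
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Biallelic variant identity: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @staticmethod
    def normalized(chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Left-align/trim: strip shared suffix then shared prefix bases."""
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return VariantKey(chrom, pos, ref, alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    key: VariantKey
    state: int

    def __post_init__(self):
        if self.state not in _STATE_NAMES:
            raise ValueError(f"invalid genotype state {self.state}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """Functional annotation attached to a variant key.

    ``effect_class`` is meaningful only for exonic/splice records;
    ``cds_position`` is present for exonic records.  ``predictor_scores``
    maps tool name to a numeric or categorical pathogenicity score.
    """

    key: VariantKey
    gene: str
    region_class: str
    effect_class: str = "other"
    cds_position: Optional[int] = None
    predictor_scores: Mapping[str, Union[float, str]] = field(default_factory=dict)


@dataclass(frozen=True)
class FrequencyRecord:
    key: VariantKey
    frequency: Optional[float]
    pathogenic_flag: bool = False

    def __post_init__(self):
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")


class ExclusionDatabase:
    """Set of common, non-pathogenic variant keys used to discard polymorphisms."""

    def __init__(self, members: Iterable[VariantKey] = ()):
        self.members: frozenset[VariantKey] = frozenset(members)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.members

    def __len__(self) -> int:
        return len(self.members)


class GenotypeMatrix:
    """Genotype states for a roster of samples over a sorted set of variant keys."""

    def __init__(self, keys: list[VariantKey], samples: list[str], data: np.ndarray):
        self.keys = list(keys)
        self.samples = list(samples)
        self.data = np.asarray(data, dtype=np.int8)
        if self.data.shape != (len(self.keys), len(self.samples)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.keys)} keys x {len(self.samples)} samples"
            )
        self._sort()
        self._sample_idx = {s: j for j, s in enumerate(self.samples)}

    def _sort(self) -> None:
        idx = sorted(range(len(self.keys)), key=lambda i: self.keys[i])
        self.keys = [self.keys[i] for i in idx]
        self.data = self.data[idx, :]

    def __len__(self) -> int:
        return len(self.keys)

    def sample_states(self, sample: str) -> np.ndarray:
        if sample not in self._sample_idx:
            raise KeyError(f"sample {sample!r} absent from genotype matrix")
        return self.data[:, self._sample_idx[sample]]

    def calls(self) -> Iterable[GenotypeCall]:
        for i, key in enumerate(self.keys):
            for j, sample in enumerate(self.samples):
                yield GenotypeCall(sample, key, int(self.data[i, j]))

    def state(self, key: VariantKey, sample: str) -> int:
        i = self.keys.index(key)
        return int(self.data[i, self._sample_idx[sample]])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [k.chrom for k in self.keys],
                "pos": [k.pos for k in self.keys],
                "ref": [k.ref for k in self.keys],
                "alt": [k.alt for k in self.keys],
            }
        )
        for j, s in enumerate(self.samples):
            df[s] = self.data[:, j]
        return df


def _recode(alleles: tuple[int, int], alt_index: int) -> int:
    """Diploid allele indices -> biallelic state for one split alternate."""
    if -1 in alleles:
        return MISSING
    n = sum(1 for a in alleles if a == alt_index)
    return (HOM_REF, HET, HOM_ALT)[n]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCFv4 file into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one key per alternate, with the
    genotype recoded relative to that alternate (e.g. GT ``1/2`` becomes
    het for both alternates).  ``./.`` becomes missing; phased and
    unphased separators are both accepted.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    keys: list[VariantKey] = []
    rows: list[list[int]] = []
    for record_no, v in enumerate(vcf, start=1):
        gts = v.genotypes  # [a1, a2, phased] per sample
        for alt_index, alt in enumerate(v.ALT, start=1):
            try:
                key = VariantKey.normalized(str(v.CHROM), int(v.POS), v.REF, alt)
            except ValueError as exc:
                raise ValueError(f"{path}: record {record_no}: {exc}") from None
            row = []
            for g in gts:
                if len(g) < 3:  # haploid or absent call
                    row.append(MISSING)
                else:
                    row.append(_recode((g[0], g[1]), alt_index))
            keys.append(key)
            rows.append(row)
    data = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(keys, samples, data)


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a minimal VCFv4.2 file (GT field only)."""
    lines = ["##fileformat=VCFv4.2", '##source=ibdmap']
    if contig_lengths:
        for chrom in sorted(contig_lengths):
            lines.append(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    for i, key in enumerate(matrix.keys):
        gts = "\t".join(_GT_STRINGS[int(s)] for s in matrix.data[i, :])
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def build_exclusion_db(records: Iterable[FrequencyRecord]) -> ExclusionDatabase:
    """Common non-pathogenic variants: not pathogenic, frequency known and >= 1%.

    Records flagged pathogenic, without frequency information, or with
    frequency below 1% are dropped ("lower than 1%" removed means exactly
    1% is retained).
    """
    members = [
        r.key
        for r in records
        if not r.pathogenic_flag and r.frequency is not None and r.frequency >= 0.01
    ]
    return ExclusionDatabase(members)


def build_control_panel(control_matrices: Iterable[GenotypeMatrix]) -> frozenset[VariantKey]:
    """Variant keys homozygous-alternate in at least one control individual."""
    panel: set[VariantKey] = set()
    for m in control_matrices:
        hom_any = (m.data == HOM_ALT).any(axis=1)
        panel.update(k for k, h in zip(m.keys, hom_any) if h)
    return frozenset(panel)


# -- TSV readers ----------------------------------------------------

_ANNOTATION_FIXED = ["chrom", "pos", "ref", "alt", "gene", "region_class", "effect_class", "cds_pos"]


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotatedVariant]:
    """Annotation TSV -> key-indexed map; extra columns are predictor scores."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _ANNOTATION_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    predictor_cols = [c for c in df.columns if c not in _ANNOTATION_FIXED]
    out: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        scores: dict[str, Union[float, str]] = {}
        for col in predictor_cols:
            val = getattr(row, col)
            if pd.isna(val):
                continue
            scores[col] = val
        cds = getattr(row, "cds_pos")
        out[key] = AnnotatedVariant(
            key=key,
            gene=str(row.gene),
            region_class=str(row.region_class),
            effect_class=str(row.effect_class),
            cds_position=None if pd.isna(cds) else int(cds),
            predictor_scores=scores,
        )
    return out


def read_frequency_table(path: str | Path) -> list[FrequencyRecord]:
    """Frequency TSV (chrom, pos, ref, alt, freq, pathogenic) -> records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        freq = row.freq
        records.append(
            FrequencyRecord(
                key=VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt),
                frequency=None if pd.isna(freq) else float(freq),
                pathogenic_flag=bool(row.pathogenic),
            )
        )
    return records


def read_panel(path: str | Path) -> frozenset[VariantKey]:
    """Control-panel TSV (chrom, pos, ref, alt) -> key set."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return frozenset(
        VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    )
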
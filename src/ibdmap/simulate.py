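"""Synthetic consanguineous-pedigree exome simulator.

Gene-drops founder haplotypes through two first-cousin-loop families,
plants a recessive causal variant on a founder haplotype shared by both
families (a founder mutation), and emits every file the prioritization
pipeline consumes: per-family VCFs, a functional-annotation table with
simulated predictor scores, a population frequency table, a control panel
of homozygous variants from unrelated individuals, control-chromosome
allele counts, STR marker genotypes and PED files.

Meiosis uses the Haldane map function: crossover counts per chromosome
are Poisson with mean equal to the genetic length in Morgans, positions
uniform, no interference.  Founder-origin labels are carried through every
transmission, so autozygosity (both labels identical) is directly
readable and the expected autozygous genome fraction of a proband equals
the pedigree inbreeding coefficient.

The genome is a scaled-down two-chromosome exome: ~1,200 variants per
chromosome, matching roughly one variant per 3 kb of captured exonic
sequence.  A single master seed determines every output byte; per-purpose
substreams are derived with fixed labels so adding a stage never perturbs
earlier draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .pedigree import Affection, Individual, Pedigree, Sex, write_ped
from .variantstore import (
    GenotypeMatrix,
    VariantKey,
    write_vcf,
)

__all__ = [
    "AlleleFrequencySpectrum",
    "CausalSpec",
    "STRMarker",
    "SimulationConfig",
    "Haplotype",
    "ChromSites",
    "FounderHaplotypePool",
    "SimulatedFamily",
    "SimulatedDataset",
    "first_cousin_family",
    "build_sites",
    "sample_founder_haplotypes",
    "gene_drop",
    "plant_causal_variant",
    "simulate_dataset",
    "emit_dataset",
    "autozygous_fraction",
    "BUNDLE_FILES",
]

_BASES = np.array(["A", "C", "G", "T"])

# substream labels (fixed; adding a stage must never renumber these)
_SS_SITES = 0
_SS_FOUNDERS = 1
_SS_ANCESTRAL = 2
_SS_DROP = 3  # extra = family index
_SS_CONTROLS = 4
_SS_ANNOT = 5
_SS_STR = 6


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Site-frequency spectrum: a common uniform component plus a rare tail.

    With probability ``1 - rare_fraction`` a site's alternate-allele
    frequency is Uniform(low, high); otherwise Uniform(rare_low, rare_high).
    The rare tail (below the 1% exclusion-database threshold) is what the
    candidate lists are ultimately made of.
    """

    low: float = 0.01
    high: float = 0.5
    rare_fraction: float = 0.2
    rare_low: float = 0.0005
    rare_high: float = 0.01

    def validate(self) -> None:
        for name in ("low", "high", "rare_low", "rare_high", "rare_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"spectrum.{name} = {v} outside [0, 1]")
        if self.low >= self.high or self.rare_low >= self.rare_high:
            raise ValueError("spectrum bounds must satisfy low < high")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        common = rng.uniform(self.low, self.high, size=n)
        rare = rng.uniform(self.rare_low, self.rare_high, size=n)
        is_rare = rng.random(n) < self.rare_fraction
        return np.where(is_rare, rare, common)


@dataclass(frozen=True)
class CausalSpec:
    """The planted recessive variant (chromosome, position, gene, alleles)."""

    chrom: str = "16"
    position: int = 5_800_000
    gene: str = "PAM16"
    ref: str = "A"
    alt: str = "G"
    cds_position: int = 226

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class STRMarker:
    name: str
    chrom: str
    position: int


# Microsatellite panel flanking the causal locus on the simulated
# chromosome 16, spanning ~8.4 Mb (marker names follow the standard
# D16S nomenclature for 16p13.3; positions are synthetic).
DEFAULT_STR_MARKERS: tuple[STRMarker, ...] = tuple(
    STRMarker(name, "16", pos)
    for name, pos in [
        ("D16S521", 1_650_000),
        ("D16S3024", 2_350_000),
        ("D16S3070", 3_050_000),
        ("D16S3027", 3_750_000),
        ("D16S758", 4_450_000),
        ("D16S3084", 5_150_000),
        ("D16S3072", 5_850_000),
        ("D16S3134", 6_550_000),
        ("D16S243", 7_250_000),
        ("D16S510", 7_950_000),
        ("D16S423", 8_650_000),
        ("AFM339XG1", 9_350_000),
        ("D16S3135", 10_050_000),
    ]
)

_STR_LADDER = np.arange(150, 166, 2)  # repeat-length allele labels

DEFAULT_REGION_CLASS_PROBS = {
    "exonic": 0.75,
    "splice": 0.05,
    "intronic": 0.12,
    "UTR": 0.05,
    "intergenic": 0.02,
    "other": 0.01,
}

DEFAULT_EFFECT_CLASS_PROBS = {
    "nonsynonymous_SNV": 0.46,
    "synonymous": 0.42,
    "stopgain": 0.02,
    "stoploss": 0.005,
    "frameshift_indel": 0.045,
    "nonframeshift_indel": 0.035,
    "other": 0.015,
}

PREDICTOR_TOOLS = ("sift", "polyphen2", "provean", "mutation_taster")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_variants_per_chrom: int = 1200
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "16": 90_354_753}
    )
    spectrum: AlleleFrequencySpectrum = field(default_factory=AlleleFrequencySpectrum)
    recombination_rate_cm_per_mb: float = 1.0
    region_class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_CLASS_PROBS)
    )
    effect_class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_CLASS_PROBS)
    )
    causal: CausalSpec = field(default_factory=CausalSpec)
    str_markers: Sequence[STRMarker] = DEFAULT_STR_MARKERS
    n_controls: int = 14
    n_control_chromosomes: int = 550
    rejection_cap: int = 10_000
    damaging_prob_causal: float = 0.9
    damaging_prob_neutral: float = 0.1
    shared_founder: str = "I.1"  # founder (per family) carrying the ancestral haplotype
    pathogenic_flag_prob: float = 0.01
    missing_frequency_prob: float = 0.02

    @property
    def fraction_exonic(self) -> float:
        return self.region_class_probs.get("exonic", 0.0) + self.region_class_probs.get(
            "splice", 0.0
        )

    def validate(self) -> None:
        self.spectrum.validate()
        for name, probs in (
            ("region_class_probs", self.region_class_probs),
            ("effect_class_probs", self.effect_class_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sum to {total}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains a negative probability")
        if self.causal.chrom not in self.chrom_lengths:
            raise ValueError(f"causal chromosome {self.causal.chrom!r} not simulated")
        if not (1 <= self.causal.position <= self.chrom_lengths[self.causal.chrom]):
            raise ValueError("causal position outside its chromosome")
        if self.n_variants_per_chrom < 2:
            raise ValueError("need at least 2 variants per chromosome")


def _rng(config: SimulationConfig, label: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(label, extra))
    )


# -- default pedigrees ----------------------------------------------


def first_cousin_family(family_id: str, proband: str = "IV.3") -> Pedigree:
    """Consanguineous family: the proband is the child of first cousins (F = 1/16)."""

    def iid(suffix: str) -> str:
        return f"{family_id}-{suffix}"

    inds = [
        Individual(iid("I.1"), sex=Sex.MALE),
        Individual(iid("I.2"), sex=Sex.FEMALE),
        Individual(iid("II.1"), iid("I.1"), iid("I.2"), Sex.MALE, Affection.UNAFFECTED),
        Individual(iid("II.2"), iid("I.1"), iid("I.2"), Sex.FEMALE, Affection.UNAFFECTED),
        Individual(iid("II.3"), sex=Sex.FEMALE),
        Individual(iid("II.4"), sex=Sex.MALE),
        Individual(iid("III.1"), iid("II.1"), iid("II.3"), Sex.MALE, Affection.UNAFFECTED),
        Individual(iid("III.2"), iid("II.4"), iid("II.2"), Sex.FEMALE, Affection.UNAFFECTED),
        Individual(
            iid(proband), iid("III.1"), iid("III.2"), Sex.FEMALE, Affection.AFFECTED
        ),
    ]
    return Pedigree(inds, family_id=family_id)


# -- site panel ------------------------------------------------------


@dataclass
class ChromSites:
    """All simulated sites (SNVs and STR markers) on one chromosome, sorted."""

    chrom: str
    length: int
    positions: np.ndarray  # int64, 1-based, sorted
    is_str: np.ndarray  # bool
    ref: np.ndarray  # object ('.' at STR sites)
    alt: np.ndarray
    freq: np.ndarray  # float (nan at STR sites)
    str_names: np.ndarray  # object (None at SNV sites)
    causal_index: int = -1  # -1 when the causal site is elsewhere

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def snv_keys(self) -> list[VariantKey]:
        return [
            VariantKey(self.chrom, int(p), str(r), str(a))
            for p, r, a, s in zip(self.positions, self.ref, self.alt, self.is_str)
            if not s
        ]


def build_sites(config: SimulationConfig) -> dict[str, ChromSites]:
    """Draw SNV positions, alleles and population frequencies; merge STR markers."""
    config.validate()
    rng = _rng(config, _SS_SITES)
    out: dict[str, ChromSites] = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        pos = np.sort(
            rng.choice(
                np.arange(1, length + 1, dtype=np.int64),
                size=config.n_variants_per_chrom,
                replace=False,
            )
            if length < 10 * config.n_variants_per_chrom
            else np.unique(rng.integers(1, length + 1, size=config.n_variants_per_chrom))
        )
        if chrom == config.causal.chrom:
            pos = pos[pos != config.causal.position]
        n = len(pos)
        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        ref = _BASES[ref_idx]
        alt = _BASES[(ref_idx + alt_shift) % 4]
        freq = config.spectrum.sample(rng, n)
        is_str = np.zeros(n, dtype=bool)
        str_names = np.full(n, None, dtype=object)

        if chrom == config.causal.chrom:
            pos = np.append(pos, config.causal.position)
            ref = np.append(ref, config.causal.ref)
            alt = np.append(alt, config.causal.alt)
            freq = np.append(freq, 0.0)  # absent from the general population
            is_str = np.append(is_str, False)
            str_names = np.append(str_names, None)

        for m in config.str_markers:
            if m.chrom != chrom:
                continue
            pos = np.append(pos, m.position)
            ref = np.append(ref, ".")
            alt = np.append(alt, ".")
            freq = np.append(freq, np.nan)
            is_str = np.append(is_str, True)
            str_names = np.append(str_names, m.name)

        order = np.argsort(pos, kind="stable")
        sites = ChromSites(
            chrom=chrom,
            length=length,
            positions=pos[order],
            is_str=is_str[order],
            ref=ref[order].astype(object),
            alt=alt[order].astype(object),
            freq=freq[order],
            str_names=str_names[order],
        )
        if chrom == config.causal.chrom:
            idx = np.flatnonzero(
                (sites.positions == config.causal.position) & ~sites.is_str
            )
            sites.causal_index = int(idx[0])
        out[chrom] = sites
    return out


# -- founder haplotypes ----------------------------------------------


@dataclass
class Haplotype:
    """Ordered allele vector plus per-site founder-origin labels."""

    alleles: np.ndarray  # int16: alt-count 0/1 at SNV sites, repeat label at STRs
    origins: np.ndarray  # int32 founder-copy labels


FounderHaplotypePool = dict[str, dict[str, list[Haplotype]]]
# founder id -> chromosome -> [haplotype copy 0, copy 1]


def sample_founder_haplotypes(
    config: SimulationConfig,
    sites: Mapping[str, ChromSites],
    pedigrees: Sequence[Pedigree],
) -> FounderHaplotypePool:
    """Independent founder haplotypes: SNV alleles Bernoulli(site frequency),
    STR alleles uniform on the repeat ladder; globally unique origin labels."""
    rng = _rng(config, _SS_FOUNDERS)
    pool: FounderHaplotypePool = {}
    label = 0
    for ped in pedigrees:
        for founder in sorted(ped.founders):
            per_chrom: dict[str, list[Haplotype]] = {}
            for chrom in sorted(sites):
                cs = sites[chrom]
                copies = []
                for _copy in range(2):
                    alleles = np.zeros(cs.n_sites, dtype=np.int16)
                    snv = ~cs.is_str
                    alleles[snv] = (
                        rng.random(int(snv.sum())) < cs.freq[snv]
                    ).astype(np.int16)
                    alleles[cs.is_str] = rng.choice(
                        _STR_LADDER, size=int(cs.is_str.sum())
                    )
                    copies.append(
                        Haplotype(
                            alleles=alleles,
                            origins=np.full(cs.n_sites, label, dtype=np.int32),
                        )
                    )
                    label += 1
                per_chrom[chrom] = copies
            pool[founder] = per_chrom
    return pool


# -- meiosis and gene dropping ---------------------------------------


def _meiosis(
    pair: Sequence[Haplotype],
    positions: np.ndarray,
    length_bp: int,
    rate_cm_per_mb: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One recombinant gamete under the Haldane model (Poisson crossovers)."""
    morgans = length_bp / 1e6 * rate_cm_per_mb / 100.0
    n_x = rng.poisson(morgans)
    start = int(rng.integers(2))
    if n_x == 0:
        src = pair[start]
        return Haplotype(src.alleles.copy(), src.origins.copy())
    points = np.sort(rng.uniform(1, length_bp, size=n_x))
    which = (start + np.searchsorted(points, positions)) % 2
    a0, a1 = pair[0], pair[1]
    return Haplotype(
        alleles=np.where(which == 0, a0.alleles, a1.alleles).astype(np.int16),
        origins=np.where(which == 0, a0.origins, a1.origins).astype(np.int32),
    )


DropResult = dict[str, dict[str, tuple[Haplotype, Haplotype]]]
# individual -> chromosome -> (paternal haplotype, maternal haplotype)


def gene_drop(
    ped: Pedigree,
    pool: FounderHaplotypePool,
    sites: Mapping[str, ChromSites],
    config: SimulationConfig,
    rng: np.random.Generator,
    chroms: Optional[Sequence[str]] = None,
) -> DropResult:
    """Transmit haplotypes down the pedigree; origin labels ride along."""
    chroms = sorted(sites) if chroms is None else list(chroms)
    result: DropResult = {}
    for ind_id in ped.topological_order():
        ind = ped.individuals[ind_id]
        per_chrom: dict[str, tuple[Haplotype, Haplotype]] = {}
        for chrom in chroms:
            cs = sites[chrom]
            if ind.is_founder:
                h0, h1 = pool[ind_id][chrom]
                per_chrom[chrom] = (h0, h1)
            else:
                pat = _meiosis(
                    result[ind.father_id][chrom],
                    cs.positions,
                    cs.length,
                    config.recombination_rate_cm_per_mb,
                    rng,
                )
                mat = _meiosis(
                    result[ind.mother_id][chrom],
                    cs.positions,
                    cs.length,
                    config.recombination_rate_cm_per_mb,
                    rng,
                )
                per_chrom[chrom] = (pat, mat)
        result[ind_id] = per_chrom
    return result


def autozygous_fraction(drop: DropResult, individual: str) -> float:
    """Fraction of sites where both haplotypes carry the same origin label."""
    total = 0
    auto = 0
    for chrom, (pat, mat) in drop[individual].items():
        total += len(pat.origins)
        auto += int((pat.origins == mat.origins).sum())
    return auto / total if total else 0.0


# -- causal planting with rejection ----------------------------------


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    proband: str
    drop: DropResult
    rejections: int


def plant_causal_variant(
    pool: FounderHaplotypePool,
    sites: Mapping[str, ChromSites],
    config: SimulationConfig,
    families: Sequence[Pedigree],
    probands: Sequence[str],
) -> list[SimulatedFamily]:
    """Write the causal allele onto a shared ancestral founder haplotype and
    gene-drop each family until its proband is homozygous for it.

    A single ancestral haplotype for the causal chromosome (carrying the
    alternate allele) is sampled once and installed as copy 0 of the
    designated founder of *each* family, with one shared origin label:
    both families' causal alleles literally descend from the same
    simulated ancestral segment.  Each family's causal chromosome is then
    re-dropped with rejection until the proband is homozygous-alternate
    and no unaffected member is (hence sequenced parents come out
    heterozygous); non-causal chromosomes need no conditioning and are
    dropped once.
    """
    causal_chrom = config.causal.chrom
    cs = sites[causal_chrom]
    if cs.causal_index < 0:
        raise SimulationError("causal site missing from the site panel")

    # one ancestral haplotype, shared by both families
    anc_rng = _rng(config, _SS_ANCESTRAL)
    alleles = np.zeros(cs.n_sites, dtype=np.int16)
    snv = ~cs.is_str
    alleles[snv] = (anc_rng.random(int(snv.sum())) < cs.freq[snv]).astype(np.int16)
    alleles[cs.is_str] = anc_rng.choice(_STR_LADDER, size=int(cs.is_str.sum()))
    alleles[cs.causal_index] = 1
    shared_label = -1  # reserved label, unique by sign
    for ped in families:
        founder = f"{ped.family_id}-{config.shared_founder}"
        if founder not in pool:
            raise SimulationError(f"shared founder {founder!r} absent from pool")
        pool[founder][causal_chrom][0] = Haplotype(
            alleles=alleles.copy(),
            origins=np.full(cs.n_sites, shared_label, dtype=np.int32),
        )

    out = []
    other_chroms = [c for c in sorted(sites) if c != causal_chrom]
    for fam_index, (ped, proband) in enumerate(zip(families, probands)):
        rng = _rng(config, _SS_DROP, extra=fam_index)
        drop = gene_drop(ped, pool, sites, config, rng, chroms=other_chroms)
        unaffected = [
            i for i, ind in ped.individuals.items() if ind.affected is not Affection.AFFECTED
        ]
        affected = ped.affected
        rejections = 0
        while True:
            causal_drop = gene_drop(ped, pool, sites, config, rng, chroms=[causal_chrom])
            geno = {
                i: int(
                    causal_drop[i][causal_chrom][0].alleles[cs.causal_index]
                    + causal_drop[i][causal_chrom][1].alleles[cs.causal_index]
                )
                for i in ped.individuals
            }
            ok = all(geno[i] == 2 for i in affected) and all(
                geno[i] != 2 for i in unaffected
            )
            if ok:
                break
            rejections += 1
            if rejections > config.rejection_cap:
                raise SimulationError(
                    f"family {ped.family_id}: rejection cap {config.rejection_cap} "
                    "exceeded while conditioning on proband homozygosity; "
                    "enlarge the autozygous target (fewer sites or stronger loop)"
                )
        for i in ped.individuals:
            drop.setdefault(i, {})[causal_chrom] = causal_drop[i][causal_chrom]
        out.append(SimulatedFamily(ped, proband, drop, rejections))
    return out


# -- dataset assembly and emission ------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sites: dict[str, ChromSites]
    families: list[SimulatedFamily]
    matrices: dict[str, GenotypeMatrix]  # family id -> sequenced-sample matrix
    annotations: pd.DataFrame
    frequency: pd.DataFrame
    control_panel: pd.DataFrame
    control_chromosomes: pd.DataFrame
    str_genotypes: pd.DataFrame

    @property
    def causal_key(self) -> VariantKey:
        return self.config.causal.key


def _genotype_states(
    fam: SimulatedFamily, sites: Mapping[str, ChromSites], samples: Sequence[str]
) -> tuple[list[VariantKey], np.ndarray]:
    keys: list[VariantKey] = []
    cols = {s: [] for s in samples}
    for chrom in sorted(sites):
        cs = sites[chrom]
        snv = ~cs.is_str
        for s in samples:
            pat, mat = fam.drop[s][chrom]
            cols[s].append((pat.alleles[snv] + mat.alleles[snv]).astype(np.int8))
        keys.extend(
            VariantKey(chrom, int(p), str(r), str(a))
            for p, r, a in zip(cs.positions[snv], cs.ref[snv], cs.alt[snv])
        )
    data = np.stack([np.concatenate(cols[s]) for s in samples], axis=1)
    return keys, data


def _sequenced_samples(fam: SimulatedFamily, trio_mode: bool) -> list[str]:
    if not trio_mode:
        return [fam.proband]
    ind = fam.pedigree[fam.proband]
    return [fam.proband, ind.father_id, ind.mother_id]


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Run the full simulation: two families, controls, annotations, STRs.

    Family F2 is sequenced as a trio (proband plus parents); family F1 as
    proband only, matching the two filtering modes of the analysis.
    """
    config.validate()
    sites = build_sites(config)
    f1 = first_cousin_family("F1")
    f2 = first_cousin_family("F2")
    probands = ["F1-IV.3", "F2-IV.3"]
    pool = sample_founder_haplotypes(config, sites, [f1, f2])
    families = plant_causal_variant(pool, sites, config, [f1, f2], probands)

    matrices: dict[str, GenotypeMatrix] = {}
    for fam in families:
        trio_mode = fam.pedigree.family_id == "F2"
        samples = _sequenced_samples(fam, trio_mode)
        keys, data = _genotype_states(fam, sites, samples)
        observed = (data > 0).any(axis=1)  # VCF lists variants seen in >=1 member
        keys = [k for k, o in zip(keys, observed) if o]
        matrices[fam.pedigree.family_id] = GenotypeMatrix(
            keys, samples, data[observed, :]
        )

    annotations = _simulate_annotations(config, sites)
    frequency = _simulate_frequency_table(config, sites)
    control_panel, control_chromosomes = _simulate_controls(config, sites)
    str_genotypes = _str_table(config, sites, families)

    return SimulatedDataset(
        config=config,
        sites=sites,
        families=families,
        matrices=matrices,
        annotations=annotations,
        frequency=frequency,
        control_panel=control_panel,
        control_chromosomes=control_chromosomes,
        str_genotypes=str_genotypes,
    )


def _simulate_annotations(
    config: SimulationConfig, sites: Mapping[str, ChromSites]
) -> pd.DataFrame:
    """Gene, region class, effect class, CDS position and predictor scores.

    The causal variant is exonic and non-synonymous with damaging scores
    drawn at ``damaging_prob_causal`` per tool; neutral variants draw
    damaging scores at ``damaging_prob_neutral`` (so the consensus rule is
    exercised without re-implementing any predictor).
    """
    rng = _rng(config, _SS_ANNOT)
    region_names = list(config.region_class_probs)
    region_p = np.array([config.region_class_probs[k] for k in region_names])
    effect_names = list(config.effect_class_probs)
    effect_p = np.array([config.effect_class_probs[k] for k in effect_names])
    rows = []
    for chrom in sorted(sites):
        cs = sites[chrom]
        snv_idx = np.flatnonzero(~cs.is_str)
        regions = rng.choice(region_names, size=len(snv_idx), p=region_p)
        effects = rng.choice(effect_names, size=len(snv_idx), p=effect_p)
        cds_pos = rng.integers(1, 1501, size=len(snv_idx))
        for gene_no, (j, i) in enumerate(zip(snv_idx, range(len(snv_idx)))):
            is_causal = j == cs.causal_index
            region = "exonic" if is_causal else str(regions[i])
            effect = "nonsynonymous_SNV" if is_causal else str(effects[i])
            gene = config.causal.gene if is_causal else f"G{chrom}_{i // 3}"
            exonic = region in ("exonic", "splice")
            p_dmg = (
                config.damaging_prob_causal if is_causal else config.damaging_prob_neutral
            )
            row = {
                "chrom": chrom,
                "pos": int(cs.positions[j]),
                "ref": str(cs.ref[j]),
                "alt": str(cs.alt[j]),
                "gene": gene,
                "region_class": region,
                "effect_class": effect if exonic else "other",
                "cds_pos": (config.causal.cds_position if is_causal else int(cds_pos[i]))
                if region == "exonic"
                else "",
            }
            if exonic:
                dmg = rng.random(4) < p_dmg
                row["sift"] = round(
                    rng.uniform(0.0, 0.0499) if dmg[0] else rng.uniform(0.05, 1.0), 4
                )
                row["polyphen2"] = round(
                    rng.uniform(0.501, 1.0) if dmg[1] else rng.uniform(0.0, 0.5), 4
                )
                row["provean"] = round(
                    rng.uniform(-8.0, -2.5) if dmg[2] else rng.uniform(-2.49, 2.0), 4
                )
                row["mutation_taster"] = (
                    "disease_causing" if dmg[3] else "polymorphism"
                )
            else:
                rng.random(4)  # keep the stream aligned across region classes
                row["sift"] = ""
                row["polyphen2"] = ""
                row["provean"] = ""
                row["mutation_taster"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def _simulate_frequency_table(
    config: SimulationConfig, sites: Mapping[str, ChromSites]
) -> pd.DataFrame:
    """dbSNP-like table: drawn site frequencies; the causal variant is absent."""
    rng = _rng(config, _SS_SITES, extra=1)
    rows = []
    for chrom in sorted(sites):
        cs = sites[chrom]
        for j in np.flatnonzero(~cs.is_str):
            if j == cs.causal_index:
                continue  # never referenced: private founder mutation
            no_freq = rng.random() < config.missing_frequency_prob
            pathogenic = rng.random() < config.pathogenic_flag_prob
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(cs.positions[j]),
                    "ref": str(cs.ref[j]),
                    "alt": str(cs.alt[j]),
                    "freq": "" if no_freq else round(float(cs.freq[j]), 6),
                    "pathogenic": int(pathogenic),
                }
            )
    return pd.DataFrame(rows)


def _simulate_controls(
    config: SimulationConfig, sites: Mapping[str, ChromSites]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unrelated controls under Hardy-Weinberg: the homozygous-variant panel
    from ``n_controls`` individuals, plus allele counts over
    ``n_control_chromosomes`` haploid control chromosomes."""
    rng = _rng(config, _SS_CONTROLS)
    panel_rows = []
    count_rows = []
    for chrom in sorted(sites):
        cs = sites[chrom]
        snv_idx = np.flatnonzero(~cs.is_str)
        freqs = cs.freq[snv_idx]
        geno = (
            rng.random((len(snv_idx), config.n_controls)) < freqs[:, None]
        ).astype(np.int8) + (
            rng.random((len(snv_idx), config.n_controls)) < freqs[:, None]
        ).astype(np.int8)
        hom_any = (geno == 2).any(axis=1)
        alt_counts = rng.binomial(config.n_control_chromosomes, freqs)
        for i, j in enumerate(snv_idx):
            rec = {
                "chrom": chrom,
                "pos": int(cs.positions[j]),
                "ref": str(cs.ref[j]),
                "alt": str(cs.alt[j]),
            }
            if hom_any[i]:
                panel_rows.append(rec)
            count_rows.append(
                {**rec, "alt_count": int(alt_counts[i]), "n_chromosomes": config.n_control_chromosomes}
            )
    return pd.DataFrame(panel_rows, columns=["chrom", "pos", "ref", "alt"]), pd.DataFrame(
        count_rows
    )


def _str_table(
    config: SimulationConfig,
    sites: Mapping[str, ChromSites],
    families: Sequence[SimulatedFamily],
) -> pd.DataFrame:
    rows = []
    for fam in families:
        for sample in sorted(fam.pedigree.individuals):
            for chrom in sorted(sites):
                cs = sites[chrom]
                for j in np.flatnonzero(cs.is_str):
                    pat, mat = fam.drop[sample][chrom]
                    rows.append(
                        {
                            "marker": str(cs.str_names[j]),
                            "chrom": chrom,
                            "position": int(cs.positions[j]),
                            "sample": sample,
                            "allele1": int(pat.alleles[j]),
                            "allele2": int(mat.alleles[j]),
                        }
                    )
    return pd.DataFrame(rows)


BUNDLE_FILES = {
    "vcf_f1": "f1.vcf",
    "vcf_f2": "f2.vcf",
    "ped_f1": "f1.ped",
    "ped_f2": "f2.ped",
    "annotations": "annotations.tsv",
    "frequency": "frequency.tsv",
    "control_panel": "control_panel.tsv",
    "control_chromosomes": "control_chromosomes.tsv",
    "str_genotypes": "str_genotypes.tsv",
    "manifest": "manifest.yaml",
}


def emit_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the full file bundle; byte-identical across runs with equal seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in BUNDLE_FILES.items()}
    try:
        for fam in ds.families:
            fid = fam.pedigree.family_id
            write_vcf(
                ds.matrices[fid],
                paths[f"vcf_{fid.lower()}"],
                contig_lengths=dict(ds.config.chrom_lengths),
            )
            write_ped(fam.pedigree, paths[f"ped_{fid.lower()}"])
        ds.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        ds.frequency.to_csv(paths["frequency"], sep="\t", index=False)
        ds.control_panel.to_csv(paths["control_panel"], sep="\t", index=False)
        ds.control_chromosomes.to_csv(paths["control_chromosomes"], sep="\t", index=False)
        ds.str_genotypes.to_csv(paths["str_genotypes"], sep="\t", index=False)
        manifest = {
            "seed": ds.config.seed,
            "files": {k: v for k, v in BUNDLE_FILES.items() if k != "manifest"},
            "probands": {f.pedigree.family_id: f.proband for f in ds.families},
            "rejections": {f.pedigree.family_id: f.rejections for f in ds.families},
            "causal": {
                "chrom": ds.config.causal.chrom,
                "pos": ds.config.causal.position,
                "ref": ds.config.causal.ref,
                "alt": ds.config.causal.alt,
                "gene": ds.config.causal.gene,
            },
        }
        paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    except OSError as exc:
        raise SimulationError(f"failed writing {exc.filename}: {exc}") from exc
    return paths


def bundle_sha256(paths: Mapping[str, Path]) -> dict[str, str]:
    return {
        k: hashlib.sha256(Path(p).read_bytes()).hexdigest() for k, p in sorted(paths.items())
    }
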
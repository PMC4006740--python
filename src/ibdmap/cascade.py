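"""Recessive-variant prioritization: the filter cascade and cross-family intersection.

The cascade mirrors the discovery strategy for a recessive disorder in
consanguineous families: under identity by descent, the causal allele is
homozygous in the proband and heterozygous in the unaffected parents, so
trio genotype filtering is applied first, then functional exclusion
(exonic/splice, protein-changing), then removal of common non-pathogenic
polymorphisms and of variants seen homozygous in an in-house control
panel.  Candidate lists from two families segregating the same phenotype
are intersected on full variant identity, and survivors are ranked by a
consensus of pathogenicity predictors.

Every filter is contractive and idempotent, and a per-stage audit report
records input/output counts and removed keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pedigree import Pedigree, Trio, extract_trio
from .variantstore import (
    HET,
    HOM_ALT,
    AnnotatedVariant,
    ExclusionDatabase,
    GenotypeMatrix,
    VariantKey,
)

__all__ = [
    "Candidate",
    "CandidateSet",
    "CascadeReport",
    "PredictorRule",
    "DEFAULT_PREDICTOR_RULES",
    "trio_ibd_filter",
    "proband_homozygous_filter",
    "region_filter",
    "effect_filter",
    "frequency_filter",
    "control_filter",
    "cross_family_intersection",
    "predictor_consensus",
    "annotate",
    "FamilyInputs",
    "run_cascade",
]

KEPT_EFFECTS = frozenset(
    {"nonsynonymous_SNV", "stopgain", "stoploss", "frameshift_indel"}
)
KEPT_REGIONS = frozenset({"exonic", "splice"})


@dataclass(frozen=True)
class Candidate:
    key: VariantKey
    annotation: Optional[AnnotatedVariant] = None
    damaging_calls: Optional[int] = None
    tools_scored: Optional[int] = None
    prioritized: bool = False


@dataclass
class CandidateSet:
    """Deterministically ordered, duplicate-free candidate list."""

    variants: list[Candidate]
    stage_label: str = ""

    def __post_init__(self):
        seen = set()
        ordered = []
        for c in sorted(self.variants, key=lambda c: c.key):
            if c.key in seen:
                raise ValueError(f"duplicate candidate key {c.key}")
            seen.add(c.key)
            ordered.append(c)
        self.variants = ordered

    def keys(self) -> list[VariantKey]:
        return [c.key for c in self.variants]

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return any(c.key == key for c in self.variants)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.variants:
            ann = c.annotation
            rows.append(
                {
                    "chrom": c.key.chrom,
                    "pos": c.key.pos,
                    "ref": c.key.ref,
                    "alt": c.key.alt,
                    "gene": ann.gene if ann else ".",
                    "region_class": ann.region_class if ann else ".",
                    "effect_class": ann.effect_class if ann else ".",
                    "damaging_calls": -1 if c.damaging_calls is None else c.damaging_calls,
                    "tools_scored": -1 if c.tools_scored is None else c.tools_scored,
                    "prioritized": int(c.prioritized),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "pos",
                "ref",
                "alt",
                "gene",
                "region_class",
                "effect_class",
                "damaging_calls",
                "tools_scored",
                "prioritized",
            ],
        )


@dataclass
class CascadeReport:
    """Per-stage audit trail: label, counts and removed keys."""

    rows: list[dict] = field(default_factory=list)

    def record(
        self,
        label: str,
        n_input: int,
        n_output: int,
        removed: Sequence[VariantKey] = (),
    ) -> None:
        if n_output != n_input - len(removed):
            raise ValueError(
                f"stage {label!r}: output {n_output} != input {n_input} - removed {len(removed)}"
            )
        self.rows.append(
            {
                "stage": label,
                "n_input": n_input,
                "n_output": n_output,
                "n_removed": len(removed),
                "removed": tuple(removed),
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in row.items() if k != "removed"} for row in self.rows],
            columns=["stage", "n_input", "n_output", "n_removed"],
        )

    def count(self, stage: str) -> int:
        for row in self.rows:
            if row["stage"] == stage:
                return row["n_output"]
        raise KeyError(f"no stage {stage!r} in report")


def _filtered(
    cands: CandidateSet,
    keep: Sequence[bool],
    label: str,
    report: Optional[CascadeReport],
) -> CandidateSet:
    kept, removed = [], []
    for c, k in zip(cands.variants, keep):
        (kept if k else removed).append(c)
    out = CandidateSet(kept, stage_label=label)
    if report is not None:
        report.record(label, len(cands), len(out), [c.key for c in removed])
    return out


# -- genotype filters -----------------------------------------------


def trio_ibd_filter(
    matrix: GenotypeMatrix,
    trio: Trio,
    report: Optional[CascadeReport] = None,
    label: str = "trio_ibd",
) -> CandidateSet:
    """Variants homozygous-alternate in the proband and heterozygous in both parents.

    A missing genotype in any trio member disqualifies the variant
    (conservative: inheritance is never fabricated).
    """
    if not trio.has_parents:
        raise ValueError(
            f"trio for proband {trio.proband!r} has no parents; use proband_homozygous_filter"
        )
    p = matrix.sample_states(trio.proband)
    f = matrix.sample_states(trio.father)
    m = matrix.sample_states(trio.mother)
    keep = (p == HOM_ALT) & (f == HET) & (m == HET)
    cands = CandidateSet([Candidate(k) for k in matrix.keys], stage_label="all")
    return _filtered(cands, list(keep), label, report)


def proband_homozygous_filter(
    matrix: GenotypeMatrix,
    proband: str,
    report: Optional[CascadeReport] = None,
    label: str = "proband_hom",
) -> CandidateSet:
    """Variants homozygous-alternate in the proband (parents unsequenced)."""
    p = matrix.sample_states(proband)
    keep = p == HOM_ALT
    cands = CandidateSet([Candidate(k) for k in matrix.keys], stage_label="all")
    return _filtered(cands, list(keep), label, report)


# -- annotation-driven filters --------------------------------------


def annotate(
    cands: CandidateSet, annotations: Mapping[VariantKey, AnnotatedVariant]
) -> CandidateSet:
    """Attach annotation records to candidates (unknown keys stay unannotated)."""
    return CandidateSet(
        [replace(c, annotation=annotations.get(c.key)) for c in cands.variants],
        stage_label=cands.stage_label,
    )


def region_filter(
    cands: CandidateSet,
    report: Optional[CascadeReport] = None,
    label: str = "exonic_splice",
) -> CandidateSet:
    """Keep exonic and splice-site variants; unannotated candidates drop."""
    keep = [
        c.annotation is not None and c.annotation.region_class in KEPT_REGIONS
        for c in cands.variants
    ]
    return _filtered(cands, keep, label, report)


def effect_filter(
    cands: CandidateSet,
    report: Optional[CascadeReport] = None,
    label: str = "protein_changing",
) -> CandidateSet:
    """Keep protein-changing classes (non-synonymous/nonsense SNVs, frameshifts).

    Splice-region variants are kept regardless of effect class; in-frame
    indels and synonymous changes drop.
    """
    keep = [
        c.annotation is not None
        and (
            c.annotation.region_class == "splice"
            or c.annotation.effect_class in KEPT_EFFECTS
        )
        for c in cands.variants
    ]
    return _filtered(cands, keep, label, report)


def frequency_filter(
    cands: CandidateSet,
    db: ExclusionDatabase,
    report: Optional[CascadeReport] = None,
    label: str = "frequency_db",
) -> CandidateSet:
    """Drop members of the common non-pathogenic exclusion database."""
    keep = [c.key not in db for c in cands.variants]
    return _filtered(cands, keep, label, report)


def control_filter(
    cands: CandidateSet,
    panel: frozenset[VariantKey] | set[VariantKey],
    report: Optional[CascadeReport] = None,
    label: str = "control_panel",
) -> CandidateSet:
    """Drop variants seen homozygous in the in-house control panel."""
    keep = [c.key not in panel for c in cands.variants]
    return _filtered(cands, keep, label, report)


def cross_family_intersection(
    set_f1: CandidateSet,
    set_f2: CandidateSet,
    report: Optional[CascadeReport] = None,
    label: str = "cross_family",
) -> CandidateSet:
    """Candidates shared by both families, matched on full variant identity."""
    keys_f1 = set(set_f1.keys())
    keep = [c.key in keys_f1 for c in set_f2.variants]
    return _filtered(set_f2, keep, label, report)


# -- predictor consensus --------------------------------------------


@dataclass(frozen=True)
class PredictorRule:
    """Damaging-call rule for one tool: comparison operator and threshold.

    ``op`` is one of ``lt``, ``le``, ``gt``, ``ge`` for numeric scores or
    ``eq`` for categorical calls (value equality, e.g. "disease_causing").
    """

    op: str
    value: Union[float, str]

    def is_damaging(self, score: Union[float, str]) -> bool:
        if self.op == "eq":
            return score == self.value
        try:
            x = float(score)
        except (TypeError, ValueError):
            return False
        t = float(self.value)
        return {
            "lt": x < t,
            "le": x <= t,
            "gt": x > t,
            "ge": x >= t,
        }[self.op]


DEFAULT_PREDICTOR_RULES: dict[str, PredictorRule] = {
    "sift": PredictorRule("lt", 0.05),
    "polyphen2": PredictorRule("gt", 0.5),
    "provean": PredictorRule("le", -2.5),
    "mutation_taster": PredictorRule("eq", "disease_causing"),
}


def predictor_consensus(
    cands: CandidateSet,
    rules: Optional[Mapping[str, PredictorRule]] = None,
    min_damaging: Optional[int] = None,
    label: str = "predictor_consensus",
) -> CandidateSet:
    """Score candidates by how many predictors call them damaging, and rank.

    Each tool with a score present is evaluated under its rule; a variant
    is flagged ``prioritized`` when its damaging-call count reaches
    ``min_damaging`` (default: every tool that scored it, i.e. unanimity).
    Variants with no scores are never prioritized.  Output is ranked by
    damaging-call count descending, ties broken by variant order.
    """
    rules = dict(DEFAULT_PREDICTOR_RULES if rules is None else rules)
    for name, rule in rules.items():
        if not isinstance(rule, PredictorRule):
            raise TypeError(f"threshold for tool {name!r} is not a PredictorRule")
        if rule.op not in {"lt", "le", "gt", "ge", "eq"}:
            raise ValueError(f"tool {name!r}: unknown comparison {rule.op!r}")
    seen_tools: set[str] = set()
    for c in cands.variants:
        if c.annotation:
            seen_tools.update(c.annotation.predictor_scores)
    if seen_tools:
        unknown = set(rules) - seen_tools - set(DEFAULT_PREDICTOR_RULES)
        if unknown:
            raise ValueError(
                f"unknown predictor tool name(s) in thresholds: {sorted(unknown)}"
            )
    scored = []
    for c in cands.variants:
        scores = c.annotation.predictor_scores if c.annotation else {}
        present = {t: s for t, s in scores.items() if t in rules}
        n_damaging = sum(1 for t, s in present.items() if rules[t].is_damaging(s))
        n_tools = len(present)
        threshold = min_damaging if min_damaging is not None else n_tools
        prioritized = n_tools > 0 and n_damaging >= threshold
        scored.append(
            replace(
                c,
                damaging_calls=n_damaging,
                tools_scored=n_tools,
                prioritized=prioritized,
            )
        )
    ranked = sorted(
        range(len(scored)), key=lambda i: (-scored[i].damaging_calls, i)
    )
    # bypass __post_init__: rank order intentionally differs from key order
    out = CandidateSet.__new__(CandidateSet)
    out.variants = [scored[i] for i in ranked]
    out.stage_label = label
    return out


def validate_predictor_rules(rules: Mapping[str, PredictorRule], known: Iterable[str]) -> None:
    """Raise when a configured tool name matches no annotation column."""
    unknown = set(rules) - set(known)
    if unknown:
        raise ValueError(f"unknown predictor tool name(s) in thresholds: {sorted(unknown)}")


# -- full pipeline --------------------------------------------------


@dataclass
class FamilyInputs:
    """Per-family genotype matrix, pedigree and proband id."""

    matrix: GenotypeMatrix
    pedigree: Pedigree
    proband: str


def _family_cascade(
    fam: FamilyInputs,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    db: ExclusionDatabase,
    panel: frozenset[VariantKey],
    report: CascadeReport,
    prefix: str,
) -> CandidateSet:
    trio = extract_trio(fam.pedigree, fam.proband)
    sequenced = set(fam.matrix.samples)
    if trio.has_parents and {trio.father, trio.mother} <= sequenced:
        cands = trio_ibd_filter(fam.matrix, trio, report, f"{prefix}:trio_ibd")
    else:
        cands = proband_homozygous_filter(
            fam.matrix, fam.proband, report, f"{prefix}:proband_hom"
        )
    cands = annotate(cands, annotations)
    cands = region_filter(cands, report, f"{prefix}:exonic_splice")
    cands = effect_filter(cands, report, f"{prefix}:protein_changing")
    cands = frequency_filter(cands, db, report, f"{prefix}:frequency_db")
    cands = control_filter(cands, panel, report, f"{prefix}:control_panel")
    return cands


def run_cascade(
    family1: FamilyInputs,
    family2: FamilyInputs,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    db: ExclusionDatabase,
    panel: frozenset[VariantKey] | set[VariantKey],
    rules: Optional[Mapping[str, PredictorRule]] = None,
    min_damaging: Optional[int] = None,
) -> tuple[CandidateSet, CascadeReport]:
    """Run the full two-family prioritization and return the ranked survivors.

    Per family: genotype filter (trio identity-by-descent where parents
    are sequenced, proband-homozygosity otherwise), exonic/splice filter,
    protein-changing filter, exclusion-database filter, control-panel
    filter; then the cross-family intersection and predictor consensus.
    The report additionally carries the raw count of variants homozygous
    in both probands before any filtering.
    """
    report = CascadeReport()
    panel = frozenset(panel)

    p1 = family1.matrix.sample_states(family1.proband)
    p2_keys = {
        k
        for k, s in zip(family2.matrix.keys, family2.matrix.sample_states(family2.proband))
        if s == HOM_ALT
    }
    n_shared_hom = sum(
        1 for k, s in zip(family1.matrix.keys, p1) if s == HOM_ALT and k in p2_keys
    )
    report.rows.append(
        {
            "stage": "shared_homozygous_prefilter",
            "n_input": n_shared_hom,
            "n_output": n_shared_hom,
            "n_removed": 0,
            "removed": (),
        }
    )

    c1 = _family_cascade(family1, annotations, db, panel, report, family1.pedigree.family_id)
    c2 = _family_cascade(family2, annotations, db, panel, report, family2.pedigree.family_id)
    final = cross_family_intersection(c1, c2, report, "cross_family")
    final = predictor_consensus(final, rules=rules, min_damaging=min_damaging)
    report.record("predictor_consensus", len(final), len(final))
    return final, report
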
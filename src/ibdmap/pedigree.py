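"""Pedigree representation, validation and relatedness coefficients.

Families are modelled as directed parent->child graphs.  Loops through
shared ancestors (consanguinity) are permitted and are exactly what the
downstream identity-by-descent analysis exploits: the offspring of a
first-cousin union has inbreeding coefficient F = 1/16, i.e. at any
autosomal locus both alleles are copies of a single ancestral allele with
probability 1/16.

Kinship ``phi(a, b)`` is the probability that one allele drawn at random
from ``a`` and one from ``b`` are identical by descent; it is computed by
the classical recursion over the pedigree with founders assumed unrelated
and non-inbred.  Inbreeding is ``F(x) = phi(father(x), mother(x))``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "Sex",
    "Affection",
    "Individual",
    "Trio",
    "Pedigree",
    "validate_pedigree",
    "kinship",
    "inbreeding",
    "extract_trio",
    "read_ped",
    "write_ped",
]


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Either both parent ids are present or neither (a founder).
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Trio:
    """Proband plus parents; ``father``/``mother`` are None in proband-only mode."""

    proband: str
    father: Optional[str]
    mother: Optional[str]

    @property
    def has_parents(self) -> bool:
        return self.father is not None and self.mother is not None


class Pedigree:
    """A named family: a collection of :class:`Individual` records."""

    def __init__(self, individuals: Iterable[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self.individuals[ind_id]
        except KeyError:
            raise KeyError(
                f"unknown individual {ind_id!r} in family {self.family_id!r}"
            ) from None

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.is_founder]

    @property
    def affected(self) -> list[str]:
        return [
            i for i, ind in self.individuals.items() if ind.affected is Affection.AFFECTED
        ]

    def graph(self) -> nx.DiGraph:
        """Parent -> child digraph (only edges whose parent resolves)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent in self.individuals:
                    g.add_edge(parent, ind.id)
        return g

    def topological_order(self) -> list[str]:
        """Founders-first ordering; ties broken lexicographically by id."""
        g = self.graph()
        try:
            return list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible:
            raise ValueError(
                f"pedigree {self.family_id!r} contains an ancestry cycle"
            ) from None

    def depths(self) -> dict[str, int]:
        """Generation depth: founders 0, child = 1 + max(parent depths)."""
        depth: dict[str, int] = {}
        for ind_id in self.topological_order():
            ind = self.individuals[ind_id]
            parents = [p for p in (ind.father_id, ind.mother_id) if p in self.individuals]
            depth[ind_id] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    # -- relatedness -------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        return kinship(self, a, b)

    def inbreeding(self, a: str) -> float:
        return inbreeding(self, a)


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Return structural issues; an empty list means the pedigree is well formed.

    Checks: parent references resolve, one-parent records, self-parenting,
    ancestry cycles, and parental sex consistency (father male / mother
    female where sexes are known).
    """
    issues: list[str] = []
    for ind in ped.individuals.values():
        n_parents = sum(p is not None for p in (ind.father_id, ind.mother_id))
        if n_parents == 1:
            issues.append(
                f"{ind.id}: exactly one parent recorded (must have both or neither)"
            )
        for role, parent_id in (("father", ind.father_id), ("mother", ind.mother_id)):
            if parent_id is None:
                continue
            if parent_id == ind.id:
                issues.append(f"{ind.id}: is its own {role}")
                continue
            if parent_id not in ped.individuals:
                issues.append(f"{ind.id}: unresolved parent {parent_id!r} ({role})")
                continue
            parent = ped.individuals[parent_id]
            want = Sex.MALE if role == "father" else Sex.FEMALE
            if parent.sex is not Sex.UNKNOWN and parent.sex is not want:
                issues.append(
                    f"{ind.id}: {role} {parent_id!r} has sex {parent.sex.value}"
                )
    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        for cyc in nx.simple_cycles(g):
            issues.append(f"{cyc[0]}: ancestry cycle through {' -> '.join(cyc)}")
    return issues


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b) by the classical pedigree recursion.

    phi(a, a) = (1 + F_a) / 2; for b not an ancestor of a,
    phi(a, b) = [phi(a, father_b) + phi(a, mother_b)] / 2.  Founders are
    unrelated and non-inbred.  The recursion always expands the argument of
    greater generation depth, which is never an ancestor of the other.
    """
    ped[a], ped[b]  # raise on unknown ids
    depth = ped.depths()
    cache: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        if depth[x] > depth[y] or (depth[x] == depth[y] and x > y):
            x, y = y, x
        key = (x, y)
        if key in cache:
            return cache[key]
        ind_y = ped.individuals[y]
        if x == y:
            if ind_y.is_founder:
                val = 0.5
            else:
                val = 0.5 * (1.0 + phi(ind_y.father_id, ind_y.mother_id))
        elif ind_y.is_founder:
            val = 0.0
        else:
            val = 0.5 * (phi(x, ind_y.father_id) + phi(x, ind_y.mother_id))
        cache[key] = val
        return val

    return phi(a, b)


def inbreeding(ped: Pedigree, a: str) -> float:
    """Inbreeding coefficient F_a = kinship of a's parents (0 for founders)."""
    ind = ped[a]
    if ind.is_founder:
        return 0.0
    return kinship(ped, ind.father_id, ind.mother_id)


def extract_trio(ped: Pedigree, proband: str) -> Trio:
    """Proband and parents, or a proband-only trio when the proband is a founder.

    A proband with exactly one recorded parent violates the individual
    invariant and raises ``ValueError``.
    """
    ind = ped[proband]
    if ind.is_founder:
        return Trio(proband, None, None)
    if ind.father_id is None or ind.mother_id is None:
        raise ValueError(
            f"{proband}: exactly one parent recorded (must have both or neither)"
        )
    return Trio(proband, ind.father_id, ind.mother_id)


# -- PED file dialect -----------------------------------------------
#
# Standard 6-column PED: family, id, father, mother, sex, phenotype.
# "0" encodes a missing parent; sex 1=male 2=female 0=unknown;
# phenotype 1=unaffected 2=affected 0/-9=unknown.

_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}
_AFF_TO_PED = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column PED file; one :class:`Pedigree` per family id."""
    families: dict[str, list[Individual]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        fam, ind_id, father, mother, sex, pheno = fields[:6]
        families.setdefault(fam, []).append(
            Individual(
                id=ind_id,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX_FROM_PED.get(sex, Sex.UNKNOWN),
                affected=_AFF_FROM_PED.get(pheno, Affection.UNKNOWN),
            )
        )
    return [Pedigree(inds, family_id=fam) for fam, inds in families.items()]


def write_ped(pedigrees: Pedigree | Iterable[Pedigree], path: str | Path) -> None:
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    lines = []
    for ped in pedigrees:
        for ind_id in sorted(ped.individuals):
            ind = ped.individuals[ind_id]
            lines.append(
                "\t".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_PED[ind.sex],
                        _AFF_TO_PED[ind.affected],
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
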
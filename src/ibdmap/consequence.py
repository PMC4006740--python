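"""Coding-sequence arithmetic and protein consequence for cDNA substitutions.

Checks HGVS-style single-base coding changes (``c.226A>G``) against a
supplied CDS and reports the protein-level consequence (``p.Asn76Asp``,
missense).  Translation uses the standard nuclear genetic code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqIO import parse as fasta_parse
from Bio.SeqUtils import seq3

__all__ = [
    "CodingChange",
    "ProteinChange",
    "codon_index",
    "codon_offset",
    "apply_substitution",
    "parse_cdna",
    "read_cds_fasta",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingChange:
    """A single-nucleotide substitution in coding coordinates (1-based)."""

    cds_position: int
    ref_base: str
    alt_base: str
    transcript: Optional[str] = None

    def __post_init__(self):
        if self.cds_position < 1:
            raise ValueError(f"cds position must be >= 1, got {self.cds_position}")
        for b in (self.ref_base, self.alt_base):
            if b not in _BASES:
                raise ValueError(f"invalid base {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref base equals alt base")

    def __str__(self) -> str:
        core = f"c.{self.cds_position}{self.ref_base}>{self.alt_base}"
        return f"{self.transcript}:{core}" if self.transcript else core


@dataclass(frozen=True)
class ProteinChange:
    residue_index: int
    ref_aa: str  # 3-letter code; "Ter" for a stop
    alt_aa: str
    category: str  # missense | nonsense | synonymous | stoploss

    def __str__(self) -> str:
        if self.category == "synonymous":
            return f"p.{self.ref_aa}{self.residue_index}="
        return f"p.{self.ref_aa}{self.residue_index}{self.alt_aa}"


def codon_index(cds_position: int) -> int:
    """1-based codon number for a 1-based coding nucleotide: ceil(pos / 3)."""
    if cds_position < 1:
        raise ValueError(f"cds position must be >= 1, got {cds_position}")
    return (cds_position + 2) // 3


def codon_offset(cds_position: int) -> int:
    """Position within the codon, in {1, 2, 3}."""
    if cds_position < 1:
        raise ValueError(f"cds position must be >= 1, got {cds_position}")
    return (cds_position - 1) % 3 + 1


def _translate_codon(codon: str) -> str:
    aa = str(Seq(codon).translate(table=1))
    return "Ter" if aa == "*" else seq3(aa)


def apply_substitution(cds_sequence: str, change: CodingChange) -> ProteinChange:
    """Apply a coding substitution and classify its protein consequence.

    The base found at ``cds_position`` must equal the stated reference base;
    a mismatch raises (guards against off-by-one coordinates and
    transcript-version drift).
    """
    seq = cds_sequence.upper()
    pos = change.cds_position
    if pos > len(seq):
        raise ValueError(
            f"cds position {pos} beyond CDS length {len(seq)}"
        )
    found = seq[pos - 1]
    if found != change.ref_base:
        raise ValueError(
            f"reference base mismatch at c.{pos}: expected {change.ref_base}, found {found}"
        )
    idx = codon_index(pos)
    start = (idx - 1) * 3
    ref_codon = seq[start : start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"incomplete codon {idx} in CDS of length {len(seq)}")
    off = codon_offset(pos) - 1
    alt_codon = ref_codon[:off] + change.alt_base + ref_codon[off + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if ref_aa == alt_aa:
        category = "synonymous"
    elif alt_aa == "Ter":
        category = "nonsense"
    elif ref_aa == "Ter":
        category = "stoploss"
    else:
        category = "missense"
    return ProteinChange(residue_index=idx, ref_aa=ref_aa, alt_aa=alt_aa, category=category)


_CDNA_RE = re.compile(r"^(?:(?P<tx>[^:]+):)?c\.(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


def parse_cdna(text: str) -> CodingChange:
    """Parse ``[transcript:]c.<pos><ref>><alt>`` (e.g. ``NM_016069:c.226A>G``)."""
    m = _CDNA_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse coding change {text!r}")
    return CodingChange(
        cds_position=int(m.group("pos")),
        ref_base=m.group("ref"),
        alt_base=m.group("alt"),
        transcript=m.group("tx"),
    )


def read_cds_fasta(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as ``(record id, sequence)``."""
    for rec in fasta_parse(str(path), "fasta"):
        return rec.id, str(rec.seq).upper()
    raise ValueError(f"{path}: no FASTA records")
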
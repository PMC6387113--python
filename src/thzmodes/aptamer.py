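"""Sequence-level bookkeeping for single-stranded DNA oligonucleotides.

Provides base composition, average molecular weight by the vendor-standard
desalted synthetic-oligo formula, and the number of monovalent counterions
needed to neutralise the phosphate backbone.  Ships the 60-nt microcystin
aptamer sequence as a packaged fixture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO

__all__ = [
    "OligoSequence",
    "base_composition",
    "molecular_weight",
    "counterion_count",
    "microcystin_aptamer",
    "MONOMER_MASS",
    "MW_OFFSET",
]

#: Average monomer masses (g/mol) for desalted synthetic ssDNA, and the
#: constant offset for a 5'-OH (no terminal phosphate) oligo:
#: MW = Σ residue masses − 61.96.  This is the convention oligo vendors quote.
MONOMER_MASS = {"A": 313.21, "T": 304.2, "C": 289.18, "G": 329.21}
MW_OFFSET = -61.96

_DECORATION = re.compile(r"^(5'?-?)|(-?3'?)$", re.IGNORECASE)


@dataclass(frozen=True)
class OligoSequence:
    """A validated single-stranded DNA sequence (A/C/G/T alphabet).

    Ingest strips whitespace and 5'-/3'- decorations and is
    case-insensitive; invalid symbols are rejected with their position.
    """

    residues: str
    name: str = field(default="")

    def __post_init__(self):
        raw = str(self.residues)
        cleaned = re.sub(r"\s+", "", raw)
        cleaned = re.sub(r"^5'?-?", "", cleaned, flags=re.IGNORECASE)
        cleaned = re.sub(r"-?3'?$", "", cleaned, flags=re.IGNORECASE)
        cleaned = cleaned.upper()
        if not cleaned:
            raise ValueError("empty oligonucleotide sequence")
        for pos, sym in enumerate(cleaned):
            if sym not in "ACGT":
                raise ValueError(
                    f"invalid residue {sym!r} at position {pos} "
                    "(alphabet is A/C/G/T)"
                )
        object.__setattr__(self, "residues", cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def base_composition(seq: OligoSequence) -> dict[str, int]:
    """Count each base; counts always sum to the sequence length."""
    s = str(seq)
    return {b: s.count(b) for b in "ACGT"}


def molecular_weight(seq: OligoSequence) -> float:
    """Average molecular weight (g/mol) of a desalted synthetic oligo.

    Uses the standard vendor formula
    MW = 313.21·nA + 304.2·nT + 289.18·nC + 329.21·nG − 61.96
    (no 5'-terminal phosphate).  Composition-only, hence
    permutation-invariant.
    """
    comp = base_composition(seq)
    return sum(MONOMER_MASS[b] * n for b, n in comp.items()) + MW_OFFSET


def counterion_count(seq: OligoSequence) -> int:
    """Number of monovalent cations neutralising the backbone.

    With no 5'-terminal phosphate an n-mer carries n−1 phosphodiester
    charges, so n−1 Na⁺ give a net-neutral system.
    """
    return len(seq) - 1


def microcystin_aptamer() -> OligoSequence:
    """The packaged 60-nt microcystin aptamer sequence."""
    ref = resources.files("thzmodes.data") / "microcystin_aptamer.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return OligoSequence(str(record.seq), name=record.id)
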
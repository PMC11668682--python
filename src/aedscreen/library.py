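"""Degenerate-codon mutagenesis library design.

Enumerates concrete codons behind IUPAC degenerate codons (NNK and friends),
translates them under the standard genetic code, and builds saturation
libraries over chosen motif positions together with their theoretical
stop-free amino-acid diversity and degenerate mutagenic oligos.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

STOP = "*"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = STOP

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-character IUPAC nucleotide pattern, e.g. NNK."""

    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) != 3:
            raise ValueError(f"degenerate codon must have 3 characters: {self.pattern!r}")
        bad = set(self.pattern.upper()) - set(IUPAC_NT)
        if bad:
            raise ValueError(f"invalid IUPAC nucleotide codes {sorted(bad)} in {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())


def expand_degenerate_codon(codon: DegenerateCodon | str) -> list[str]:
    """All concrete codons matching the pattern, sorted, duplicate-free."""
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    choices = [IUPAC_NT[ch] for ch in codon.pattern]
    return sorted("".join(p) for p in itertools.product(*choices))


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation of one concrete codon; stop is '*'."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"not a concrete ACGT codon: {codon!r}")
    return _CODON_TABLE[codon]


@dataclass
class LibraryDesign:
    """A mutagenesis library over selected positions of a parent motif."""

    parent_motif: str
    mutated_positions: list[int]
    scheme: list[DegenerateCodon]
    codon_variants: list[tuple[str, ...]] = field(default_factory=list)
    protein_variants: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def theoretical_protein_diversity(self) -> int:
        return len(self.protein_variants)

    def motif_for(self, variant: tuple[str, ...]) -> str:
        return variant_protein(
            self.parent_motif, dict(zip(self.mutated_positions, variant))
        )

    @property
    def variant_motifs(self) -> list[str]:
        return [self.motif_for(v) for v in self.protein_variants]


def variant_protein(parent_motif: str, substitutions: dict[int, str]) -> str:
    """Substitute amino acids at given 0-based motif positions."""
    residues = list(parent_motif)
    for pos, aa in substitutions.items():
        if not 0 <= pos < len(parent_motif):
            raise ValueError(f"position {pos} outside motif of length {len(parent_motif)}")
        if aa == STOP:
            raise ValueError(f"substitution to stop symbol at position {pos}")
        residues[pos] = aa
    return "".join(residues)


def design_library(
    parent_motif: str,
    mutated_positions: list[int],
    scheme: DegenerateCodon | str | list[DegenerateCodon | str] = "NNK",
) -> LibraryDesign:
    """Enumerate all codon combinations and stop-free protein variants.

    ``scheme`` may be a single degenerate codon applied at every mutated
    position or one per position.  Protein variants are unique amino-acid
    tuples (synonymous codons pooled), sorted for order stability.
    """
    bad = set(parent_motif) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid amino acids {sorted(bad)} in parent motif")
    if len(set(mutated_positions)) != len(mutated_positions):
        raise ValueError("duplicate mutated positions")
    for pos in mutated_positions:
        if not 0 <= pos < len(parent_motif):
            raise ValueError(f"mutated position {pos} outside motif")

    if not isinstance(scheme, list):
        scheme = [scheme] * len(mutated_positions)
    if len(scheme) != len(mutated_positions):
        raise ValueError("one degenerate codon required per mutated position")
    codons = [c if isinstance(c, DegenerateCodon) else DegenerateCodon(c) for c in scheme]

    expansions = [expand_degenerate_codon(c) for c in codons]
    codon_variants = sorted(itertools.product(*expansions))
    proteins = set()
    for combo in codon_variants:
        aas = tuple(translate_codon(c) for c in combo)
        if STOP not in aas:
            proteins.add(aas)
    return LibraryDesign(
        parent_motif=parent_motif,
        mutated_positions=list(mutated_positions),
        scheme=codons,
        codon_variants=codon_variants,
        protein_variants=sorted(proteins),
    )


def make_mutagenic_oligos(
    template_nt: str,
    motif_nt_span: tuple[int, int],
    scheme: dict[int, DegenerateCodon | str],
    flank_length: int = 15,
) -> list[str]:
    """Emit one degenerate oligo covering the motif span plus fixed flanks.

    ``scheme`` maps motif codon indices (0-based within the span) to the
    degenerate codon placed there; untouched codons keep the template
    sequence.  The span must be codon-aligned relative to the template frame.
    """
    template_nt = template_nt.upper()
    start, end = motif_nt_span
    if not (0 <= start < end <= len(template_nt)):
        raise ValueError("motif span outside template")
    if start % 3 or (end - start) % 3:
        raise ValueError("motif span is not codon-aligned")
    if start - flank_length < 0 or end + flank_length > len(template_nt):
        raise ValueError("flank length exceeds template bounds")

    n_codons = (end - start) // 3
    middle = []
    for i in range(n_codons):
        if i in scheme:
            codon = scheme[i]
            pattern = codon.pattern if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon).pattern
            middle.append(pattern)
        else:
            middle.append(template_nt[start + 3 * i : start + 3 * i + 3])
    oligo = (
        template_nt[start - flank_length : start]
        + "".join(middle)
        + template_nt[end : end + flank_length]
    )
    return [oligo]


def library_to_tsv(design: LibraryDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tmutated_aa\tmotif\tcodon_count\n")
        codon_counts: dict[tuple[str, ...], int] = {}
        for combo in design.codon_variants:
            aas = tuple(translate_codon(c) for c in combo)
            if STOP not in aas:
                codon_counts[aas] = codon_counts.get(aas, 0) + 1
        for i, variant in enumerate(design.protein_variants):
            fh.write(
                f"v{i:04d}\t{''.join(variant)}\t{design.motif_for(variant)}\t"
                f"{codon_counts[variant]}\n"
            )
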
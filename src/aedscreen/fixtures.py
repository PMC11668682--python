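"""Deterministic built-in germline fixture sets.

The bundled J-gene-like set plants two conserved blocks in otherwise
variable sequence: one inside the annotated CDR3 span (a decoy that motif
filtering must remove) and one just outside it with a single variable
column, shaped like the FGxGT motif at the end of real J genes.
"""

from __future__ import annotations

from pathlib import Path

from .germline import GermlineGene

# layout of the 20-residue fixture (alignment == sequence coordinates,
# the sequences are equal length and gap-free):
#   0-1   variable
#   2-6   conserved decoy block "ASSKP" (inside CDR3)
#   7-8   variable
#   9-13  F G x G T with x varying per gene
#   14-19 variable tail
_DECOY = "ASSKP"
_MOTIF = "FG.GT"
_CDR3_SPAN = (0, 8)
_VARIABLE_POOLS = {
    0: "LIVM", 1: "DENQ", 7: "KRHG", 8: "STAN",
    14: "RKQE", 15: "LIVF", 16: "TSAG", 17: "VLIA", 18: "LVMI", 19: "PQSA",
}
_X_POOL = "QSKA"


def traj_like_genes(
    n: int = 15, species: str = "synthetic", annotate: bool = True
) -> list[GermlineGene]:
    """``n`` equal-length J-gene-like sequences sharing the planted blocks."""
    genes = []
    for i in range(n):
        residues = []
        for pos in range(20):
            if 2 <= pos <= 6:
                residues.append(_DECOY[pos - 2])
            elif 9 <= pos <= 13 and pos != 11:
                residues.append(_MOTIF[pos - 9])
            elif pos == 11:
                residues.append(_X_POOL[i % len(_X_POOL)])
            else:
                pool = _VARIABLE_POOLS[pos]
                residues.append(pool[(i + pos) % len(pool)])
        seq = "".join(residues)
        annotations = [(_CDR3_SPAN[0], _CDR3_SPAN[1], "CDR3")] if annotate else None
        genes.append(GermlineGene(f"TRAJ{i + 1:02d}S", "TRAJ", species, seq, annotations))
    return genes


def write_fixture_fasta(path: str | Path, n: int = 15) -> None:
    with open(path, "w") as fh:
        for gene in traj_like_genes(n):
            fh.write(f">{gene.name}\n{gene.sequence}\n")


def write_fixture_annotations(path: str | Path, n: int = 15) -> None:
    with open(path, "w") as fh:
        for gene in traj_like_genes(n):
            for start, end, label in gene.annotations or []:
                fh.write(f"{gene.name}\t{start}\t{end}\t{label}\n")
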
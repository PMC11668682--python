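"""Germline gene alignment, conservation profiling and wildcard-motif discovery.

Workflow: read annotated germline amino-acid sequences (FASTA + BED-like
annotation TSV), build a progressive multiple alignment (UPGMA guide tree over
pairwise identity distances, exact affine-gap dynamic programming for every
pairwise/profile step), compute a per-column conservation profile, scan it for
short highly conserved windows that tolerate a bounded number of wildcard
('x') columns, and filter the resulting motifs against excluded sequence
regions (CDR spans, signalling motifs) carried on the input genes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

VALID_REGIONS = {"TRAJ", "TRAV", "TRBJ", "TRBV", "TRAC", "TRBC", "IGH-J", "IGL-J"}


class GermlineParseError(ValueError):
    """Raised when a FASTA record cannot be interpreted as a germline gene."""


@dataclass
class GermlineGene:
    """One germline amino-acid sequence with optional labelled spans.

    Annotation spans are 0-based half-open intervals on the ungapped sequence,
    stored as ``(start, end, label)``.
    """

    name: str
    region: str
    species: str
    sequence: str
    annotations: list[tuple[int, int, str]] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene {self.name!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise GermlineParseError(
                f"gene {self.name!r}: illegal residue characters {sorted(bad)}"
            )
        if self.annotations is not None:
            n = len(self.sequence)
            for start, end, label in self.annotations:
                if start < 0 or end > n or end < start:
                    raise ValueError(
                        f"gene {self.name!r}: annotation {label!r} span "
                        f"[{start}, {end}) outside sequence bounds [0, {n})"
                    )

    def spans(self, label: str) -> list[tuple[int, int]]:
        if self.annotations is None:
            return []
        return [(s, e) for s, e, lab in self.annotations if lab == label]


@dataclass
class AlignedSet:
    """A multiple alignment of a gene set.

    ``rows[i]`` is the gapped sequence of ``genes[i]``; ``column_map[i][c]``
    gives the ungapped position of alignment column ``c`` in gene ``i``, or
    ``None`` where the row carries a gap.
    """

    genes: list[GermlineGene]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")
        for gene, row in zip(self.genes, self.rows):
            if row.replace(GAP, "") != gene.sequence:
                raise ValueError(
                    f"row for gene {gene.name!r} does not degap to its sequence"
                )
        self.column_map: list[list[int | None]] = []
        for row in self.rows:
            cm: list[int | None] = []
            pos = 0
            for ch in row:
                if ch == GAP:
                    cm.append(None)
                else:
                    cm.append(pos)
                    pos += 1
            self.column_map.append(cm)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ColumnStats:
    modal_residue: str | None
    modal_frequency: float
    gap_fraction: float
    frequencies: dict[str, float]


@dataclass
class ConservationProfile:
    columns: list[ColumnStats]

    def __len__(self) -> int:
        return len(self.columns)

    def modal_frequencies(self) -> np.ndarray:
        return np.array([c.modal_frequency for c in self.columns])

    def gap_fractions(self) -> np.ndarray:
        return np.array([c.gap_fraction for c in self.columns])


@dataclass
class MotifPattern:
    """A conserved window rendered over residues plus wildcard 'x'."""

    pattern: str
    start_column: int
    conservation: list[float]
    wildcard_positions: list[int] = field(default_factory=list)
    criteria_passed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"motif pattern {self.pattern!r} shorter than 3")
        if len(self.conservation) != len(self.pattern):
            raise ValueError("conservation length must match pattern length")

    @property
    def columns(self) -> range:
        return range(self.start_column, self.start_column + len(self.pattern))


# ---------------------------------------------------------------------------
# I/O


def read_germline_fasta(
    path: str | Path, region: str, species: str
) -> list[GermlineGene]:
    """Read one FASTA file of amino-acid sequences into GermlineGene records.

    Record order is preserved; headers supply the gene names.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GermlineParseError(f"no records in {path}")
    genes = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise GermlineParseError(
                f"record {rec.id!r}: illegal residue characters {sorted(bad)}"
            )
        genes.append(GermlineGene(rec.id, region, species, seq))
    return genes


def read_annotations_tsv(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read a BED-like TSV (name, start, end, label), 0-based half-open."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path, newline="") as fh:
        for line in csv.reader(fh, delimiter="\t"):
            if not line or line[0].startswith("#"):
                continue
            name, start, end, label = line[0], int(line[1]), int(line[2]), line[3]
            out.setdefault(name, []).append((start, end, label))
    return out


def attach_annotations(
    genes: Iterable[GermlineGene], annotations: Mapping[str, list[tuple[int, int, str]]]
) -> list[GermlineGene]:
    return [
        GermlineGene(g.name, g.region, g.species, g.sequence, annotations.get(g.name))
        for g in genes
    ]


def write_alignment_fasta(aln: AlignedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, row in zip(aln.genes, aln.rows):
            fh.write(f">{gene.name}\n{row}\n")


def profile_to_tsv(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tmodal_residue\tmodal_frequency\tgap_fraction\n")
        for i, col in enumerate(profile.columns):
            modal = col.modal_residue if col.modal_residue is not None else "."
            fh.write(f"{i}\t{modal}\t{col.modal_frequency:.6g}\t{col.gap_fraction:.6g}\n")


# ---------------------------------------------------------------------------
# Alignment

_NEG_INF = float("-inf")


def _load_matrix(name: str):
    return substitution_matrices.load(name)


def _column_score(col_a: str, col_b: str, matrix) -> float:
    """Mean substitution score over residue pairs; gap-involving pairs score 0."""
    total = 0.0
    n = 0
    for ra in col_a:
        for rb in col_b:
            n += 1
            if ra != GAP and rb != GAP:
                total += matrix[ra, rb]
    return total / n


def _align_profiles(
    prof_a: list[str],
    prof_b: list[str],
    matrix,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[str]]:
    """Global affine-gap (Gotoh) alignment of two alignment profiles.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.  With
    single-sequence profiles this is exact pairwise Needleman-Wunsch; for
    wider profiles columns are scored by the mean pairwise substitution score.
    Returns the optimal score and the merged rows (A's rows first).
    """
    cols_a = ["".join(r[c] for r in prof_a) for c in range(len(prof_a[0]))]
    cols_b = ["".join(r[c] for r in prof_b) for c in range(len(prof_b[0]))]
    n, m = len(cols_a), len(cols_b)

    S = np.empty((n, m))
    for i, ca in enumerate(cols_a):
        for j, cb in enumerate(cols_b):
            S[i, j] = _column_score(ca, cb, matrix)

    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), _NEG_INF)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)

    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback
    ops: list[str] = []
    i, j = n, m
    state = max(((M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y")), key=lambda t: t[0])[1]
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            prev = max(
                ((M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"), (Y[i - 1, j - 1], "Y")),
                key=lambda t: t[0],
            )[1]
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            ops.append("X")
            cands = [(M[i - 1, j] + gap_open, "M"), (X[i - 1, j] + gap_extend, "X"),
                     (Y[i - 1, j] + gap_open, "Y")]
            state = max(cands, key=lambda t: t[0])[1]
            i -= 1
        else:
            ops.append("Y")
            cands = [(M[i, j - 1] + gap_open, "M"), (Y[i, j - 1] + gap_extend, "Y"),
                     (X[i, j - 1] + gap_open, "X")]
            state = max(cands, key=lambda t: t[0])[1]
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0 and state != "Y":
            state = "Y"
        if j == 0 and state != "X":
            state = "X"
    ops.reverse()

    rows_a = ["" for _ in prof_a]
    rows_b = ["" for _ in prof_b]
    ia = jb = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(prof_a):
                rows_a[k] += r[ia]
            for k, r in enumerate(prof_b):
                rows_b[k] += r[jb]
            ia += 1
            jb += 1
        elif op == "X":
            for k, r in enumerate(prof_a):
                rows_a[k] += r[ia]
            for k in range(len(prof_b)):
                rows_b[k] += GAP
            ia += 1
        else:
            for k in range(len(prof_a)):
                rows_a[k] += GAP
            for k, r in enumerate(prof_b):
                rows_b[k] += r[jb]
            jb += 1
    return score, rows_a + rows_b


def pairwise_align(
    seq_a: str,
    seq_b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[float, str, str]:
    """Optimal global pairwise alignment (score, gapped_a, gapped_b)."""
    matrix = _load_matrix(substitution_matrix)
    score, rows = _align_profiles([seq_a], [seq_b], matrix, gap_open, gap_extend)
    return score, rows[0], rows[1]


def _pairwise_identity(row_a: str, row_b: str) -> float:
    matches = sum(1 for a, b in zip(row_a, row_b) if a == b and a != GAP)
    return matches / len(row_a) if row_a else 0.0


def align_sequences(
    genes: Sequence[GermlineGene],
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignedSet:
    """Progressive multiple alignment over a UPGMA guide tree.

    Guide-tree distances are 1 - pairwise identity from exact pairwise
    alignments; each merge step is an exact affine-gap profile alignment.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("align_sequences requires at least one sequence")
    matrix = _load_matrix(substitution_matrix)
    if len(genes) == 1:
        return AlignedSet(genes, [genes[0].sequence])

    n = len(genes)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ra, rb = pairwise_align(
                genes[i].sequence, genes[j].sequence,
                substitution_matrix, gap_open, gap_extend,
            )
            d = 1.0 - _pairwise_identity(ra, rb)
            dist[i, j] = dist[j, i] = d

    if n == 2:
        _, rows = _align_profiles(
            [genes[0].sequence], [genes[1].sequence], matrix, gap_open, gap_extend
        )
        return AlignedSet(genes, rows)

    Z = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [genes[i].sequence]) for i in range(n)
    }
    next_id = n
    for a, b, _, _ in Z:
        idx_a, prof_a = clusters.pop(int(a))
        idx_b, prof_b = clusters.pop(int(b))
        _, rows = _align_profiles(prof_a, prof_b, matrix, gap_open, gap_extend)
        clusters[next_id] = (idx_a + idx_b, rows)
        next_id += 1

    order, rows = clusters[next_id - 1]
    ordered_rows = [None] * n
    for gene_idx, row in zip(order, rows):
        ordered_rows[gene_idx] = row
    return AlignedSet(genes, ordered_rows)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Conservation and motif discovery


def conservation_profile(aln: AlignedSet) -> ConservationProfile:
    """Per-column modal residue, frequency table over non-gap symbols, gap fraction."""
    n_rows = len(aln)
    columns: list[ColumnStats] = []
    for c in range(aln.width):
        residues = [row[c] for row in aln.rows]
        non_gap = [r for r in residues if r != GAP]
        gap_fraction = (n_rows - len(non_gap)) / n_rows
        if not non_gap:
            columns.append(ColumnStats(None, 0.0, 1.0, {}))
            continue
        counts: dict[str, int] = {}
        for r in non_gap:
            counts[r] = counts.get(r, 0) + 1
        total = len(non_gap)
        freqs = {r: k / total for r, k in counts.items()}
        # lexicographic tie-break for determinism
        modal = min(
            (r for r in freqs if freqs[r] == max(freqs.values())),
        )
        columns.append(ColumnStats(modal, freqs[modal], gap_fraction, freqs))
    return ConservationProfile(columns)


MAX_GAP_FRACTION = 0.5  # columns gappier than this cannot belong to a motif


def find_conserved_motifs(
    profile: ConservationProfile,
    k: int = 5,
    min_conservation: float = 0.85,
    max_wildcards: int = 1,
    merge: bool = True,
) -> list[MotifPattern]:
    """Scan for length-``k`` windows of conserved columns with bounded wildcards.

    A column is *conserved* when its modal frequency is at least
    ``min_conservation`` and its gap fraction at most ``MAX_GAP_FRACTION``;
    other low-gap columns may serve as wildcards ('x').  A window qualifies
    when every column is low-gap and at most ``max_wildcards`` columns are
    unconserved.  With ``merge=True`` overlapping qualifying windows are
    united into maximal runs and edge wildcards trimmed.
    """
    width = len(profile)
    if k > width:
        raise ValueError(f"window length {k} exceeds alignment width {width}")
    modal = profile.modal_frequencies()
    gaps = profile.gap_fractions()
    usable = gaps <= MAX_GAP_FRACTION
    conserved = usable & (modal >= min_conservation)

    qualifying: list[tuple[int, int]] = []
    for start in range(width - k + 1):
        window = slice(start, start + k)
        if not usable[window].all():
            continue
        if (~conserved[window]).sum() <= max_wildcards:
            qualifying.append((start, start + k))
    if not qualifying:
        return []

    if not merge:
        return [_render_motif(profile, s, e, conserved) for s, e in qualifying]

    runs: list[tuple[int, int]] = []
    cur_s, cur_e = qualifying[0]
    for s, e in qualifying[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            runs.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    runs.append((cur_s, cur_e))

    motifs = []
    for s, e in runs:
        # trim wildcard edges: motifs start and end on conserved residues
        while s < e and not conserved[s]:
            s += 1
        while e > s and not conserved[e - 1]:
            e -= 1
        if e - s >= 3:
            motifs.append(_render_motif(profile, s, e, conserved))
    return motifs


def _render_motif(
    profile: ConservationProfile, start: int, end: int, conserved: np.ndarray
) -> MotifPattern:
    pattern = []
    wildcards = []
    conservation = []
    for offset, c in enumerate(range(start, end)):
        col = profile.columns[c]
        conservation.append(col.modal_frequency)
        if conserved[c]:
            pattern.append(col.modal_residue or "x")
        else:
            pattern.append("x")
            wildcards.append(offset)
    return MotifPattern("".join(pattern), start, conservation, wildcards)


def filter_candidate_motifs(
    motifs: Sequence[MotifPattern],
    aln: AlignedSet,
    excluded_labels: set[str],
) -> list[MotifPattern]:
    """Drop motifs overlapping any excluded annotated span in any gene.

    Motif columns are mapped through each row's column map onto ungapped
    coordinates before the overlap test.  Surviving motifs record per-label
    pass flags in ``criteria_passed``.
    """
    for gene in aln.genes:
        if gene.annotations is None:
            raise ValueError(f"gene {gene.name!r} carries no annotations")

    kept: list[MotifPattern] = []
    for motif in motifs:
        passed = {label: True for label in excluded_labels}
        for gene, cmap in zip(aln.genes, aln.column_map):
            positions = {
                cmap[c] for c in motif.columns if c < len(cmap) and cmap[c] is not None
            }
            for label in excluded_labels:
                for s, e in gene.spans(label):
                    if any(s <= p < e for p in positions):
                        passed[label] = False
        if all(passed.values()):
            kept.append(
                MotifPattern(
                    motif.pattern,
                    motif.start_column,
                    motif.conservation,
                    motif.wildcard_positions,
                    {f"outside_{label}": True for label in excluded_labels}
                    | {"conserved": True},
                )
            )
    return kept
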
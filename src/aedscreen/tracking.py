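"""Amplicon read parsing, variant counting, ranking and rank trajectories.

Reads covering a mutated motif with fixed flanks are located by anchored
matching against the template, cleaned (anchor mismatches, off-target
mutations outside the targeted codons, stop codons, ambiguous bases), and
aggregated at the amino-acid level into per-population count/frequency/rank
tables from which rank trajectories and log2 enrichments are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import translate_codon

ColumnKey = tuple[str, int]  # (population, round)

_BASE_IDX = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i

_AA_BY_CODON_IDX = np.zeros(64, dtype="U1")
for _i0 in range(4):
    for _i1 in range(4):
        for _i2 in range(4):
            _codon = "ACGT"[_i0] + "ACGT"[_i1] + "ACGT"[_i2]
            _AA_BY_CODON_IDX[16 * _i0 + 4 * _i1 + _i2] = translate_codon(_codon)

FAIL_ORDER = ("low_quality", "anchor_mismatch", "ambiguous_base", "off_target_mutation", "stop_codon")


@dataclass(frozen=True)
class VariantCall:
    read_id: str
    passed: bool
    fail_reason: str | None = None
    amino_acids: tuple[str, ...] | None = None
    motif: str | None = None
    codons: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.passed and self.fail_reason is not None:
            raise ValueError("passing call cannot carry a failure reason")
        if not self.passed and self.fail_reason not in FAIL_ORDER:
            raise ValueError(f"unknown failure reason {self.fail_reason!r}")


@dataclass
class AmpliconLayout:
    """Geometry of the amplicon: template, motif span, targeted codons, anchors."""

    template_nt: str
    motif_nt_span: tuple[int, int]
    mutated_positions: list[int]  # codon indices within the motif span
    anchor_length: int = 10
    max_anchor_mismatches: int = 1
    min_quality: int = 20

    def __post_init__(self) -> None:
        start, end = self.motif_nt_span
        if start % 3 or (end - start) % 3:
            raise ValueError("motif span is not codon-aligned")
        if start - self.anchor_length < 0 or end + self.anchor_length > len(self.template_nt):
            raise ValueError("anchors do not fit around the motif span")
        self.left_anchor = self.template_nt[start - self.anchor_length : start]
        self.right_anchor = self.template_nt[end : end + self.anchor_length]
        for anchor in (self.left_anchor, self.right_anchor):
            if self.template_nt.count(anchor) != 1:
                raise ValueError(f"anchor {anchor!r} not unique in template")
        n_codons = (end - start) // 3
        for mp in self.mutated_positions:
            if not 0 <= mp < n_codons:
                raise ValueError(f"mutated codon index {mp} outside motif")
        self.parent_codons = [
            self.template_nt[start + 3 * i : start + 3 * i + 3] for i in range(n_codons)
        ]


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Minimal Phred-33 FASTQ reader returning (id, sequence, quality)."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header: {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"malformed FASTQ record {header!r}")
            out.append((header[1:].split()[0], seq, qual))
    return out


def _as_records(
    reads: str | Path | Iterable,
) -> list[tuple[str, str, str | None]]:
    if isinstance(reads, (str, Path)):
        return [(rid, seq, qual) for rid, seq, qual in read_fastq(reads)]
    records = []
    for i, item in enumerate(reads):
        if isinstance(item, str):
            records.append((f"read_{i}", item, None))
        elif len(item) == 2:
            records.append((item[0], item[1], None))
        else:
            records.append((item[0], item[1], item[2]))
    return records


def _locate(seq: str, layout: AmpliconLayout) -> int | None:
    """Offset of the motif start in the read, by near-exact left-anchor match,
    confirmed by the right anchor.  Returns None when not locatable."""
    start, end = layout.motif_nt_span
    la, ra = layout.left_anchor, layout.right_anchor
    span = end - start
    maxmm = layout.max_anchor_mismatches

    def mismatches(a: str, b: str) -> int:
        return sum(1 for x, y in zip(a, b) if x != y)

    # fast path: read laid out like the template
    expected = start
    if len(seq) >= end + layout.anchor_length:
        lmm = mismatches(seq[expected - layout.anchor_length : expected], la)
        rmm = mismatches(seq[expected + span : expected + span + layout.anchor_length], ra)
        if lmm <= maxmm and rmm <= maxmm:
            return expected
    # fallback: scan for the left anchor
    for off in range(len(seq) - layout.anchor_length - span - layout.anchor_length + 1):
        if mismatches(seq[off : off + layout.anchor_length], la) <= maxmm:
            motif_at = off + layout.anchor_length
            if (
                motif_at + span + layout.anchor_length <= len(seq)
                and mismatches(seq[motif_at + span : motif_at + span + layout.anchor_length], ra) <= maxmm
            ):
                return motif_at
    return None


def parse_reads(
    reads: str | Path | Iterable,
    layout: AmpliconLayout,
) -> list[VariantCall]:
    """Parse reads into variant calls with an exhaustive, exclusive cleaning
    rule: the first failing check in the order low-quality -> anchor ->
    ambiguous base -> off-target mutation -> stop codon labels the read."""
    start, end = layout.motif_nt_span
    n_codons = (end - start) // 3
    targeted = set(layout.mutated_positions)
    calls: list[VariantCall] = []
    for rid, seq, qual in _as_records(reads):
        if qual is not None:
            quals = [ord(q) - 33 for q in qual[start:end]]
            if quals and min(quals) < layout.min_quality:
                calls.append(VariantCall(rid, False, "low_quality"))
                continue
        motif_at = _locate(seq, layout)
        if motif_at is None:
            calls.append(VariantCall(rid, False, "anchor_mismatch"))
            continue
        motif_nt = seq[motif_at : motif_at + (end - start)]
        if set(motif_nt) - set("ACGT"):
            calls.append(VariantCall(rid, False, "ambiguous_base"))
            continue
        codons = tuple(motif_nt[3 * i : 3 * i + 3] for i in range(n_codons))
        off_target = any(
            codons[i] != layout.parent_codons[i] for i in range(n_codons) if i not in targeted
        )
        if off_target:
            calls.append(VariantCall(rid, False, "off_target_mutation"))
            continue
        aas = tuple(translate_codon(codons[i]) for i in sorted(targeted))
        if "*" in aas:
            calls.append(VariantCall(rid, False, "stop_codon"))
            continue
        motif_aa = "".join(
            aas[sorted(targeted).index(i)] if i in targeted else translate_codon(codons[i])
            for i in range(n_codons)
        )
        calls.append(VariantCall(rid, True, None, aas, motif_aa, codons))
    return calls


def tally_reads(reads: Sequence[str], layout: AmpliconLayout) -> dict[str, int]:
    """Vectorised pass-read tally at amino-acid motif level.

    Equivalent to counting passing ``parse_reads`` calls, for equal-length
    reads laid out like the template (the synthetic amplicon fast path);
    reads failing the fixed-position anchor test fall back to the full
    per-read parser.
    """
    if not reads:
        return {}
    start, end = layout.motif_nt_span
    al = layout.anchor_length
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        counts: dict[str, int] = {}
        for call in parse_reads(reads, layout):
            if call.passed:
                counts[call.motif] = counts.get(call.motif, 0) + 1
        return counts
    L = lengths.pop()
    if L < end + al:
        raise ValueError("reads do not cover the motif span plus anchors")
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(len(reads), L)

    left = np.frombuffer(layout.left_anchor.encode(), dtype=np.uint8)
    right = np.frombuffer(layout.right_anchor.encode(), dtype=np.uint8)
    lmm = (arr[:, start - al : start] != left).sum(axis=1)
    rmm = (arr[:, end : end + al] != right).sum(axis=1)
    anchored = (lmm <= layout.max_anchor_mismatches) & (rmm <= layout.max_anchor_mismatches)

    motif = arr[:, start:end]
    base_idx = _BASE_IDX[motif]
    ok = anchored & (base_idx >= 0).all(axis=1)

    n_codons = (end - start) // 3
    codon_idx = (
        16 * base_idx[:, 0::3] + 4 * base_idx[:, 1::3] + base_idx[:, 2::3]
    )  # (n_reads, n_codons); garbage where ambiguous, masked by ok
    targeted = sorted(layout.mutated_positions)
    parent_idx = np.array(
        [
            16 * _BASE_IDX[ord(c[0])] + 4 * _BASE_IDX[ord(c[1])] + _BASE_IDX[ord(c[2])]
            for c in layout.parent_codons
        ]
    )
    for i in range(n_codons):
        if i not in targeted:
            ok &= codon_idx[:, i] == parent_idx[i]
    aa = _AA_BY_CODON_IDX[np.clip(codon_idx, 0, 63)]
    for i in targeted:
        ok &= aa[:, i] != "*"

    good = aa[ok]
    if good.size == 0:
        # residual anchored-elsewhere reads handled by the slow parser
        good_motifs: dict[str, int] = {}
    else:
        uniq, counts_arr = np.unique(good.view(f"U{n_codons}").ravel(), return_counts=True)
        good_motifs = dict(zip(uniq.tolist(), counts_arr.tolist()))
    return good_motifs


@dataclass
class RankTable:
    """Per-(population, round) variant count/frequency/rank tables.

    Rank 1 is the most frequent variant; ties break lexicographically by
    amino-acid motif.
    """

    tables: dict[ColumnKey, pd.DataFrame] = field(default_factory=dict)
    empty_columns: list[ColumnKey] = field(default_factory=list)

    def add_column(self, key: ColumnKey, counts: dict[str, int]) -> None:
        counts = {v: c for v, c in counts.items() if c > 0}
        if not counts:
            self.empty_columns.append(key)
            return
        variants = sorted(counts, key=lambda v: (-counts[v], v))
        total = sum(counts.values())
        frame = pd.DataFrame(
            {
                "count": [counts[v] for v in variants],
                "frequency": [counts[v] / total for v in variants],
                "rank": np.arange(1, len(variants) + 1),
            },
            index=pd.Index(variants, name="variant"),
        )
        self.tables[key] = frame

    def column(self, key: ColumnKey) -> pd.DataFrame:
        return self.tables[key]

    def depth(self, key: ColumnKey) -> int:
        return int(self.tables[key]["count"].sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("population\tround\tvariant\tcount\tfrequency\trank\n")
            for (pop, rnd), frame in sorted(self.tables.items()):
                for variant, row in frame.iterrows():
                    fh.write(
                        f"{pop}\t{rnd}\t{variant}\t{int(row['count'])}\t"
                        f"{row['frequency']:.8g}\t{int(row['rank'])}\n"
                    )


def count_and_rank(
    calls_by_column: dict[ColumnKey, list[VariantCall]]
) -> RankTable:
    """Aggregate passing calls into a RankTable, one column per group."""
    table = RankTable()
    for key, calls in calls_by_column.items():
        counts: dict[str, int] = {}
        for call in calls:
            if call.passed:
                counts[call.motif] = counts.get(call.motif, 0) + 1
        table.add_column(key, counts)
    return table


def rank_table_from_reads(
    reads_by_column: dict[ColumnKey, Sequence[str]], layout: AmpliconLayout
) -> RankTable:
    """Fast path: tally reads per column directly into a RankTable."""
    table = RankTable()
    for key, reads in reads_by_column.items():
        table.add_column(key, tally_reads(reads, layout))
    return table


def rank_table_from_counts(counts_by_column: dict[ColumnKey, dict[str, int]]) -> RankTable:
    table = RankTable()
    for key, counts in counts_by_column.items():
        table.add_column(key, counts)
    return table


@dataclass
class TrajectoryDelta:
    delta_rank: int | None
    log2_enrichment: float
    missing_in_selected: bool


@dataclass
class RankTrajectory:
    variant: str
    entries: list[tuple[str, int, int, float]]  # (population, round, rank, frequency)
    reference: ColumnKey
    reference_rank: int
    reference_frequency: float
    deltas: dict[ColumnKey, TrajectoryDelta] = field(default_factory=dict)


def build_trajectories(
    table: RankTable,
    reference_column: ColumnKey,
    selected_columns: Sequence[ColumnKey],
) -> list[RankTrajectory]:
    """Per-variant rank trajectories and enrichments relative to a reference.

    log2 enrichment uses per-column pseudocounts eps = 1 / (2 * depth);
    variants absent from a selected column are flagged, their rank delta left
    undefined, and their enrichment computed with the pseudocount alone.
    """
    if reference_column not in table.tables:
        raise ValueError(f"reference column {reference_column} empty or missing")
    for col in selected_columns:
        if col not in table.tables:
            raise ValueError(f"selected column {col} empty or missing")

    ref = table.column(reference_column)
    eps_ref = 1.0 / (2.0 * table.depth(reference_column))
    trajectories = []
    for variant, ref_row in ref.iterrows():
        entries = []
        all_cols = sorted(
            {reference_column, *selected_columns}, key=lambda c: (c[1], c[0])
        )
        for col in all_cols:
            frame = table.column(col)
            if variant in frame.index:
                row = frame.loc[variant]
                entries.append((col[0], col[1], int(row["rank"]), float(row["frequency"])))
        deltas = {}
        for col in selected_columns:
            frame = table.column(col)
            eps_sel = 1.0 / (2.0 * table.depth(col))
            if variant in frame.index:
                row = frame.loc[variant]
                delta_rank = int(row["rank"]) - int(ref_row["rank"])
                enrich = float(
                    np.log2((row["frequency"] + eps_sel) / (ref_row["frequency"] + eps_ref))
                )
                deltas[col] = TrajectoryDelta(delta_rank, enrich, False)
            else:
                enrich = float(np.log2(eps_sel / (ref_row["frequency"] + eps_ref)))
                deltas[col] = TrajectoryDelta(None, enrich, True)
        trajectories.append(
            RankTrajectory(
                variant=str(variant),
                entries=entries,
                reference=reference_column,
                reference_rank=int(ref_row["rank"]),
                reference_frequency=float(ref_row["frequency"]),
                deltas=deltas,
            )
        )
    return trajectories


def trajectories_to_tsv(trajectories: list[RankTrajectory], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tref_rank\tref_frequency\tcolumn\tdelta_rank\t"
                 "log2_enrichment\tmissing\n")
        for t in trajectories:
            for (pop, rnd), d in sorted(t.deltas.items()):
                dr = "" if d.delta_rank is None else str(d.delta_rank)
                fh.write(
                    f"{t.variant}\t{t.reference_rank}\t{t.reference_frequency:.8g}\t"
                    f"{pop}:{rnd}\t{dr}\t{d.log2_enrichment:.6g}\t{int(d.missing_in_selected)}\n"
                )
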
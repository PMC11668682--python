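"""Decoupling-candidate calling from rank trajectories.

A candidate variant is de-enriched (frequency and rank) in the
peptide-responsive population while keeping its rank and frequency in the
bispecific-antibody-responsive population, both relative to the same
expression/binding reference sort.  The decoupling score D is the log2
enrichment difference between the two selected populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .tracking import ColumnKey, RankTrajectory


@dataclass
class SelectionThresholds:
    min_rank_drop_pep: int = 20
    max_abs_rank_change_blina: int = 20
    max_log2_enrich_pep: float = -2.0
    min_log2_enrich_blina: float = 0.0
    min_reference_frequency: float = 1.0 / 1600.0  # 1/(4 * library size) for 400

    def __post_init__(self) -> None:
        if self.min_rank_drop_pep < 0:
            raise ValueError("min_rank_drop_pep must be >= 0")
        if not 0.0 <= self.min_reference_frequency < 1.0:
            raise ValueError("min_reference_frequency must lie in [0, 1)")
        if self.max_log2_enrich_pep > 0:
            raise ValueError("max_log2_enrich_pep must be <= 0 (de-enrichment)")


@dataclass
class CandidateCall:
    variant: str
    reference_rank: int
    reference_frequency: float
    delta_rank_pep: int | None
    delta_rank_blina: int | None
    log2_enrich_pep: float
    log2_enrich_blina: float
    score: float  # D = log2_enrich_blina - log2_enrich_pep
    criteria: dict[str, bool]
    candidate_rank: int | None = None


def score_decoupling(
    trajectories: Sequence[RankTrajectory],
    pep_column: ColumnKey,
    blina_column: ColumnKey,
) -> list[CandidateCall]:
    """Score every reference-observed variant: D = e_blina - e_pep.

    Output is sorted by D descending, ties by peptide rank drop descending
    then variant name; ``candidate_rank`` is assigned over the full list.
    """
    if not trajectories:
        return []
    references = {t.reference for t in trajectories}
    if len(references) != 1:
        raise ValueError(f"trajectories mix reference columns: {sorted(references)}")
    calls = []
    for t in trajectories:
        if pep_column not in t.deltas or blina_column not in t.deltas:
            raise ValueError(
                f"trajectory for {t.variant} lacks the requested selected columns"
            )
        dp = t.deltas[pep_column]
        db = t.deltas[blina_column]
        calls.append(
            CandidateCall(
                variant=t.variant,
                reference_rank=t.reference_rank,
                reference_frequency=t.reference_frequency,
                delta_rank_pep=dp.delta_rank,
                delta_rank_blina=db.delta_rank,
                log2_enrich_pep=dp.log2_enrichment,
                log2_enrich_blina=db.log2_enrichment,
                score=db.log2_enrichment - dp.log2_enrichment,
                criteria={},
            )
        )
    calls.sort(
        key=lambda c: (
            -c.score,
            -(c.delta_rank_pep if c.delta_rank_pep is not None else 10**9),
            c.variant,
        )
    )
    for i, c in enumerate(calls, start=1):
        c.candidate_rank = i
    return calls


def call_candidates(
    scored: Sequence[CandidateCall],
    thresholds: SelectionThresholds | None = None,
    exclude_variants: set[str] | None = None,
    n_observed_pep: int | None = None,
) -> list[CandidateCall]:
    """Apply the full candidate rule and return survivors, re-ranked.

    Rules (all must hold): peptide rank drop >= ``min_rank_drop_pep``
    (a variant missing from the peptide population counts as dropped to one
    past the last observed rank); peptide log2 enrichment <=
    ``max_log2_enrich_pep``; rank degradation in the blinatumomab population
    <= ``max_abs_rank_change_blina`` (rank improvement never disqualifies;
    missing there fails); blinatumomab log2 enrichment >=
    ``min_log2_enrich_blina``; reference frequency >=
    ``min_reference_frequency``.  ``exclude_variants`` removes e.g. the
    library backbone clone from candidacy.
    """
    thresholds = thresholds or SelectionThresholds()
    exclude_variants = exclude_variants or set()
    survivors = []
    for call in scored:
        if call.variant in exclude_variants:
            continue
        if call.delta_rank_pep is not None:
            drop = call.delta_rank_pep
        elif n_observed_pep is not None:
            drop = (n_observed_pep + 1) - call.reference_rank
        else:
            drop = None
        criteria = {
            "rank_drop_pep": drop is not None and drop >= thresholds.min_rank_drop_pep,
            "deenriched_pep": call.log2_enrich_pep <= thresholds.max_log2_enrich_pep,
            # one-sided: rank degradation is bounded, improvement never
            # disqualifies
            "rank_maintained_blina": (
                call.delta_rank_blina is not None
                and call.delta_rank_blina <= thresholds.max_abs_rank_change_blina
            ),
            "not_deenriched_blina": call.log2_enrich_blina >= thresholds.min_log2_enrich_blina,
            "abundant_in_reference": call.reference_frequency >= thresholds.min_reference_frequency,
        }
        call.criteria = criteria
        if all(criteria.values()):
            survivors.append(call)
    survivors.sort(
        key=lambda c: (
            -c.score,
            -(c.delta_rank_pep if c.delta_rank_pep is not None else 10**9),
            c.variant,
        )
    )
    for i, c in enumerate(survivors, start=1):
        c.candidate_rank = i
    return survivors


def rank_improvement_report(
    trajectories: Sequence[RankTrajectory],
    columns: Sequence[ColumnKey],
) -> list[dict]:
    """Per-variant rank changes normalised by the available headroom.

    A variant starting at reference rank r can improve by at most r - 1
    ranks; normalised improvement = (r_ref - r_col) / (r_ref - 1), clipped to
    [-1, 1], and 0 when r_ref == 1 (no room to improve).
    """
    rows = []
    for t in trajectories:
        row: dict = {
            "variant": t.variant,
            "start_rank": t.reference_rank,
            "improvement_capacity": t.reference_rank - 1,
        }
        ranks = {(pop, rnd): rank for pop, rnd, rank, _ in t.entries}
        for col in columns:
            rank = ranks.get(col)
            row[f"rank_{col[0]}_{col[1]}"] = rank
            if rank is None:
                row[f"norm_improvement_{col[0]}_{col[1]}"] = None
            elif t.reference_rank == 1:
                row[f"norm_improvement_{col[0]}_{col[1]}"] = 0.0
            else:
                raw = (t.reference_rank - rank) / (t.reference_rank - 1)
                row[f"norm_improvement_{col[0]}_{col[1]}"] = max(-1.0, min(1.0, raw))
        rows.append(row)
    return rows


def candidates_to_tsv(calls: Sequence[CandidateCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "variant\tcandidate_rank\tscore\tref_rank\tref_frequency\t"
            "delta_rank_pep\tdelta_rank_blina\tlog2_enrich_pep\tlog2_enrich_blina\t"
            "criteria\n"
        )
        for c in calls:
            drp = "" if c.delta_rank_pep is None else str(c.delta_rank_pep)
            drb = "" if c.delta_rank_blina is None else str(c.delta_rank_blina)
            crit = ";".join(f"{k}={int(v)}" for k, v in sorted(c.criteria.items()))
            fh.write(
                f"{c.variant}\t{c.candidate_rank}\t{c.score:.6g}\t{c.reference_rank}\t"
                f"{c.reference_frequency:.8g}\t{drp}\t{drb}\t"
                f"{c.log2_enrich_pep:.6g}\t{c.log2_enrich_blina:.6g}\t{crit}\n"
            )
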
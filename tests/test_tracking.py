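import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aedscreen.screensim import default_template, representative_codon
from aedscreen.tracking import (
    AmpliconLayout,
    VariantCall,
    build_trajectories,
    count_and_rank,
    parse_reads,
    rank_table_from_counts,
    rank_table_from_reads,
    read_fastq,
    tally_reads,
)

TEMPLATE, SPAN = default_template("FEQWT")


@pytest.fixture()
def layout():
    return AmpliconLayout(TEMPLATE, SPAN, [1, 3])


def _read_for(motif: str, layout: AmpliconLayout) -> str:
    start, _ = layout.motif_nt_span
    seq = list(TEMPLATE)
    for mp in layout.mutated_positions:
        codon = representative_codon(motif[mp])
        seq[start + 3 * mp : start + 3 * mp + 3] = codon
    return "".join(seq)


class TestParseReads:
    def test_feqwt_read_passes(self, layout):
        start, _ = SPAN
        seq = list(TEMPLATE)
        seq[start + 3 : start + 6] = "GAA"   # E at motif codon 1
        seq[start + 9 : start + 12] = "TGG"  # W at motif codon 3
        (call,) = parse_reads(["".join(seq)], layout)
        assert call.passed
        assert call.amino_acids == ("E", "W")
        assert call.motif == "FEQWT"

    def test_anchor_mismatch_beyond_limit(self, layout):
        seq = list(_read_for("FEQWT", layout))
        start, _ = SPAN
        seq[start - 1] = "A" if seq[start - 1] != "A" else "C"
        seq[start - 2] = "A" if seq[start - 2] != "A" else "C"
        (call,) = parse_reads(["".join(seq)], layout)
        assert not call.passed
        assert call.fail_reason == "anchor_mismatch"

    def test_off_target_mutation(self, layout):
        seq = list(_read_for("FEQWT", layout))
        start, _ = SPAN
        # codon 2 (non-targeted 'Q') mutated
        seq[start + 6] = "A" if seq[start + 6] != "A" else "G"
        (call,) = parse_reads(["".join(seq)], layout)
        assert not call.passed
        assert call.fail_reason == "off_target_mutation"

    def test_stop_codon(self, layout):
        seq = list(_read_for("FEQWT", layout))
        start, _ = SPAN
        seq[start + 3 : start + 6] = "TAG"
        (call,) = parse_reads(["".join(seq)], layout)
        assert not call.passed
        assert call.fail_reason == "stop_codon"

    def test_ambiguous_base(self, layout):
        seq = list(_read_for("FEQWT", layout))
        start, _ = SPAN
        seq[start + 4] = "N"
        (call,) = parse_reads(["".join(seq)], layout)
        assert not call.passed
        assert call.fail_reason == "ambiguous_base"

    def test_low_quality_discarded(self, layout):
        seq = _read_for("FEQWT", layout)
        qual = "I" * len(seq)
        start, _ = SPAN
        bad_qual = qual[:start] + "#" + qual[start + 1 :]
        calls = parse_reads([("r1", seq, qual), ("r2", seq, bad_qual)], layout)
        assert calls[0].passed
        assert calls[1].fail_reason == "low_quality"

    def test_shifted_read_located_by_scan(self, layout):
        seq = "ACGT" + _read_for("FIQWT", layout)  # offset by 4 nt
        (call,) = parse_reads([seq], layout)
        assert call.passed
        assert call.motif == "FIQWT"

    def test_single_failure_reason(self, layout):
        # stop codon AND off-target: off-target is checked first
        seq = list(_read_for("FEQWT", layout))
        start, _ = SPAN
        seq[start + 3 : start + 6] = "TAG"
        seq[start + 6] = "A" if seq[start + 6] != "A" else "G"
        (call,) = parse_reads(["".join(seq)], layout)
        assert call.fail_reason == "off_target_mutation"

    def test_fastq_round_trip(self, layout, tmp_path):
        seq = _read_for("FAQCT", layout)
        p = tmp_path / "reads.fastq"
        p.write_text(f"@r0\n{seq}\n+\n{'I' * len(seq)}\n")
        assert read_fastq(p) == [("r0", seq, "I" * len(seq))]
        (call,) = parse_reads(p, layout)
        assert call.passed and call.motif == "FAQCT"

    def test_non_unique_anchor_rejected(self):
        bad = "AAAAAAAAAAAA" + TEMPLATE[SPAN[0] : SPAN[1]] + "AAAAAAAAAAAA"
        with pytest.raises(ValueError, match="not unique"):
            AmpliconLayout(bad, (12, 12 + (SPAN[1] - SPAN[0])), [1, 3])

    def test_call_invariant(self):
        with pytest.raises(ValueError):
            VariantCall("r", True, "stop_codon")


class TestTally:
    def test_matches_parse_reads(self, layout, rng):
        motifs = ["FEQWT", "FAQCT", "FGQGT", "FIQWT"]
        reads = [_read_for(m, layout) for m in rng.choice(motifs, size=500)]
        # throw in failures
        bad = list(reads[0])
        bad[SPAN[0] + 6] = "A" if bad[SPAN[0] + 6] != "A" else "G"
        reads.append("".join(bad))
        slow: dict[str, int] = {}
        for call in parse_reads(reads, layout):
            if call.passed:
                slow[call.motif] = slow.get(call.motif, 0) + 1
        assert tally_reads(reads, layout) == slow


class TestCountAndRank:
    def test_counts_frequencies_ranks(self):
        calls = (
            [VariantCall(f"a{i}", True, None, ("A",), "A", ("GCT",)) for i in range(5)]
            + [VariantCall(f"b{i}", True, None, ("C",), "B", ("TGT",)) for i in range(3)]
            + [VariantCall(f"c{i}", True, None, ("D",), "C", ("GAT",)) for i in range(2)]
        )
        table = count_and_rank({("POP", 1): calls})
        frame = table.column(("POP", 1))
        assert frame.loc["A", "frequency"] == 0.5
        assert frame.loc["B", "frequency"] == 0.3
        assert frame.loc["C", "frequency"] == 0.2
        assert list(frame["rank"]) == [1, 2, 3]

    def test_tie_broken_lexicographically(self):
        counts = {("POP", 1): {"FZZZT": 4, "FAAAT": 4, "FMMMT": 9}}
        table = rank_table_from_counts(counts)
        frame = table.column(("POP", 1))
        assert list(frame.index) == ["FMMMT", "FAAAT", "FZZZT"]
        assert list(frame["rank"]) == [1, 2, 3]

    def test_empty_column_flagged(self):
        table = rank_table_from_counts({("POP", 1): {}})
        assert ("POP", 1) in table.empty_columns
        assert ("POP", 1) not in table.tables

    @settings(max_examples=25, deadline=None)
    @given(
        st.dictionaries(
            st.text(alphabet="ACDEF", min_size=3, max_size=5),
            st.integers(min_value=1, max_value=1000),
            min_size=1,
            max_size=30,
        )
    )
    def test_rank_permutation_and_sum_properties(self, counts):
        table = rank_table_from_counts({("P", 1): counts})
        frame = table.column(("P", 1))
        assert sorted(frame["rank"]) == list(range(1, len(frame) + 1))
        assert frame["frequency"].sum() == pytest.approx(1.0, abs=1e-9)


class TestTrajectories:
    def _table(self):
        return rank_table_from_counts(
            {
                ("REF", 1): {"A": 50, "B": 30, "C": 20},
                ("SEL", 1): {"A": 50, "B": 30, "C": 20},
            }
        )

    def test_zero_deltas_for_identical_columns(self):
        table = self._table()
        trajs = build_trajectories(table, ("REF", 1), [("SEL", 1)])
        for t in trajs:
            d = t.deltas[("SEL", 1)]
            assert d.delta_rank == 0
            assert d.log2_enrichment == pytest.approx(0.0)

    def test_missing_variant_closed_form(self):
        table = rank_table_from_counts(
            {
                ("REF", 1): {"A": 50, "B": 50},
                ("SEL", 1): {"A": 100},
            }
        )
        trajs = {t.variant: t for t in build_trajectories(table, ("REF", 1), [("SEL", 1)])}
        d = trajs["B"].deltas[("SEL", 1)]
        assert d.missing_in_selected
        assert d.delta_rank is None
        eps_sel = 1.0 / (2 * 100)
        eps_ref = 1.0 / (2 * 100)
        assert d.log2_enrichment == pytest.approx(np.log2(eps_sel / (0.5 + eps_ref)))

    def test_missing_reference_column(self):
        table = self._table()
        with pytest.raises(ValueError):
            build_trajectories(table, ("NOPE", 1), [("SEL", 1)])

    def test_entries_ordered(self):
        table = rank_table_from_counts(
            {
                ("REF", 1): {"A": 5, "B": 3},
                ("SEL_B", 2): {"A": 5, "B": 3},
                ("SEL_A", 2): {"A": 5, "B": 3},
            }
        )
        trajs = build_trajectories(table, ("REF", 1), [("SEL_B", 2), ("SEL_A", 2)])
        for t in trajs:
            keys = [(rnd, pop) for pop, rnd, _, _ in t.entries]
            assert keys == sorted(keys)


class TestRoundTrip:
    def test_zero_error_exact(self, nnk_library, amplicon):
        from aedscreen.screensim import ScreenConfig, assign_phenotypes, emit_reads, run_screen

        template, span, layout = amplicon
        ph = assign_phenotypes(nnk_library, seed=6)
        sc = run_screen(nnk_library, ph, ScreenConfig(rounds=1, cells_per_round=10_000), seed=6)
        reads = emit_reads(
            sc, nnk_library, template, span, error_rate=0.0,
            reads_per_population=20_000, seed=7,
            populations=[("DEX_CD3", 1), ("PEP_GFPhigh", 1)],
        )
        table = rank_table_from_reads(reads, layout)
        for key in [("DEX_CD3", 1), ("PEP_GFPhigh", 1)]:
            sim = sc.frequencies(*key)
            sim = sim[sim > 0]
            frame = table.column(key)
            assert set(frame.index) == set(sim.index)
            for v in frame.index:
                assert frame.loc[v, "frequency"] == pytest.approx(sim[v], abs=1e-12)
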
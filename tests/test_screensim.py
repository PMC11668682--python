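import numpy as np
import pandas as pd
import pytest

from aedscreen import screensim
from aedscreen.screensim import (
    GateSpec,
    PhenotypeConfig,
    ScreenConfig,
    VariantPhenotype,
    assign_phenotypes,
    default_template,
    emit_reads,
    run_screen,
    simulate_sort,
)
from aedscreen.tracking import AmpliconLayout, parse_reads


def _uniform_phenotypes(library, expression=1.0, dex=1.0, pep=0.5, blina=0.5):
    return {
        m: VariantPhenotype(m, expression, dex, pep, blina, False)
        for m in library.variant_motifs
    }


class TestAssignPhenotypes:
    def test_deterministic(self, nnk_library):
        a = assign_phenotypes(nnk_library, seed=11)
        b = assign_phenotypes(nnk_library, seed=11)
        assert a == b

    def test_exactly_five_planted(self, nnk_library):
        ph = assign_phenotypes(nnk_library, PhenotypeConfig(n_planted_decoupled=5), seed=2)
        assert sum(p.is_decoupled for p in ph.values()) == 5

    def test_planted_satisfy_thresholds(self, nnk_library):
        cfg = PhenotypeConfig()
        ph = assign_phenotypes(nnk_library, cfg, seed=3)
        for p in ph.values():
            in_corner = (
                p.peptide_response <= cfg.peptide_low
                and p.blina_response >= cfg.blina_high
                and p.expression >= cfg.expression_min
            )
            assert in_corner == p.is_decoupled

    def test_planted_count_exceeds_library(self, nnk_library):
        with pytest.raises(ValueError):
            assign_phenotypes(
                nnk_library, PhenotypeConfig(n_planted_decoupled=401), seed=0
            )

    def test_response_correlation(self, nnk_library):
        cfg = PhenotypeConfig()
        cors = []
        for seed in range(20):
            ph = assign_phenotypes(nnk_library, cfg, seed=seed)
            vals = np.array(
                [
                    (p.peptide_response, p.blina_response)
                    for p in ph.values()
                    if not p.is_decoupled
                ]
            )
            cors.append(np.corrcoef(vals[:, 0], vals[:, 1])[0, 1])
        assert abs(np.mean(cors) - cfg.response_correlation) <= 0.15


class TestSimulateSort:
    def test_zero_expression_never_passes(self, nnk_library):
        ph = _uniform_phenotypes(nnk_library, expression=0.0)
        counts = pd.Series(100, index=nnk_library.variant_motifs)
        for gate in ("DEX_CD3", "PEP_GFPhigh", "BLINA_GFPhigh"):
            passed, failed = simulate_sort(counts, GateSpec(gate, 1.0), ph, seed=0)
            assert (passed == 0).all()
            assert (failed == counts).all()

    def test_pi_one_all_pass(self, nnk_library):
        ph = _uniform_phenotypes(nnk_library, expression=1.0, dex=1.0)
        counts = pd.Series(57, index=nnk_library.variant_motifs)
        passed, failed = simulate_sort(counts, GateSpec("DEX_CD3"), ph, seed=0)
        assert (passed == counts).all()
        assert (failed == 0).all()

    def test_conservation_of_cells(self, nnk_library, rng):
        ph = assign_phenotypes(nnk_library, seed=5)
        counts = pd.Series(
            rng.integers(0, 500, size=len(nnk_library.variant_motifs)),
            index=nnk_library.variant_motifs,
        )
        for gate in screensim.POPULATIONS:
            passed, failed = simulate_sort(counts, GateSpec(gate, 1.0), ph, seed=1)
            assert ((passed + failed) == counts).all()
            assert (passed >= 0).all() and (failed >= 0).all()

    def test_binomial_tail(self, nnk_library):
        # pi = 0.3 via expression 0.6 x dextramer 0.5; input 10,000
        ph = _uniform_phenotypes(nnk_library, expression=0.6, dex=0.5)
        counts = pd.Series(0, index=nnk_library.variant_motifs)
        counts.iloc[0] = 10_000
        sd = np.sqrt(10_000 * 0.3 * 0.7)
        hits = 0
        for seed in range(200):
            passed, _ = simulate_sort(counts, GateSpec("DEX_CD3"), ph, seed=seed)
            hits += abs(passed.iloc[0] - 3000) <= 3 * sd
        assert hits >= 198  # >= 99% of seeds

    def test_unknown_gate(self):
        with pytest.raises(ValueError):
            GateSpec("NOT_A_GATE")


class TestRunScreen:
    def test_lineage_three_rounds_five_populations(self, nnk_library):
        ph = assign_phenotypes(nnk_library, seed=1)
        sc = run_screen(nnk_library, ph, ScreenConfig(cells_per_round=20_000), seed=1)
        assert len(sc.lineage) == 3 * 5
        assert sc.counts.shape == (400, 15)

    def test_all_pass_single_round(self, nnk_library):
        ph = _uniform_phenotypes(nnk_library, expression=1.0, dex=1.0)
        cfg = ScreenConfig(rounds=1, cells_per_round=50_000, abundance_sigma=0.0,
                           backbone_boost=1.0)
        sc = run_screen(nnk_library, ph, cfg, seed=0)
        # DEX gate has pi = 1: the sorted column equals the starting population
        assert sc.column("DEX_CD3", 1).sum() == 50_000

    def test_rounds_must_be_positive(self, nnk_library):
        ph = assign_phenotypes(nnk_library, seed=0)
        with pytest.raises(ValueError):
            run_screen(nnk_library, ph, ScreenConfig(rounds=0), seed=0)

    def test_determinism(self, nnk_library):
        ph = assign_phenotypes(nnk_library, seed=4)
        cfg = ScreenConfig(cells_per_round=20_000)
        a = run_screen(nnk_library, ph, cfg, seed=9)
        b = run_screen(nnk_library, ph, cfg, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_planted_enrich_through_rounds(self, nnk_library):
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            ph = assign_phenotypes(nnk_library, seed=seed)
            sc = run_screen(nnk_library, ph, ScreenConfig(cells_per_round=50_000), seed=seed)
            planted = [v for v, p in ph.items() if p.is_decoupled]
            freqs = [sc.frequencies("PEP_GFPlow", r)[planted].sum() for r in (1, 2, 3)]
            ok += freqs[0] <= freqs[1] <= freqs[2]
        assert ok >= 0.9 * n_seeds

    def test_frequencies_normalize(self, nnk_library):
        ph = assign_phenotypes(nnk_library, seed=2)
        sc = run_screen(nnk_library, ph, ScreenConfig(cells_per_round=20_000), seed=2)
        for pop, rnd in sc.counts.columns:
            total = sc.frequencies(pop, rnd).sum()
            assert total == pytest.approx(1.0, abs=1e-9)


class TestEmitReads:
    def test_zero_error_round_trip(self, nnk_library, amplicon):
        template, span, layout = amplicon
        ph = assign_phenotypes(nnk_library, seed=1)
        sc = run_screen(nnk_library, ph, ScreenConfig(rounds=1, cells_per_round=5_000), seed=1)
        reads = emit_reads(
            sc, nnk_library, template, span, error_rate=0.0,
            reads_per_population=10_000, seed=3, populations=[("DEX_CD3", 1)],
        )[("DEX_CD3", 1)]
        calls = parse_reads(reads, layout)
        assert all(c.passed for c in calls)
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.motif] = counts.get(c.motif, 0) + 1
        expected = sc.column("DEX_CD3", 1)
        assert counts == {v: int(n) for v, n in expected.items() if n > 0}

    def test_error_fraction_binomial(self, nnk_library, amplicon):
        template, span, layout = amplicon
        rate, depth = 0.001, 100_000
        counts = pd.Series(0, index=nnk_library.variant_motifs)
        counts[nnk_library.parent_motif] = depth
        rng = np.random.default_rng(12)
        reads = screensim.variant_reads(
            counts, nnk_library, template, span, depth, rate, None, rng
        )
        n_err = sum(r != template for r in reads)
        L = len(template)
        p_any = 1 - (1 - rate) ** L
        sd = np.sqrt(depth * p_any * (1 - p_any))
        assert abs(n_err - depth * p_any) <= 3 * sd

    def test_empty_column_empty_fastq(self, nnk_library, amplicon, tmp_path):
        template, span, _ = amplicon
        frame = pd.DataFrame(
            {("DEX_CD3", 1): pd.Series(0, index=nnk_library.variant_motifs)}
        )
        frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["population", "round"])
        sc = screensim.ScreenCounts(frame, [(1, "DEX_CD3")])
        out = emit_reads(sc, nnk_library, template, span, out_dir=tmp_path)
        assert out[("DEX_CD3", 1)] == []
        assert (tmp_path / "1_DEX_CD3.fastq").read_text() == ""

    def test_read_length_too_short(self, nnk_library, amplicon):
        template, span, _ = amplicon
        counts = pd.Series(10, index=nnk_library.variant_motifs)
        with pytest.raises(ValueError):
            screensim.variant_reads(
                counts, nnk_library, template, span, 100, 0.0,
                span[1] - 1, np.random.default_rng(0),
            )

    def test_determinism(self, nnk_library, amplicon):
        template, span, _ = amplicon
        ph = assign_phenotypes(nnk_library, seed=1)
        sc = run_screen(nnk_library, ph, ScreenConfig(rounds=1, cells_per_round=2_000), seed=1)
        kw = dict(error_rate=0.001, reads_per_population=2_000, seed=8,
                  populations=[("DEX_CD3", 1)])
        a = emit_reads(sc, nnk_library, template, span, **kw)
        b = emit_reads(sc, nnk_library, template, span, **kw)
        assert a == b


def test_default_template_encodes_parent():
    template, (start, end) = default_template("FEQWT")
    from aedscreen.library import translate_codon

    aa = "".join(
        translate_codon(template[i : i + 3]) for i in range(start, end, 3)
    )
    assert aa == "FEQWT"
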
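"""Synthetic three-round FACS sort-seq screen simulator.

Generates ground-truth per-variant phenotypes for an NNK library, pushes a
cell population through expression/binding and reporter gates with binomial
sorting noise, carries the low-responder fraction forward between rounds, and
emits amplicon reads with substitution sequencing error.  Every stage is
deterministic under a fixed seed, which makes the simulator usable as an
oracle for the downstream tracking and candidate-calling code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .library import LibraryDesign, expand_degenerate_codon, translate_codon

POPULATIONS = ("DEX_CD3", "PEP_GFPhigh", "PEP_GFPlow", "BLINA_GFPhigh", "BLINA_GFPlow")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class VariantPhenotype:
    variant: str
    expression: float
    dextramer_binding: float
    peptide_response: float
    blina_response: float
    is_decoupled: bool

    def __post_init__(self) -> None:
        for name in ("expression", "dextramer_binding", "peptide_response", "blina_response"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GateSpec:
    name: str
    stimulus: float = 0.0
    round_index: int = 1

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown gate {self.name!r}; expected one of {POPULATIONS}")
        if self.round_index < 1:
            raise ValueError("round index must be >= 1")


@dataclass
class PhenotypeConfig:
    """Latent phenotype model: planted decoupled variants, non-expressors,
    and correlated Beta-distributed responses for the rest."""

    n_planted_decoupled: int = 5
    peptide_low: float = 0.1      # decoupled: peptide_response <= this
    blina_high: float = 0.8       # decoupled: blina_response >= this
    expression_min: float = 0.6   # decoupled: expression >= this
    nonexpressor_fraction: float = 0.05
    # non-planted variants are kept out of the low-peptide/high-blina corner
    # (pep < margin_peptide and blina > margin_blina) so the planted ground
    # truth is unambiguous
    margin_peptide: float = 0.25
    margin_blina: float = 0.5
    response_beta: tuple[float, float] = (5.0, 5.0)
    expression_beta: tuple[float, float] = (8.0, 2.0)
    dextramer_beta: tuple[float, float] = (8.0, 2.0)
    response_correlation: float = 0.6


@dataclass
class ScreenConfig:
    rounds: int = 3
    cells_per_round: int = 200_000
    reads_per_population: int = 100_000
    abundance_sigma: float = 0.8   # log-normal skew of the starting library
    backbone_boost: float = 5.0    # abundance multiplier for the parent clone
    peptide_conc: float = 0.1      # µg/ml
    blina_conc: float = 12.0       # ng/ml
    peptide_ec50: float = 0.05
    blina_ec50: float = 4.0
    hill: float = 1.5
    error_rate: float = 0.001
    phenotypes: PhenotypeConfig = field(default_factory=PhenotypeConfig)


@dataclass
class ScreenCounts:
    """Variant x (population, round) integer count matrix."""

    counts: pd.DataFrame  # index: variant motif, columns: MultiIndex (population, round)
    lineage: list[tuple[int, str]]

    def column(self, population: str, round_index: int) -> pd.Series:
        return self.counts[(population, round_index)]

    def frequencies(self, population: str, round_index: int) -> pd.Series:
        col = self.column(population, round_index)
        total = col.sum()
        return col / total if total else col.astype(float)


def assign_phenotypes(
    library: LibraryDesign, config: PhenotypeConfig | None = None, seed: int = 0
) -> dict[str, VariantPhenotype]:
    """Draw one VariantPhenotype per library variant, deterministic per seed.

    A configured number of planted decoupled variants get low peptide
    response, high blinatumomab response and high expression; a fraction of
    the remainder are non-expressors; everyone else draws correlated
    (Gaussian-copula) Beta responses.  Non-planted variants falling into a
    margin around the decoupled phenotype corner have their peptide response
    resampled upwards, so the ground-truth flag marks exactly the planted
    set with a clear phenotypic moat around it.
    """
    config = config or PhenotypeConfig()
    motifs = library.variant_motifs
    n = len(motifs)
    if n == 0:
        raise ValueError("empty library")
    if config.n_planted_decoupled > n - 1:
        raise ValueError("more planted decoupled variants than library size allows")
    rng = np.random.default_rng(seed)

    backbone = library.parent_motif
    candidates = [i for i, m in enumerate(motifs) if m != backbone]
    planted = set(
        rng.choice(candidates, size=config.n_planted_decoupled, replace=False).tolist()
    )
    rest = [i for i in range(n) if i not in planted and motifs[i] != backbone]
    n_nonexpr = int(round(config.nonexpressor_fraction * len(rest)))
    nonexpr = set(rng.choice(rest, size=n_nonexpr, replace=False).tolist()) if n_nonexpr else set()

    rho = config.response_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    a, b = config.response_beta
    pep = stats.beta.ppf(u[:, 0], a, b)
    blina = stats.beta.ppf(u[:, 1], a, b)
    ea, eb = config.expression_beta
    expression = rng.beta(ea, eb, size=n)
    da, db = config.dextramer_beta
    dex = rng.beta(da, db, size=n)

    for i in nonexpr:
        expression[i] = rng.beta(1.0, 30.0)
    for i in planted:
        pep[i] = rng.uniform(0.01, 0.7 * config.peptide_low)
        blina[i] = rng.uniform(max(config.blina_high, 0.85), 0.98)
        expression[i] = rng.uniform(max(config.expression_min, 0.75), 0.95)
        dex[i] = rng.uniform(0.7, 0.95)

    # keep ground truth unambiguous: push non-planted variants out of a
    # margin around the decoupled phenotype corner
    for i in range(n):
        if i in planted:
            continue
        if pep[i] < config.margin_peptide and blina[i] > config.margin_blina:
            pep[i] = rng.uniform(config.margin_peptide + 0.05, 0.7)

    phenotypes = {}
    for i, motif in enumerate(motifs):
        phenotypes[motif] = VariantPhenotype(
            variant=motif,
            expression=float(np.clip(expression[i], 0, 1)),
            dextramer_binding=float(np.clip(dex[i], 0, 1)),
            peptide_response=float(np.clip(pep[i], 0, 1)),
            blina_response=float(np.clip(blina[i], 0, 1)),
            is_decoupled=i in planted,
        )
    return phenotypes


def _dose_scale(stimulus: float, ec50: float, hill: float) -> float:
    if stimulus <= 0:
        return 0.0
    s = stimulus**hill
    return s / (s + ec50**hill)


def gate_pass_probability(
    phenotype: VariantPhenotype, gate: GateSpec, config: ScreenConfig
) -> float:
    """Multiplicative gate-passage model: expression x (scaled) response."""
    e = phenotype.expression
    if gate.name == "DEX_CD3":
        return e * phenotype.dextramer_binding
    if gate.name in ("PEP_GFPhigh", "PEP_GFPlow"):
        p = e * _dose_scale(gate.stimulus, config.peptide_ec50, config.hill) * phenotype.peptide_response
        return p if gate.name == "PEP_GFPhigh" else 1.0 - p
    if gate.name in ("BLINA_GFPhigh", "BLINA_GFPlow"):
        p = e * _dose_scale(gate.stimulus, config.blina_ec50, 1.0) * phenotype.blina_response
        return p if gate.name == "BLINA_GFPhigh" else 1.0 - p
    raise ValueError(f"unknown gate {gate.name!r}")


def simulate_sort(
    input_counts: pd.Series,
    gate: GateSpec,
    phenotypes: dict[str, VariantPhenotype],
    seed: int = 0,
    config: ScreenConfig | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Binomial sort of each variant through one gate: (pass, fail) counts.

    pass + fail == input exactly, per variant.
    """
    config = config or ScreenConfig()
    if (input_counts < 0).any():
        raise ValueError("negative input counts")
    rng = np.random.default_rng(seed)
    pis = np.array(
        [gate_pass_probability(phenotypes[v], gate, config) for v in input_counts.index]
    )
    pis = np.clip(pis, 0.0, 1.0)
    passed = rng.binomial(input_counts.to_numpy(), pis)
    pass_counts = pd.Series(passed, index=input_counts.index)
    return pass_counts, input_counts - pass_counts


def initial_population(
    library: LibraryDesign, config: ScreenConfig, seed: int
) -> pd.Series:
    """Log-normally skewed starting abundances, parent clone boosted."""
    rng = np.random.default_rng(seed)
    motifs = library.variant_motifs
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(motifs))
    for i, m in enumerate(motifs):
        if m == library.parent_motif:
            weights[i] *= config.backbone_boost
    probs = weights / weights.sum()
    cells = rng.multinomial(config.cells_per_round, probs)
    return pd.Series(cells, index=motifs)


def run_screen(
    library: LibraryDesign,
    phenotypes: dict[str, VariantPhenotype],
    config: ScreenConfig | None = None,
    seed: int = 0,
) -> ScreenCounts:
    """Run the multi-round screen: DEX/CD3 gate first, then peptide and
    blinatumomab reporter gates on the gated cells; the peptide GFP-low
    output seeds the next round (with regrowth to the configured depth)."""
    config = config or ScreenConfig()
    if config.rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    motifs = library.variant_motifs

    current = initial_population(library, config, seed=int(rng.integers(2**31)))
    columns: dict[tuple[str, int], pd.Series] = {}
    lineage: list[tuple[int, str]] = []

    for r in range(1, config.rounds + 1):
        dex_pass, _ = simulate_sort(
            current, GateSpec("DEX_CD3", round_index=r), phenotypes,
            seed=int(rng.integers(2**31)), config=config,
        )
        pep_high, pep_low = simulate_sort(
            dex_pass, GateSpec("PEP_GFPhigh", config.peptide_conc, r), phenotypes,
            seed=int(rng.integers(2**31)), config=config,
        )
        bl_high, bl_low = simulate_sort(
            dex_pass, GateSpec("BLINA_GFPhigh", config.blina_conc, r), phenotypes,
            seed=int(rng.integers(2**31)), config=config,
        )
        for pop, counts in zip(
            POPULATIONS, (dex_pass, pep_high, pep_low, bl_high, bl_low)
        ):
            columns[(pop, r)] = counts
            lineage.append((r, pop))

        if r < config.rounds:
            total = pep_low.sum()
            if total == 0:
                raise RuntimeError(f"peptide GFP-low population empty after round {r}")
            probs = pep_low.to_numpy() / total
            regrown = rng.multinomial(config.cells_per_round, probs)
            current = pd.Series(regrown, index=motifs)

    frame = pd.DataFrame(columns)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["population", "round"])
    return ScreenCounts(counts=frame, lineage=lineage)


# ---------------------------------------------------------------------------
# Read emission


def default_template(parent_motif: str = "FEQWT", flank: int = 21, seed: int = 7) -> tuple[str, tuple[int, int]]:
    """A synthetic amplicon template: random fixed flanks around the parent
    motif's codons.  Returns (template, motif nucleotide span)."""
    rng = np.random.default_rng(seed)
    codons = "".join(representative_codon(aa) for aa in parent_motif)
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
    return left + codons + right, (flank, flank + len(codons))


_REPRESENTATIVE: dict[str, str] = {}
for _codon in expand_degenerate_codon("NNK"):
    _aa = translate_codon(_codon)
    _REPRESENTATIVE.setdefault(_aa, _codon)


def representative_codon(aa: str) -> str:
    """A fixed NNK codon encoding the given amino acid (lexicographically first)."""
    try:
        return _REPRESENTATIVE[aa]
    except KeyError:
        raise ValueError(f"no NNK codon encodes {aa!r}") from None


def variant_reads(
    column_counts: pd.Series,
    library: LibraryDesign,
    template_nt: str,
    motif_nt_span: tuple[int, int],
    n_reads: int,
    error_rate: float,
    read_length: int | None,
    rng: np.random.Generator,
) -> list[str]:
    """Sample reads for one sorted population (vectorised).

    Each read is the template with the variant's codons substituted at the
    mutated positions, truncated to ``read_length``, with i.i.d. substitution
    errors at ``error_rate``.
    """
    start, end = motif_nt_span
    L = read_length if read_length is not None else len(template_nt)
    if L < end:
        raise ValueError("read length does not cover the motif span")
    total = int(column_counts.sum())
    if total == 0 or n_reads == 0:
        return []
    # reads sample cells without replacement: with depth >= column total the
    # emitted reads reproduce the sorted-cell counts exactly
    depth = min(n_reads, total)
    per_variant = rng.multivariate_hypergeometric(
        column_counts.to_numpy(dtype=np.int64), depth
    )

    template = np.frombuffer(template_nt[:L].encode(), dtype=np.uint8)
    reads = np.tile(template, (depth, 1))

    mut_pos = library.mutated_positions
    row = 0
    for counts_i, motif in zip(per_variant, column_counts.index):
        if counts_i == 0:
            continue
        block = slice(row, row + counts_i)
        for mp in mut_pos:
            codon = representative_codon(motif[mp])
            cstart = start + 3 * mp
            reads[block, cstart : cstart + 3] = np.frombuffer(codon.encode(), dtype=np.uint8)
        row += counts_i

    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        if err.any():
            idx = np.searchsorted(_BASES, reads[err])
            shift = rng.integers(1, 4, size=idx.shape)
            reads[err] = _BASES[(idx + shift) % 4]

    order = rng.permutation(depth)
    return ["".join(map(chr, r)) for r in reads[order]]


def emit_reads(
    counts: ScreenCounts,
    library: LibraryDesign,
    template_nt: str,
    motif_nt_span: tuple[int, int],
    error_rate: float = 0.001,
    read_length: int | None = None,
    reads_per_population: int = 100_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    populations: list[tuple[str, int]] | None = None,
) -> dict[tuple[str, int], list[str]]:
    """Emit synthetic amplicon reads per (population, round) column.

    Returns reads in memory keyed by column; when ``out_dir`` is given also
    writes Phred-33 FASTQ files named ``{round}_{population}.fastq`` with a
    constant 'I' quality line.
    """
    rng = np.random.default_rng(seed)
    cols = populations or [(p, r) for (p, r) in counts.counts.columns]
    out: dict[tuple[str, int], list[str]] = {}
    for pop, rnd in cols:
        col = counts.column(pop, rnd)
        reads = variant_reads(
            col, library, template_nt, motif_nt_span,
            reads_per_population, error_rate, read_length, rng,
        )
        out[(pop, rnd)] = reads
        if out_dir is not None:
            path = Path(out_dir) / f"{rnd}_{pop}.fastq"
            with open(path, "w") as fh:
                for i, seq in enumerate(reads):
                    fh.write(f"@{pop}_{rnd}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return out


def ground_truth_tsv(phenotypes: dict[str, VariantPhenotype], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant\texpression\tdextramer_binding\tpeptide_response\t"
                 "blina_response\tis_decoupled\n")
        for v in phenotypes.values():
            fh.write(
                f"{v.variant}\t{v.expression:.6g}\t{v.dextramer_binding:.6g}\t"
                f"{v.peptide_response:.6g}\t{v.blina_response:.6g}\t{int(v.is_decoupled)}\n"
            )
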
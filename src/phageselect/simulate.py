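"""Synthetic NNK selection simulator.

Generates a desk-scale naïve 9-mer NNK library and multiplicative
selection rounds with composition-dependent fitness, then emits FASTQ
reads, so the whole decode → statistics → clustering pipeline can be run
and validated without real sequencing data. Selection pressure is a
log-linear fitness in three composition features — an N-terminal-Met
bonus, a per-cysteine penalty and a per-cationic-residue penalty — the
qualitative signature reported for cathepsin-based cytoplasmic-entry
selections (N-term-Met clusters expand to majority; Cys-containing and
multi-cationic clusters are depleted).

All randomness flows from user-supplied seeds through
``numpy.random.SeedSequence`` spawning, so every output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codons import (
    AMBER_CODON,
    AmberPolicy,
    NNKCodonTable,
    STOP_SYMBOL,
    build_nnk_codon_table,
)
from .count_table import PeptideCountTable, write_sample_sheet

#: Default flanks bracketing the NNK insert in each read. The upstream flank
#: is an SfiI cloning-site sequence, the downstream flank encodes the start
#: of a Gly-Gly-Gly-Ser linker — placeholders with the right structure; real
#: amplicon designs supply their own.
DEFAULT_FLANK5 = "GCCCAGCCGGCC"
DEFAULT_FLANK3 = "GGTGGAGGCTCT"

CATIONIC = ("K", "R")


@dataclass(frozen=True)
class NNKLibrarySpec:
    """Design of the synthetic naïve library and its amplicon structure."""

    peptide_length: int = 9
    pool_size: int = 50_000
    amber_policy: AmberPolicy = AmberPolicy.SUPPRESS_TO_Q
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for flank in (self.flank5, self.flank3):
            if set(flank) - set("ACGT"):
                raise ValueError(f"flank {flank!r} contains non-ACGT characters")

    @property
    def insert_length(self) -> int:
        return 3 * self.peptide_length


@dataclass(frozen=True)
class FitnessModel:
    """Log-linear composition-dependent per-round fitness.

    log w = intercept + beta_nterm_met * [position 1 is M]
          + beta_cys * (#C) + beta_cation * (#K + #R) + eps,
    eps ~ Normal(0, noise_sd) drawn once per peptide (log-normal
    peptide-level dispersion). With all betas and noise_sd zero every
    peptide has identical fitness (neutral drift).
    """

    intercept: float = 0.0
    beta_nterm_met: float = 0.7
    beta_cys: float = -1.0
    beta_cation: float = -0.6
    noise_sd: float = 0.3
    seed: int | None = None

    def log_fitness(self, peptides: list[str]) -> np.ndarray:
        lp = np.full(len(peptides), self.intercept, dtype=float)
        for i, p in enumerate(peptides):
            if p and p[0] == "M":
                lp[i] += self.beta_nterm_met
            lp[i] += self.beta_cys * p.count("C")
            lp[i] += self.beta_cation * sum(p.count(a) for a in CATIONIC)
        if self.noise_sd > 0:
            rng = np.random.default_rng(self.seed)
            lp += rng.normal(0.0, self.noise_sd, size=len(peptides))
        return lp

    def fitness(self, peptides: list[str]) -> np.ndarray:
        return np.exp(self.log_fitness(peptides))


@dataclass(frozen=True)
class SelectionConfig:
    """Round structure and sequencing parameters of a selection arm."""

    n_rounds: int = 5
    reads_per_round: int = 100_000
    error_rate: float = 0.001
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


def sample_naive_pool(
    spec: NNKLibrarySpec, seed: int | None = None
) -> PeptideCountTable:
    """Draw the naïve pool: i.i.d. NNK codons at every position.

    Each of ``pool_size`` clones contributes count 1 (aggregated by
    sequence). Under the DISCARD amber policy clones containing TAG are
    dropped, so the realized pool may be smaller than ``pool_size``.
    """
    table = build_nnk_codon_table()
    codons = table.codons  # sorted, deterministic order
    aas = np.array([table.codon_to_aa[c] for c in codons])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(codons), size=(spec.pool_size, spec.peptide_length))
    residues = aas[draws]
    if spec.amber_policy is AmberPolicy.SUPPRESS_TO_Q:
        residues[residues == STOP_SYMBOL] = "Q"
    else:
        keep = ~(residues == STOP_SYMBOL).any(axis=1)
        residues = residues[keep]
        if residues.shape[0] == 0:
            raise ValueError("amber discard removed every clone; increase pool_size")
    peptides = ["".join(row) for row in residues]
    counts: dict[str, int] = {}
    for p in peptides:
        counts[p] = counts.get(p, 0) + 1
    return PeptideCountTable.from_counts(
        counts, sample_id="naive", cell_line="", round_label="naive"
    )


def simulate_selection(
    pool: PeptideCountTable,
    model: FitnessModel,
    cfg: SelectionConfig,
    fitness: np.ndarray | None = None,
    cell_line: str = "",
) -> list[PeptideCountTable]:
    """Run ``cfg.n_rounds`` rounds of multiplicative selection + resampling.

    Each round updates frequencies f_i ∝ f_i · w_i and resamples them
    multinomially at ``reads_per_round`` depth; the realized counts seed the
    next round, so a peptide lost to sampling stays lost (as in a real
    selection, where an un-amplified clone cannot return). Rounds are
    labeled ORD1..ORDn. ``fitness`` overrides the model's weights (useful
    for hard-zero fitness experiments).

    Raises ValueError if every peptide has zero fitness (no survivors).
    """
    if pool.unique_sequences == 0:
        raise ValueError("empty pool")
    peptides = pool.peptides
    w = model.fitness(peptides) if fitness is None else np.asarray(fitness, float)
    if w.shape != (len(peptides),):
        raise ValueError("fitness vector length mismatch")
    if (w < 0).any():
        raise ValueError("fitness must be non-negative")
    if not (w > 0).any():
        raise ValueError("all-zero fitness: no survivors")
    rng = np.random.default_rng(cfg.seed)
    freq = pool.data["count"].to_numpy(float)
    freq = freq / freq.sum()
    rounds: list[PeptideCountTable] = []
    for r in range(1, cfg.n_rounds + 1):
        weighted = freq * w
        total = weighted.sum()
        if total <= 0:
            raise ValueError(f"round {r}: no surviving peptides")
        counts = rng.multinomial(cfg.reads_per_round, weighted / total)
        label = f"ORD{r}"
        table = PeptideCountTable.from_counts(
            {p: int(c) for p, c in zip(peptides, counts) if c > 0},
            sample_id=f"{cell_line}_{label}" if cell_line else label,
            cell_line=cell_line,
            round_label=label,
        )
        rounds.append(table)
        freq = counts.astype(float) / cfg.reads_per_round
    return rounds


def emit_reads(
    table: PeptideCountTable,
    spec: NNKLibrarySpec,
    cfg: SelectionConfig,
    seed: int | None = None,
) -> list[tuple[str, str, str]]:
    """Reverse the decode step: one (name, sequence, quality) per count.

    Each read is flank5 + insert + flank3, the insert a uniformly chosen
    synonymous NNK encoding of the peptide (TAG counts as a Q codon under
    amber suppression). Substitution errors are applied per base at
    ``cfg.error_rate``; quality is a constant Phred-33 'I' string.
    """
    codon_table = build_nnk_codon_table()
    syn: dict[str, list[str]] = {
        aa: codon_table.synonymous_codons(aa, spec.amber_policy)
        for aa in set("".join(table.peptides))
    }
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    read_len = len(spec.flank5) + spec.insert_length + len(spec.flank3)
    quality = "I" * read_len
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    n = 0
    for peptide, count in zip(table.data["peptide"], table.data["count"]):
        if len(peptide) != spec.peptide_length:
            raise ValueError(
                f"peptide {peptide!r} length != spec.peptide_length {spec.peptide_length}"
            )
        for _ in range(int(count)):
            insert = "".join(
                syn[aa][rng.integers(0, len(syn[aa]))] for aa in peptide
            )
            seq = spec.flank5 + insert + spec.flank3
            if cfg.error_rate > 0:
                arr = np.array(list(seq))
                hit = rng.random(read_len) < cfg.error_rate
                if hit.any():
                    arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
                    seq = "".join(arr)
            n += 1
            reads.append((f"{table.sample_id}_read{n}", seq, quality))
    return reads


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


#: Per-arm multiplier on all fitness betas, emulating the reported cell-type
#: ordering of enrichment rates (fastest in Caco2, slowest in CHO).
ARM_RATE_FACTORS = {"293": 1.0, "Caco2": 1.15, "CHO": 0.85}

#: Output rounds carried to sequencing in the emulated study design.
SEQUENCED_ROUNDS = (2, 3, 4, 5)


def simulate_study(
    seed: int,
    spec: NNKLibrarySpec | None = None,
    cfg: SelectionConfig | None = None,
    model: FitnessModel | None = None,
    arms: tuple[str, ...] = ("293", "Caco2", "CHO"),
    outdir: str | Path | None = None,
) -> dict[str, PeptideCountTable]:
    """Emulate the 13-sample study: naïve library + rounds 2-5 for 3 arms.

    Returns count tables keyed by sample id (``naive``, ``<arm>_ORD<r>``).
    If ``outdir`` is given, additionally writes one FASTQ per sample and a
    sample sheet (sample_id, cell_line, round, file).
    """
    spec = spec or NNKLibrarySpec()
    cfg = cfg or SelectionConfig()
    base = model or FitnessModel()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + 2 * len(arms))
    pool_seed = children[0].generate_state(1)[0] % (2**31)
    pool = sample_naive_pool(spec, seed=int(pool_seed))
    samples: dict[str, PeptideCountTable] = {"naive": pool}
    for i, arm in enumerate(arms):
        factor = ARM_RATE_FACTORS.get(arm, 1.0)
        noise_seed = int(children[2 + 2 * i].generate_state(1)[0] % (2**31))
        sel_seed = int(children[3 + 2 * i].generate_state(1)[0] % (2**31))
        arm_model = FitnessModel(
            intercept=base.intercept,
            beta_nterm_met=base.beta_nterm_met * factor,
            beta_cys=base.beta_cys * factor,
            beta_cation=base.beta_cation * factor,
            noise_sd=base.noise_sd,
            seed=noise_seed,
        )
        arm_cfg = SelectionConfig(
            n_rounds=cfg.n_rounds,
            reads_per_round=cfg.reads_per_round,
            error_rate=cfg.error_rate,
            seed=sel_seed,
        )
        rounds = simulate_selection(pool, arm_model, arm_cfg, cell_line=arm)
        for r in SEQUENCED_ROUNDS:
            if r <= len(rounds):
                samples[rounds[r - 1].sample_id] = rounds[r - 1]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        emit_seed = int(children[1].generate_state(1)[0] % (2**31))
        entries = []
        for j, (sid, table) in enumerate(samples.items()):
            path = outdir / f"{sid}.fastq"
            write_fastq(emit_reads(table, spec, cfg, seed=emit_seed + j), path)
            entries.append(
                {
                    "sample_id": sid,
                    "cell_line": table.cell_line,
                    "round": table.round_label,
                    "file": str(path),
                }
            )
        write_sample_sheet(entries, outdir / "sample_sheet.tsv")
    return samples
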
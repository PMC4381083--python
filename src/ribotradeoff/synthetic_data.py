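"""Synthetic genomes with a planted structure/codon-time coupling.

The generator emulates the statistical layout the pipeline is designed to
detect: genes composed of alternating high/low "structural" blocks, with
synonymous codon choice coupled to the block class at tunable strength
``beta`` — inside high blocks each amino acid's codon is the *fastest*
synonym with probability ``beta`` (otherwise uniform), inside low blocks
the *slowest*.  ``beta = 0`` decouples codon choice from structure
entirely; ``beta = 1`` is the deterministic limit.  Amino acids are drawn
uniformly over the 20, so amino-acid composition carries no structure
signal and synonymous shuffling alone destroys the planted effect.

Two structure channels are supported:

* ``pars`` (default) — per-nucleotide PARS-like scores, block mean +1
  (high) or -1 (low) plus Gaussian noise.  Structure truth is decoupled
  from sequence content, so planted effects are exact and analytically
  tractable (:func:`expected_delta_t`).
* ``mfe`` — no scores are emitted; structure must be *predicted* from the
  sequence.  Because the packaged time tables make fast codons GC-rich,
  high blocks fold strongly and low blocks weakly under the fallback
  engine, exercising the folding path end to end.

The planted effect is analytic: the codon-time distribution of each class
is a finite mixture whose exact median (:func:`expected_delta_t`) the
pipeline estimate should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .elongation import TranslationTimeTable, packaged_time_table
from .genetics import AMINO_ACIDS, SYNONYMS
from .sequence_io import CodingSequence, write_fasta

TERMINAL_CODONS = 17  # trimmed away by the pipeline's 51-nt rule


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome.

    ``gene_len_codons`` counts the *analyzed core* (the part that survives
    terminal trimming); 17 terminal codons are added on each side.  Block
    length must be a multiple of 3 so block boundaries align with codons.
    """

    n_genes: int = 200
    gene_len_codons: int | tuple[int, int] = 300
    block_len_nt: int = 60
    beta: float = 0.5
    pars_noise_sd: float = 0.5
    time_table: TranslationTimeTable = field(
        default_factory=lambda: packaged_time_table("synthetic_ecoli")
    )
    seed: int = 0
    structure_mode: Literal["pars", "mfe"] = "pars"
    #: fraction of each gene's blocks belonging to its majority class.
    #: 0.5 strictly alternates high/low; larger values (majority class
    #: alternating between genes) give genes distinct overall codon usage,
    #: which randomized-genome studies need so that shuffled genomes still
    #: contain classifiable structure of both kinds.
    block_duty: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.block_len_nt < 3 or self.block_len_nt % 3:
            raise ValueError("block_len_nt must be a positive multiple of 3")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.pars_noise_sd < 0:
            raise ValueError("pars_noise_sd must be >= 0")
        if not 0.5 <= self.block_duty < 1:
            raise ValueError("block_duty must lie in [0.5, 1)")
        lens = (
            (self.gene_len_codons, self.gene_len_codons)
            if isinstance(self.gene_len_codons, int)
            else self.gene_len_codons
        )
        if lens[0] < 1 or lens[1] < lens[0]:
            raise ValueError(f"invalid gene_len_codons {self.gene_len_codons}")

    def draw_core_len(self, rng: np.random.Generator) -> int:
        if isinstance(self.gene_len_codons, int):
            return self.gene_len_codons
        lo, hi = self.gene_len_codons
        return int(rng.integers(lo, hi + 1))


@dataclass
class SyntheticGenome:
    """Generator output: genes, PARS-like scores, and per-nucleotide truth."""

    spec: SyntheticSpec
    genes: list[CodingSequence]
    #: columns gene_id, position (0-based, untrimmed), score; empty for mfe mode
    scores: pd.DataFrame
    #: gene_id -> int8 per untrimmed nucleotide: +1 high, -1 low, 0 terminal
    truth: dict[str, np.ndarray]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genes, outdir / "genes.fasta")
        self.scores.to_csv(outdir / "structure_scores.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({g: t.tolist() for g, t in self.truth.items()}, fh)


def _speed_maps(table: TranslationTimeTable):
    fastest = {aa: table.speed_rank(c)[0] for aa, c in SYNONYMS.items()}
    slowest = {aa: table.speed_rank(c)[-1] for aa, c in SYNONYMS.items()}
    return fastest, slowest


def _draw_codon(
    aa: str,
    label: int,
    beta: float,
    fastest: dict[str, str],
    slowest: dict[str, str],
    rng: np.random.Generator,
) -> str:
    synonyms = SYNONYMS[aa]
    if label != 0 and rng.random() < beta:
        return fastest[aa] if label > 0 else slowest[aa]
    return synonyms[rng.integers(len(synonyms))]


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Generate a multi-gene genome with the planted coupling.

    Deterministic given ``spec.seed``.  Block phase alternates between
    genes so both classes are equally represented genome-wide; terminal
    codons (uniform over sense codons, ATG first, TAA last) carry no
    signal and no scores.
    """
    rng = np.random.default_rng(spec.seed)
    fastest, slowest = _speed_maps(spec.time_table)
    block_codons = spec.block_len_nt // 3

    genes: list[CodingSequence] = []
    truth: dict[str, np.ndarray] = {}
    score_frames = []
    width = len(str(spec.n_genes - 1))
    for g in range(spec.n_genes):
        core_len = spec.draw_core_len(rng)
        majority = 1 if g % 2 == 0 else -1
        labels = np.empty(core_len, dtype=np.int8)
        duty = spec.block_duty
        for k in range(core_len):
            b = k // block_codons
            # Bresenham-style spacing: majority blocks at frequency `duty`
            is_majority = int((b + 1) * duty) - int(b * duty) == 1
            labels[k] = majority if is_majority else -majority

        core = [
            _draw_codon(
                AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))],
                labels[k],
                spec.beta,
                fastest,
                slowest,
                rng,
            )
            for k in range(core_len)
        ]
        lead = ["ATG"] + [
            _draw_codon(AMINO_ACIDS[rng.integers(20)], 0, 0.0, fastest, slowest, rng)
            for _ in range(TERMINAL_CODONS - 1)
        ]
        tail = [
            _draw_codon(AMINO_ACIDS[rng.integers(20)], 0, 0.0, fastest, slowest, rng)
            for _ in range(TERMINAL_CODONS - 1)
        ] + ["TAA"]
        gene_id = f"synth{g:0{width}d}"
        seq = "".join(lead + core + tail)
        genes.append(CodingSequence(id=gene_id, seq=seq))

        nt_labels = np.zeros(len(seq), dtype=np.int8)
        nt_labels[3 * TERMINAL_CODONS : 3 * (TERMINAL_CODONS + core_len)] = np.repeat(
            labels, 3
        )
        truth[gene_id] = nt_labels

        if spec.structure_mode == "pars":
            core_nt = 3 * core_len
            positions = np.arange(core_nt) + 3 * TERMINAL_CODONS
            means = np.repeat(labels, 3).astype(float)
            noise = rng.normal(0.0, spec.pars_noise_sd, core_nt)
            score_frames.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_id,
                        "position": positions,
                        "score": means + noise,
                    }
                )
            )

    scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(columns=["gene_id", "position", "score"])
    )
    return SyntheticGenome(spec=spec, genes=genes, scores=scores, truth=truth)


def _class_mixture(
    table: TranslationTimeTable, beta: float, label: int
) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the codon-time mixture for one class."""
    fastest, slowest = _speed_maps(table)
    extreme = fastest if label > 0 else slowest
    prob: dict[float, float] = {}
    n_aa = len(AMINO_ACIDS)
    for aa in AMINO_ACIDS:
        synonyms = SYNONYMS[aa]
        for codon in synonyms:
            p = (1 - beta) / len(synonyms)
            if codon == extreme[aa]:
                p += beta
            t = table.times[codon]
            prob[t] = prob.get(t, 0.0) + p / n_aa
    support = np.array(sorted(prob))
    return support, np.array([prob[t] for t in support])


def _discrete_median(support: np.ndarray, probs: np.ndarray) -> float:
    """Median matching the large-sample behaviour of ``np.median``.

    If the CDF crosses 0.5 strictly inside a support point, that point is
    the median; if it hits 0.5 exactly at a point, the sample median
    converges to the midpoint of that point and the next.
    """
    cdf = np.cumsum(probs)
    i = int(np.searchsorted(cdf, 0.5 - 1e-9))
    if abs(cdf[i] - 0.5) < 1e-9 and i + 1 < len(support):
        return float((support[i] + support[i + 1]) / 2)
    return float(support[i])


def expected_delta_t(spec: SyntheticSpec) -> float:
    """Analytic ``median_low - median_high`` of the planted codon mixtures.

    Computed exactly from the finite support of the per-class codon-time
    distributions; 0 at ``beta = 0`` and monotone non-decreasing in beta.
    """
    sup_h, p_h = _class_mixture(spec.time_table, spec.beta, +1)
    sup_l, p_l = _class_mixture(spec.time_table, spec.beta, -1)
    return _discrete_median(sup_l, p_l) - _discrete_median(sup_h, p_h)


# -- synonymous variant libraries --------------------------------------------


@dataclass
class VariantLibrary:
    """A planted synonymous-variant library with expression measurements."""

    variants: list[CodingSequence]
    #: columns variant_id, expression
    expression: pd.DataFrame
    #: columns variant_id, beta, planted_score (median_high - median_low)
    truth: pd.DataFrame
    #: PARS-style structure scores, columns gene_id, position, score
    scores: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.variants, outdir / "variants.fasta")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.scores.to_csv(outdir / "structure_scores.tsv", sep="\t", index=False)


def generate_variant_library(
    base_protein_len: int = 400,
    n_variants: int = 30,
    beta_range: tuple[float, float] = (0.25, 1.0),
    slope: float = -0.09,
    noise_sd: float = 0.5,
    seed: int = 0,
    block_len_nt: int = 150,
    intercept: float = 12.0,
    pars_noise_sd: float = 0.5,
    time_table: TranslationTimeTable | None = None,
) -> VariantLibrary:
    """Synonymous variants of one random protein with planted expression.

    All variants encode the same protein (terminal codons are shared
    verbatim); the analyzed core is recoded with a variant-specific
    coupling ``beta`` spanning ``beta_range`` over the alternating block
    template, and PARS-style scores for the template are emitted alongside
    (the default structure channel, which keeps the planted scores exact).
    Expression is linear in the planted trade-off score:
    ``intercept + slope * planted_score + N(0, noise_sd)``, where
    ``planted_score = -expected_delta_t(beta)`` (the more-negative-is-
    stronger convention).
    """
    if n_variants < 3:
        raise ValueError("n_variants must be >= 3")
    table = time_table if time_table is not None else packaged_time_table("synthetic_ecoli")
    rng = np.random.default_rng(seed)
    fastest, slowest = _speed_maps(table)
    block_codons = block_len_nt // 3

    protein = [AMINO_ACIDS[i] for i in rng.integers(0, 20, base_protein_len)]
    labels = np.array(
        [1 if (k // block_codons) % 2 == 0 else -1 for k in range(base_protein_len)],
        dtype=np.int8,
    )
    lead = ["ATG"] + [
        SYNONYMS[AMINO_ACIDS[rng.integers(20)]][0] for _ in range(TERMINAL_CODONS - 1)
    ]
    tail = [
        SYNONYMS[AMINO_ACIDS[rng.integers(20)]][0] for _ in range(TERMINAL_CODONS - 1)
    ] + ["TAA"]

    betas = np.linspace(beta_range[0], beta_range[1], n_variants)
    variants, rows, truth_rows, score_frames = [], [], [], []
    core_positions = np.arange(3 * base_protein_len) + 3 * TERMINAL_CODONS
    nt_means = np.repeat(labels, 3).astype(float)
    width = len(str(n_variants - 1))
    for v, beta in enumerate(betas):
        spec = SyntheticSpec(n_genes=1, beta=float(beta), time_table=table)
        planted = -expected_delta_t(spec)
        core = [
            _draw_codon(protein[k], int(labels[k]), float(beta), fastest, slowest, rng)
            for k in range(base_protein_len)
        ]
        variant_id = f"variant{v:0{width}d}"
        variants.append(
            CodingSequence(id=variant_id, seq="".join(lead + core + tail))
        )
        expression = intercept + slope * planted + rng.normal(0.0, noise_sd)
        rows.append({"variant_id": variant_id, "expression": expression})
        truth_rows.append(
            {"variant_id": variant_id, "beta": float(beta), "planted_score": planted}
        )
        score_frames.append(
            pd.DataFrame(
                {
                    "gene_id": variant_id,
                    "position": core_positions,
                    "score": nt_means
                    + rng.normal(0.0, pars_noise_sd, len(core_positions)),
                }
            )
        )
    return VariantLibrary(
        variants=variants,
        expression=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        scores=pd.concat(score_frames, ignore_index=True),
    )
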
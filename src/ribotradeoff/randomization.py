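"""Randomized-genome null models for the structure/codon-time trade-off.

Two per-gene shuffling schemes destroy different layers of sequence order
while conserving the codon multiset exactly:

* ``synonymous_shuffle`` — within each amino acid, the codons at that
  amino acid's positions are permuted uniformly; codon usage *and* the
  protein sequence are conserved, only the synonymous ordering is lost.
* ``codon_shuffle`` — every codon position is permuted uniformly; codon
  usage (hence GC content) is conserved but the amino-acid order is not.

For each randomized genome the structure landscape is *recomputed* with
the same folding engine/window/thresholds as the observed genome (this is
why the null pipeline requires an MFE rule: experimental PARS scores
cannot be re-measured for shuffled sequences), and the trade-off score is
re-evaluated.  The 100-genome score distribution forms the null against
which the observed trade-off is compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .elongation import TranslationTimeTable
from .folding import FoldingEngine, NussinovEngine
from .genetics import translate
from .ranktests import mann_whitney_u, wilcoxon_signed_rank
from .sequence_io import CodingSequence
from .structure import DEFAULT_WINDOW_NT, ThresholdRule, mfe_profiles
from .tradeoff_stats import genome_tradeoff

Method = Literal["synonymous_shuffle", "codon_shuffle"]

DEFAULT_N_GENOMES = 100


@dataclass(frozen=True)
class NullDistribution:
    """Trade-off scores of randomized genomes under one shuffling scheme."""

    method: Method
    values: tuple[float, ...]
    n_genomes: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_genomes:
            raise ValueError("values length does not match n_genomes")

    def defined_values(self) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        return arr[~np.isnan(arr)]


def shuffle_synonymous(cds: CodingSequence, rng: np.random.Generator) -> CodingSequence:
    """Permute synonymous codons within each amino acid's position set.

    The translated protein and the per-gene codon multiset are conserved
    exactly; stop codons (should the input be untrimmed) form their own
    group.
    """
    codons = cds.codons()
    protein = translate(cds.seq)
    positions_by_aa: dict[str, list[int]] = {}
    for k, aa in enumerate(protein):
        positions_by_aa.setdefault(aa, []).append(k)
    out = list(codons)
    for positions in positions_by_aa.values():
        perm = rng.permutation(len(positions))
        for dst, src in zip(positions, perm):
            out[dst] = codons[positions[src]]
    return CodingSequence(
        id=cds.id, seq="".join(out), trimmed=cds.trimmed, offset_nt=cds.offset_nt
    )


def shuffle_codons(cds: CodingSequence, rng: np.random.Generator) -> CodingSequence:
    """Uniformly permute all codon positions of the gene.

    Conserves the codon multiset (hence GC content) but generally changes
    the amino-acid sequence.
    """
    codons = cds.codons()
    perm = rng.permutation(len(codons))
    return CodingSequence(
        id=cds.id,
        seq="".join(codons[i] for i in perm),
        trimmed=cds.trimmed,
        offset_nt=cds.offset_nt,
    )


_SHUFFLERS = {"synonymous_shuffle": shuffle_synonymous, "codon_shuffle": shuffle_codons}


def shuffle_genome(
    genome: Sequence[CodingSequence], method: Method, rng: np.random.Generator
) -> list[CodingSequence]:
    """Shuffle every gene with one scheme, in sorted-id order.

    A single generator is threaded through the genes in sorted-id order so
    results do not depend on the caller's gene ordering.
    """
    shuffler = _SHUFFLERS[method]
    return [shuffler(g, rng) for g in sorted(genome, key=lambda g: g.id)]


def null_distribution(
    genome: Sequence[CodingSequence],
    table: TranslationTimeTable,
    rule: ThresholdRule,
    method: Method,
    n_genomes: int = DEFAULT_N_GENOMES,
    seed: int = 0,
    engine: FoldingEngine | None = None,
    window_nt: int = DEFAULT_WINDOW_NT,
) -> NullDistribution:
    """Trade-off scores of ``n_genomes`` randomized genomes.

    Each replicate shuffles every (trimmed) gene, recomputes window-MFE
    structure profiles with the configured engine, and re-evaluates the
    genome trade-off score.  Deterministic given ``seed``.  Replicates in
    which one region class is absent yield NaN.
    """
    if rule.kind != "mfe":
        raise ValueError(
            "null models require an MFE rule: experimental structure scores "
            "cannot be recomputed for shuffled sequences"
        )
    if method not in _SHUFFLERS:
        raise ValueError(f"unknown randomization method {method!r}")
    engine = engine if engine is not None else NussinovEngine()
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_genomes):
        shuffled = shuffle_genome(genome, method, rng)
        profiles = mfe_profiles(shuffled, window_nt, engine)
        result = genome_tradeoff(shuffled, profiles, table, rule)
        values.append(result.tradeoff_score)
    return NullDistribution(
        method=method, values=tuple(values), n_genomes=n_genomes, seed=seed
    )


def compare_to_null(
    observed: float, null: NullDistribution
) -> tuple[float, dict[str, float]]:
    """One-sample Wilcoxon of the null scores against the observed score.

    Two-sided signed-rank test of ``null.values`` against hypothesised
    median ``observed``; the summary reports the observed score, the null
    median and the null 2.5/97.5 percentiles.  All null values equal to
    the observed score is a degenerate test and raises.
    """
    vals = null.defined_values()
    if len(vals) == 0:
        raise ValueError("null distribution has no defined values")
    _, p = wilcoxon_signed_rank(vals, mu=observed)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    summary = {
        "observed": float(observed),
        "null_median": float(np.median(vals)),
        "null_p2.5": float(lo),
        "null_p97.5": float(hi),
        "n_defined": float(len(vals)),
    }
    return p, summary


def compare_methods(null_a: NullDistribution, null_b: NullDistribution) -> float:
    """Two-sided Mann-Whitney p between two null score distributions."""
    a, b = null_a.defined_values(), null_b.defined_values()
    _, p = mann_whitney_u(a, b)
    return p


def export_null_tsv(nulls: Sequence[NullDistribution], path: str | Path) -> None:
    """TSV export: replicate, method, tradeoff_score, seed."""
    rows = [
        {"replicate": i, "method": nd.method, "tradeoff_score": v, "seed": nd.seed}
        for nd in nulls
        for i, v in enumerate(nd.values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
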
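"""Per-gene trade-off scores, CAI, and correlation with measured expression.

For a library of synonymous variants of one gene, each variant's trade-off
score is ``median_high - median_low`` of its own codon-time pools (more
negative = highly structured regions biased toward faster codons = a
stronger trade-off).  The score is correlated against absolute expression
(Pearson R, two-sided p) with an ordinary least-squares fit of expression
on score.  The codon adaptation index (CAI) — the geometric mean of each
codon's relative adaptiveness to a reference gene set — is computed
alongside as the classical whole-gene comparator that ignores local
structure context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, log
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elongation import InternalStopError, TranslationTimeTable, codon_time_profile
from .folding import FoldingEngine
from .genetics import CODON_TO_AA, SINGLE_CODON_AAS, STOP_CODONS, SYNONYMS
from .sequence_io import CodingSequence
from .structure import (
    DEFAULT_WINDOW_NT,
    StructureProfile,
    ThresholdRule,
    extract_regions,
    sliding_window_mfe,
)
from .tradeoff_stats import assign_codons

logger = logging.getLogger(__name__)


@dataclass
class VariantRecord:
    """One synonymous variant: sequence, expression, derived scores."""

    variant_id: str
    cds: CodingSequence
    expression: float
    tradeoff_score: float | None = None
    cai: float | None = None


def per_gene_tradeoff(
    cds: CodingSequence,
    table: TranslationTimeTable,
    rule: ThresholdRule,
    engine: FoldingEngine | None = None,
    profile: StructureProfile | None = None,
    window_nt: int = DEFAULT_WINDOW_NT,
) -> float | None:
    """Trade-off score ``median_high - median_low`` for a single gene.

    The structure profile is predicted with *engine* (window MFE) unless a
    pre-computed *profile* is supplied.  Returns ``None`` (logged) when the
    gene lacks regions of one class — such variants are excluded from
    correlations rather than scored 0, since a difference of medians is
    undefined with an empty pool.
    """
    if profile is None:
        profile = sliding_window_mfe(cds, window_nt, engine)
    regions = extract_regions(profile, rule)
    assigned = assign_codons(cds, regions)
    if not assigned["high"] or not assigned["low"]:
        logger.warning(
            "%s: missing %s-structure regions, no trade-off score",
            cds.id,
            "high" if not assigned["high"] else "low",
        )
        return None
    try:
        speed = codon_time_profile(cds, table)
    except InternalStopError as exc:
        logger.warning("%s", exc)
        return None
    med_high = float(np.median(speed.codon_times[assigned["high"]]))
    med_low = float(np.median(speed.codon_times[assigned["low"]]))
    return med_high - med_low


@dataclass(frozen=True)
class CaiWeights:
    """Relative adaptiveness w(codon) in (0, 1] from a reference gene set."""

    weights: dict[str, float]
    reference: str = "user"

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if not 0 < w <= 1:
                raise ValueError(f"weight out of (0, 1] for {codon}: {w}")


def cai_weights(
    reference: Sequence[CodingSequence], name: str = "reference"
) -> CaiWeights:
    """Relative adaptiveness from codon counts in a reference gene set.

    Per amino acid, ``w = count / count(most frequent synonymous codon)``.
    Zero-count codons receive a positive floor (half the smallest observed
    weight of that amino acid) so geometric means stay defined; amino
    acids absent from the reference get uninformative weights of 1.
    """
    counts: dict[str, int] = {}
    for gene in reference:
        for codon in gene.codons():
            if codon in CODON_TO_AA:
                counts[codon] = counts.get(codon, 0) + 1
    weights: dict[str, float] = {}
    for aa, codons in SYNONYMS.items():
        aa_counts = {c: counts.get(c, 0) for c in codons}
        top = max(aa_counts.values())
        if top == 0:
            logger.warning("amino acid %s absent from CAI reference", aa)
            weights.update({c: 1.0 for c in codons})
            continue
        observed = {c: n / top for c, n in aa_counts.items() if n > 0}
        floor = 0.5 * min(observed.values())
        weights.update({c: observed.get(c, floor) for c in codons})
    return CaiWeights(weights=weights, reference=name)


def cai(cds: CodingSequence, weights: CaiWeights) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Single-codon amino acids (Met, Trp) and stop codons are excluded from
    the mean, as their weight is structurally 1.
    """
    log_sum = 0.0
    n = 0
    for codon in cds.codons():
        if codon in STOP_CODONS or CODON_TO_AA[codon] in SINGLE_CODON_AAS:
            continue
        log_sum += log(weights.weights[codon])
        n += 1
    if n == 0:
        raise ValueError(f"{cds.id}: no codons eligible for CAI")
    return exp(log_sum / n)


def correlate_expression(
    variants: Sequence[VariantRecord],
) -> tuple[float, float, float]:
    """Pearson correlation and OLS fit of expression on trade-off score.

    Uses only variants with a defined score and expression; returns
    ``(R, p_two_sided, slope)``.  Fewer than 3 usable variants or zero
    variance in either variable is an error.
    """
    usable = [
        v
        for v in variants
        if v.tradeoff_score is not None and not np.isnan(v.expression)
    ]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 scored variants, have {len(usable)}")
    score = np.array([v.tradeoff_score for v in usable], dtype=float)
    expr = np.array([v.expression for v in usable], dtype=float)
    if np.ptp(score) == 0 or np.ptp(expr) == 0:
        raise ValueError("zero variance in trade-off score or expression")
    r, p = stats.pearsonr(score, expr)
    fit = stats.linregress(score, expr)
    return float(r), float(p), float(fit.slope)


def load_variant_library(
    variants_fasta: str | Path,
    expression_tsv: str | Path,
) -> list[VariantRecord]:
    """Load variant CDS FASTA plus a TSV of ``variant_id, expression``.

    Variants without a (positive) expression measurement are excluded, as
    absence of expression can stem from factors outside elongation.
    """
    from .sequence_io import load_coding_sequences

    genes = {g.id: g for g in load_coding_sequences(variants_fasta, "fasta")}
    table = pd.read_csv(expression_tsv, sep="\t", dtype={"variant_id": str})
    if not {"variant_id", "expression"}.issubset(table.columns):
        raise ValueError("expression file needs columns variant_id, expression")
    records = []
    for row in table.itertuples():
        if row.variant_id not in genes:
            logger.warning("expression for unknown variant %s skipped", row.variant_id)
            continue
        if not np.isfinite(row.expression) or row.expression <= 0:
            logger.warning("variant %s has no measurable expression", row.variant_id)
            continue
        records.append(
            VariantRecord(
                variant_id=row.variant_id,
                cds=genes[row.variant_id],
                expression=float(row.expression),
            )
        )
    return records


def score_variant_library(
    records: Sequence[VariantRecord],
    table: TranslationTimeTable,
    rule: ThresholdRule,
    engine: FoldingEngine | None = None,
    cai_ref: CaiWeights | None = None,
    window_nt: int = DEFAULT_WINDOW_NT,
    trim_nt: int = 51,
) -> list[VariantRecord]:
    """Fill trade-off scores (and CAI if a reference is given) in place.

    Each variant is terminally trimmed before structure prediction and
    scoring, mirroring the genome-scale pipeline; CAI uses the full CDS.
    """
    from .sequence_io import GeneTooShortError, trim_terminal_regions

    for rec in records:
        try:
            trimmed = trim_terminal_regions(rec.cds, trim_nt)
        except GeneTooShortError as exc:
            logger.warning("%s", exc)
            continue
        rec.tradeoff_score = per_gene_tradeoff(
            trimmed, table, rule, engine=engine, window_nt=window_nt
        )
        if cai_ref is not None:
            rec.cai = cai(rec.cds, cai_ref)
    return list(records)
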
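"""The Δt trade-off statistic: codon times in high vs low structure regions.

The central quantity of the pipeline.  Codons are assigned to high/low
structure regions (full containment of all three nucleotides), their
translation times pooled genome-wide per class, and the two pools compared
by medians: ``delta_t = median_low - median_high`` is positive when highly
structured regions favour fast (abundant-tRNA) codons — the trade-off.
The same quantity with the opposite sign, ``tradeoff_score = median_high -
median_low`` (more negative = stronger trade-off), is carried alongside so
the two sign conventions in use never get confused.  Distributions are
non-Gaussian, so medians/IQRs summarise them and a two-sided Mann-Whitney
test compares the pools.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .elongation import InternalStopError, TranslationTimeTable, codon_time_profile
from .genetics import CODON_TO_AA, SYNONYMS
from .ranktests import mann_whitney_u
from .sequence_io import CodingSequence, GeneSubset
from .structure import StructureProfile, StructureRegion, ThresholdRule, extract_regions

logger = logging.getLogger(__name__)

Klass = Literal["high", "low"]


@dataclass
class TradeoffResult:
    """Summary of one high-vs-low codon-time comparison.

    ``delta_t = median_low - median_high`` and ``tradeoff_score`` is its
    negation.  All medians/IQRs are NaN (an NA row) when either class is
    empty; counts are still reported.
    """

    label: str
    n_regions_high: int
    n_regions_low: int
    n_codons_high: int
    n_codons_low: int
    median_high: float
    median_low: float
    iqr_high: tuple[float, float]
    iqr_low: tuple[float, float]
    p_value: float

    @property
    def delta_t(self) -> float:
        return self.median_low - self.median_high

    @property
    def tradeoff_score(self) -> float:
        return self.median_high - self.median_low

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.median_high) or np.isnan(self.median_low))

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "n_regions_high": self.n_regions_high,
            "n_regions_low": self.n_regions_low,
            "n_codons_high": self.n_codons_high,
            "n_codons_low": self.n_codons_low,
            "median_high": self.median_high,
            "q1_high": self.iqr_high[0],
            "q3_high": self.iqr_high[1],
            "median_low": self.median_low,
            "q1_low": self.iqr_low[0],
            "q3_low": self.iqr_low[1],
            "delta_t": self.delta_t,
            "p_value": self.p_value,
        }


def assign_codons(
    cds: CodingSequence, regions: Sequence[StructureRegion]
) -> dict[Klass, list[int]]:
    """Map codons to region classes by full containment.

    Codon ``k`` (nucleotides ``[3k, 3k+3)`` on the trimmed sequence) is
    assigned to a region's class iff all three nucleotides lie inside the
    region; codons straddling a boundary stay unassigned.  Overlapping
    regions of the same class violate maximality and raise.
    """
    out: dict[Klass, list[int]] = {"high": [], "low": []}
    seen: dict[Klass, set[int]] = {"high": set(), "low": set()}
    for region in regions:
        first = (region.start_nt + 2) // 3  # first codon fully inside
        last = region.end_nt // 3  # one past the last fully inside
        idx = range(first, last)
        if seen[region.klass].intersection(idx):
            raise ValueError(
                f"{cds.id}: overlapping {region.klass} regions at {region.start_nt}"
            )
        seen[region.klass].update(idx)
        out[region.klass].extend(idx)
    return out


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def tradeoff_statistic(
    times_high: Sequence[float],
    times_low: Sequence[float],
    label: str = "",
    n_regions: tuple[int, int] = (0, 0),
) -> TradeoffResult:
    """Medians, IQRs (linear-interpolation quartiles) and Mann-Whitney p.

    Either pool empty yields an NA result (NaN medians/p) with counts kept.
    """
    th = np.asarray(times_high, dtype=float)
    tl = np.asarray(times_low, dtype=float)
    if len(th) == 0 or len(tl) == 0:
        return TradeoffResult(
            label=label,
            n_regions_high=n_regions[0],
            n_regions_low=n_regions[1],
            n_codons_high=len(th),
            n_codons_low=len(tl),
            median_high=float("nan"),
            median_low=float("nan"),
            iqr_high=(float("nan"), float("nan")),
            iqr_low=(float("nan"), float("nan")),
            p_value=float("nan"),
        )
    q1h, mh, q3h = _quartiles(th)
    q1l, ml, q3l = _quartiles(tl)
    _, p = mann_whitney_u(th, tl)
    return TradeoffResult(
        label=label,
        n_regions_high=n_regions[0],
        n_regions_low=n_regions[1],
        n_codons_high=len(th),
        n_codons_low=len(tl),
        median_high=mh,
        median_low=ml,
        iqr_high=(q1h, q3h),
        iqr_low=(q1l, q3l),
        p_value=p,
    )


def _pooled_class_times(
    genome: Sequence[CodingSequence],
    profiles: Sequence[StructureProfile],
    table: TranslationTimeTable,
    rule: ThresholdRule,
    subset: GeneSubset | None = None,
) -> tuple[dict[Klass, list[float]], dict[Klass, int]]:
    by_id = {p.gene_id: p for p in profiles}
    pools: dict[Klass, list[float]] = {"high": [], "low": []}
    n_regions = {"high": 0, "low": 0}
    for gene in sorted(genome, key=lambda g: g.id):
        if subset is not None and gene.id not in subset:
            continue
        profile = by_id.get(gene.id)
        if profile is None:
            continue
        try:
            speed = codon_time_profile(gene, table)
        except InternalStopError as exc:
            logger.warning("skipping gene: %s", exc)
            continue
        regions = extract_regions(profile, rule)
        assigned = assign_codons(gene, regions)
        for region in regions:
            n_regions[region.klass] += 1
        for klass in ("high", "low"):
            pools[klass].extend(speed.codon_times[assigned[klass]].tolist())
    return pools, n_regions


def genome_tradeoff(
    genome: Sequence[CodingSequence],
    profiles: Sequence[StructureProfile],
    table: TranslationTimeTable,
    rule: ThresholdRule,
    subset: GeneSubset | None = None,
    label: str = "",
    pooling: Literal["codons", "region_means"] = "codons",
) -> TradeoffResult:
    """Genome-wide trade-off: pool codon times across genes, then compare.

    Genes are processed in sorted-id order, so the result is invariant to
    input order.  ``pooling='region_means'`` replaces each region's codon
    times by their per-region mean before comparison (a sensitivity
    switch; codon pooling is the default convention).
    """
    if pooling == "codons":
        pools, n_regions = _pooled_class_times(genome, profiles, table, rule, subset)
        return tradeoff_statistic(
            pools["high"],
            pools["low"],
            label=label,
            n_regions=(n_regions["high"], n_regions["low"]),
        )
    if pooling != "region_means":
        raise ValueError(f"unknown pooling {pooling!r}")
    by_id = {p.gene_id: p for p in profiles}
    means: dict[Klass, list[float]] = {"high": [], "low": []}
    n_regions = {"high": 0, "low": 0}
    for gene in sorted(genome, key=lambda g: g.id):
        if subset is not None and gene.id not in subset:
            continue
        profile = by_id.get(gene.id)
        if profile is None:
            continue
        try:
            speed = codon_time_profile(gene, table)
        except InternalStopError as exc:
            logger.warning("skipping gene: %s", exc)
            continue
        for region in extract_regions(profile, rule):
            assigned = assign_codons(gene, [region])[region.klass]
            if assigned:
                n_regions[region.klass] += 1
                means[region.klass].append(float(np.mean(speed.codon_times[assigned])))
    return tradeoff_statistic(
        means["high"],
        means["low"],
        label=label,
        n_regions=(n_regions["high"], n_regions["low"]),
    )


@dataclass
class CodonUsageTable:
    """Codon counts and within-class fractions for one region class."""

    klass: Klass
    counts: dict[str, int]
    fractions: dict[str, float] = field(default_factory=dict)
    #: amino acid -> [(codon, fraction)] ordered fastest -> slowest
    by_aa: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


def codon_usage_by_region(
    genome: Sequence[CodingSequence],
    profiles: Sequence[StructureProfile],
    rule: ThresholdRule,
    table: TranslationTimeTable,
) -> tuple[CodonUsageTable, CodonUsageTable]:
    """Per-class codon counts/fractions, grouped per amino acid.

    Within each amino-acid group codons are ordered fastest to slowest by
    the active time table; fractions are normalised over all codons of the
    class, so they sum to 1 per class.
    """
    by_id = {p.gene_id: p for p in profiles}
    counters = {"high": Counter(), "low": Counter()}
    for gene in sorted(genome, key=lambda g: g.id):
        profile = by_id.get(gene.id)
        if profile is None:
            continue
        codons = gene.codons()
        assigned = assign_codons(gene, extract_regions(profile, rule))
        for klass in ("high", "low"):
            counters[klass].update(codons[k] for k in assigned[klass])

    tables = []
    for klass in ("high", "low"):
        counts = dict(counters[klass])
        total = sum(counts.values())
        fractions = {c: n / total for c, n in counts.items()} if total else {}
        by_aa = {}
        if total:
            for aa, codons in SYNONYMS.items():
                ordered = table.speed_rank(codons)
                by_aa[aa] = [(c, fractions.get(c, 0.0)) for c in ordered]
        tables.append(
            CodonUsageTable(klass=klass, counts=counts, fractions=fractions, by_aa=by_aa)
        )
    return tables[0], tables[1]


def aa_composition_by_region(
    genome: Sequence[CodingSequence],
    profiles: Sequence[StructureProfile],
    rule: ThresholdRule,
) -> dict[Klass, dict[str, float]]:
    """Amino-acid fractions of the codons assigned to each region class."""
    by_id = {p.gene_id: p for p in profiles}
    counters = {"high": Counter(), "low": Counter()}
    for gene in sorted(genome, key=lambda g: g.id):
        profile = by_id.get(gene.id)
        if profile is None:
            continue
        codons = gene.codons()
        assigned = assign_codons(gene, extract_regions(profile, rule))
        for klass in ("high", "low"):
            counters[klass].update(
                CODON_TO_AA[codons[k]]
                for k in assigned[klass]
                if codons[k] in CODON_TO_AA
            )
    out: dict[Klass, dict[str, float]] = {}
    for klass in ("high", "low"):
        total = sum(counters[klass].values())
        out[klass] = (
            {aa: n / total for aa, n in sorted(counters[klass].items())} if total else {}
        )
    return out


def bootstrap_delta_t(
    times_high: Sequence[float],
    times_low: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap SE and 95% CI of ``delta_t = median_low - median_high``."""
    rng = np.random.default_rng(seed)
    th = np.asarray(times_high, dtype=float)
    tl = np.asarray(times_low, dtype=float)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        deltas[b] = np.median(rng.choice(tl, len(tl))) - np.median(
            rng.choice(th, len(th))
        )
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return float(deltas.std(ddof=1)), (float(lo), float(hi))


def results_table(results: Sequence[TradeoffResult]) -> pd.DataFrame:
    """Stack TradeoffResults into a report table (one row per result)."""
    return pd.DataFrame([r.as_row() for r in results])
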
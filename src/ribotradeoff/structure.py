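"""Per-nucleotide structure profiles and high/low structure regions.

A structure profile is a per-nucleotide score track aligned to a *trimmed*
coding sequence — either an experimental PARS-style score (positive =
double-stranded propensity) or a predicted minimum free energy of a centred
sliding window (kcal/mol, more negative = more stable).  Regions are maximal
runs of consecutive nucleotides uniformly classified high or low that reach
a minimum length ``min_len_nt``.

Classification follows the two-threshold convention:

* PARS: score > 0 -> high, score <= 0 -> low (every defined position is
  classified).
* MFE: window energy < -35 kcal/mol -> high, > -20 kcal/mol -> low; values
  in between are unclassified and break runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .folding import FoldingEngine, NussinovEngine
from .sequence_io import CodingSequence, DEFAULT_TRIM_NT

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_NT = 101
MFE_HIGH_CUT = -35.0  # kcal/mol, high structure below this
MFE_LOW_CUT = -20.0  # kcal/mol, low structure above this
DEFAULT_MIN_LEN_NT = 20


@dataclass
class StructureProfile:
    """Per-nucleotide structure score track for one (trimmed) gene.

    ``values`` holds the score; ``defined`` is False where no centred
    window fits or no experimental score exists (``values`` is NaN there).
    """

    gene_id: str
    kind: Literal["pars", "mfe"]
    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise ValueError(f"{self.gene_id}: values/defined shape mismatch")
        if self.kind == "mfe" and np.any(self.values[self.defined] > 0):
            raise ValueError(f"{self.gene_id}: positive MFE values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class StructureRegion:
    """A maximal run of uniformly high- or low-structure nucleotides."""

    gene_id: str
    start_nt: int  # 0-based, on the trimmed sequence
    end_nt: int  # half-open
    klass: Literal["high", "low"]

    @property
    def length_nt(self) -> int:
        return self.end_nt - self.start_nt


@dataclass(frozen=True)
class ThresholdRule:
    """Classification thresholds plus the minimum region length R_l."""

    kind: Literal["pars", "mfe"]
    high_cut: float
    low_cut: float
    min_len_nt: int = DEFAULT_MIN_LEN_NT

    def __post_init__(self) -> None:
        if self.kind == "mfe" and not self.high_cut < self.low_cut:
            raise ValueError("mfe rule needs high_cut < low_cut")
        if self.kind == "pars" and self.high_cut != self.low_cut:
            raise ValueError("pars rule uses a single cut (high_cut == low_cut)")
        if self.min_len_nt < 1:
            raise ValueError("min_len_nt must be positive")

    @classmethod
    def pars_default(cls, min_len_nt: int = DEFAULT_MIN_LEN_NT) -> "ThresholdRule":
        """PARS > 0 high, <= 0 low."""
        return cls(kind="pars", high_cut=0.0, low_cut=0.0, min_len_nt=min_len_nt)

    @classmethod
    def mfe_default(cls, min_len_nt: int = DEFAULT_MIN_LEN_NT) -> "ThresholdRule":
        """Window MFE < -35 kcal/mol high, > -20 kcal/mol low."""
        return cls(
            kind="mfe",
            high_cut=MFE_HIGH_CUT,
            low_cut=MFE_LOW_CUT,
            min_len_nt=min_len_nt,
        )

    def classify(self, profile: StructureProfile) -> np.ndarray:
        """Per-nucleotide labels: +1 high, -1 low, 0 unclassified/undefined."""
        if profile.kind != self.kind:
            raise ValueError(
                f"profile kind {profile.kind!r} does not match rule {self.kind!r}"
            )
        v = profile.values
        labels = np.zeros(len(v), dtype=np.int8)
        with np.errstate(invalid="ignore"):
            if self.kind == "pars":
                labels[profile.defined & (v > self.high_cut)] = 1
                labels[profile.defined & (v <= self.low_cut)] = -1
            else:
                labels[profile.defined & (v < self.high_cut)] = 1
                labels[profile.defined & (v > self.low_cut)] = -1
        return labels


def sliding_window_mfe(
    cds: CodingSequence,
    window_nt: int = DEFAULT_WINDOW_NT,
    engine: FoldingEngine | None = None,
) -> StructureProfile:
    """Centred sliding-window MFE profile over a trimmed coding sequence.

    The window energy is assigned to the centre nucleotide; positions within
    ``(window_nt - 1) / 2`` of either end are undefined (no truncated
    windows — they would bias MFE upward).  A sequence shorter than the
    window yields an all-undefined profile.
    """
    if window_nt % 2 == 0 or window_nt < 3:
        raise ValueError("window_nt must be odd and >= 3")
    engine = engine if engine is not None else NussinovEngine()
    n = len(cds.seq)
    values = np.full(n, np.nan)
    if n >= window_nt:
        if hasattr(engine, "window_profile"):
            values = engine.window_profile(cds.seq, window_nt)
        else:
            half = (window_nt - 1) // 2
            for c in range(half, n - half):
                values[c] = engine.fold_mfe(cds.seq[c - half : c + half + 1])
    defined = ~np.isnan(values)
    return StructureProfile(gene_id=cds.id, kind="mfe", values=values, defined=defined)


def mfe_profiles(
    genes: Sequence[CodingSequence],
    window_nt: int = DEFAULT_WINDOW_NT,
    engine: FoldingEngine | None = None,
) -> list[StructureProfile]:
    """Window-MFE profiles for every gene in a (trimmed) genome."""
    engine = engine if engine is not None else NussinovEngine()
    return [sliding_window_mfe(g, window_nt, engine) for g in genes]


def load_structure_scores(
    path: str | Path,
    genes: Sequence[CodingSequence],
    offset_nt: int = DEFAULT_TRIM_NT,
) -> list[StructureProfile]:
    """Load PARS-style per-nucleotide scores and align them to trimmed genes.

    The file is TSV with header columns ``gene_id, position, score``;
    positions are 0-based on the *untrimmed* CDS.  Scores are re-aligned by
    subtracting ``offset_nt``; positions falling outside the trimmed range
    are dropped; unscored positions are undefined.  Genes present in the
    file but absent from *genes* are skipped with a warning.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = {"gene_id", "position", "score"}
    if not expected.issubset(table.columns):
        raise ValueError(f"structure score file must have columns {sorted(expected)}")
    if table["position"].isna().any() or table["score"].isna().any():
        bad = int(table[table[["position", "score"]].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"malformed structure score row at line {bad}")

    by_gene = {g.id: g for g in genes}
    profiles = []
    grouped = dict(iter(table.groupby("gene_id", sort=False)))
    for unknown in set(grouped) - set(by_gene):
        logger.warning("structure scores for unknown gene %s skipped", unknown)
    for gene_id, gene in by_gene.items():
        n = len(gene.seq)
        values = np.full(n, np.nan)
        if gene_id in grouped:
            sub = grouped[gene_id]
            pos = sub["position"].to_numpy(dtype=int) - offset_nt
            keep = (pos >= 0) & (pos < n)
            values[pos[keep]] = sub["score"].to_numpy(dtype=float)[keep]
        profiles.append(
            StructureProfile(
                gene_id=gene_id, kind="pars", values=values, defined=~np.isnan(values)
            )
        )
    return profiles


def extract_regions(
    profile: StructureProfile, rule: ThresholdRule
) -> list[StructureRegion]:
    """All maximal high/low runs of length >= ``rule.min_len_nt``.

    Runs are maximal (never split into shorter qualifying sub-runs) and
    reported in coordinate order; unclassified or undefined positions break
    runs.
    """
    labels = rule.classify(profile)
    regions: list[StructureRegion] = []
    n = len(labels)
    if n == 0:
        return regions
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        lab = labels[s]
        if lab != 0 and e - s >= rule.min_len_nt:
            regions.append(
                StructureRegion(
                    gene_id=profile.gene_id,
                    start_nt=int(s),
                    end_nt=int(e),
                    klass="high" if lab == 1 else "low",
                )
            )
    return regions


def write_regions_tsv(regions: Sequence[StructureRegion], path: str | Path) -> None:
    """BED-like TSV: gene_id, start, end, class, length (0-based half-open)."""
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "start": [r.start_nt for r in regions],
            "end": [r.end_nt for r in regions],
            "class": [r.klass for r in regions],
            "length": [r.length_nt for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)
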
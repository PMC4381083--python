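"""Codon translation-time tables and per-gene elongation-speed profiles.

The model assumes translation elongation is limited by diffusion of the
cognate aminoacyl-tRNA to the ribosomal A-site, so each sense codon carries
a fixed translation time (arbitrary units) inversely related to the
abundance of its cognate tRNA pool.  Mapping a table over a transcript
gives the instantaneous per-codon speed profile; smoothing with a sliding
window of 27 nt (9 codons, the approximate ribosome footprint) captures
local effects such as clusters of slow codons.

The tables packaged under ``data/`` are deterministic *synthetic stand-ins*
(see their headers): organism-specific experimental time tables are a user
input supplied via :func:`load_translation_times` in the same TSV format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import SENSE_CODONS, STOP_CODONS
from .sequence_io import CodingSequence

DEFAULT_SMOOTH_WINDOW_NT = 27


class InternalStopError(ValueError):
    """Raised when a CDS contains a stop codon where a time is required.

    Pipeline loops catch this and skip the gene with a warning.
    """


@dataclass(frozen=True)
class TranslationTimeTable:
    """Codon -> translation time (a.u.) for the 61 sense codons."""

    times: dict[str, float]
    source: str = "user"

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.times]
        if missing:
            raise ValueError(f"missing sense codons: {missing[:5]}...")
        extra_stops = sorted(set(self.times) & STOP_CODONS)
        if extra_stops:
            raise ValueError(f"stop codons present in table: {extra_stops}")
        unknown = sorted(set(self.times) - set(SENSE_CODONS))
        if unknown:
            raise ValueError(f"unknown codons in table: {unknown}")
        for codon, t in self.times.items():
            if not t > 0:
                raise ValueError(f"non-positive time for codon {codon}: {t}")

    def __getitem__(self, codon: str) -> float:
        return self.times[codon]

    def speed_rank(self, codons: tuple[str, ...]) -> list[str]:
        """Codons sorted fastest (shortest time) to slowest."""
        return sorted(codons, key=lambda c: self.times[c])


def uniform_time_table(time: float = 1.0) -> TranslationTimeTable:
    """All sense codons share one time; the null table used in tests."""
    return TranslationTimeTable({c: time for c in SENSE_CODONS}, source="uniform")


def load_translation_times(path: str | Path) -> TranslationTimeTable:
    """Load a codon-time table from TSV with columns ``codon, time_au``.

    Validates completeness (61 sense codons), uniqueness, positivity and
    absence of stop codons.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"codon", "time_au"}.issubset(table.columns):
        raise ValueError("time table needs columns codon, time_au")
    codons = table["codon"].str.upper().str.replace("U", "T")
    dup = codons[codons.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate codon in table: {dup.iloc[0]}")
    source = str(table["source"].iloc[0]) if "source" in table.columns else Path(path).stem
    return TranslationTimeTable(
        dict(zip(codons, table["time_au"].astype(float))), source=source
    )


def packaged_time_table(name: str) -> TranslationTimeTable:
    """Load a table shipped with the package.

    Available names: ``synthetic_ecoli``, ``synthetic_scer`` (deterministic
    stand-in tables in which GC-rich codons are fast and A-rich codons
    slow) and ``uniform``.
    """
    if name == "uniform":
        return uniform_time_table()
    ref = resources.files("ribotradeoff.data") / f"codon_times_{name}.tsv"
    if not ref.is_file():
        raise ValueError(f"no packaged time table named {name!r}")
    with resources.as_file(ref) as path:
        return load_translation_times(path)


@dataclass
class SpeedProfile:
    """Per-codon translation times for one gene, instantaneous + smoothed."""

    gene_id: str
    codon_times: np.ndarray
    smoothed_times: np.ndarray | None = None
    window_nt: int | None = None

    def __post_init__(self) -> None:
        self.codon_times = np.asarray(self.codon_times, dtype=float)

    @property
    def n_codons(self) -> int:
        return len(self.codon_times)


def codon_time_profile(
    cds: CodingSequence, table: TranslationTimeTable
) -> SpeedProfile:
    """Instantaneous per-codon times by direct table lookup.

    Raises :class:`InternalStopError` for genes containing stop codons
    (trimmed sequences should contain none).
    """
    times = np.empty(cds.n_codons)
    for k, codon in enumerate(cds.codons()):
        if codon in STOP_CODONS:
            raise InternalStopError(f"{cds.id}: stop codon {codon} at codon {k}")
        times[k] = table.times[codon]
    return SpeedProfile(gene_id=cds.id, codon_times=times)


def smooth_profile(
    profile: SpeedProfile, window_nt: int = DEFAULT_SMOOTH_WINDOW_NT
) -> SpeedProfile:
    """Centred sliding-window mean of the instantaneous times.

    ``window_nt`` must be a positive multiple of 3 with an odd codon count
    (27 nt = 9 codons by default).  Windows are truncated at profile ends
    (mean over the available codons), so every codon keeps a smoothed time.
    """
    if window_nt <= 0 or window_nt % 3:
        raise ValueError("window_nt must be a positive multiple of 3")
    w = window_nt // 3
    if w % 2 == 0:
        raise ValueError("window must cover an odd number of codons")
    x = profile.codon_times
    n = len(x)
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return SpeedProfile(
        gene_id=profile.gene_id,
        codon_times=x,
        smoothed_times=smoothed,
        window_nt=window_nt,
    )


def export_profile_tsv(
    cds: CodingSequence, profile: SpeedProfile, path: str | Path
) -> None:
    """TSV export: gene_id, codon_index, codon, time_au, smoothed_time_au."""
    pd.DataFrame(
        {
            "gene_id": profile.gene_id,
            "codon_index": np.arange(profile.n_codons),
            "codon": cds.codons(),
            "time_au": profile.codon_times,
            "smoothed_time_au": (
                profile.smoothed_times
                if profile.smoothed_times is not None
                else np.full(profile.n_codons, np.nan)
            ),
        }
    ).to_csv(path, sep="\t", index=False)
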
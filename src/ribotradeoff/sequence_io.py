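"""Loading, validation, trimming and subsetting of coding sequences.

Coding sequences enter the pipeline from multi-record FASTA files or from
GenBank records (CDS features, ``join()`` locations honoured, reverse-strand
features reverse-complemented).  Records that violate the reading frame
(length not a multiple of 3) or the plain A/C/G/T alphabet are excluded with
a logged warning: codon-time lookup and folding are undefined on ambiguous
bases and no masking rule is defensible.  Internal stop codons do *not*
cause exclusion here; they are flagged downstream when codon times are
assigned.

All coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import translate

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

#: nucleotides removed from each end of every CDS before analysis
#: (17 codons; insulates statistics from initiation/termination effects)
DEFAULT_TRIM_NT = 51


class EmptyGenomeError(ValueError):
    """Raised when a sequence file yields zero valid coding sequences."""


class GeneTooShortError(ValueError):
    """Raised when a CDS is too short to survive terminal trimming.

    Callers iterating over a genome should catch this and exclude the gene
    (it is a signal, not a silent drop).
    """


@dataclass(frozen=True)
class CodingSequence:
    """One protein-coding sequence.

    Attributes
    ----------
    id:
        Transcript/gene identifier.
    seq:
        Upper-case nucleotide string over {A, C, G, T}; length a multiple
        of 3.
    trimmed:
        Whether terminal trimming has been applied.
    offset_nt:
        Nucleotides removed from the 5' end (0 or the trim width); used to
        re-align externally supplied per-nucleotide scores.
    """

    id: str
    seq: str
    trimmed: bool = False
    offset_nt: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) % 3:
            raise ValueError(
                f"{self.id}: length {len(self.seq)} is not a multiple of 3"
            )
        if not _VALID_BASES.issuperset(self.seq):
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise ValueError(f"{self.id}: invalid characters {bad}")
        if self.offset_nt < 0:
            raise ValueError(f"{self.id}: negative offset_nt")
        if self.offset_nt and not self.trimmed:
            raise ValueError(f"{self.id}: offset_nt set on untrimmed sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def protein(self) -> str:
        return translate(self.seq)


@dataclass(frozen=True)
class GeneSubset:
    """A named subset of gene ids (e.g. ``highly_expressed``, a length bin)."""

    name: str
    member_ids: frozenset[str] = field(default_factory=frozenset)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.member_ids

    def __len__(self) -> int:
        return len(self.member_ids)


def _clean_candidate(rec_id: str, seq: str) -> CodingSequence | None:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        logger.warning("excluding %s: length %d not a multiple of 3", rec_id, len(seq))
        return None
    if not _VALID_BASES.issuperset(seq):
        logger.warning("excluding %s: non-ACGT characters", rec_id)
        return None
    if not seq:
        logger.warning("excluding %s: empty sequence", rec_id)
        return None
    return CodingSequence(id=rec_id, seq=seq)


def _iter_genbank_cds(path: Path) -> Iterable[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                continue
            tags = feat.qualifiers.get("locus_tag") or feat.qualifiers.get("gene")
            name = tags[0] if tags else f"{rec.id}:{feat.location}"
            yield name, str(feat.location.extract(rec.seq))


def load_coding_sequences(
    path: str | Path, format: Literal["fasta", "genbank"] = "fasta"
) -> list[CodingSequence]:
    """Load protein-coding sequences from FASTA or GenBank.

    Untranslated-RNA entries are not expected in FASTA input (users supply
    CDS FASTA); for GenBank only CDS features are extracted, so RNA genes
    are excluded by construction.  Frame or alphabet violations are dropped
    with a warning.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    EmptyGenomeError
        If no valid CDS remains after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        pairs = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
    elif format == "genbank":
        pairs = _iter_genbank_cds(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    genes = []
    for rec_id, seq in pairs:
        cds = _clean_candidate(rec_id, seq)
        if cds is not None:
            genes.append(cds)
    if not genes:
        raise EmptyGenomeError(f"no valid coding sequences in {path}")
    return genes


def write_fasta(genes: Sequence[CodingSequence], path: str | Path) -> None:
    """Write coding sequences to a multi-record FASTA file."""
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genes]
    SeqIO.write(records, str(Path(path)), "fasta")


def trim_terminal_regions(
    cds: CodingSequence, n_nt: int = DEFAULT_TRIM_NT
) -> CodingSequence:
    """Remove ``n_nt`` nucleotides (default 51 = 17 codons) from each end.

    Raises
    ------
    GeneTooShortError
        If nothing would remain (``len(cds) <= 2 * n_nt``); the caller
        excludes the gene from analysis.
    """
    if n_nt % 3:
        raise ValueError(f"trim width {n_nt} is not a multiple of 3")
    if n_nt == 0:
        return replace(cds, trimmed=True)
    if len(cds.seq) <= 2 * n_nt:
        raise GeneTooShortError(
            f"{cds.id}: length {len(cds.seq)} <= 2*{n_nt}, nothing remains"
        )
    return CodingSequence(
        id=cds.id, seq=cds.seq[n_nt:-n_nt], trimmed=True, offset_nt=n_nt
    )


def trim_genome(
    genes: Sequence[CodingSequence], n_nt: int = DEFAULT_TRIM_NT
) -> list[CodingSequence]:
    """Trim every gene, excluding (with a warning) those that are too short."""
    out = []
    for g in genes:
        try:
            out.append(trim_terminal_regions(g, n_nt))
        except GeneTooShortError as exc:
            logger.warning("%s", exc)
    return out


def gc_content(seqs: Sequence[CodingSequence | str]) -> float:
    """Pooled G+C fraction over all input sequences."""
    total = 0
    gc = 0
    for s in seqs:
        text = s.seq if isinstance(s, CodingSequence) else s
        total += len(text)
        gc += text.count("G") + text.count("C")
    if total == 0:
        raise ValueError("gc_content of empty input")
    return gc / total


# -- subset selection ---------------------------------------------------------

#: untrimmed length bins used for the gene-length stratification
LENGTH_BINS = {"short": (0, 500), "medium": (500, 1500), "long": (1500, None)}


def select_subset(genome: Sequence[CodingSequence], rule: dict) -> GeneSubset:
    """Select a named gene subset.

    ``rule`` is either ``{"kind": "ids", "ids": [...], "name": ...}`` or
    ``{"kind": "length", "bin": "short" | "medium" | "long"}``.  Length bins
    use untrimmed CDS length in bp; boundaries 500 and 1500 belong to the
    middle bin (short: <500, medium: 500..1500 inclusive, long: >1500).
    """
    kind = rule.get("kind")
    if kind == "ids":
        wanted = list(rule["ids"])
        present = {g.id for g in genome}
        missing = [i for i in wanted if i not in present]
        if missing:
            logger.warning("subset %s: %d ids not in genome", rule.get("name"), len(missing))
        return GeneSubset(
            name=rule.get("name", "id_list"),
            member_ids=frozenset(i for i in wanted if i in present),
        )
    if kind == "length":
        bin_name = rule["bin"]
        if bin_name not in LENGTH_BINS:
            raise ValueError(f"unknown length bin {bin_name!r}")
        members = set()
        for g in genome:
            n = len(g.seq) + (2 * g.offset_nt if g.trimmed else 0)
            if bin_name == "short" and n < 500:
                members.add(g.id)
            elif bin_name == "medium" and 500 <= n <= 1500:
                members.add(g.id)
            elif bin_name == "long" and n > 1500:
                members.add(g.id)
        return GeneSubset(name=bin_name, member_ids=frozenset(members))
    raise ValueError(f"unknown subset rule kind {kind!r}")


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text id list, one id per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
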
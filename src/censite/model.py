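"""Core domain types: miRNAs, transcripts, site classes and site matches.

Coordinate conventions used throughout the package:

* transcript (mRNA) coordinates are 0-based, half-open;
* miRNA positions are 1-based from the 5' end (so a centered window
  "starting at position 3" covers miRNA positions 3..13 inclusive).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick complement on the RNA alphabet.
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A, C, G, U}."""


def normalize_rna(sequence: str, name: str = "sequence") -> str:
    """Uppercase, convert DNA T to RNA U, and validate the alphabet.

    Raises :class:`AlphabetError` naming the offending symbol otherwise.
    """
    seq = sequence.upper().replace("T", "U")
    for ch in seq:
        if ch not in RNA_ALPHABET:
            raise AlphabetError(
                f"{name}: invalid character {ch!r}; expected A/C/G/U (or T)"
            )
    return seq


def revcomp(sequence: str) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return "".join(COMPLEMENT[b] for b in reversed(sequence))


class SiteClass(str, Enum):
    """Mutually exclusive binding-site classes.

    Seed classes are exact Watson-Crick matches to the miRNA 5' region;
    centered classes are 11-nt duplexes with the central region of the
    miRNA, optionally with G:U wobbles (GU) and at most one internal
    mismatch (1MM).
    """

    SEED_8MER = "SEED_8MER"
    SEED_7MER_M8 = "SEED_7MER_M8"
    SEED_7MER_A1 = "SEED_7MER_A1"
    CEN_WC_0MM = "CEN_WC_0MM"
    CEN_WC_1MM = "CEN_WC_1MM"
    CEN_GU_0MM = "CEN_GU_0MM"
    CEN_GU_1MM = "CEN_GU_1MM"

    @property
    def is_seed(self) -> bool:
        return self.name.startswith("SEED")

    @property
    def is_centered(self) -> bool:
        return self.name.startswith("CEN")


#: Stringency order (most stringent first) used for precedence resolution
#: when one locus is hit by several windows / seed anchors.
SEED_PRECEDENCE = (
    SiteClass.SEED_8MER,
    SiteClass.SEED_7MER_M8,
    SiteClass.SEED_7MER_A1,
)
CENTERED_PRECEDENCE = (
    SiteClass.CEN_WC_0MM,
    SiteClass.CEN_GU_0MM,
    SiteClass.CEN_WC_1MM,
    SiteClass.CEN_GU_1MM,
)
STRINGENCY_RANK = {
    cls: rank for rank, cls in enumerate(SEED_PRECEDENCE + CENTERED_PRECEDENCE)
}


class Region(str, Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence, 5'->3', with 1-based position numbering."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, f"miRNA {self.id}")
        )
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.id}: length {len(self.sequence)} < 8; "
                "positions 1..8 are required for seed definitions"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def position(self, pos: int) -> str:
        """Base at 1-based position ``pos`` from the 5' end."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"miRNA {self.id}: position {pos} out of range")
        return self.sequence[pos - 1]


@dataclass
class TranscriptModel:
    """A transcript sequence partitioned into 5'UTR / CDS / 3'UTR.

    ``utr5_end`` and ``cds_end`` are 0-based offsets; the regions
    ``[0, utr5_end)``, ``[utr5_end, cds_end)`` and ``[cds_end, len)``
    partition the sequence.
    """

    id: str
    gene_id: str
    sequence: str
    utr5_end: int
    cds_end: int
    is_canonical: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, f"transcript {self.id}")
        n = len(self.sequence)
        if not (0 <= self.utr5_end <= self.cds_end <= n):
            raise ValueError(
                f"transcript {self.id}: invalid region boundaries "
                f"utr5_end={self.utr5_end}, cds_end={self.cds_end}, length={n}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def region_bounds(self, region: Region) -> tuple[int, int]:
        if region is Region.UTR5:
            return 0, self.utr5_end
        if region is Region.CDS:
            return self.utr5_end, self.cds_end
        return self.cds_end, len(self.sequence)

    def region_length(self, region: Region) -> int:
        lo, hi = self.region_bounds(region)
        return hi - lo

    def region_of(self, position: int) -> Region:
        """Region containing a 0-based transcript offset."""
        if not 0 <= position < len(self.sequence):
            raise IndexError(
                f"transcript {self.id}: position {position} outside sequence"
            )
        if position < self.utr5_end:
            return Region.UTR5
        if position < self.cds_end:
            return Region.CDS
        return Region.UTR3


@dataclass(frozen=True)
class MatchResult:
    """Pair-by-pair evaluation of one 11-nt window against one site.

    Positions are 1-based positions within the 11-mer window, in miRNA
    orientation (window position 1 = 5'-most miRNA base of the window).
    """

    n_wc: int
    n_gu: int
    n_mm: int
    mm_positions: tuple[int, ...] = ()
    gu_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_wc + self.n_gu + self.n_mm != 11:
            raise ValueError("pair counts must sum to the window length (11)")


@dataclass
class SiteMatch:
    """A located, classified binding site on one transcript."""

    transcript_id: str
    mirna_id: str
    site_class: SiteClass
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    mirna_window_start: int  # 1-based miRNA position (3/4/5 centered, 1/2 seed)
    n_gu: int = 0
    n_mm: int = 0
    mm_window_position: Optional[int] = None
    region: Optional[Region] = None

    @property
    def midpoint(self) -> int:
        """0-based position used for region assignment."""
        return (self.start + self.end) // 2


@dataclass
class Peak:
    """An AGO-bound region: sequence context centered on the peak summit.

    ``center_offset`` is the 0-based index of the peak center within
    ``sequence``; ``differential`` marks peaks detected only in the
    wild-type condition (candidate miRNA-dependent peaks).
    """

    id: str
    sequence: str
    center_offset: int
    differential: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, f"peak {self.id}")
        if len(self.sequence) < 11:
            raise ValueError(f"peak {self.id}: sequence shorter than 11 nt")
        if not 0 <= self.center_offset < len(self.sequence):
            raise ValueError(f"peak {self.id}: center outside sequence")


def assign_canonical(transcripts: Iterable[TranscriptModel]) -> None:
    """Flag, per gene, the longest transcript as canonical (in place).

    Ties are broken by transcript id so the assignment is deterministic.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for members in by_gene.values():
        best = min(members, key=lambda t: (-len(t.sequence), t.id))
        for t in members:
            t.is_canonical = t is best
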
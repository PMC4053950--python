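"""Seed and centered binding-site scanning.

A *centered site* is an 11-nt duplex between the mRNA and the central
region of the miRNA, with the 11-mer window starting at miRNA position
3, 4 or 5.  Imperfect centered sites allow G:U wobble pairs and at most
one internal mismatch, giving four mutually exclusive classes
(WC 0MM, WC 1MM, GU 0MM, GU 1MM).  Seed sites are exact Watson-Crick
matches to the miRNA 5' region: 8mer, 7mer-m8 and 7mer-A1.

Pairing is antiparallel: window position j (1-based, miRNA 5'->3')
pairs with site position 12-j (site read 5'->3' on the mRNA).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .model import (
    COMPLEMENT,
    AlphabetError,
    CENTERED_PRECEDENCE,
    MatchResult,
    MiRNA,
    Region,
    SiteClass,
    SiteMatch,
    STRINGENCY_RANK,
    TranscriptModel,
)

WINDOW_LEN = 11
#: miRNA positions at which centered 11-mer windows may start.
WINDOW_STARTS = (3, 4, 5)

# Base encoding and pair classification tables for the vectorized scan.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGU"):
    _ENC[ord(_b)] = _i
_WC, _GU, _MM = 0, 1, 2
_PAIR = np.full((4, 4), _MM, dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGU")}
for _x, _y in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR[_IDX[_x], _IDX[_y]] = _WC
for _x, _y in (("G", "U"), ("U", "G")):
    _PAIR[_IDX[_x], _IDX[_y]] = _GU


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise AlphabetError(f"invalid RNA character {bad!r}")
    return arr


def pair_class(mirna_base: str, mrna_base: str) -> str:
    """Classify one miRNA:mRNA base pair as ``WC``, ``GU`` or ``MM``.

    Watson-Crick pairs are A:U, U:A, G:C, C:G; wobble pairs are G:U and
    U:G; anything else is a mismatch.
    """
    for b in (mirna_base, mrna_base):
        if b not in _IDX:
            raise AlphabetError(f"invalid RNA character {b!r}")
    code = _PAIR[_IDX[mirna_base], _IDX[mrna_base]]
    return ("WC", "GU", "MM")[code]


def centered_windows(mirna: MiRNA) -> list[tuple[int, str]]:
    """The 11-mer miRNA windows starting at positions 3, 4 and 5.

    Returns ``(window_start, window_seq)`` pairs in ascending start
    order, keeping only windows fully contained in the miRNA.  A miRNA
    shorter than 13 nt admits no window (error); 13-14 nt yields a
    partial set with a warning.
    """
    n = len(mirna.sequence)
    if n < WINDOW_LEN + WINDOW_STARTS[0] - 1:
        raise ValueError(
            f"miRNA {mirna.id}: length {n} < 13; no centered window fits"
        )
    out = [
        (s, mirna.sequence[s - 1 : s - 1 + WINDOW_LEN])
        for s in WINDOW_STARTS
        if s - 1 + WINDOW_LEN <= n
    ]
    if len(out) < len(WINDOW_STARTS):
        warnings.warn(
            f"miRNA {mirna.id}: length {n} < 15; only {len(out)} of "
            f"{len(WINDOW_STARTS)} centered windows fit",
            stacklevel=2,
        )
    return out


def match_window(window_seq: str, site_seq: str) -> MatchResult:
    """Evaluate an 11-mer miRNA window against an 11-mer mRNA site.

    Both sequences are read 5'->3'; pairing is antiparallel, so window
    position j pairs with site position 12-j.
    """
    if len(window_seq) != WINDOW_LEN or len(site_seq) != WINDOW_LEN:
        raise ValueError("window and site must both be 11 nt")
    n_wc = n_gu = n_mm = 0
    mm_pos: list[int] = []
    gu_pos: list[int] = []
    for j in range(1, WINDOW_LEN + 1):
        kind = pair_class(window_seq[j - 1], site_seq[WINDOW_LEN - j])
        if kind == "WC":
            n_wc += 1
        elif kind == "GU":
            n_gu += 1
            gu_pos.append(j)
        else:
            n_mm += 1
            mm_pos.append(j)
    return MatchResult(n_wc, n_gu, n_mm, tuple(mm_pos), tuple(gu_pos))


def classify_centered(
    m: MatchResult,
    allow_gu: bool = True,
    max_mm: int = 1,
    interior_only: bool = True,
    max_gu: Optional[int] = None,
) -> Optional[SiteClass]:
    """Assign a centered-site class to a window evaluation, or ``None``.

    With ``allow_gu`` false, wobble pairs count as mismatches.  A single
    permitted mismatch must lie at an interior window position (2-10)
    when ``interior_only`` is set; the precedence CEN_WC_0MM >
    CEN_GU_0MM > CEN_WC_1MM > CEN_GU_1MM makes classes exclusive.
    """
    if allow_gu:
        n_gu, n_mm = m.n_gu, m.n_mm
        mm_positions = m.mm_positions
    else:
        n_gu = 0
        n_mm = m.n_mm + m.n_gu
        mm_positions = tuple(sorted(m.mm_positions + m.gu_positions))
    if n_mm > max_mm:
        return None
    if interior_only and any(p in (1, WINDOW_LEN) for p in mm_positions):
        return None
    if max_gu is not None and n_gu > max_gu:
        return None
    if n_mm == 0:
        return SiteClass.CEN_WC_0MM if n_gu == 0 else SiteClass.CEN_GU_0MM
    return SiteClass.CEN_WC_1MM if n_gu == 0 else SiteClass.CEN_GU_1MM


def _merge_hits(hits: list[SiteMatch]) -> list[SiteMatch]:
    """Collapse chains of overlapping hits to one site per locus.

    Each chain keeps its most stringent class; ties go to the smallest
    start.  This prevents double-counting one duplex that is matched by
    several window starts.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h.start, STRINGENCY_RANK[h.site_class]))
    merged: list[SiteMatch] = []
    chain: list[SiteMatch] = [hits[0]]
    chain_end = hits[0].end
    for h in hits[1:]:
        if h.start < chain_end:
            chain.append(h)
            chain_end = max(chain_end, h.end)
        else:
            merged.append(min(chain, key=lambda x: (STRINGENCY_RANK[x.site_class], x.start)))
            chain = [h]
            chain_end = h.end
    merged.append(min(chain, key=lambda x: (STRINGENCY_RANK[x.site_class], x.start)))
    return merged


def scan_centered(
    mirna: MiRNA,
    transcript: TranscriptModel,
    allow_gu: bool = True,
    max_mm: int = 1,
    interior_only: bool = True,
    max_gu: Optional[int] = None,
    merge: bool = True,
) -> list[SiteMatch]:
    """Find centered sites for one miRNA in one transcript.

    Every transcript position is evaluated against every centered
    window; overlapping hits are merged (most stringent class, smallest
    start on ties) unless ``merge`` is disabled.  Output is sorted by
    start.
    """
    seq = transcript.sequence
    if len(seq) < WINDOW_LEN:
        return []
    arr = _encode(seq)
    sites = sliding_window_view(arr, WINDOW_LEN)  # (L-10, 11) mRNA 5'->3'
    hits: list[SiteMatch] = []
    for wstart, wseq in centered_windows(mirna):
        # reversed window: element k pairs site element k (window pos 11-k)
        rw = _encode(wseq)[::-1]
        codes = _PAIR[rw[np.newaxis, :], sites]
        if not allow_gu:
            codes = np.where(codes == _GU, _MM, codes)
        is_mm = codes == _MM
        n_mm = is_mm.sum(axis=1)
        n_gu = (codes == _GU).sum(axis=1)
        ok = n_mm <= max_mm
        if interior_only:
            # window positions 1 and 11 are site indices 10 and 0
            ok &= ~(is_mm[:, WINDOW_LEN - 1] | is_mm[:, 0])
        if max_gu is not None:
            ok &= n_gu <= max_gu
        for s in np.flatnonzero(ok):
            mm = int(n_mm[s])
            gu = int(n_gu[s])
            if mm == 0:
                cls = SiteClass.CEN_WC_0MM if gu == 0 else SiteClass.CEN_GU_0MM
            else:
                cls = SiteClass.CEN_WC_1MM if gu == 0 else SiteClass.CEN_GU_1MM
            mm_window_pos = None
            if mm == 1:
                k = int(np.flatnonzero(is_mm[s])[0])
                mm_window_pos = WINDOW_LEN - k
            hits.append(
                SiteMatch(
                    transcript_id=transcript.id,
                    mirna_id=mirna.id,
                    site_class=cls,
                    start=int(s),
                    end=int(s) + WINDOW_LEN,
                    mirna_window_start=wstart,
                    n_gu=gu,
                    n_mm=mm,
                    mm_window_position=mm_window_pos,
                    region=transcript.region_of((2 * int(s) + WINDOW_LEN) // 2),
                )
            )
    if merge:
        hits = _merge_hits(hits)
    else:
        hits.sort(key=lambda h: (h.start, STRINGENCY_RANK[h.site_class]))
    return hits


def scan_seed(mirna: MiRNA, transcript: TranscriptModel) -> list[SiteMatch]:
    """Find seed matches (8mer, 7mer-m8, 7mer-A1) for one miRNA.

    Seed matches are exact Watson-Crick only.  Following the TargetScanS
    convention, 7mer-A1 requires an A in the mRNA opposite miRNA
    position 1, irrespective of the miRNA's own first base; 6mers are
    not counted.  Each locus is reported once with the most stringent
    class (8mer > 7mer-m8 > 7mer-A1).
    """
    seq = transcript.sequence
    m = mirna.sequence
    # reverse complements of miRNA positions 2-8 and 2-7, as mRNA 5'->3'
    rc28 = "".join(COMPLEMENT[b] for b in reversed(m[1:8]))
    rc27 = "".join(COMPLEMENT[b] for b in reversed(m[1:7]))
    comp_m8 = COMPLEMENT[m[7]]
    hits: list[SiteMatch] = []
    L = len(seq)
    for s in range(L - 6):
        if seq[s : s + 7] == rc28:
            if s + 7 < L and seq[s + 7] == "A":
                hits.append(
                    SiteMatch(transcript.id, mirna.id, SiteClass.SEED_8MER,
                              s, s + 8, 1,
                              region=transcript.region_of((2 * s + 8) // 2))
                )
            else:
                hits.append(
                    SiteMatch(transcript.id, mirna.id, SiteClass.SEED_7MER_M8,
                              s, s + 7, 2,
                              region=transcript.region_of((2 * s + 7) // 2))
                )
        elif (
            seq[s : s + 6] == rc27
            and s + 6 < L
            and seq[s + 6] == "A"
            and (s == 0 or seq[s - 1] != comp_m8)
        ):
            # the elif + preceding-base guard suppress the 7mer-A1 calls
            # already covered by an 8mer / 7mer-m8 at this locus
            hits.append(
                SiteMatch(transcript.id, mirna.id, SiteClass.SEED_7MER_A1,
                          s, s + 7, 2,
                          region=transcript.region_of((2 * s + 7) // 2))
            )
    return hits


def scan_all(
    mirna: MiRNA,
    transcript: TranscriptModel,
    allow_gu: bool = True,
    max_mm: int = 1,
    interior_only: bool = True,
    max_gu: Optional[int] = None,
) -> list[SiteMatch]:
    """Seed and centered sites for one (miRNA, transcript) pair."""
    out = scan_seed(mirna, transcript) + scan_centered(
        mirna, transcript, allow_gu=allow_gu, max_mm=max_mm,
        interior_only=interior_only, max_gu=max_gu,
    )
    out.sort(key=lambda h: (h.start, STRINGENCY_RANK[h.site_class]))
    return out


# ---------------------------------------------------------------------------
# Count tables (the x_{a,b} covariates of the association analyses)
# ---------------------------------------------------------------------------

ALL_CLASSES = tuple(SiteClass)
ALL_REGIONS = tuple(Region)


def count_column(cls: SiteClass, region: Region) -> str:
    return f"count_{cls.value}_{region.value}"


def density_column(cls: SiteClass, region: Region) -> str:
    return f"density_{cls.value}_{region.value}"


@dataclass
class SiteCountRow:
    """Per-(transcript, miRNA) site counts and densities by region.

    Density is sites per kilobase of region; a zero-length region gets
    density 0 and is flagged.
    """

    transcript_id: str
    mirna_id: str
    counts: dict = field(default_factory=dict)  # (SiteClass, Region) -> int
    densities: dict = field(default_factory=dict)
    zero_length_regions: frozenset = frozenset()


def count_sites_by_region(
    matches: Sequence[SiteMatch],
    transcript: TranscriptModel,
    mirna_id: Optional[str] = None,
) -> SiteCountRow:
    """Tabulate site counts and densities per (class, region).

    Each match is assigned to exactly one region by its midpoint, so
    per-class region counts always sum to the per-class total.
    """
    if mirna_id is None:
        mirna_id = matches[0].mirna_id if matches else ""
    counts = {(c, r): 0 for c in ALL_CLASSES for r in ALL_REGIONS}
    for match in matches:
        if match.transcript_id != transcript.id:
            raise ValueError(
                f"match on {match.transcript_id} does not belong to "
                f"transcript {transcript.id}"
            )
        if not (0 <= match.start < match.end <= len(transcript.sequence)):
            raise ValueError(
                f"match {match.start}-{match.end} outside transcript "
                f"{transcript.id} (length {len(transcript.sequence)})"
            )
        region = transcript.region_of(match.midpoint)
        counts[(match.site_class, region)] += 1
    zero = frozenset(
        r for r in ALL_REGIONS if transcript.region_length(r) == 0
    )
    densities = {}
    for (c, r), n in counts.items():
        rl = transcript.region_length(r)
        densities[(c, r)] = (n * 1000.0 / rl) if rl > 0 else 0.0
    return SiteCountRow(transcript.id, mirna_id, counts, densities, zero)


class SiteCountTable:
    """Table of site counts/densities keyed by (transcript_id, mirna_id).

    Wraps a :class:`pandas.DataFrame` with one ``count_<class>_<region>``
    and one ``density_<class>_<region>`` column per (class, region).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df

    @classmethod
    def from_rows(cls, rows: Iterable[SiteCountRow]) -> "SiteCountTable":
        records = []
        index = []
        for row in rows:
            rec = {}
            for c in ALL_CLASSES:
                for r in ALL_REGIONS:
                    rec[count_column(c, r)] = row.counts[(c, r)]
                    rec[density_column(c, r)] = row.densities[(c, r)]
            rec["zero_length_regions"] = ",".join(
                sorted(r.value for r in row.zero_length_regions)
            )
            records.append(rec)
            index.append((row.transcript_id, row.mirna_id))
        df = pd.DataFrame.from_records(
            records,
            index=pd.MultiIndex.from_tuples(
                index or [], names=["transcript_id", "mirna_id"]
            ),
        )
        return cls(df)

    @classmethod
    def from_scan(
        cls,
        mirnas: Sequence[MiRNA],
        transcripts: Mapping[str, TranscriptModel],
        **scan_params,
    ) -> "SiteCountTable":
        rows = []
        for mirna in mirnas:
            for tid in transcripts:
                t = transcripts[tid]
                matches = scan_all(mirna, t, **scan_params)
                rows.append(count_sites_by_region(matches, t, mirna.id))
        return cls.from_rows(rows)

    def class_total(self, cls_: SiteClass) -> pd.Series:
        """Total count of a class across regions, per row."""
        cols = [count_column(cls_, r) for r in ALL_REGIONS]
        return self.df[cols].sum(axis=1)

    def has_class(self, cls_: SiteClass) -> pd.Series:
        return self.class_total(cls_) > 0

    def classes_present(self, transcript_id: str, mirna_id: str) -> set[SiteClass]:
        row = self.df.loc[(transcript_id, mirna_id)]
        return {c for c in ALL_CLASSES if sum(
            row[count_column(c, r)] for r in ALL_REGIONS) > 0}

    def n_distinct_classes(self) -> pd.Series:
        """Number of distinct site classes present, per row."""
        out = pd.Series(0, index=self.df.index)
        for c in ALL_CLASSES:
            out += self.has_class(c).astype(int)
        return out


def transcript_site_classes(
    table: SiteCountTable, transcript_id: str, mirna_id: str
) -> tuple[set[SiteClass], bool]:
    """Classes present in one transcript and whether they are exclusive.

    ``exclusive_ok`` is true iff at most one distinct class is present
    anywhere in the transcript (the filter used before the single-type
    contingency analyses).
    """
    present = table.classes_present(transcript_id, mirna_id)
    return present, len(present) <= 1


def summarize_site_coverage(
    target_keys: set, table: SiteCountTable
) -> dict[str, float]:
    """Proportion of targets carrying at least one site, per class.

    ``target_keys`` are (transcript_id, mirna_id) index keys.  Also
    reports ``any_seed``, ``any_centered`` and the cumulative ``any``
    proportion, which by construction dominates every per-class value.
    """
    if not target_keys:
        raise ValueError("empty target set")
    missing = set(target_keys) - set(table.df.index)
    if missing:
        raise KeyError(f"targets absent from count table: {sorted(missing)[:3]}")
    sub = table.df.loc[sorted(target_keys)]
    out: dict[str, float] = {}
    any_seed = pd.Series(False, index=sub.index)
    any_cen = pd.Series(False, index=sub.index)
    for c in ALL_CLASSES:
        cols = [count_column(c, r) for r in ALL_REGIONS]
        has = sub[cols].sum(axis=1) > 0
        out[c.value] = float(has.mean())
        if c.is_seed:
            any_seed |= has
        else:
            any_cen |= has
    out["any_seed"] = float(any_seed.mean())
    out["any_centered"] = float(any_cen.mean())
    out["any"] = float((any_seed | any_cen).mean())
    return out
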
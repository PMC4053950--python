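"""Readers and writers for the package's plain-text formats.

All transcript coordinates in these files are 0-based half-open; miRNA
positions are the sole 1-based quantity.  Writers are deterministic:
stable column order, fixed float formats (6 significant digits, p/q in
scientific notation) and LF line endings.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import EnrichmentResult, ExpressionMatrix, TargetSet
from .model import MiRNA, Peak, Region, SiteMatch, TranscriptModel, normalize_rna
from .scanner import SiteCountTable

FLOAT_FMT = "%.6g"
PVAL_FMT = "%.6e"

COORD_COMMENT = (
    "# coordinates: transcript 0-based half-open; miRNA positions 1-based\n"
)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: normalized RNA sequence}.

    Ids are taken to the first whitespace; sequences are uppercased and
    T is converted to U.  Duplicate ids and empty sequences are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r}")
        out[rec.id] = normalize_rna(seq, f"record {rec.id}")
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Mapping[str, str], path) -> None:
    """Write sequences 60 columns wide with LF endings."""
    with open(path, "w", newline="\n") as fh:
        for rid in records:
            fh.write(f">{rid}\n")
            seq = records[rid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_mirnas(path) -> list[MiRNA]:
    return [MiRNA(rid, seq) for rid, seq in read_fasta(path).items()]


def read_region_table(path, sequences: Mapping[str, str]) -> dict[str, TranscriptModel]:
    """Read the region-annotation TSV and build transcript models.

    Expected header: transcript_id, gene_id, utr5_end, cds_end,
    is_canonical.  Offsets are validated against sequence lengths; if a
    gene has no canonical flag, the longest transcript is auto-assigned
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["transcript_id", "gene_id", "utr5_end", "cds_end", "is_canonical"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    out: dict[str, TranscriptModel] = {}
    for row in df.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in sequences:
            raise ValueError(f"transcript {tid!r} in region table absent from FASTA")
        seq = sequences[tid]
        if row.cds_end > len(seq):
            raise ValueError(
                f"transcript {tid}: cds_end={row.cds_end} exceeds length {len(seq)}"
            )
        out[tid] = TranscriptModel(
            id=tid,
            gene_id=str(row.gene_id),
            sequence=seq,
            utr5_end=int(row.utr5_end),
            cds_end=int(row.cds_end),
            is_canonical=bool(row.is_canonical),
        )
    # validate the canonical rule per gene
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in out.values():
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene, members in by_gene.items():
        flagged = [t for t in members if t.is_canonical]
        longest = min(members, key=lambda t: (-len(t.sequence), t.id))
        if not flagged:
            warnings.warn(
                f"gene {gene}: no canonical transcript flagged; "
                f"auto-assigning the longest ({longest.id})",
                stacklevel=2,
            )
            longest.is_canonical = True
        elif len(flagged) > 1:
            raise ValueError(f"gene {gene}: multiple canonical transcripts flagged")
    return out


def write_region_table(transcripts: Mapping[str, TranscriptModel], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(COORD_COMMENT)
        fh.write("transcript_id\tgene_id\tutr5_end\tcds_end\tis_canonical\n")
        for tid in sorted(transcripts):
            t = transcripts[tid]
            fh.write(
                f"{t.id}\t{t.gene_id}\t{t.utr5_end}\t{t.cds_end}\t"
                f"{int(t.is_canonical)}\n"
            )


def read_expression_table(
    expr_path, samples_path, detection_path=None
) -> ExpressionMatrix:
    """Read expression TSV (probe_id + sample columns) and sample sheet."""
    expr = pd.read_csv(expr_path, sep="\t", comment="#", index_col=0)
    for col in expr.columns:
        if not pd.api.types.is_numeric_dtype(expr[col]):
            bad = expr.index[expr[col].map(
                lambda v: not isinstance(v, (int, float))).to_numpy()]
            raise ValueError(
                f"non-numeric value in column {col!r}"
                + (f" at probe {bad[0]!r}" if len(bad) else "")
            )
    sheet = pd.read_csv(samples_path, sep="\t", comment="#")
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise ValueError("sample sheet requires columns sample_id, group")
    groups = sheet.set_index("sample_id")["group"]
    missing = [c for c in expr.columns if c not in groups.index]
    if missing:
        raise ValueError(f"sample columns without group assignment: {missing}")
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", comment="#", index_col=0)
        detection = detection.loc[expr.index, expr.columns]
    return ExpressionMatrix(
        values=expr, groups=groups, detection_p=detection, log_scale=False
    )


def write_expression_table(matrix: ExpressionMatrix, expr_path, samples_path,
                           detection_path=None) -> None:
    matrix.values.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT,
                         lineterminator="\n")
    with open(samples_path, "w", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for s in matrix.values.columns:
            fh.write(f"{s}\t{matrix.groups[s]}\n")
    if detection_path is not None and matrix.detection_p is not None:
        matrix.detection_p.to_csv(detection_path, sep="\t",
                                  float_format=PVAL_FMT, lineterminator="\n")


def write_probe_map(probe_map: Mapping[str, set], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("probe_id\ttranscript_id\n")
        for probe in sorted(probe_map):
            for tid in sorted(probe_map[probe]):
                fh.write(f"{probe}\t{tid}\n")


def read_probe_map(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.probe_id), set()).add(str(row.transcript_id))
    return out


SITE_COLUMNS = [
    "transcript_id", "mirna_id", "site_class", "start", "end", "region",
    "mirna_window_start", "n_gu", "n_mm", "mm_window_position",
]


def write_site_table(matches: Sequence[SiteMatch], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(COORD_COMMENT)
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for m in sorted(matches, key=lambda x: (x.transcript_id, x.mirna_id, x.start)):
            mmp = "" if m.mm_window_position is None else str(m.mm_window_position)
            region = m.region.value if m.region is not None else ""
            fh.write(
                f"{m.transcript_id}\t{m.mirna_id}\t{m.site_class.value}\t"
                f"{m.start}\t{m.end}\t{region}\t{m.mirna_window_start}\t"
                f"{m.n_gu}\t{m.n_mm}\t{mmp}\n"
            )


def write_bed6(matches: Sequence[SiteMatch], path) -> None:
    """Sites as BED6: name = class, score = 11 - n_mm - n_gu."""
    with open(path, "w", newline="\n") as fh:
        for m in sorted(matches, key=lambda x: (x.transcript_id, x.start)):
            score = 11 - m.n_mm - m.n_gu
            fh.write(
                f"{m.transcript_id}\t{m.start}\t{m.end}\t"
                f"{m.site_class.value}\t{score}\t+\n"
            )


def write_enrichment_table(result: EnrichmentResult, path) -> None:
    df = result.table.copy()
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# moderated t: prior_df={result.prior_df:.6g} "
            f"prior_var={result.prior_var:.6g} residual_df={result.residual_df:.6g}\n"
        )
        fh.write("probe_id\tlogFC\tt\tp\tq\tenriched\n")
        for probe, row in df.iterrows():
            fh.write(
                f"{probe}\t{row['logFC']:.6g}\t{row['t']:.6g}\t"
                f"{row['p']:.6e}\t{row['q']:.6e}\t{int(row['enriched'])}\n"
            )


def write_targets_table(targets: TargetSet, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("transcript_id\tmirna_id\tambiguous\n")
        for tid in sorted(targets.transcripts):
            fh.write(f"{tid}\t{targets.mirna_id}\t0\n")
        for tid in sorted(targets.ambiguous):
            fh.write(f"{tid}\t{targets.mirna_id}\t1\n")


def write_peaks_table(peaks: Sequence[Peak], path) -> None:
    """Combined peak TSV: id, sequence, center_offset, differential."""
    with open(path, "w", newline="\n") as fh:
        fh.write("peak_id\tsequence\tcenter_offset\tdifferential\n")
        for p in peaks:
            fh.write(
                f"{p.id}\t{p.sequence}\t{p.center_offset}\t{int(p.differential)}\n"
            )


def read_peaks(path, fasta_path=None) -> list[Peak]:
    """Read peaks from a combined TSV, or BED6 plus a sequence FASTA.

    BED6 columns: chrom, start, end, name, score (0/1 differential
    flag), strand; the companion FASTA is keyed by peak name and the
    center defaults to the interval midpoint.
    """
    if fasta_path is None:
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"peak_id", "sequence", "center_offset", "differential"}
        if not required <= set(df.columns):
            raise ValueError(f"peak TSV requires columns {sorted(required)}")
        return [
            Peak(
                id=str(r.peak_id),
                sequence=str(r.sequence),
                center_offset=int(r.center_offset),
                differential=bool(int(r.differential)),
            )
            for r in df.itertuples(index=False)
        ]
    seqs = read_fasta(fasta_path)
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED6 line with {len(parts)} fields: {line!r}")
            chrom, start, end, name, score, _strand = parts[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"peak {name}: interval end <= start")
            if name not in seqs:
                raise ValueError(f"peak {name}: no sequence in FASTA")
            seq = seqs[name]
            if len(seq) != end - start:
                raise ValueError(
                    f"peak {name}: sequence length {len(seq)} != interval "
                    f"length {end - start}"
                )
            peaks.append(
                Peak(
                    id=name,
                    sequence=seq,
                    center_offset=(end - start) // 2,
                    differential=bool(int(score)),
                )
            )
    return peaks
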
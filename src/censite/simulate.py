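"""Synthetic study generator with machine-readable ground truth.

Emulates the inputs of a biotin pull-down study: a transcriptome with
realistic region lengths and i.i.d. base composition, binding sites of
each class planted at controlled per-region rates, replicate pull-down
and control expression matrices whose log-intensity shift is linear in
site counts, and AGO-peak sets whose planted sites cluster near peak
centers.  Every planted feature is verified with the scanner before it
enters the truth record, so downstream recovery checks are exact.

All randomness flows from a master seed through named substreams, so
each stage is reproducible independently of the others.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import CONTROL, PULLDOWN, ExpressionMatrix
from .model import (
    COMPLEMENT,
    MiRNA,
    Peak,
    Region,
    SiteClass,
    TranscriptModel,
    assign_canonical,
    revcomp,
)
from .scanner import (
    SiteCountTable,
    WINDOW_LEN,
    centered_windows,
    count_column,
    scan_centered,
    scan_seed,
)

BASES = "ACGU"


def substream(seed: int, *labels) -> np.random.Generator:
    """Independent generator derived from the master seed and labels."""
    key = tuple(
        int.from_bytes(
            hashlib.blake2s(str(lab).encode(), digest_size=4).digest(), "little"
        )
        for lab in labels
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

def _default_plant_rates() -> dict:
    """Per-transcript probability of one planted site per (class, region).

    Rates are modest so most site occurrences remain class-typical
    (imperfect GU classes also arise from background sequence, as in a
    real transcriptome).
    """
    U3, CDS = Region.UTR3, Region.CDS
    return {
        (SiteClass.SEED_8MER, U3): 0.06,
        (SiteClass.SEED_7MER_M8, U3): 0.08,
        (SiteClass.SEED_7MER_A1, U3): 0.08,
        (SiteClass.CEN_WC_0MM, U3): 0.05,
        (SiteClass.CEN_WC_1MM, U3): 0.06,
        (SiteClass.CEN_GU_0MM, U3): 0.06,
        (SiteClass.CEN_GU_1MM, U3): 0.10,
        (SiteClass.SEED_7MER_M8, CDS): 0.04,
        (SiteClass.CEN_GU_1MM, CDS): 0.06,
    }


def _default_betas() -> dict:
    """Log2-shift per site count, mirroring the association model.

    Seed effects exceed centered effects, 3'UTR effects exceed CDS
    effects, and every class has a positive effect.
    """
    U3, CDS = Region.UTR3, Region.CDS
    return {
        (SiteClass.SEED_8MER, U3): 1.2,
        (SiteClass.SEED_7MER_M8, U3): 0.9,
        (SiteClass.SEED_7MER_A1, U3): 0.7,
        (SiteClass.CEN_WC_0MM, U3): 0.8,
        (SiteClass.CEN_WC_1MM, U3): 0.5,
        (SiteClass.CEN_GU_0MM, U3): 0.5,
        (SiteClass.CEN_GU_1MM, U3): 0.35,
        (SiteClass.SEED_7MER_M8, CDS): 0.45,
        (SiteClass.CEN_GU_1MM, CDS): 0.2,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study scale."""

    seed: int = 0
    # transcriptome
    n_transcripts: int = 5000
    isoform_fraction: float = 0.2  # genes with a second, shorter isoform
    region_log_mean: dict = field(
        default_factory=lambda: {Region.UTR5: 5.0, Region.CDS: 7.0, Region.UTR3: 6.5}
    )
    region_log_sd: dict = field(
        default_factory=lambda: {Region.UTR5: 0.7, Region.CDS: 0.5, Region.UTR3: 0.8}
    )
    region_min_len: dict = field(
        default_factory=lambda: {Region.UTR5: 20, Region.CDS: 90, Region.UTR3: 60}
    )
    base_composition: tuple = (0.27, 0.23, 0.24, 0.26)  # A, C, G, U
    mirna_length: int = 22
    # site planting
    plant_rates: dict = field(default_factory=_default_plant_rates)
    # pull-down expression model
    beta0: float = -1.2
    betas: dict = field(default_factory=_default_betas)
    n_pulldown: int = 3
    n_control: int = 3
    baseline_log2: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    undetected_fraction: float = 0.02
    # AGO peaks
    n_peaks: int = 2000
    differential_fraction: float = 0.05
    peak_planted_rate: float = 0.8
    peak_background_rate: float = 0.1
    offset_sd: float = 15.0
    half_window: int = 200
    peak_site_class: SiteClass = SiteClass.CEN_GU_1MM

    def validate(self) -> None:
        if any(r < 0 for r in self.plant_rates.values()):
            raise ValueError("planting rates must be non-negative")
        if self.n_pulldown < 2 or self.n_control < 2:
            raise ValueError("replicate counts must be >= 2")
        if self.offset_sd >= self.half_window:
            raise ValueError("offset s.d. must be smaller than the half-window")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the synthetic files."""

    planted_sites: list = field(default_factory=list)
    status: dict = field(default_factory=dict)  # probe -> bool
    true_shift: dict = field(default_factory=dict)  # probe -> float
    peak_records: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_sites": self.planted_sites,
                    "status": self.status,
                    "true_shift": self.true_shift,
                    "peak_records": self.peak_records,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_sites=d["planted_sites"],
            status=d["status"],
            true_shift=d["true_shift"],
            peak_records=d["peak_records"],
        )


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def random_sequence(n: int, composition, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(composition)))


def random_mirna(rng: np.random.Generator, length: int = 22, mirna_id: str = "mir-sim") -> MiRNA:
    return MiRNA(mirna_id, "".join(rng.choice(list(BASES), size=length)))


def generate_transcriptome(
    config: SimulationConfig,
) -> dict[str, TranscriptModel]:
    """Sample transcripts with log-normal region lengths.

    A configured fraction of genes carries a second, shorter isoform so
    the canonical-transcript rule (longest per gene) is exercised.
    Deterministic given the config seed.
    """
    config.validate()
    rng = substream(config.seed, "transcriptome")
    transcripts: dict[str, TranscriptModel] = {}
    gene_idx = 0
    i = 0
    while i < config.n_transcripts:
        gene_id = f"G{gene_idx:05d}"
        n_iso = 2 if (
            rng.random() < config.isoform_fraction
            and i + 1 < config.n_transcripts
        ) else 1
        for k in range(n_iso):
            lengths = {}
            for region in Region:
                raw = rng.lognormal(
                    config.region_log_mean[region], config.region_log_sd[region]
                )
                lengths[region] = max(config.region_min_len[region], int(raw))
            if k == 1:  # secondary isoform: truncated 3'UTR
                lengths[Region.UTR3] = max(
                    config.region_min_len[Region.UTR3], lengths[Region.UTR3] // 2
                )
            total = sum(lengths.values())
            seq = random_sequence(total, config.base_composition, rng)
            tid = f"T{i:05d}"
            transcripts[tid] = TranscriptModel(
                id=tid,
                gene_id=gene_id,
                sequence=seq,
                utr5_end=lengths[Region.UTR5],
                cds_end=lengths[Region.UTR5] + lengths[Region.CDS],
            )
            i += 1
            if i >= config.n_transcripts:
                break
        gene_idx += 1
    assign_canonical(transcripts.values())
    return transcripts


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def _mm_base(window_base: str, rng: np.random.Generator) -> str:
    """An mRNA base that mismatches the given miRNA base (no WC, no GU)."""
    banned = {COMPLEMENT[window_base]}
    if window_base == "G":
        banned.add("U")
    elif window_base == "U":
        banned.add("G")
    choices = [b for b in BASES if b not in banned]
    return choices[int(rng.integers(len(choices)))]


def _centered_site_sequence(
    window_seq: str, site_class: SiteClass, rng: np.random.Generator
) -> Optional[str]:
    """Construct an 11-mer mRNA site realizing exactly one centered class.

    Returns None when the window cannot support the class (a GU class
    needs at least one G or U in the window).
    """
    site = list(revcomp(window_seq))  # site[k] pairs window position 11-k
    if site_class in (SiteClass.CEN_GU_0MM, SiteClass.CEN_GU_1MM):
        eligible = [
            k for k in range(WINDOW_LEN) if window_seq[WINDOW_LEN - 1 - k] in "GU"
        ]
        if not eligible:
            return None
        n_gu = 1 + int(rng.integers(0, min(2, len(eligible))))
        for k in rng.choice(eligible, size=n_gu, replace=False):
            wb = window_seq[WINDOW_LEN - 1 - k]
            site[k] = "U" if wb == "G" else "G"
    if site_class in (SiteClass.CEN_WC_1MM, SiteClass.CEN_GU_1MM):
        j = int(rng.integers(2, WINDOW_LEN))  # interior window position 2..10
        k = WINDOW_LEN - j
        site[k] = _mm_base(window_seq[j - 1], rng)
    return "".join(site)


def _verify_planted(
    transcript: TranscriptModel,
    mirna: MiRNA,
    records: list[dict],
) -> bool:
    """Check every planted record is recovered at its exact class/start."""
    cen = scan_centered(mirna, transcript)
    seed = scan_seed(mirna, transcript)
    cen_at = {(m.start, m.site_class) for m in cen}
    seed_at = {(m.start, m.site_class) for m in seed}
    for rec in records:
        cls = SiteClass(rec["site_class"])
        found = (rec["start"], cls) in (seed_at if cls.is_seed else cen_at)
        if not found:
            return False
    return True


def plant_site(
    transcript: TranscriptModel,
    mirna: MiRNA,
    site_class: SiteClass,
    region: Region,
    rng: np.random.Generator,
    reserved: Optional[list] = None,
    existing_records: Optional[list] = None,
    max_retries: int = 40,
) -> dict:
    """Write one site of exactly the requested class into a transcript.

    The position is uniform within the region; after writing, the
    scanner must recover the site at the planted position with the
    planted class (no accidental upgrade through overlapping windows),
    otherwise the bases are reverted and a new position/realization is
    drawn.  Raises when the region is too short or retries exhaust.
    """
    reserved = reserved if reserved is not None else []
    existing_records = existing_records if existing_records is not None else []
    lo, hi = transcript.region_bounds(region)
    if site_class.is_seed:
        site_len = 8 if site_class is SiteClass.SEED_8MER else 7
    else:
        site_len = WINDOW_LEN
    if hi - lo < site_len:
        raise ValueError(
            f"region {region.value} of {transcript.id} too short for "
            f"{site_class.value} ({hi - lo} < {site_len})"
        )
    windows = centered_windows(mirna)
    m = mirna.sequence
    for _ in range(max_retries):
        s = int(rng.integers(lo, hi - site_len + 1))
        # keep a margin so merging cannot chain into neighbouring plants
        if any(s - 12 < r_end and r_start < s + site_len + 12
               for r_start, r_end in reserved):
            continue
        seq = transcript.sequence
        if site_class.is_seed:
            if site_class is SiteClass.SEED_8MER:
                site = revcomp(m[1:8]) + "A"
            elif site_class is SiteClass.SEED_7MER_M8:
                site = revcomp(m[1:8])
            else:  # 7mer-A1
                site = revcomp(m[1:7]) + "A"
            lo_w, hi_w = s, s + len(site)
            new = seq[:s] + site + seq[s + len(site):]
            # guard the flanks so the class cannot silently upgrade
            if site_class is SiteClass.SEED_7MER_M8:
                if s + 7 < len(new) and new[s + 7] == "A":
                    new = new[: s + 7] + "C" + new[s + 8:]
                    hi_w = s + 8
            if site_class is SiteClass.SEED_7MER_A1:
                if s > 0 and new[s - 1] == COMPLEMENT[m[7]]:
                    repl = "A" if COMPLEMENT[m[7]] != "A" else "C"
                    new = new[: s - 1] + repl + new[s:]
                    lo_w = s - 1
        else:
            wstart, wseq = windows[int(rng.integers(len(windows)))]
            site = _centered_site_sequence(wseq, site_class, rng)
            if site is None:
                continue
            lo_w, hi_w = s, s + WINDOW_LEN
            new = seq[:s] + site + seq[s + WINDOW_LEN:]
        original = transcript.sequence
        transcript.sequence = new
        rec = {
            "transcript_id": transcript.id,
            "mirna_id": mirna.id,
            "site_class": site_class.value,
            "region": region.value,
            "start": s,
            "end": s + site_len,
        }
        if _verify_planted(transcript, mirna, existing_records + [rec]):
            reserved.append((min(s, lo_w), max(s + site_len, hi_w)))
            existing_records.append(rec)
            return rec
        transcript.sequence = original
    raise RuntimeError(
        f"could not plant {site_class.value} in {region.value} of "
        f"{transcript.id} after {max_retries} attempts"
    )


def plant_sites(
    transcripts: dict[str, TranscriptModel],
    mirna: MiRNA,
    config: SimulationConfig,
) -> list[dict]:
    """Plant sites across a transcriptome at the configured rates."""
    rng = substream(config.seed, "planting")
    records: list[dict] = []
    order = sorted(config.plant_rates)
    for tid in transcripts:
        t = transcripts[tid]
        reserved: list = []
        trecords: list = []
        for (cls, region) in order:
            rate = config.plant_rates[(cls, region)]
            if rng.random() >= rate:
                continue
            site_len = 8 if cls.is_seed else WINDOW_LEN
            lo, hi = t.region_bounds(region)
            if hi - lo < site_len + 1:
                continue
            try:
                rec = plant_site(
                    t, mirna, cls, region, rng,
                    reserved=reserved, existing_records=trecords,
                )
            except RuntimeError:
                continue
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Pull-down expression
# ---------------------------------------------------------------------------

def deterministic_shift(
    table: SiteCountTable, config: SimulationConfig
) -> pd.Series:
    """Deterministic part of the pull-down log2 shift, per row.

    shift_i = beta0 + sum_{a,b} beta_{a,b} * count_{a,b,i}; computed
    from *scanned* counts, so background sites contribute exactly as
    planted ones do.
    """
    shift = pd.Series(config.beta0, index=table.df.index, dtype=float)
    for (cls, region), beta in sorted(config.betas.items()):
        shift += beta * table.df[count_column(cls, region)].astype(float)
    return shift


def simulate_pulldown(
    table: SiteCountTable,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict, pd.DataFrame]:
    """Replicate expression matrices for pull-down vs control.

    One probe per transcript (identity probe map).  The true enrichment
    status is deterministic_shift > 0; pull-down samples add the
    *rectified* shift max(0, deterministic_shift) plus replicate noise,
    so non-target probes are genuinely unchanged between groups (a
    pull-down enriches targets, it does not deplete non-targets) and
    the one-sided false-discovery calibration is meaningful after
    normalization.  Detection p-values are emitted so the detection
    filter is exercised (a configured fraction of probes is undetected
    in a control sample and should be filtered).
    """
    rng = substream(config.seed, "pulldown")
    shift = deterministic_shift(table, config)
    n = len(shift)
    probes = [f"P_{tid}" for tid, _ in shift.index]
    baseline = rng.normal(config.baseline_log2, config.baseline_sd, size=n)
    cols = {}
    groups = {}
    applied_shift = np.maximum(shift.to_numpy(), 0.0)
    for j in range(config.n_pulldown):
        name = f"pulldown_{j + 1}"
        cols[name] = baseline + applied_shift + rng.normal(
            0.0, config.noise_sd, size=n
        )
        groups[name] = PULLDOWN
    for j in range(config.n_control):
        name = f"control_{j + 1}"
        cols[name] = baseline + rng.normal(0.0, config.noise_sd, size=n)
        groups[name] = CONTROL
    log2 = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"))
    linear = np.power(2.0, log2)
    detect = rng.uniform(0.0, 0.005, size=(n, len(cols)))
    undetected = rng.random(n) < config.undetected_fraction
    # undetected probes miss the threshold in the first control sample
    ctrl0 = list(cols).index("control_1")
    detect[undetected, ctrl0] = rng.uniform(0.02, 1.0, size=int(undetected.sum()))
    detection_p = pd.DataFrame(detect, index=linear.index, columns=linear.columns)
    matrix = ExpressionMatrix(
        values=linear,
        groups=pd.Series(groups),
        detection_p=detection_p,
        log_scale=False,
    )
    probe_map = {p: {tid} for p, (tid, _) in zip(probes, shift.index)}
    truth = pd.DataFrame(
        {
            "probe_id": probes,
            "transcript_id": [tid for tid, _ in shift.index],
            "true_shift": shift.to_numpy(),
            "true_status": shift.to_numpy() > 0,
            "detected": ~undetected,
        }
    ).set_index("probe_id")
    return matrix, probe_map, truth


def simulate_expression_experiment(
    n_probes: int,
    frac_enriched: float,
    effect: float,
    n_pulldown: int = 3,
    n_control: int = 3,
    noise_sd: float = 0.3,
    baseline_log2: float = 7.0,
    baseline_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Minimal calibration experiment: a fraction of probes is shifted.

    Returns the (linear-scale) matrix and the boolean truth vector.
    Used for null calibration and false-discovery-proportion checks.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_true = int(round(n_probes * frac_enriched))
    truth = np.zeros(n_probes, dtype=bool)
    truth[:n_true] = True
    shift = np.where(truth, effect, 0.0)
    baseline = rng.normal(baseline_log2, baseline_sd, size=n_probes)
    cols = {}
    groups = {}
    for j in range(n_pulldown):
        cols[f"pulldown_{j + 1}"] = baseline + shift + rng.normal(
            0, noise_sd, n_probes
        )
        groups[f"pulldown_{j + 1}"] = PULLDOWN
    for j in range(n_control):
        cols[f"control_{j + 1}"] = baseline + rng.normal(0, noise_sd, n_probes)
        groups[f"control_{j + 1}"] = CONTROL
    probes = pd.Index([f"P{i:05d}" for i in range(n_probes)], name="probe_id")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(cols, index=probes),
        groups=pd.Series(groups),
        log_scale=True,
    )
    return matrix, truth


def simulate_logistic_status(
    table: SiteCountTable,
    beta0: float,
    betas: dict,
    rng: np.random.Generator,
    mode: str = "count",
) -> pd.Series:
    """Bernoulli enrichment status drawn from the logistic model.

    Used for parameter-recovery studies where the estimand is the
    logistic coefficient vector itself.
    """
    from .scanner import density_column

    colfun = count_column if mode == "count" else density_column
    eta = pd.Series(beta0, index=table.df.index, dtype=float)
    for (cls, region), beta in sorted(betas.items()):
        eta += beta * table.df[colfun(cls, region)].astype(float)
    p = 1.0 / (1.0 + np.exp(-eta.to_numpy()))
    return pd.Series(rng.random(len(p)) < p, index=table.df.index).astype(int)


# ---------------------------------------------------------------------------
# AGO peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    config: SimulationConfig, mirna: MiRNA
) -> tuple[list[Peak], list[dict]]:
    """Peak sequences with sites concentrated at differential centers.

    A configured fraction of peaks is differential; those receive a
    planted site at a Gaussian offset (s.d. ``offset_sd``) from the
    center.  Unchanged peaks receive sites at the background rate at
    uniform offsets.  Deterministic given the config seed.
    """
    config.validate()
    rng = substream(config.seed, "peaks")
    hw = config.half_window
    peak_len = 2 * hw + 1
    n_diff = int(round(config.n_peaks * config.differential_fraction))
    cls = config.peak_site_class
    site_len = (8 if cls is SiteClass.SEED_8MER else 7) if cls.is_seed else WINDOW_LEN
    windows = centered_windows(mirna)
    m = mirna.sequence
    peaks: list[Peak] = []
    records: list[dict] = []
    for i in range(config.n_peaks):
        differential = i < n_diff
        seq = random_sequence(peak_len, config.base_composition, rng)
        planted_offset = None
        rate = config.peak_planted_rate if differential else config.peak_background_rate
        if rng.random() < rate:
            for _ in range(40):
                if differential:
                    off = int(round(rng.normal(0.0, config.offset_sd)))
                else:
                    off = int(rng.integers(-(hw - site_len), hw - site_len + 1))
                mid_shift = site_len // 2  # site midpoint relative to start
                s = hw + off - mid_shift
                if s < 0 or s + site_len > peak_len:
                    continue
                if cls.is_seed:
                    if cls is SiteClass.SEED_8MER:
                        site = revcomp(m[1:8]) + "A"
                    elif cls is SiteClass.SEED_7MER_M8:
                        site = revcomp(m[1:8])
                    else:
                        site = revcomp(m[1:7]) + "A"
                else:
                    wstart, wseq = windows[int(rng.integers(len(windows)))]
                    site = _centered_site_sequence(wseq, cls, rng)
                    if site is None:
                        continue
                cand = seq[:s] + site + seq[s + site_len:]
                probe = TranscriptModel(
                    id=f"pk{i:05d}", gene_id="peak", sequence=cand,
                    utr5_end=0, cds_end=0,
                )
                matches = (
                    scan_seed(mirna, probe) if cls.is_seed
                    else scan_centered(mirna, probe)
                )
                realized = [
                    mt for mt in matches if mt.start == s and mt.site_class is cls
                ]
                if realized:
                    seq = cand
                    planted_offset = realized[0].midpoint - hw
                    break
        pid = f"pk{i:05d}"
        peaks.append(Peak(id=pid, sequence=seq, center_offset=hw,
                          differential=differential))
        records.append(
            {
                "peak_id": pid,
                "differential": differential,
                "planted_offset": planted_offset,
                "site_class": cls.value if planted_offset is not None else None,
            }
        )
    return peaks, records


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one synthetic pull-down study produces."""

    mirna: MiRNA
    transcripts: dict
    table: SiteCountTable
    matrix: ExpressionMatrix
    probe_map: dict
    peaks: list
    truth: SimulationTruth


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate transcriptome, plant sites, scan, and simulate assays."""
    config.validate()
    rng = substream(config.seed, "mirna")
    mirna = random_mirna(rng, config.mirna_length)
    transcripts = generate_transcriptome(config)
    planted = plant_sites(transcripts, mirna, config)
    table = SiteCountTable.from_scan([mirna], transcripts)
    matrix, probe_map, expr_truth = simulate_pulldown(table, config)
    peaks, peak_records = simulate_peaks(config, mirna)
    truth = SimulationTruth(
        planted_sites=planted,
        status={p: bool(s) for p, s in expr_truth["true_status"].items()},
        true_shift={p: float(v) for p, v in expr_truth["true_shift"].items()},
        peak_records=peak_records,
    )
    return StudyBundle(
        mirna=mirna,
        transcripts=transcripts,
        table=table,
        matrix=matrix,
        probe_map=probe_map,
        peaks=peaks,
        truth=truth,
    )
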
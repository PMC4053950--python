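"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions alone (per-position
enumeration, direct step-up computation, exact hypergeometric sums)
and deliberately shares no code with the package.
"""
from __future__ import annotations

import math

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}
COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

CEN_RANK = {"CEN_WC_0MM": 0, "CEN_GU_0MM": 1, "CEN_WC_1MM": 2, "CEN_GU_1MM": 3}
ALL_RANK = {
    "SEED_8MER": 0, "SEED_7MER_M8": 1, "SEED_7MER_A1": 2,
    "CEN_WC_0MM": 3, "CEN_GU_0MM": 4, "CEN_WC_1MM": 5, "CEN_GU_1MM": 6,
}


def oracle_pair(mi: str, mr: str) -> str:
    if (mi, mr) in WC_PAIRS:
        return "WC"
    if (mi, mr) in GU_PAIRS:
        return "GU"
    return "MM"


def oracle_match_window(window: str, site: str):
    """Counts over the 11 antiparallel pairs; positions are window 1-based."""
    assert len(window) == 11 and len(site) == 11
    n_wc = n_gu = 0
    mm_positions = []
    for j in range(1, 12):
        kind = oracle_pair(window[j - 1], site[11 - j])
        if kind == "WC":
            n_wc += 1
        elif kind == "GU":
            n_gu += 1
        else:
            mm_positions.append(j)
    return n_wc, n_gu, mm_positions


def oracle_classify(n_gu: int, mm_positions, allow_gu=True, max_mm=1):
    """Centered class label or None; mismatch must avoid positions 1/11."""
    n_mm = len(mm_positions)
    if n_mm > max_mm:
        return None
    if any(p in (1, 11) for p in mm_positions):
        return None
    if not allow_gu and n_gu > 0:
        return None
    if n_mm == 0:
        return "CEN_WC_0MM" if n_gu == 0 else "CEN_GU_0MM"
    return "CEN_WC_1MM" if n_gu == 0 else "CEN_GU_1MM"


def oracle_scan_centered(mirna_seq: str, transcript_seq: str,
                         allow_gu=True, max_mm=1):
    """All merged centered hits as (start, class) pairs, sorted by start.

    Enumerates every (window, position) pair, classifies each with
    effective mismatches (GU counted as MM when disallowed), then
    merges overlap chains keeping the most stringent class / smallest
    start.
    """
    windows = [
        (s, mirna_seq[s - 1 : s + 10])
        for s in (3, 4, 5)
        if s + 10 <= len(mirna_seq)
    ]
    raw = []
    L = len(transcript_seq)
    for s in range(L - 10):
        site = transcript_seq[s : s + 11]
        for wstart, w in windows:
            n_wc, n_gu, mm_pos = oracle_match_window(w, site)
            if allow_gu:
                cls = oracle_classify(n_gu, mm_pos, max_mm=max_mm)
            else:
                eff_mm = sorted(
                    mm_pos + [j for j in range(1, 12)
                              if oracle_pair(w[j - 1], site[11 - j]) == "GU"]
                )
                cls = oracle_classify(0, eff_mm, max_mm=max_mm)
            if cls is not None:
                raw.append((s, cls))
    # merge overlap chains
    raw.sort(key=lambda h: (h[0], CEN_RANK[h[1]]))
    merged = []
    chain = []
    chain_end = None
    for s, cls in raw:
        if chain and s < chain_end:
            chain.append((s, cls))
            chain_end = max(chain_end, s + 11)
        else:
            if chain:
                merged.append(min(chain, key=lambda h: (CEN_RANK[h[1]], h[0])))
            chain = [(s, cls)]
            chain_end = s + 11
    if chain:
        merged.append(min(chain, key=lambda h: (CEN_RANK[h[1]], h[0])))
    return merged


def oracle_scan_seed(mirna_seq: str, transcript_seq: str):
    """Seed calls as (start, class); 8mer > 7mer-m8 > 7mer-A1 per locus."""
    rc28 = "".join(COMP[b] for b in reversed(mirna_seq[1:8]))
    rc27 = "".join(COMP[b] for b in reversed(mirna_seq[1:7]))
    out = []
    L = len(transcript_seq)
    for s in range(L - 6):
        if transcript_seq[s : s + 7] == rc28:
            if s + 7 < L and transcript_seq[s + 7] == "A":
                out.append((s, "SEED_8MER"))
            else:
                out.append((s, "SEED_7MER_M8"))
        elif (
            transcript_seq[s : s + 6] == rc27
            and s + 6 < L
            and transcript_seq[s + 6] == "A"
        ):
            # skip if this A1 locus is covered by an m8 match one base 5'
            if s > 0 and transcript_seq[s - 1] == COMP[mirna_seq[7]]:
                continue
            out.append((s, "SEED_7MER_A1"))
    return out


def oracle_quantile_normalize(mat):
    """Reference quantile normalization on a tie-free 2-D list."""
    import numpy as np

    arr = np.asarray(mat, dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = arr[:, j].argsort().argsort()
        out[:, j] = ref[ranks]
    return out


def oracle_bh(pvals):
    """Direct min-over-tails Benjamini-Hochberg computation, O(m^2)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(
            min(pvals[j] * m / (rank_j) for rank_j, j in
                list(enumerate(order, start=1))[rank_i - 1 :]),
            1.0,
        )
    return q


def oracle_hypergeom_upper(w: int, x: int, y: int, z: int) -> float:
    """P[W >= w] by exact enumeration of tables with the same margins."""
    r1, r2 = w + x, y + z
    c1 = w + y
    n = r1 + r2
    denom = math.comb(n, c1)
    total = 0
    for k in range(w, min(r1, c1) + 1):
        if c1 - k > r2:
            continue
        total += math.comb(r1, k) * math.comb(r2, c1 - k)
    return total / denom


def oracle_excess_kurtosis(values):
    """g2 = m4 / m2^2 - 3 from raw central moments."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    return m4 / m2**2 - 3.0
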
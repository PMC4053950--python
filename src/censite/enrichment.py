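"""Pull-down enrichment calling from replicate expression matrices.

Transcripts captured by a biotinylated miRNA are profiled alongside
mock-transfected controls; probes whose intensity is significantly
higher in the pull-down group are called enriched at a 5% FDR using an
empirical-Bayes moderated t statistic (per-probe variances shrunk
toward a common prior) and Benjamini-Hochberg adjustment of one-sided
upper-tail p-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

PULLDOWN = "PULLDOWN"
CONTROL = "CONTROL"


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities with group labels.

    ``values`` rows are probes, columns samples; ``groups`` maps each
    sample to PULLDOWN or CONTROL.  ``detection_p`` (optional) holds
    per-probe per-sample detection p-values; ``log_scale`` records
    whether intensities are already log2.
    """

    values: pd.DataFrame
    groups: pd.Series
    detection_p: Optional[pd.DataFrame] = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.loc[list(self.values.columns)]) - {PULLDOWN, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.detection_p is not None:
            dp = self.detection_p.to_numpy()
            if ((dp < 0) | (dp > 1)).any():
                raise ValueError("detection p-values must lie in [0, 1]")

    def samples(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == group]


@dataclass
class EnrichmentResult:
    """Per-probe moderated-t output plus the fitted prior, for audit."""

    table: pd.DataFrame  # columns: logFC, t, p, q, enriched
    prior_df: float  # d0
    prior_var: float  # s0^2
    residual_df: float  # d, per-probe residual degrees of freedom
    fdr: float = 0.05


@dataclass
class TargetSet:
    """Putative targets of one miRNA derived from enriched probes."""

    mirna_id: str
    probes: set = field(default_factory=set)
    transcripts: set = field(default_factory=set)
    ambiguous: set = field(default_factory=set)
    genes: set = field(default_factory=set)


def detection_filter(matrix: ExpressionMatrix, alpha: float = 0.01) -> ExpressionMatrix:
    """Retain probes detected (p < alpha) in every control sample."""
    if matrix.detection_p is None:
        raise ValueError("detection filter requires detection p-values")
    controls = matrix.samples(CONTROL)
    if not controls:
        raise ValueError("no control samples present")
    keep = (matrix.detection_p[controls] < alpha).all(axis=1)
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        groups=matrix.groups,
        detection_p=matrix.detection_p.loc[keep],
        log_scale=matrix.log_scale,
    )


def normalize_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform then quantile-normalize across samples.

    After normalization every sample has the same sorted intensity
    vector (the column-wise mean of sorted log2 values); within-sample
    rank order is preserved, ties broken by row order.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if matrix.log_scale:
        logv = vals
    else:
        if (vals <= 0).any():
            i, j = np.argwhere(vals <= 0)[0]
            raise ValueError(
                "non-positive intensity at probe "
                f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
            )
        logv = np.log2(vals)
    order = np.argsort(logv, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(logv, order, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(logv)
    for j in range(logv.shape[1]):
        out[order[:, j], j] = reference
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.values.index,
                            columns=matrix.values.columns),
        groups=matrix.groups,
        detection_p=matrix.detection_p,
        log_scale=True,
    )


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square variance prior.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0), the log sample
    variances satisfy
      E[log s^2]  = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
      Var[log s^2] = psi'(df/2) + psi'(d0/2).
    The trigamma relation is inverted by bracketed root finding; when
    the observed spread is no larger than the sampling noise the prior
    df is infinite (full shrinkage).
    """
    z = np.log(s2)
    mean_z, var_z = float(np.mean(z)), float(np.var(z, ddof=1))
    target = var_z - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(mean_z - special.psi(df / 2.0) + np.log(df / 2.0)))
        return d0, s0_2
    f = lambda x: float(special.polygamma(1, x)) - target
    lo, hi = 1e-8, 1e8
    if f(lo) < 0 or f(hi) > 0:
        raise FloatingPointError("trigamma inversion failed")
    half_d0 = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    d0 = 2.0 * half_d0
    s0_2 = float(
        np.exp(
            mean_z
            - special.psi(df / 2.0) + np.log(df / 2.0)
            + special.psi(half_d0) - np.log(half_d0)
        )
    )
    return d0, s0_2


def moderated_t_enrichment(
    matrix: ExpressionMatrix,
    prior_df: Optional[float] = None,
    fdr: float = 0.05,
) -> EnrichmentResult:
    """Empirical-Bayes moderated t test of pull-down vs control.

    Per-probe pooled variances are shrunk toward a prior fitted by
    moment matching on the log sample variances; the one-sided upper
    tail p tests for enrichment in the pull-down.  ``prior_df``
    overrides the fitted d0 (0 gives the ordinary t, inf a z-like
    statistic with variance s0^2).
    """
    pd_samples = matrix.samples(PULLDOWN)
    ct_samples = matrix.samples(CONTROL)
    n1, n2 = len(pd_samples), len(ct_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    x1 = matrix.values[pd_samples].to_numpy(dtype=float)
    x2 = matrix.values[ct_samples].to_numpy(dtype=float)
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    df = float(n1 + n2 - 2)
    s2 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 += ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 /= df
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all probes have zero variance")

    if prior_df is None:
        try:
            d0, s0_2 = _fit_variance_prior(s2[positive], df)
        except FloatingPointError:
            warnings.warn(
                "variance-prior estimation failed; falling back to ordinary t",
                stacklevel=2,
            )
            d0, s0_2 = 0.0, float(np.median(s2[positive]))
    else:
        d0 = float(prior_df)
        s0_2 = float(np.exp(np.mean(np.log(s2[positive]))))
        if np.isinf(d0):
            _, s0_2 = _fit_variance_prior(s2[positive], df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        p = stats.norm.sf(t)
    else:
        p = stats.t.sf(t, df_total)
    q = bh_fdr(pd.Series(p, index=matrix.values.index))
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "q": q.to_numpy(),
            "enriched": q.to_numpy() <= fdr,
        },
        index=matrix.values.index,
    )
    return EnrichmentResult(table=table, prior_df=d0, prior_var=s0_2,
                            residual_df=df, fdr=fdr)


def bh_fdr(p) -> pd.Series:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  Ties are ordered
    stably by (p, probe id) so q assignment is reproducible.
    """
    p = pd.Series(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = p.reset_index(drop=True).sort_values(kind="stable").index.to_numpy()
    sorted_p = p.to_numpy()[order]
    q_sorted = sorted_p * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return pd.Series(q, index=p.index)


def call_targets(
    results: EnrichmentResult,
    probe_map: Mapping[str, set],
    mirna_id: str = "",
    fdr: Optional[float] = None,
    exclude_ambiguous: bool = True,
    gene_map: Optional[Mapping[str, str]] = None,
) -> TargetSet:
    """Derive a transcript/gene target set from enriched probes.

    Transcripts also matched by a retained but non-enriched probe are
    *ambiguous* and excluded (unless ``exclude_ambiguous`` is false).
    Probes absent from ``probe_map`` are logged and dropped.
    """
    if len(results.table) == 0:
        raise ValueError("empty enrichment results")
    fdr = results.fdr if fdr is None else fdr
    enriched = results.table.index[results.table["q"] <= fdr]
    unmapped = [pr for pr in enriched if pr not in probe_map]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} enriched probes missing from probe map; dropped",
            stacklevel=2,
        )
    targets: set = set()
    for pr in enriched:
        targets |= set(probe_map.get(pr, ()))
    ambiguous: set = set()
    if exclude_ambiguous:
        non_enriched = results.table.index[results.table["q"] > fdr]
        hit_by_non_enriched: set = set()
        for pr in non_enriched:
            hit_by_non_enriched |= set(probe_map.get(pr, ()))
        ambiguous = targets & hit_by_non_enriched
        targets -= ambiguous
    genes = (
        {gene_map[t] for t in targets if t in gene_map} if gene_map else set()
    )
    return TargetSet(
        mirna_id=mirna_id,
        probes=set(enriched) - set(unmapped),
        transcripts=targets,
        ambiguous=ambiguous,
        genes=genes,
    )
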
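"""Association statistics between predicted sites and enrichment status.

Covers the 2x2 exact tests (site presence vs target status, external
target-set overlap, shared isomiR targets), the logistic regression of
enrichment status on per-region site counts or densities, the
Nagelkerke pseudo-r2, and the one-sided Kolmogorov-Smirnov fold-change
shift test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .model import Region, SiteClass, TranscriptModel
from .scanner import (
    ALL_CLASSES,
    ALL_REGIONS,
    SiteCountTable,
    count_column,
    density_column,
)


class SeparationError(RuntimeError):
    """Complete separation in a logistic fit; names the covariate."""


@dataclass
class ContingencyResult:
    """Upper-tailed exact 2x2 test: OR = (w/x)/(y/z).

    Cells: w = target with site, x = target without, y = non-target
    with site, z = non-target without (row 1 = targets).  The CI is a
    Woolf logit interval; with any empty cell the Haldane-Anscombe +0.5
    correction is applied to OR and CI and flagged.
    """

    w: int
    x: int
    y: int
    z: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_upper: float
    corrected: bool


@dataclass
class RegressionFit:
    """Maximum-likelihood logistic fit summary."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float  # fitted log-likelihood (L1)
    llnull: float  # intercept-only log-likelihood (L0)
    nobs: int
    r2_nagelkerke: float
    converged: bool
    mode: str
    dropped: tuple = ()


@dataclass
class OverlapSummary:
    a_only: int
    b_only: int
    shared: int


def fisher_exact_upper(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """One-sided (upper-tail) Fisher exact test on a 2x2 table.

    The p-value is P[X >= w] under the hypergeometric distribution
    conditioned on the margins; the alternative is OR > 1.
    """
    (w, x), (y, z) = table
    cells = [w, x, y, z]
    if any(int(c) != c or c < 0 for c in cells):
        raise ValueError("cells must be non-negative integers")
    w, x, y, z = (int(c) for c in cells)
    n = w + x + y + z
    if n == 0:
        raise ValueError("empty contingency table")
    r1, c1 = w + x, w + y
    # hypergeometric upper tail conditioned on margins
    p_upper = float(stats.hypergeom.sf(w - 1, n, c1, r1))
    p_upper = min(p_upper, 1.0)
    corrected = any(c == 0 for c in (w, x, y, z))
    if corrected:
        wf, xf, yf, zf = (c + 0.5 for c in (w, x, y, z))
    else:
        wf, xf, yf, zf = float(w), float(x), float(y), float(z)
    or_ = (wf * zf) / (xf * yf)
    se_log = np.sqrt(1 / wf + 1 / xf + 1 / yf + 1 / zf)
    ci_low = float(np.exp(np.log(or_) - 1.959963984540054 * se_log))
    ci_high = float(np.exp(np.log(or_) + 1.959963984540054 * se_log))
    return ContingencyResult(w, x, y, z, float(or_), ci_low, ci_high,
                             p_upper, corrected)


ClassSpec = Union[SiteClass, Iterable[SiteClass]]


def _as_classes(site_class: ClassSpec) -> tuple[SiteClass, ...]:
    if isinstance(site_class, SiteClass):
        return (site_class,)
    return tuple(site_class)


def _has_site_mask(table: SiteCountTable, classes: tuple[SiteClass, ...]) -> pd.Series:
    mask = pd.Series(False, index=table.df.index)
    for c in classes:
        mask |= table.has_class(c)
    return mask


def site_type_enrichment(
    targets: set,
    background: set,
    table: SiteCountTable,
    mirna_id: str,
    site_class: ClassSpec,
    exclusive: bool = False,
) -> ContingencyResult:
    """2x2 test: target status vs presence of >= 1 site of a class.

    ``targets`` and ``background`` are transcript-id sets (targets must
    be a subset of background).  With ``exclusive``, transcripts that
    carry more than one distinct site class are removed first, so the
    association is attributable to a single site type.
    """
    if not set(targets) <= set(background):
        raise ValueError("targets must be a subset of the background")
    classes = _as_classes(site_class)
    sub = table.df.loc[[(t, mirna_id) for t in sorted(background)]]
    sub_table = SiteCountTable(sub)
    keep = pd.Series(True, index=sub.index)
    if exclusive:
        keep = sub_table.n_distinct_classes() <= 1
    if not keep.any():
        raise ValueError("empty background after exclusive-type filtering")
    has = _has_site_mask(sub_table, classes)[keep]
    tids = pd.Index([k[0] for k in has.index])
    is_target = tids.isin(targets)
    w = int((is_target & has.to_numpy()).sum())
    x = int((is_target & ~has.to_numpy()).sum())
    y = int((~is_target & has.to_numpy()).sum())
    z = int((~is_target & ~has.to_numpy()).sum())
    return fisher_exact_upper([[w, x], [y, z]])


def nagelkerke_r2(l0: float, l1: float, n: int) -> float:
    """Nagelkerke pseudo-r2 from null and fitted log-likelihoods."""
    if n <= 0:
        raise ValueError("n must be positive")
    if l1 < l0 - 1e-9:
        raise ValueError("fitted log-likelihood below the null log-likelihood")
    r2_cs = max(0.0, float(1.0 - np.exp(2.0 * (l0 - l1) / n)))
    denom = 1.0 - np.exp(2.0 * l0 / n)
    if denom <= 0:
        return 0.0
    return min(1.0, r2_cs / float(denom))


def _logistic_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(
    X: np.ndarray, y: np.ndarray, names: Sequence[str], max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iteratively reweighted least squares for the logistic model."""
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        wgt = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > 30.0:
            resid = np.abs(y - mu)
            if np.max(resid) < 1e-6:
                j = int(np.argmax(np.abs(beta[1:])) + 1) if len(beta) > 1 else 0
                raise SeparationError(
                    f"complete separation detected (covariate {names[j]!r})"
                )
        XtW = X.T * wgt
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    H = (X.T * (mu * (1 - mu))) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full_like(H, np.nan)
    return beta, cov, converged


def fit_logistic_sites(
    status: Mapping,
    table: SiteCountTable,
    mode: str = "count",
    regions: Sequence[Region] = ALL_REGIONS,
    classes: Sequence[SiteClass] = ALL_CLASSES,
    canonical_only: bool = False,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
    min_obs_per_coef: int = 10,
) -> RegressionFit:
    """Logistic regression of enrichment status on site covariates.

    Fits logit(p_i) = b0 + sum_{a,b} b_{a,b} x_{a,b,i}, where x is the
    count (or per-kb density) of sites of class a in region b of
    observation i.  Zero-variance covariates are dropped and recorded.
    With ``canonical_only``, observations are restricted to the longest
    transcript per gene (requires ``transcripts``).
    """
    if mode not in ("count", "density"):
        raise ValueError("mode must be 'count' or 'density'")
    status = pd.Series(status).astype(float)
    keys = [k for k in table.df.index if k in status.index]
    if not keys:
        raise ValueError("no overlap between status and count table")
    if canonical_only:
        if transcripts is None:
            raise ValueError("canonical_only requires transcript models")
        keys = [k for k in keys if transcripts[k[0]].is_canonical]
    sub = table.df.loc[keys]
    y = status.loc[keys].to_numpy()
    colfun = count_column if mode == "count" else density_column
    cols = [colfun(c, r) for c in classes for r in regions]
    X_df = sub[cols].astype(float)
    variances = X_df.var(axis=0)
    dropped = tuple(variances.index[variances == 0])
    X_df = X_df.loc[:, variances > 0]
    names = ["(intercept)"] + list(X_df.columns)
    X = np.column_stack([np.ones(len(X_df)), X_df.to_numpy()])
    n = len(y)
    if n < min_obs_per_coef * X.shape[1]:
        import warnings

        warnings.warn(
            f"only {n} observations for {X.shape[1]} coefficients",
            stacklevel=2,
        )
    beta, cov, converged = _irls(X, y, names)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    l1 = _logistic_ll(y, X @ beta)
    # intercept-only closed form: beta0 = logit(mean(y))
    pbar = float(np.mean(y))
    if 0.0 < pbar < 1.0:
        eta0 = np.log(pbar / (1.0 - pbar))
    else:
        eta0 = np.sign(pbar - 0.5) * np.inf
    l0 = float(n * (pbar * np.log(pbar + (pbar == 0.0)) +
                    (1 - pbar) * np.log(1 - pbar + (pbar == 1.0))))
    idx = pd.Index(names)
    return RegressionFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        zvalues=pd.Series(zvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        llf=l1,
        llnull=l0,
        nobs=n,
        r2_nagelkerke=nagelkerke_r2(l0, max(l0, l1), n),
        converged=converged,
        mode=mode,
        dropped=dropped,
    )


def ks_shift_test(
    fc_in_set: Sequence[float],
    fc_out_set: Sequence[float],
    exact: bool = False,
) -> tuple[float, float]:
    """One-sided two-sample KS test that the in-set logFC is larger.

    Tests that the in-set ECDF lies below the out-set ECDF (the in-set
    is stochastically greater).  Returns (D, one-sided p); asymptotic
    by default, exact small-sample computation behind ``exact``.
    """
    fc_in = np.asarray(fc_in_set, dtype=float)
    fc_out = np.asarray(fc_out_set, dtype=float)
    if len(fc_in) < 2 or len(fc_out) < 2:
        raise ValueError("each sample must have >= 2 values")
    res = stats.ks_2samp(
        fc_in, fc_out, alternative="less", method="exact" if exact else "asymp"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def external_set_enrichment(
    targets: set, external_targets: set, universe: set
) -> ContingencyResult:
    """2x2 test of pull-down target status vs external target status."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not set(external_targets) <= universe or not set(targets) <= universe:
        raise ValueError("target sets must be subsets of the universe")
    t, e = set(targets), set(external_targets)
    w = len(t & e)
    x = len(t - e)
    y = len(e - t)
    z = len(universe - t - e)
    return fisher_exact_upper([[w, x], [y, z]])


def set_overlap(set_a: set, set_b: set) -> OverlapSummary:
    """Exact Venn counts for two id sets."""
    a, b = set(set_a), set(set_b)
    return OverlapSummary(len(a - b), len(b - a), len(a & b))


def isomir_shared_site_test(
    targets_a: set,
    targets_b: set,
    table: SiteCountTable,
    mirna_id: str,
    site_class: ClassSpec,
    exclusive: bool = False,
) -> tuple[ContingencyResult, ContingencyResult]:
    """Shared vs unique targets of two related miRNAs: site enrichment.

    Tests whether transcripts targeted by both miRNAs (for example a
    canonical miRNA and its shifted isomiR, which share centered but
    not seed sites) are more likely to carry a site of the given class
    than transcripts targeted by only one.  Returns the shared-vs-A-only
    and shared-vs-B-only results.
    """
    a, b = set(targets_a), set(targets_b)
    if not a or not b:
        raise ValueError("both target sets must be non-empty")
    shared = a & b
    if not shared:
        raise ValueError("empty shared target set")
    out = []
    for only in (a - shared, b - shared):
        if not only:
            raise ValueError("one miRNA has no unique targets")
        background = shared | only
        res = site_type_enrichment(
            shared, background, table, mirna_id, site_class, exclusive=exclusive
        )
        out.append(res)
    return out[0], out[1]
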
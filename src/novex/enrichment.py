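"""Negative-binomial count statistics for tissue enrichment and exon usage.

The testing machinery is a self-contained reimplementation of the
classic count-based toolkit for small-replicate RNA-seq designs:

* median-of-ratios **size factors** for sequencing-depth normalization;
* per-feature method-of-moments **dispersion** estimates shrunk toward
  a parametric mean-dispersion trend ``alpha(mu) = a0/mu + a1``, taking
  the maximum of the per-feature estimate and the trend (conservative);
* an **exact two-group test**: conditional on the summed count, the
  probability of group splits at most as probable as the observed one
  under a negative binomial with a shared mean apportioned by group
  size-factor totals.  With dispersion 0 it reduces to the conditional
  binomial split test;
* **pairwise tissue enrichment**: a feature is enriched in a target
  tissue when *every* pairwise comparison against the other tissues is
  individually significant (p < threshold) and in the target's favour;
  the minimum and maximum p-value over comparisons are reported;
* a **differential exon-usage test** for two-condition designs: a
  quasi-binomial score for the change in the exon inclusion proportion
  ``exon / (exon + rest-of-gene)``, with overdispersion estimated from
  within-condition replicate variability.

No multiple-testing correction is applied by default; raw p < 0.05 is
the reporting rule, with an optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_size_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "pairwise_enrichment",
    "exon_usage_test",
    "gene_level_test",
    "ExonUsageResult",
]

DEFAULT_SEED = 20140713
_EPS = 1e-12


def estimate_size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over features with no zero
    count, of its counts divided by the feature's geometric mean across
    samples.  If no feature is positive in every sample, either an
    error is raised or (``pseudo_reference=True``) the ratio set falls
    back to features with a positive geometric mean over the samples in
    which they are observed.
    """
    k = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    allpos = np.isfinite(logk).all(axis=1)
    if allpos.any():
        loggeo = logk[allpos].mean(axis=1)
        logratios = logk[allpos] - loggeo[:, None]
    elif pseudo_reference:
        anypos = np.isfinite(logk).any(axis=1)
        if not anypos.any():
            raise ValueError("all counts are zero; size factors undefined")
        loggeo = np.nanmean(np.where(np.isfinite(logk), logk, np.nan)[anypos], axis=1)
        logratios = logk[anypos] - loggeo[:, None]
    else:
        raise ValueError(
            "no feature has positive counts in every sample; "
            "pass pseudo_reference=True to fall back to a pseudo-reference"
        )
    logs = np.nanmedian(np.where(np.isfinite(logratios), logratios, np.nan), axis=0)
    logs = logs - logs.mean()  # geometric mean 1
    return pd.Series(np.exp(logs), index=counts.columns, name="size_factor")


def _fit_trend(mu: np.ndarray, alpha_raw: np.ndarray) -> tuple[float, float]:
    """Nonnegative least-squares fit of alpha = a0/mu + a1."""
    ok = (mu > 0) & np.isfinite(alpha_raw)
    if ok.sum() < 2:
        return 0.0, float(np.nanmean(alpha_raw[ok])) if ok.any() else 0.0
    A = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, _ = nnls(A, alpha_raw[ok])
    return float(coef[0]), float(coef[1])


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.Series,
    size_factors: pd.Series,
    shrink: bool = True,
) -> pd.Series:
    """Per-feature NB dispersion (variance = mu + alpha * mu^2).

    Method-of-moments on normalized counts with group-specific means:
    for each replicated group, the excess of the within-group variance
    over the shot-noise term ``xi * mu_g`` is modelled as
    ``alpha * mu_g**2``, and the per-feature estimate pools these
    moment equations weighted by their degrees of freedom.  Using the
    group's own mean (rather than the grand mean) keeps the estimator
    unbiased for features whose expression differs strongly between
    groups — precisely the features being tested.  The raw estimates
    are then shrunk by taking the maximum of each and a fitted
    ``a0/mu + a1`` trend.  If no group has replicates, the variance is
    pooled across all samples as a conservative blind estimate.
    All-zero features get NaN and are excluded from testing by callers.
    """
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    x = counts.to_numpy(dtype=float) / s  # normalized counts
    groups = design.loc[counts.columns].to_numpy()
    mu = x.mean(axis=1)
    xi = float(np.mean(1.0 / s))  # shot-noise scale on the common scale

    num = np.zeros(x.shape[0])  # sum of df-weighted (v_g - xi*mu_g)
    den = np.zeros(x.shape[0])  # sum of df-weighted mu_g^2
    df = 0
    for g in np.unique(groups):
        cols = groups == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        xg = x[:, cols]
        mu_g = xg.mean(axis=1)
        v_g = ((xg - mu_g[:, None]) ** 2).sum(axis=1) / (n_g - 1)
        num += (n_g - 1) * (v_g - xi * mu_g)
        den += (n_g - 1) * mu_g**2
        df += n_g - 1
    if df == 0:
        # no replicated group: pool all samples (conservative blind estimate)
        v = ((x - mu[:, None]) ** 2).sum(axis=1) / max(x.shape[1] - 1, 1)
        num = v - xi * mu
        den = mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = num / den
    alpha_raw = np.where(den > 0, np.maximum(alpha_raw, 0.0), np.nan)
    if shrink:
        a0, a1 = _fit_trend(mu, alpha_raw)
        trend = np.where(mu > 0, a0 / np.maximum(mu, _EPS) + a1, np.nan)
        alpha = np.fmax(alpha_raw, trend)
    else:
        alpha = alpha_raw
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _group_pmf(total_grid: np.ndarray, mu: float, alpha_eff: float) -> np.ndarray:
    if alpha_eff <= 1e-12:
        return sps.poisson.pmf(total_grid, mu)
    r = 1.0 / alpha_eff
    p = r / (r + mu)
    return sps.nbinom.pmf(total_grid, r, p)


def nb_exact_test(
    k_a,
    k_b,
    s_a,
    s_b,
    alpha: float,
) -> tuple[float, int]:
    """Exact conditional two-group NB test.

    Conditional on the summed count K, enumerates all splits (a, K-a),
    scoring each by the product of the two group-sum NB probabilities
    under the shared normalized mean ``q = K / (sA + sB)``; the
    two-sided p-value sums the probabilities of splits at most as
    probable as the observed one.  Group sums are moment-matched to a
    negative binomial: mean ``s_g * q`` and effective dispersion
    ``alpha * sum(s_j^2) / s_g^2`` (exact for equal size factors).

    Returns ``(p, sign)`` with sign +1 when group A's normalized mean
    is higher, -1 when lower, 0 when tied; ``p = 1`` when both groups
    are all-zero.
    """
    k_a = np.asarray(k_a, dtype=float)
    k_b = np.asarray(k_b, dtype=float)
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be nonnegative")
    ka, kb = float(k_a.sum()), float(k_b.sum())
    ks = ka + kb
    ra, rb = ka / s_a.sum(), kb / s_b.sum()
    sign = 0 if ra == rb else (1 if ra > rb else -1)
    if ks == 0:
        return 1.0, 0
    sa, sb = float(s_a.sum()), float(s_b.sum())
    q = ks / (sa + sb)
    mu_a, mu_b = sa * q, sb * q
    aa = alpha * float((s_a**2).sum()) / sa**2
    ab = alpha * float((s_b**2).sum()) / sb**2
    grid = np.arange(int(ks) + 1)
    fa = _group_pmf(grid, mu_a, aa)
    fb = _group_pmf(grid[::-1], mu_b, ab)
    joint = fa * fb
    total = joint.sum()
    if total <= 0:  # numerically degenerate; fall back to uninformative
        return 1.0, sign
    p_obs = joint[int(ka)]
    p = joint[joint <= p_obs * (1.0 + 1e-7)].sum() / total
    return float(min(max(p, p_obs / total), 1.0)), sign


def _bh(pvals: pd.Series) -> pd.Series:
    mask = pvals.notna()
    adj = pd.Series(np.nan, index=pvals.index)
    if mask.any():
        adj[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return adj


def pairwise_enrichment(
    counts: pd.DataFrame,
    design: pd.Series,
    target: str,
    threshold: float = 0.05,
    size_factors: pd.Series | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Aggregate all pairwise comparisons of the target group vs the rest.

    Runs the exact NB test of the target tissue against every other
    group separately (dispersion estimated per pair, with the trend
    pooled over the pair's samples) and calls a feature enriched when
    every comparison is significant below ``threshold`` *and* the
    target's normalized mean exceeds the other group's in every
    comparison.  Output columns include one p-value per comparison plus
    ``p_min``/``p_max`` and the boolean ``enriched``.

    Features with zero counts in every sample are excluded from testing
    (``tested = False``).
    """
    design = design.loc[counts.columns]
    groups = [g for g in pd.unique(design) if g != target]
    if target not in set(design):
        raise ValueError(f"target group {target!r} absent from design")
    if not groups:
        raise ValueError("design must contain at least one non-target group")
    for g in list(groups) + [target]:
        if (design == g).sum() == 0:
            raise ValueError(f"group {g!r} has zero samples")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    tested = counts.sum(axis=1) > 0

    pvals = pd.DataFrame(np.nan, index=counts.index, columns=[f"p_vs_{g}" for g in groups])
    favours = pd.DataFrame(False, index=counts.index, columns=groups)
    target_cols = design.index[design == target]
    for g in groups:
        other_cols = design.index[design == g]
        pair_cols = list(target_cols) + list(other_cols)
        sub = counts[pair_cols]
        disp = estimate_dispersion(sub, design.loc[pair_cols], size_factors.loc[pair_cols])
        s_t = size_factors.loc[target_cols].to_numpy()
        s_o = size_factors.loc[other_cols].to_numpy()
        kt = counts[target_cols].to_numpy()
        ko = counts[other_cols].to_numpy()
        for i, fid in enumerate(counts.index):
            if not tested.iloc[i]:
                continue
            a = disp.iloc[i]
            p, sign = nb_exact_test(kt[i], ko[i], s_t, s_o, 0.0 if np.isnan(a) else float(a))
            pvals.loc[fid, f"p_vs_{g}"] = p
            favours.loc[fid, g] = sign > 0

    out = pd.DataFrame(index=counts.index)
    out["target_group"] = target
    for c in pvals.columns:
        out[c] = pvals[c]
    out["p_min"] = pvals.min(axis=1)
    out["p_max"] = pvals.max(axis=1)
    pcols = pvals if not adjust else pvals.apply(_bh, axis=0)
    if adjust:
        for c in pvals.columns:
            out[c + "_adj"] = pcols[c]
    out["enriched"] = (
        tested & (pcols < threshold).all(axis=1) & favours.all(axis=1)
    )
    out["tested"] = tested
    return out


@dataclass(frozen=True)
class ExonUsageResult:
    """Outcome of a differential exon-usage test for one exon."""

    exon_id: str
    gene_id: str
    usage_change: float
    p_usage: float
    p_gene: float | None = None


def _usage_stat(exon: np.ndarray, other: np.ndarray, cond2: np.ndarray) -> tuple[float, float, int]:
    """Quasi-binomial t statistic for an inclusion-proportion shift.

    Weighted binomial GLM score with a Pearson overdispersion factor
    estimated from replicate variability; returns (t, diff, df).
    """
    n = exon + other
    ok = n > 0
    exon, other, n, cond2 = exon[ok], other[ok], n[ok], cond2[ok]
    if len(n) < 3 or cond2.all() or (~cond2).all():
        return np.nan, np.nan, 0
    p1 = exon[~cond2].sum() / n[~cond2].sum()
    p2 = exon[cond2].sum() / n[cond2].sum()
    diff = p2 - p1
    fitted = np.where(cond2, p2, p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = (exon - n * fitted) ** 2 / np.maximum(n * fitted * (1 - fitted), _EPS)
    dof = len(n) - 2
    phi = max(1.0, float(pearson.sum()) / dof)  # quasi-binomial scale, floored at binomial
    var = phi * (
        p1 * (1 - p1) / max(n[~cond2].sum(), 1) + p2 * (1 - p2) / max(n[cond2].sum(), 1)
    )
    if var <= 0:
        # proportions pinned at 0 or 1 in both conditions
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / np.sqrt(var)
    return float(t), float(diff), dof


def exon_usage_test(
    exon_counts,
    gene_other_counts,
    design: pd.Series,
    baseline: str | None = None,
    exon_id: str = "exon",
    gene_id: str = "gene",
) -> ExonUsageResult:
    """Test whether exon inclusion differs between two conditions.

    ``exon_counts`` are reads on the exon, ``gene_other_counts`` reads
    on the rest of the gene, per sample.  The inclusion proportion
    ``exon / (exon + other)`` is compared between the two condition
    groups with a quasi-binomial t test (overdispersion from replicate
    variability, df = samples - 2).  ``usage_change`` is the pooled
    proportion in the non-baseline condition minus the baseline one.
    """
    conditions = list(pd.unique(design))
    if len(conditions) != 2:
        raise ValueError(f"exon usage test requires exactly 2 conditions, got {conditions}")
    if baseline is None:
        baseline = conditions[0]
    elif baseline not in conditions:
        raise ValueError(f"baseline {baseline!r} not among conditions {conditions}")
    exon = np.asarray(exon_counts, dtype=float)
    other = np.asarray(gene_other_counts, dtype=float)
    if (exon < 0).any() or (other < 0).any():
        raise ValueError("counts must be nonnegative")
    cond2 = (design.to_numpy() != baseline)
    totals = exon + other
    for flag, name in ((~cond2, baseline), (cond2, "non-baseline")):
        if totals[flag].sum() == 0:
            return ExonUsageResult(exon_id, gene_id, np.nan, np.nan)
    t, diff, dof = _usage_stat(exon, other, cond2)
    if not np.isfinite(t):
        p = np.nan if np.isnan(t) else 0.0
    else:
        p = float(2 * sps.t.sf(abs(t), dof))
    return ExonUsageResult(exon_id, gene_id, diff, min(p, 1.0) if not np.isnan(p) else p)


def gene_level_test(
    counts: pd.DataFrame,
    design: pd.Series,
    gene: str,
    baseline: str | None = None,
    size_factors: pd.Series | None = None,
) -> tuple[float, float]:
    """Exact NB test on a gene's summed counts between two conditions.

    Returns ``(p, fold_change)`` where fold change is the non-baseline
    normalized mean over the baseline one (NaN when baseline is zero).
    """
    conditions = list(pd.unique(design.loc[counts.columns]))
    if len(conditions) != 2:
        raise ValueError("gene-level test requires exactly 2 conditions")
    if baseline is None:
        baseline = conditions[0]
    if size_factors is None:
        size_factors = estimate_size_factors(counts, pseudo_reference=True)
    design = design.loc[counts.columns]
    base_cols = design.index[design == baseline]
    alt_cols = design.index[design != baseline]
    row = counts.loc[gene]
    disp = estimate_dispersion(counts, design, size_factors)
    a = disp.loc[gene]
    k_base = row[base_cols].to_numpy()
    k_alt = row[alt_cols].to_numpy()
    s_base = size_factors.loc[base_cols].to_numpy()
    s_alt = size_factors.loc[alt_cols].to_numpy()
    p, _sign = nb_exact_test(k_alt, k_base, s_alt, s_base, 0.0 if np.isnan(a) else float(a))
    m_base = k_base.sum() / s_base.sum()
    m_alt = k_alt.sum() / s_alt.sum()
    fold = m_alt / m_base if m_base > 0 else np.nan
    return p, float(fold)
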
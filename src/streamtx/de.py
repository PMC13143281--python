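"""Differential expression from first principles, at each snapshot.

The model is the standard negative-binomial GLM for counts: for feature g
and sample j,

    K_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha mu^2,
    log mu_gj = log s_j + beta0_g + beta1_g * x_j,

with x_j the condition indicator and s_j the median-of-ratios size factor.
``log2FC = beta1 / ln 2`` is the condition effect; significance comes from a
Wald test beta1 / SE(beta1) with SE from the observed Fisher information,
followed by Benjamini-Hochberg adjustment.  Dispersions are method-of-
moments per gene (within-group pooled mean/variance) shrunk halfway toward
a fitted mean-dispersion trend alpha(mu) = a0 + a1/mu.

Gene-level and transcript-level analyses share this code path verbatim;
only the feature-by-sample matrix differs.

Deliberate simplifications relative to full DESeq2-style machinery: no
posterior log-fold-change shrinkage, no outlier refitting, a fixed count
pre-filter instead of adaptive independent filtering, and ``log2(norm+1)``
instead of a variance-stabilizing transform for PCA and distances.
Complete separation (a group with all-zero counts, e.g. a knockout) is
handled by bounding |log2FC| at ``MAX_ABS_LOG2FC`` and evaluating the Wald
statistic at the boundary estimate, which mirrors how bounded GLM fitting
behaves in the established implementations and keeps such genes testable.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

ALPHA_FLOOR = 1e-8
MAX_ABS_LOG2FC = 8.0
LN2 = float(np.log(2.0))

RESULT_COLUMNS = ["baseMean", "log2FC", "lfcSE", "stat", "pvalue", "padj"]


def _groups_to_series(groups: Mapping[str, str] | pd.Series,
                      samples: Sequence[str]) -> pd.Series:
    g = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    return g.reindex(samples)


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes (with positive counts in every sample) of
    count(g, j) / geometric-mean_g.  Raises when no gene is positive
    everywhere — more sequencing depth is needed before normalization.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined — accumulate more sequencing depth before normalizing")
    logs = np.log(mat[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / sf.reindex(counts.columns)


# ---------------------------------------------------------------------------
# Dispersion


@dataclass
class DispersionEstimates:
    alpha: pd.Series          # final (shrunken) per-feature dispersion
    genewise: pd.Series       # raw method-of-moments estimates
    trend: tuple[float, float]  # (a0, a1) of alpha(mu) = a0 + a1/mu

    def trend_at(self, mu: np.ndarray) -> np.ndarray:
        a0, a1 = self.trend
        return np.maximum(a0 + a1 / np.maximum(mu, 1e-8), ALPHA_FLOOR)


def estimate_dispersions(normalized: pd.DataFrame,
                         groups: Mapping[str, str] | pd.Series
                         ) -> DispersionEstimates:
    """Method-of-moments dispersion with trend shrinkage.

    Per gene: alpha = max(floor, (s^2 - mu) / mu^2) with mu the grand mean of
    normalized counts and s^2 the within-group pooled variance (so condition
    effects do not inflate dispersion).  A hyperbolic trend a0 + a1/mu is
    fitted by least squares over genes with mu > 1, and the final estimate is
    the average of the gene-wise value and the trend — a simple shrinkage
    that stabilizes the n-of-2-or-3 regime.
    """
    g = _groups_to_series(groups, normalized.columns)
    mat = normalized.to_numpy(dtype=float)
    pooled_num = np.zeros(mat.shape[0])
    pooled_den = 0
    for cond in g.unique():
        cols = np.where((g == cond).to_numpy())[0]
        if len(cols) < 2:
            raise ValueError(f"group {cond!r} has fewer than 2 replicates")
        sub = mat[:, cols]
        pooled_num += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        pooled_den += len(cols) - 1
    s2 = pooled_num / pooled_den
    mu = mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, ALPHA_FLOOR)
    genewise = np.maximum(raw, ALPHA_FLOOR)

    fit_mask = mu > 1
    if fit_mask.sum() >= 2:
        x = 1.0 / mu[fit_mask]
        design = np.column_stack([np.ones(fit_mask.sum()), x])
        coef, *_ = np.linalg.lstsq(design, genewise[fit_mask], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = float(np.median(genewise)), 0.0
    trend_vals = np.maximum(a0 + a1 / np.maximum(mu, 1e-8), ALPHA_FLOOR)
    final = np.maximum(0.5 * genewise + 0.5 * trend_vals, ALPHA_FLOOR)
    idx = normalized.index
    return DispersionEstimates(pd.Series(final, index=idx, name="alpha"),
                               pd.Series(genewise, index=idx, name="genewise"),
                               (a0, a1))


# ---------------------------------------------------------------------------
# Wald test


def wald_test(counts: pd.DataFrame,
              sf: pd.Series,
              dispersions: DispersionEstimates,
              groups: Mapping[str, str] | pd.Series,
              contrast: tuple[str, str] | None = None,
              min_total_count: int = 10,
              max_iter: int = 50,
              tol: float = 1e-8) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of condition B vs condition A.

    Fitting is IRLS with log link and per-feature fixed dispersion,
    vectorized across features (the 2x2 weighted normal equations have a
    closed-form solve).  Features with total raw count below
    ``min_total_count`` are reported with null p/padj; non-converged fits
    get a null p-value.  When one group is entirely zero the reported
    log2FC comes from +0.5-pseudo-count group means while the Wald statistic
    is evaluated at the bounded estimate (see module docstring).
    """
    g = _groups_to_series(groups, counts.columns)
    conds = list(dict.fromkeys(g))
    if contrast is None:
        if len(conds) != 2:
            raise ValueError("need exactly two conditions or an explicit contrast")
        contrast = (conds[0], conds[1])
    cond_a, cond_b = contrast
    in_b = (g == cond_b).to_numpy()
    in_a = (g == cond_a).to_numpy()
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each condition needs >= 2 samples")
    use = in_a | in_b
    y_all = counts.to_numpy(dtype=float)[:, use]
    x = in_b[use].astype(float)
    offs = np.log(sf.reindex(counts.columns).to_numpy(dtype=float))[use]
    alpha = dispersions.alpha.reindex(counts.index).to_numpy(dtype=float)

    norm = y_all / np.exp(offs)
    base_mean = norm.mean(axis=1)
    tested = y_all.sum(axis=1) >= min_total_count

    n_feat = y_all.shape[0]
    log2fc = np.full(n_feat, np.nan)
    se = np.full(n_feat, np.nan)
    zstat = np.full(n_feat, np.nan)
    pval = np.full(n_feat, np.nan)

    if tested.any():
        y = y_all[tested]
        a = alpha[tested]
        beta_cap = MAX_ABS_LOG2FC * LN2
        mean_a = norm[tested][:, x == 0].mean(axis=1)
        mean_b = norm[tested][:, x == 1].mean(axis=1)
        beta0 = np.log(np.maximum(mean_a, 1e-4))
        beta1 = np.clip(np.log((mean_b + 0.5) / (mean_a + 0.5)),
                        -beta_cap, beta_cap)
        converged = np.zeros(len(y), dtype=bool)
        for _ in range(max_iter):
            eta = np.clip(offs + beta0[:, None] + beta1[:, None] * x, -30, 30)
            mu = np.exp(eta)
            w = mu / (1.0 + a[:, None] * mu)
            z = (eta - offs) + (y - mu) / mu
            sw = w.sum(axis=1)
            swb = (w * x).sum(axis=1)
            swz = (w * z).sum(axis=1)
            swbz = (w * z * x).sum(axis=1)
            det = sw * swb - swb**2
            det = np.where(det > 1e-12, det, np.nan)
            new1 = (sw * swbz - swb * swz) / det
            new1 = np.clip(np.where(np.isfinite(new1), new1, beta1),
                           -beta_cap, beta_cap)
            # intercept conditional on the (possibly bounded) slope; equals
            # the joint Newton solution whenever the slope is interior
            new0 = (swz - new1 * swb) / sw
            new0 = np.clip(np.where(np.isfinite(new0), new0, beta0), -30, 30)
            step = np.maximum(np.abs(new0 - beta0), np.abs(new1 - beta1))
            beta0, beta1 = new0, new1
            converged = step < tol
            if converged.all():
                break
        at_bound = np.abs(np.abs(beta1) - beta_cap) < 1e-9
        ok = converged | at_bound

        eta = np.clip(offs + beta0[:, None] + beta1[:, None] * x, -30, 30)
        mu = np.exp(eta)
        w_obs = mu * (1.0 + a[:, None] * y) / (1.0 + a[:, None] * mu) ** 2
        sw = w_obs.sum(axis=1)
        swb = (w_obs * x).sum(axis=1)
        det = sw * swb - swb**2
        with np.errstate(divide="ignore", invalid="ignore"):
            var1 = np.where(det > 1e-12, sw / det, np.nan)
        se_t = np.sqrt(var1)
        z_t = beta1 / se_t
        p_t = 2.0 * stats.norm.sf(np.abs(z_t))
        p_t = np.where(ok, p_t, np.nan)

        lfc = beta1 / LN2
        zero_a = (y[:, x == 0].sum(axis=1) == 0)
        zero_b = (y[:, x == 1].sum(axis=1) == 0)
        sep = zero_a ^ zero_b
        if sep.any():
            lfc_sep = np.log2((mean_b[sep] + 0.5) / (mean_a[sep] + 0.5))
            lfc[sep] = lfc_sep

        log2fc[tested] = lfc
        se[tested] = se_t
        zstat[tested] = z_t
        pval[tested] = p_t

    padj = bh_adjust(pval)
    return pd.DataFrame(
        {"baseMean": base_mean, "log2FC": log2fc, "lfcSE": se,
         "stat": zstat, "pvalue": pval, "padj": padj},
        index=counts.index)


# ---------------------------------------------------------------------------
# Multiple testing, ranking, transforms


def bh_adjust(pvals: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Null (NaN) entries are excluded from the number of tests and stay null.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    m = int(valid.sum())
    if m == 0:
        return out
    pv = p[valid]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[valid] = res
    return out


def top_k(results: pd.DataFrame, k: int = 20,
          alpha: float = 0.05) -> pd.DataFrame:
    """Top differentially expressed features: padj < alpha, sorted by padj
    ascending with |log2FC| descending as tie-break."""
    sig = results[results["padj"] < alpha].copy()
    sig["_abs_lfc"] = sig["log2FC"].abs()
    sig = sig.sort_values(["padj", "_abs_lfc"],
                          ascending=[True, False], kind="mergesort")
    return sig.drop(columns="_abs_lfc").head(k)


def transform_log(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """log2(normalized + 1); the package's stand-in for a variance-
    stabilizing transform feeding PCA and sample distances."""
    return np.log2(normalize(counts, sf) + 1.0)


# ---------------------------------------------------------------------------
# Sample-level views


@dataclass
class PCAResult:
    coordinates: pd.DataFrame              # samples x components
    explained_variance_fraction: np.ndarray


def pca(transformed: pd.DataFrame, n_top: int = 500) -> PCAResult:
    """PCA of samples over the ``n_top`` most variable features.

    Features are centered, not scaled; coordinates are the sample scores
    U * S of the SVD of the centered samples-by-features matrix.
    """
    if transformed.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if transformed.shape[0] < 2:
        raise ValueError("PCA needs at least 2 features")
    var = transformed.var(axis=1)
    top = var.sort_values(ascending=False, kind="mergesort").index[:n_top]
    mat = transformed.loc[top].to_numpy(dtype=float).T  # samples x features
    mat = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    coords = u * s
    total_var = (s**2).sum()
    evf = (s**2 / total_var) if total_var > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAResult(pd.DataFrame(coords, index=transformed.columns,
                                  columns=cols), evf)


def sample_distances(transformed: pd.DataFrame) -> pd.DataFrame:
    """Euclidean sample-to-sample distances over transformed values."""
    d = squareform(pdist(transformed.to_numpy(dtype=float).T))
    return pd.DataFrame(d, index=transformed.columns,
                        columns=transformed.columns)


def genewise(counts: pd.DataFrame, sf: pd.Series,
             gene_ids: Sequence[str],
             groups: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Raw and normalized counts for selected genes, long format.

    A gene that is annotated but unexpressed (a knockout) reports zeros;
    an unknown gene raises with near-match suggestions.
    """
    g = _groups_to_series(groups, counts.columns)
    unknown = [gid for gid in gene_ids if gid not in counts.index]
    if unknown:
        hints = {gid: difflib.get_close_matches(gid, counts.index, n=3)
                 for gid in unknown}
        raise KeyError(f"unknown gene id(s) {unknown}; near matches: {hints}")
    norm = normalize(counts, sf)
    rows = []
    for gid in gene_ids:
        for s in counts.columns:
            rows.append({"gene_id": gid, "sample_id": s,
                         "condition": g[s],
                         "raw": float(counts.at[gid, s]),
                         "normalized": float(norm.at[gid, s])})
    return pd.DataFrame(rows)
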
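"""Differential transcript usage: isoform-proportion shifts within genes.

For every transcript t of a multi-isoform gene g, the per-replicate usage
proportion is estimated with a Haldane correction,

    p_hat_tj = (x_tj + 0.5) / (n_gj + 1),

where x_tj is the transcript's count and n_gj the gene's total in sample j.
Proportions are logit-transformed and compared between conditions with a
Welch two-sample t test; p-values are BH-adjusted across all tested
transcripts.  This is a deliberately simple, fully specified proportion
test standing in for Dirichlet-multinomial or per-bin GLM machinery; it is
calibrated by simulation and inherits the usual two-sample-t behavior at
small replicate numbers.

The test ignores absolute expression changes by construction: scaling all
counts of a sample leaves its proportions (up to the vanishing Haldane
term) unchanged, so DTU is orthogonal to differential expression.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from streamtx.de import _groups_to_series, bh_adjust

_SE_FLOOR = 1e-8


def eligible_genes(transcript_counts: pd.DataFrame,
                   tx2gene: pd.Series,
                   groups: Mapping[str, str] | pd.Series,
                   min_gene_count: int = 10,
                   min_replicates: int = 2) -> set[str]:
    """Genes testable for DTU: >= 2 annotated isoforms and a gene-level
    count of at least ``min_gene_count`` in at least ``min_replicates``
    samples of each condition."""
    g = _groups_to_series(groups, transcript_counts.columns)
    t2g = tx2gene.reindex(transcript_counts.index)
    gene_counts = transcript_counts.groupby(t2g).sum()
    iso_counts = t2g.value_counts()
    multi = set(iso_counts[iso_counts >= 2].index)
    ok = pd.Series(True, index=gene_counts.index)
    for cond in g.unique():
        cols = g.index[(g == cond).to_numpy()]
        ok &= (gene_counts[cols] >= min_gene_count).sum(axis=1) >= min_replicates
    return set(gene_counts.index[ok]) & multi


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p, with zero-variance conventions:
    equal means give (0, 1); unequal means with no variance give a
    floor-variance (effectively certain) result."""
    na, nb = len(a), len(b)
    diff = b.mean() - a.mean()
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    se2 = va / na + vb / nb
    if se2 < _SE_FLOOR**2:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        se2 = _SE_FLOOR**2
    t = diff / np.sqrt(se2)
    if va > 0 or vb > 0:
        num = se2**2
        den = ((va / na) ** 2 / (na - 1) if na > 1 and va > 0 else 0.0) + \
              ((vb / nb) ** 2 / (nb - 1) if nb > 1 and vb > 0 else 0.0)
        df = num / den if den > 0 else na + nb - 2
    else:
        df = na + nb - 2
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def dtu_test(transcript_counts: pd.DataFrame,
             tx2gene: pd.Series,
             groups: Mapping[str, str] | pd.Series,
             contrast: tuple[str, str] | None = None,
             min_gene_count: int = 10,
             min_replicates: int = 2) -> pd.DataFrame:
    """Welch t on logit isoform proportions, condition B vs A.

    Replicates where the gene's total falls below ``min_gene_count`` are
    dropped for that gene; if either condition then has fewer than
    ``min_replicates`` usable replicates, the gene's transcripts are
    skipped.  Returns one row per tested transcript with mean proportions,
    ``delta_proportion`` (B - A), the t statistic, p, and BH-adjusted p.
    """
    g = _groups_to_series(groups, transcript_counts.columns)
    conds = list(dict.fromkeys(g))
    if contrast is None:
        if len(conds) != 2:
            raise ValueError("need exactly two conditions or an explicit contrast")
        contrast = (conds[0], conds[1])
    cond_a, cond_b = contrast
    t2g = tx2gene.reindex(transcript_counts.index)
    genes = eligible_genes(transcript_counts, tx2gene, g,
                           min_gene_count, min_replicates)
    gene_totals = transcript_counts.groupby(t2g).sum()
    cols_a = [s for s in transcript_counts.columns if g[s] == cond_a]
    cols_b = [s for s in transcript_counts.columns if g[s] == cond_b]

    rows = []
    for gene in sorted(genes):
        tids = transcript_counts.index[(t2g == gene).to_numpy()]
        n_g = gene_totals.loc[gene]
        use_a = [s for s in cols_a if n_g[s] >= min_gene_count]
        use_b = [s for s in cols_b if n_g[s] >= min_gene_count]
        if len(use_a) < min_replicates or len(use_b) < min_replicates:
            continue
        for tid in tids:
            x = transcript_counts.loc[tid]
            pa = ((x[use_a] + 0.5) / (n_g[use_a] + 1.0)).to_numpy(dtype=float)
            pb = ((x[use_b] + 0.5) / (n_g[use_b] + 1.0)).to_numpy(dtype=float)
            la, lb = np.log(pa / (1 - pa)), np.log(pb / (1 - pb))
            t, p = _welch(la, lb)
            rows.append({"transcript_id": tid, "gene_id": gene,
                         "prop_" + cond_a: float(pa.mean()),
                         "prop_" + cond_b: float(pb.mean()),
                         "delta_proportion": float(pb.mean() - pa.mean()),
                         "stat": t, "pvalue": p})
    result = pd.DataFrame(rows, columns=[
        "transcript_id", "gene_id", "prop_" + cond_a, "prop_" + cond_b,
        "delta_proportion", "stat", "pvalue"])
    result["padj"] = bh_adjust(result["pvalue"]) if len(result) else []
    return result.set_index("transcript_id")
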
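"""Validation of top-ranked plasma markers.

Sample scores from an exact SVD PCA of the (imputed) liver omics matrices,
simple linear regressions of each liver PC on a marker's plasma intensity
(r^2 equals the squared Pearson correlation for simple regression), and the
tissue-enrichment factor of a gene over a panel of per-tissue median
expressions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix


def pca_scores(m: OmicsMatrix, k: int) -> dict:
    """Per-sample principal-component scores of a fully observed matrix.

    Features (rows) are mean-centered, samples are the observations; scores
    come from the SVD of the centered sample x feature matrix. Each
    component is oriented so that its largest-magnitude feature loading is
    positive, making signs reproducible.

    Returns ``{"scores": DataFrame (sample x PC1..PCk),
    "variance_explained": ndarray, "loadings": DataFrame}``.
    """
    vals = m.values
    if vals.isna().any().any():
        raise ValueError("pca_scores requires a fully observed matrix (impute first)")
    x = vals.to_numpy(float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    max_k = min(x.shape)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}]")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    var_exp = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return {
        "scores": pd.DataFrame(scores, index=vals.columns, columns=cols),
        "variance_explained": var_exp,
        "loadings": pd.DataFrame(vt[:k].T, index=vals.index, columns=cols),
    }


def marker_pc_regression(
    plasma: pd.Series, pca: dict, components: int = 3
) -> pd.DataFrame:
    """Regress each liver PC on a marker's per-sample plasma intensity.

    Simple linear regression with the plasma intensity as predictor, for
    PC1..PCcomponents; reports r^2 and the two-sided p of the slope. Only
    samples shared between the plasma vector and the PCA scores are used
    (>= 3 required).
    """
    scores = pca["scores"]
    shared = [s for s in scores.index if s in plasma.index and np.isfinite(plasma[s])]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between plasma vector and PCA")
    x = plasma.loc[shared].to_numpy(float)
    rows = []
    n_comp = min(components, scores.shape[1])
    for j in range(n_comp):
        y = scores.iloc[:, j].loc[shared].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((f"PC{j + 1}", 0.0, np.nan))
            continue
        res = stats.linregress(x, y)
        rows.append((f"PC{j + 1}", res.rvalue**2, res.pvalue))
    return pd.DataFrame(rows, columns=["component", "r2", "p"])


def tissue_enrichment(
    panel: pd.DataFrame, denominator: str = "median", top_n: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-enrichment factors from a gene x tissue table of medians.

    enrichment(gene, tissue) = median expression in tissue / reference,
    where the reference is the median over the per-tissue medians (default)
    or their geometric mean (``denominator="geomean"``). Genes whose
    reference is zero are flagged NaN. Also returns the top-``top_n``
    enriched tissues per gene.
    """
    if panel.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    if (panel < 0).any().any():
        raise ValueError("medians must be >= 0")
    if denominator == "median":
        ref = panel.median(axis=1)
    elif denominator == "geomean":
        if (panel == 0).any().any():
            raise ValueError("geometric-mean denominator undefined with zeros")
        ref = np.exp(np.log(panel).mean(axis=1))
    else:
        raise ValueError("denominator must be 'median' or 'geomean'")
    enr = panel.div(ref.replace(0, np.nan), axis=0)
    top_rows = []
    for gene, row in enr.iterrows():
        ranked = row.dropna().sort_values(ascending=False)
        for t, v in ranked.iloc[:top_n].items():
            top_rows.append((gene, t, v))
    top = pd.DataFrame(top_rows, columns=["gene_id", "tissue", "enrichment"])
    return enr, top
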
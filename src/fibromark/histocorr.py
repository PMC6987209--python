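"""Sample-level correlation with liver fibrosis and cross-matrix concordance.

Each feature's expression (FPKM for RNA, relative intensity for protein) is
linearly correlated against the per-animal ordinal fibrosis score; the
squared Pearson coefficient r^2 is the histology subscore fed to the
ranking. Concordance classification compares regulation calls between two
matrices (e.g. liver RNA vs liver protein) into co-regulated,
anti-regulated, single and none classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix, SampleAnnotation


def histology_correlation(
    m: OmicsMatrix, ann: SampleAnnotation, method: str = "pearson"
) -> pd.DataFrame:
    """Per-feature correlation of expression with the fibrosis score.

    Pairwise-complete: samples with missing expression for a feature are
    dropped for that feature. The fibrosis score is treated as numeric
    (linear correlation); Spearman is available via ``method``. Features
    with constant expression (or a constant score) get r = NaN, r2 = 0 and
    ``undefined = True``.

    Returns columns: feature_id, r, r2, p, n_used, undefined.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ann.check_covers(m)
    fib = ann.subset(m.samples).table["fibrosis_score"].astype(float)
    fib = fib.loc[list(m.samples)]
    x = m.values.to_numpy(float)
    y = fib.to_numpy(float)
    rows = []
    for i, fid in enumerate(m.features):
        xi = x[i]
        ok = ~np.isnan(xi)
        n = int(ok.sum())
        if n < 3:
            rows.append((fid, np.nan, 0.0, np.nan, n, True))
            continue
        xv, yv = xi[ok], y[ok]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append((fid, np.nan, 0.0, np.nan, n, True))
            continue
        if method == "pearson":
            r, p = stats.pearsonr(xv, yv)
        else:
            r, p = stats.spearmanr(xv, yv)
        rows.append((fid, r, r * r, p, n, False))
    return pd.DataFrame(
        rows, columns=["feature_id", "r", "r2", "p", "n_used", "undefined"]
    )


def concordance_classes(
    de_a: pd.DataFrame, de_b: pd.DataFrame, call_col: str = "call"
) -> tuple[pd.DataFrame, dict]:
    """Classify shared features by their regulation calls in two contrasts.

    co_regulated: significant in both with the same sign; anti_regulated:
    significant in both with opposite signs; single: significant in exactly
    one; none: in neither. The summary reports per-class counts, the overlap
    size, and the Pearson r of the shared log2 fold changes.

    Both inputs need feature_id, log2fc and a call column ('up'/'down'/'none').
    """
    a = de_a.set_index("feature_id")
    b = de_b.set_index("feature_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no overlapping features between the two contrasts")
    ca, cb = a.loc[shared, call_col], b.loc[shared, call_col]
    sig_a, sig_b = ca != "none", cb != "none"
    cls = pd.Series("none", index=shared)
    cls[sig_a & sig_b & (ca == cb)] = "co_regulated"
    cls[sig_a & sig_b & (ca != cb)] = "anti_regulated"
    cls[sig_a ^ sig_b] = "single"
    table = pd.DataFrame(
        {
            "feature_id": shared,
            "call_a": ca.to_numpy(),
            "call_b": cb.to_numpy(),
            "log2fc_a": a.loc[shared, "log2fc"].to_numpy(),
            "log2fc_b": b.loc[shared, "log2fc"].to_numpy(),
            "class": cls.to_numpy(),
        }
    )
    lfc_a = table["log2fc_a"].to_numpy()
    lfc_b = table["log2fc_b"].to_numpy()
    ok = np.isfinite(lfc_a) & np.isfinite(lfc_b)
    if ok.sum() >= 3 and np.ptp(lfc_a[ok]) > 0 and np.ptp(lfc_b[ok]) > 0:
        r = float(stats.pearsonr(lfc_a[ok], lfc_b[ok])[0])
    else:
        r = float("nan")
    counts = table["class"].value_counts().to_dict()
    summary = {
        "overlap_n": int(len(shared)),
        "log2fc_pearson_r": r,
        "counts": {k: int(counts.get(k, 0)) for k in
                   ("co_regulated", "anti_regulated", "single", "none")},
    }
    return table, summary
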
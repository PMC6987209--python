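"""Differential expression statistics and enrichment.

Per-feature two-group comparison (pooled-variance Student t on log2 data),
Benjamini-Hochberg adjustment, SAM-style permutation FDR, up/down/none
regulation calls at the padj < 0.01 and |log2FC| >= 1 cutoffs, the
differential-expression subscore

    dge_score = -log10(padj) * |log2FC|,

z-scored time-profile clustering (Euclidean distance, average linkage), and
one-sided Fisher-exact overrepresentation analysis against an
expressed-gene background.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .matrix import OmicsMatrix, SampleAnnotation


def _pooled_t(
    x: np.ndarray, a_mask: np.ndarray, b_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Vectorized pooled-variance Student t for features x samples.

    Returns (log2fc, t, p, df). Handles NaN entries by per-feature pairwise
    deletion. Features with zero pooled variance get NaN t and p.
    """
    xa, xb = x[:, a_mask], x[:, b_mask]
    na = np.sum(~np.isnan(xa), axis=1).astype(float)
    nb = np.sum(~np.isnan(xb), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(xa, axis=1), np.nanmean(xb, axis=1)
        va = np.nanvar(xa, axis=1, ddof=1)
        vb = np.nanvar(xb, axis=1, ddof=1)
    lfc = mb - ma
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    t = np.where(se > 0, t, np.nan)
    p = np.full_like(t, np.nan)
    ok = np.isfinite(t) & (df > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return lfc, t, p, df


def differential_stats(
    m: OmicsMatrix,
    ann: SampleAnnotation,
    contrast: tuple[str, str],
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided Student t-test per feature for contrast (groupA, groupB).

    log2FC = mean(groupB) - mean(groupA) on log2-scale data. Pooled-variance
    Student t by default (Welch available via flag). Features with zero
    pooled variance get NaN p with a warning. Returns a DataFrame with
    columns feature_id, log2fc, t, p, padj.
    """
    if m.scale != "log2":
        raise ValueError("differential_stats expects a log2-scale matrix")
    ann.check_covers(m)
    sub = ann.subset(m.samples)
    ga, gb = contrast
    a_cols = sub.group_samples(ga)
    b_cols = sub.group_samples(gb)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    x = m.values.to_numpy(float)
    a_mask = np.isin(np.asarray(m.samples), a_cols)
    b_mask = np.isin(np.asarray(m.samples), b_cols)
    if welch:
        xa, xb = x[:, a_mask], x[:, b_mask]
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=False, nan_policy="omit")
        lfc = np.nanmean(xb, axis=1) - np.nanmean(xa, axis=1)
        t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    else:
        lfc, t, p, _ = _pooled_t(x, a_mask, b_mask)
    if np.isnan(p).any():
        warnings.warn(
            f"{int(np.isnan(p).sum())} features with undefined p (zero variance)",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "feature_id": m.features,
            "contrast": f"{ga}_vs_{gb}",
            "log2fc": lfc,
            "t": t,
            "p": p,
        }
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out


def permutation_fdr(
    m: OmicsMatrix,
    ann: SampleAnnotation,
    contrast: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style permutation FDR (s0 = 0) for a two-group contrast.

    For each feature i with observed statistic |t_i|,

        q_i = E_perm[ #{null |t| >= |t_i|} ] / #{observed |t| >= |t_i|},

    then made monotone non-increasing in |t| (each feature takes the
    minimum raw q among features with smaller or equal |t|, the step-up
    convention) and capped at 1. Sampled label permutations are seeded and
    balanced (each permuted group draws half its members from each original
    group, so real group effects cancel in the null statistics). If n_perm
    meets or exceeds the number of distinct label arrangements, all
    arrangements are enumerated instead. Features with undefined t (zero
    variance) get q = 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ann.check_covers(m)
    sub = ann.subset(m.samples)
    ga, gb = contrast
    a_cols = set(sub.group_samples(ga))
    b_cols = set(sub.group_samples(gb))
    cols = [s for s in m.samples if s in a_cols or s in b_cols]
    labels = np.array([s in b_cols for s in cols])  # True = group B
    x = m.values[cols].to_numpy(float)
    n_tot, n_b = labels.size, int(labels.sum())

    _, t_obs, _, _ = _pooled_t(x, ~labels, labels)
    abs_obs = np.abs(t_obs)
    abs_obs_f = np.where(np.isfinite(abs_obs), abs_obs, -np.inf)

    n_arrangements = math.comb(n_tot, n_b)
    rng = np.random.default_rng(seed)
    if n_perm >= n_arrangements:
        combos = itertools.combinations(range(n_tot), n_b)
        perms = [np.isin(np.arange(n_tot), c) for c in combos]
    else:
        # balanced sampling: permuted group B takes k_a members from the
        # original A and n_b - k_a from the original B
        a_idx = np.where(~labels)[0]
        b_idx = np.where(labels)[0]
        n_a = len(a_idx)
        k_a = int(round(n_a * n_b / n_tot))
        k_a = min(max(k_a, max(0, n_b - len(b_idx))), min(n_a, n_b))
        perms = []
        for _ in range(n_perm):
            pick = np.concatenate([
                rng.choice(a_idx, size=k_a, replace=False),
                rng.choice(b_idx, size=n_b - k_a, replace=False),
            ])
            perms.append(np.isin(np.arange(n_tot), pick))
    null_abs = []
    for pb in perms:
        _, t_null, _, _ = _pooled_t(x, ~pb, pb)
        null_abs.append(np.abs(t_null))
    pool = np.concatenate(null_abs)
    pool = pool[np.isfinite(pool)]
    pool.sort()

    # counts via sorted search: #pool >= threshold, averaged over perms
    null_ge = len(pool) - np.searchsorted(pool, abs_obs_f, side="left")
    mean_null = null_ge / len(perms)
    sorted_obs = np.sort(abs_obs_f)
    obs_ge = len(sorted_obs) - np.searchsorted(sorted_obs, abs_obs_f, side="left")
    obs_ge = np.maximum(obs_ge, 1)
    q_raw = mean_null / obs_ge

    # monotonize: descending |t|; q at rank r = min of raw q at ranks >= r
    order = np.argsort(-abs_obs_f, kind="stable")
    q_sorted = q_raw[order]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_raw)
    q[order] = np.minimum(q_mono, 1.0)
    q[~np.isfinite(abs_obs)] = 1.0
    return pd.DataFrame({"feature_id": m.features, "abs_t": abs_obs, "q": q})


def call_regulated(
    de: pd.DataFrame, padj_cut: float = 0.01, lfc_cut: float = 1.0,
    padj_col: str = "padj",
) -> pd.Series:
    """Regulation call per feature: 'up', 'down' or 'none'.

    up iff padj < padj_cut and log2FC >= lfc_cut; down iff padj < padj_cut
    and log2FC <= -lfc_cut; otherwise none. Missing padj yields none.
    """
    padj = de[padj_col]
    if padj.isna().any():
        warnings.warn("missing adjusted p-values; calling those features none", stacklevel=2)
    sig = padj < padj_cut
    call = pd.Series("none", index=de.index)
    call[sig & (de["log2fc"] >= lfc_cut)] = "up"
    call[sig & (de["log2fc"] <= -lfc_cut)] = "down"
    return call


def dge_score(padj, log2fc):
    """Differential-expression subscore: -log10(padj) * |log2fc|.

    Accepts scalars or arrays; padj of exactly 0 is clamped to the smallest
    positive float with a warning. padj must lie in (0, 1] otherwise.
    """
    padj = np.asarray(padj, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("padj must lie in [0, 1]")
    if (padj == 0).any():
        warnings.warn("padj of 0 clamped to smallest positive float", stacklevel=2)
        padj = np.where(padj == 0, np.finfo(float).tiny, padj)
    out = -np.log10(padj) * np.abs(log2fc)
    if out.ndim == 0:
        return float(out)
    return out


def cluster_time_profiles(
    log_ratios: pd.DataFrame, k: int
) -> tuple[pd.DataFrame, list[str]]:
    """Cluster z-scored time profiles by average-linkage on Euclidean distance.

    Each feature's time course of log2 ratios is standardized to mean 0,
    SD 1 across time points, then agglomeratively clustered and the tree cut
    into k clusters. Constant profiles (zero SD) cannot be z-scored; they
    are excluded and returned separately. Features are processed in sorted
    id order for deterministic tie behaviour.

    Returns (assignments DataFrame with feature_id and cluster in 1..k,
    list of excluded feature ids).
    """
    if log_ratios.shape[1] < 2:
        raise ValueError("need >= 2 time points")
    lr = log_ratios.sort_index()
    sd = lr.std(axis=1, ddof=0)
    excluded = list(lr.index[sd == 0])
    lr = lr.loc[sd > 0]
    if len(lr) < k:
        raise ValueError(f"fewer usable features ({len(lr)}) than clusters ({k})")
    z = lr.sub(lr.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    link = linkage(z.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(link, t=k, criterion="maxclust")
    return (
        pd.DataFrame({"feature_id": z.index, "cluster": labels}),
        excluded,
    )


def fisher_ora(
    selected: set[str] | list[str],
    background: set[str] | list[str],
    term_sets: dict[str, set[str] | list[str]],
) -> pd.DataFrame:
    """One-sided Fisher-exact overrepresentation of term sets in a selection.

    p is the hypergeometric upper tail P(X >= overlap) for drawing
    len(selected) features from the background; enrichment factor =
    (overlap/selected size) / (term size/background size). BH-adjusted
    across terms.
    """
    selected = set(selected)
    background = set(background)
    if not selected:
        raise ValueError("selected set is empty")
    if not selected <= background:
        raise ValueError("selected must be a subset of background")
    rows = []
    big_n, n_sel = len(background), len(selected)
    for term, members in sorted(term_sets.items()):
        members = set(members) & background
        k_term = len(members)
        overlap = len(members & selected)
        if k_term == 0:
            p = 1.0
            enr = np.nan
        else:
            p = float(stats.hypergeom.sf(overlap - 1, big_n, k_term, n_sel))
            enr = (overlap / n_sel) / (k_term / big_n)
        rows.append((term, overlap, k_term, n_sel, big_n, enr, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "overlap",
            "term_size",
            "selected_size",
            "background_size",
            "enrichment",
            "p",
        ],
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
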
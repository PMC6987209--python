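"""Matrix-level preprocessing for proteomics and RNA-Seq data.

The proteomics chain mirrors the standard TMT workflow: keep proteins
quantified in at least ``min_present`` replicates of one experimental group,
normalize each channel on total intensity and scale to a channel average of
100, log2-transform, impute left-censored missing values by sampling from a
downshifted narrow normal distribution (the Perseus convention: downshift
and width are multiples of the per-column observed SD), and mean-center
each run (batch) to remove batch effects.

The RNA chain converts counts to CPM and flags genes expressed at >= 1 CPM
in the majority of samples of at least one group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix, SampleAnnotation


def filter_by_group_presence(
    m: OmicsMatrix, ann: SampleAnnotation, min_present: int
) -> OmicsMatrix:
    """Keep features observed in >= min_present samples of at least one group.

    The sample set is unchanged; only rows are dropped.
    """
    ann.check_covers(m)
    sizes = [len(ann.subset(m.samples).group_samples(g)) for g in ann.subset(m.samples).groups]
    if min_present > min(sizes):
        raise ValueError(
            f"min_present={min_present} exceeds smallest group size {min(sizes)}"
        )
    sub = ann.subset(m.samples)
    keep = pd.Series(False, index=m.features)
    for g in sub.groups:
        cols = sub.group_samples(g)
        keep |= m.values[cols].notna().sum(axis=1) >= min_present
    return m.with_values(m.values.loc[keep])


def normalize_total_and_scale(m: OmicsMatrix, target_mean: float = 100.0) -> OmicsMatrix:
    """Normalize on total per-sample intensity, then scale each channel so
    the mean of its observed values equals ``target_mean``.

    Each column is divided by its total (equalizing loading) and the
    resulting columns are rescaled so every column's observed mean is
    exactly ``target_mean``; within-column ratios are preserved.
    """
    if m.scale == "log2":
        raise ValueError("normalize_total_and_scale expects a linear-scale matrix")
    vals = m.values
    if (vals < 0).any().any():
        raise ValueError("negative intensities")
    totals = vals.sum(axis=0, skipna=True)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero total intensity in columns: {bad[:5]}")
    normed = vals.div(totals, axis=1) * totals.mean()
    col_means = normed.mean(axis=0, skipna=True)
    out = normed.div(col_means, axis=1) * target_mean
    return m.with_values(out)


def impute_downshifted(
    m: OmicsMatrix, downshift: float = 2.5, width: float = 0.2, seed: int = 0
) -> OmicsMatrix:
    """Replace missing values by draws from a downshifted normal distribution.

    For each sample column j with observed mean m_j and SD s_j (log2 scale),
    missing entries are drawn from Normal(m_j - downshift*s_j, (width*s_j)^2).
    Observed entries are untouched; the draw is seeded.
    """
    if m.scale != "log2":
        raise ValueError("impute_downshifted expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    vals = m.values.copy()
    for col in vals.columns:
        x = vals[col]
        miss = x.isna()
        if not miss.any():
            continue
        obs = x[~miss]
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has <2 observed values; cannot impute")
        mu, sd = obs.mean(), obs.std(ddof=1)
        vals.loc[miss, col] = rng.normal(mu - downshift * sd, width * sd, size=int(miss.sum()))
    return m.with_values(vals)


def center_batches(m: OmicsMatrix, ann: SampleAnnotation) -> OmicsMatrix:
    """Mean-center each feature within each batch (experimental run).

    Removes additive per-run offsets; within-batch per-feature means are
    exactly zero afterwards. Expects a fully observed log-scale matrix
    (run after imputation).
    """
    if m.scale != "log2":
        raise ValueError("center_batches expects a log2-scale matrix")
    ann.check_covers(m)
    sub = ann.subset(m.samples)
    vals = m.values.copy()
    for batch, cols in sub.table.groupby("batch").groups.items():
        cols = list(cols)
        if len(cols) == 1:
            warnings.warn(
                f"batch {batch!r} has a single sample; centering zeroes it",
                stacklevel=2,
            )
        block = vals[cols]
        vals[cols] = block.sub(block.mean(axis=1), axis=0)
    return m.with_values(vals)


def cpm_and_expressed_filter(
    counts: OmicsMatrix, ann: SampleAnnotation, threshold: float = 1.0
) -> tuple[OmicsMatrix, pd.Series]:
    """Counts-per-million plus the expressed-gene flag.

    A gene is expressed iff its CPM is >= threshold in strictly more than
    half the samples of at least one experimental group ("majority" read
    strictly). Returns the CPM matrix (column sums = 1e6) and the mask.
    """
    ann.check_covers(counts)
    vals = counts.values
    if (vals < 0).any().any() or vals.isna().any().any():
        raise ValueError("counts must be non-negative and fully observed")
    totals = vals.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-count sample columns: {bad[:5]}")
    cpm = vals.div(totals, axis=1) * 1e6
    sub = ann.subset(counts.samples)
    expressed = pd.Series(False, index=counts.features)
    for g in sub.groups:
        cols = sub.group_samples(g)
        n_pass = (cpm[cols] >= threshold).sum(axis=1)
        expressed |= n_pass > len(cols) / 2
    return OmicsMatrix(cpm, scale="linear", kind=counts.kind), expressed


def prep_protein_matrix(
    m: OmicsMatrix,
    ann: SampleAnnotation,
    min_present: int = 6,
    target_mean: float = 100.0,
    downshift: float = 2.5,
    width: float = 0.2,
    seed: int = 0,
) -> OmicsMatrix:
    """Full proteomics preprocessing chain: presence filter, total/channel
    normalization, log2, downshifted imputation, batch mean-centering."""
    m = filter_by_group_presence(m, ann, min_present)
    m = normalize_total_and_scale(m, target_mean)
    m = m.log2()
    m = impute_downshifted(m, downshift=downshift, width=width, seed=seed)
    m = center_batches(m, ann)
    return m
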
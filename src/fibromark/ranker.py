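"""Multi-dimensional weighted-sum biomarker ranking.

The core method: candidate plasma proteins (rat proteins with a human
ortholog, detected in both the liver and plasma protein data) are scored on
twelve subscores grouped into four dimensions:

* plasma specificity — plasma differential-expression score and plasma
  fibrosis-correlation r^2;
* liver specificity — liver protein and liver RNA differential-expression
  scores and their fibrosis-correlation r^2;
* prior evidence — a disease-association score, two literature subscores
  (rank-normalized publication counts and observed/expected publication
  ratio), a patent flag and a database flag;
* secreted protein class — a binary flag.

Differential-expression subscores use dge_score = -log10(padj)*|log2FC| and
are rank-normalized to [0, 1] across the candidate cohort so unbounded
scores cannot dominate bounded ones; r^2, association score and flags enter
raw (already in [0, 1]). Each dimension score is the mean of its subscores
(a raw-sum mode is available), the total score is the weighted sum of the
four dimension scores under a weight setting whose weights sum to 1, and
the sensitivity analysis compares rankings across weight settings.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata

DIMENSIONS = ("plasma", "liver", "prior", "secreted")

#: Mapping of the twelve subscores onto the four ranking dimensions.
DIMENSION_SUBSCORES: dict[str, tuple[str, ...]] = {
    "plasma": ("plasma_dge", "plasma_histo_r2"),
    "liver": (
        "liver_protein_dge",
        "liver_rna_dge",
        "liver_protein_histo_r2",
        "liver_rna_histo_r2",
    ),
    "prior": (
        "fibrosis_association",
        "lit_pubcount",
        "lit_pub_vs_expected",
        "patent_flag",
        "database_flag",
    ),
    "secreted": ("secreted_flag",),
}

ALL_SUBSCORES = tuple(s for subs in DIMENSION_SUBSCORES.values() for s in subs)


@dataclass(frozen=True)
class WeightSetting:
    """Weights over the four ranking dimensions; must sum to 1."""

    name: str
    plasma: float
    liver: float
    prior: float
    secreted: float

    def __post_init__(self) -> None:
        w = self.as_array()
        if ((w < 0) | (w > 1)).any():
            raise ValueError(f"weights must lie in [0, 1]: {self}")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1 (got {w.sum()}): {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.plasma, self.liver, self.prior, self.secreted])


def load_weight_settings(path: str | Path | None = None) -> list[WeightSetting]:
    """Load weight settings from YAML; the packaged six-setting file by default."""
    if path is None:
        ref = importlib.resources.files("fibromark").joinpath("data/weight_settings.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    settings = [WeightSetting(**row) for row in raw]
    names = [s.name for s in settings]
    if len(set(names)) != len(names):
        raise ValueError("duplicate weight-setting names")
    return settings


def rank_normalize(values) -> np.ndarray:
    """Map values to [0, 1] by average ranks: (rank - 1) / (n - 1).

    Ties share their average rank; the minimum maps to 0, the maximum to 1;
    a single value maps to 0.5.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.isnan(v).all():
        raise ValueError("rank_normalize needs at least one finite value")
    if np.isnan(v).any():
        raise ValueError("rank_normalize input contains NaN; fill missing first")
    if v.size == 1:
        return np.array([0.5])
    ranks = rankdata(v, method="average")
    return (ranks - 1.0) / (v.size - 1.0)


def literature_subscore(
    pub_count: np.ndarray, expected: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two literature subscores over the candidate cohort.

    A: rank-normalized publication counts; B: rank-normalized observed /
    expected publication ratio. Both in [0, 1].
    """
    pub_count = np.asarray(pub_count, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if (pub_count < 0).any():
        raise ValueError("negative publication counts")
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return rank_normalize(pub_count), rank_normalize(pub_count / expected)


def assemble_subscores(
    de: dict[str, pd.DataFrame],
    corr: dict[str, pd.DataFrame],
    prior: pd.DataFrame,
    id_map: pd.DataFrame,
    padj_col: str = "padj",
) -> pd.DataFrame:
    """Build the candidate x 12-subscore table.

    Parameters
    ----------
    de
        Differential results keyed by contrast: ``plasma_protein``,
        ``liver_protein``, ``liver_rna``; each with feature_id, log2fc and
        an adjusted-p column. Feature sets define post-filter detection.
    corr
        Fibrosis-correlation tables (feature_id, r2) under the same keys.
    prior
        Prior-evidence table (gene_id, fibrosis_association,
        publication_count, expected_count, patent_flag, database_flag).
        Genes absent from it receive zero evidence.
    id_map
        rat_gene_id -> human_gene_id (empty = no ortholog) and secreted flag.

    Candidates are genes with a human ortholog detected in both protein
    matrices. dge subscores are rank-normalized over the candidate cohort
    after the filter, so normalization cohorts equal the candidate set.
    """
    from .diffexp import dge_score  # local import to avoid cycle

    for key in ("plasma_protein", "liver_protein", "liver_rna"):
        if key not in de:
            raise KeyError(f"missing DE results for contrast {key!r}")
    imap = id_map.set_index("rat_gene_id")
    has_ortholog = imap.index[imap["human_gene_id"].fillna("").astype(str) != ""]
    detected_liver = set(de["liver_protein"]["feature_id"])
    detected_plasma = set(de["plasma_protein"]["feature_id"])
    candidates = sorted(set(has_ortholog) & detected_liver & detected_plasma)
    if not candidates:
        raise ValueError("candidate set is empty")

    out = pd.DataFrame(index=pd.Index(candidates, name="gene_id"))

    def _dge_col(tbl: pd.DataFrame) -> pd.Series:
        t = tbl.set_index("feature_id")
        padj = t[padj_col].reindex(candidates)
        lfc = t["log2fc"].reindex(candidates)
        raw = pd.Series(0.0, index=out.index)
        ok = padj.notna() & lfc.notna() & (padj > 0)
        raw[ok] = dge_score(padj[ok].to_numpy(), lfc[ok].to_numpy())
        return raw

    out["plasma_dge"] = rank_normalize(_dge_col(de["plasma_protein"]))
    out["liver_protein_dge"] = rank_normalize(_dge_col(de["liver_protein"]))
    out["liver_rna_dge"] = rank_normalize(_dge_col(de["liver_rna"]))

    for key, col in [
        ("plasma_protein", "plasma_histo_r2"),
        ("liver_protein", "liver_protein_histo_r2"),
        ("liver_rna", "liver_rna_histo_r2"),
    ]:
        c = corr[key].set_index("feature_id")["r2"].reindex(candidates)
        out[col] = c.fillna(0.0).to_numpy()

    pr = prior.set_index("gene_id").reindex(candidates)
    out["fibrosis_association"] = pr["fibrosis_association"].fillna(0.0).to_numpy()
    pubs = pr["publication_count"].fillna(0.0).to_numpy()
    expected = pr["expected_count"].fillna(1.0).to_numpy()
    lit_a, lit_b = literature_subscore(pubs, expected)
    out["lit_pubcount"] = lit_a
    out["lit_pub_vs_expected"] = lit_b
    out["patent_flag"] = pr["patent_flag"].fillna(0).astype(float).to_numpy()
    out["database_flag"] = pr["database_flag"].fillna(0).astype(float).to_numpy()
    out["secreted_flag"] = (
        imap["secreted"].reindex(candidates).fillna(0).astype(float).to_numpy()
    )
    return out[list(ALL_SUBSCORES)]


def dimension_scores(subscores: pd.DataFrame, aggregation: str = "mean") -> pd.DataFrame:
    """Aggregate the twelve subscores into the four dimension scores.

    ``mean`` (default) keeps each dimension in [0, 1]; ``sum`` reproduces a
    literal raw-sum reading.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError("aggregation must be 'mean' or 'sum'")
    missing = [s for s in ALL_SUBSCORES if s not in subscores.columns]
    if missing:
        raise ValueError(f"subscore table incomplete; missing {missing}")
    dims = pd.DataFrame(index=subscores.index)
    for dim, subs in DIMENSION_SUBSCORES.items():
        block = subscores[list(subs)]
        dims[dim] = block.mean(axis=1) if aggregation == "mean" else block.sum(axis=1)
    return dims


def total_score_and_rank(dims: pd.DataFrame, setting: WeightSetting) -> pd.DataFrame:
    """Weighted total score and 1-based rank under one weight setting.

    total = sum_j w_j * dimension_j. Candidates are sorted by descending
    total; ties broken lexicographically by candidate id (stable,
    documented). Per-dimension contributions w_j * dim_j are included.
    """
    w = setting.as_array()
    missing = [d for d in DIMENSIONS if d not in dims.columns]
    if missing:
        raise ValueError(f"dimension table incomplete; missing {missing}")
    out = dims[list(DIMENSIONS)].copy()
    contrib = out.to_numpy() * w[None, :]
    for j, d in enumerate(DIMENSIONS):
        out[f"contrib_{d}"] = contrib[:, j]
    out["total"] = contrib.sum(axis=1)
    out["setting"] = setting.name
    out = out.sort_index()  # lexicographic tie-break base order
    out = out.sort_values("total", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def sensitivity_analysis(
    dims: pd.DataFrame, settings: list[WeightSetting]
) -> dict:
    """Total scores and ranks across weight settings.

    Returns a dict with ``scores`` (candidate x setting totals), ``ranks``
    (candidate x setting), ``best_rank`` (min across settings per
    candidate) and ``order`` (candidate ids ordered by average-linkage
    hierarchical clustering of their score vectors, for heatmap display).
    """
    if len(settings) < 2:
        raise ValueError("need >= 2 weight settings")
    names = [s.name for s in settings]
    if len(set(names)) != len(names):
        raise ValueError("duplicate weight-setting names")
    scores = pd.DataFrame(index=dims.index.sort_values(), columns=names, dtype=float)
    ranks = scores.copy()
    for s in settings:
        res = total_score_and_rank(dims, s)
        scores[s.name] = res["total"].reindex(scores.index)
        ranks[s.name] = res["rank"].reindex(scores.index)
    best = ranks.min(axis=1).astype(int)
    x = scores.to_numpy()
    if len(scores) > 2:
        order_idx = leaves_list(linkage(x, method="average", metric="euclidean"))
        order = list(scores.index[order_idx])
    else:
        order = list(scores.index)
    return {"scores": scores, "ranks": ranks, "best_rank": best, "order": order}
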
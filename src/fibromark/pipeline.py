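"""End-to-end orchestration: simulate -> prep -> diffexp -> correlate ->
rank -> evaluate, from a single config with one global seed.

Per-stage seeds are derived deterministically from the global seed by
hashing the stage name, so any stage can be rerun in isolation. Every stage
records its parameters and outputs in a JSON manifest; rerunning with the
same config and seed reproduces byte-identical tables (6-significant-digit
TSV formatting).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexp import call_regulated, differential_stats, permutation_fdr
from .evaluate import marker_pc_regression, pca_scores
from .histocorr import concordance_classes, histology_correlation
from .matrix import OmicsMatrix, SampleAnnotation
from .prep import cpm_and_expressed_filter, prep_protein_matrix
from .ranker import (
    assemble_subscores,
    dimension_scores,
    load_weight_settings,
    sensitivity_analysis,
    total_score_and_rank,
)
from .synthgen import EffectConfig, StudyDesign, generate_study, generate_prior_evidence

logger = logging.getLogger("fibromark")

FLOAT_FMT = "%.6g"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic-study mode)."""

    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectConfig = field(default_factory=EffectConfig)
    evidence_fraction: float = 0.8
    min_present: int = 6
    target_mean: float = 100.0
    downshift: float = 2.5
    width: float = 0.2
    padj_cut: float = 0.01
    lfc_cut: float = 1.0
    n_perm: int = 1000
    weights_path: str | None = None
    seed: int = 0
    outdir: str = "fibromark_run"
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = StudyDesign(**{
            **raw.get("design", {}),
            **({"groups": tuple(raw["design"]["groups"])} if "groups" in raw.get("design", {}) else {}),
            **({"weeks": tuple(raw["design"]["weeks"])} if "weeks" in raw.get("design", {}) else {}),
        })
        effects = EffectConfig(**raw.get("effects", {}))
        rest = {k: v for k, v in raw.items() if k not in ("design", "effects")}
        return cls(design=design, effects=effects, **rest)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="NA")
    return str(path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON).

    Partial outputs are retained on stage failure; the manifest names the
    failing stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "design": dataclasses.asdict(cfg.design),
            "effects": dataclasses.asdict(cfg.effects),
            **{
                k: getattr(cfg, k)
                for k in (
                    "evidence_fraction", "min_present", "target_mean", "downshift",
                    "width", "padj_cut", "lfc_cut", "n_perm", "weights_path", "top_k",
                )
            },
        },
        "stages": {},
    }
    current = "simulate"
    try:
        # --- simulate --------------------------------------------------------
        logger.info("stage simulate")
        design = dataclasses.replace(cfg.design, seed=stage_seed(cfg.seed, "simulate"))
        study = generate_study(design, cfg.effects)
        prior = generate_prior_evidence(
            study.truth["feature_id"].to_numpy(),
            study.truth,
            seed=stage_seed(cfg.seed, "evidence"),
            evidence_fraction=cfg.evidence_fraction,
        )
        paths = study.write(out)
        paths["prior_evidence"] = _write(prior, out / "prior_evidence.tsv")
        manifest["stages"]["simulate"] = {"seed": design.seed, "outputs": paths}

        # --- prep ------------------------------------------------------------
        current = "prep"
        logger.info("stage prep")
        ann = study.annotation
        liver_prot = prep_protein_matrix(
            study.liver_protein, ann, cfg.min_present, cfg.target_mean,
            cfg.downshift, cfg.width, seed=stage_seed(cfg.seed, "impute_liver"),
        )
        plasma_prot = prep_protein_matrix(
            study.plasma_protein, ann, cfg.min_present, cfg.target_mean,
            cfg.downshift, cfg.width, seed=stage_seed(cfg.seed, "impute_plasma"),
        )
        cpm, expressed = cpm_and_expressed_filter(study.liver_rna, ann)
        cpm_expr = cpm.with_values(cpm.values.loc[expressed])
        liver_prot.to_tsv(out / "liver_protein_prepped.tsv")
        plasma_prot.to_tsv(out / "plasma_protein_prepped.tsv")
        cpm_expr.to_tsv(out / "liver_rna_cpm.tsv")
        manifest["stages"]["prep"] = {
            "liver_protein_features": int(liver_prot.values.shape[0]),
            "plasma_protein_features": int(plasma_prot.values.shape[0]),
            "expressed_genes": int(expressed.sum()),
        }

        # --- diffexp ---------------------------------------------------------
        current = "diffexp"
        logger.info("stage diffexp")
        contrast = (design.control, design.diseased)
        last_week = max(design.weeks)
        lw_samples = ann.table.index[ann.table["week"] == last_week]
        rna_lw = OmicsMatrix(
            np.log2(cpm_expr.values[list(lw_samples)] + 1.0),
            scale="log2", kind="liver_rna",
        )
        de: dict[str, pd.DataFrame] = {}
        for key, mat in [
            ("liver_rna", rna_lw),
            ("liver_protein", liver_prot),
            ("plasma_protein", plasma_prot),
        ]:
            tbl = differential_stats(mat, ann, contrast)
            if key != "liver_rna":  # permutation FDR for the proteomics contrasts
                q = permutation_fdr(
                    mat, ann, contrast, n_perm=cfg.n_perm,
                    seed=stage_seed(cfg.seed, f"perm_{key}"),
                )
                tbl = tbl.merge(q[["feature_id", "q"]], on="feature_id")
            tbl["call"] = call_regulated(tbl, cfg.padj_cut, cfg.lfc_cut)
            de[key] = tbl
            _write(tbl, out / f"de_{key}.tsv")
        conc_table, conc_summary = concordance_classes(de["liver_rna"], de["liver_protein"])
        _write(conc_table, out / "concordance_rna_protein.tsv")
        manifest["stages"]["diffexp"] = {
            "contrast": list(contrast),
            "n_perm": cfg.n_perm,
            "concordance": conc_summary,
        }

        # --- correlate -------------------------------------------------------
        current = "correlate"
        logger.info("stage correlate")
        corr: dict[str, pd.DataFrame] = {}
        corr["liver_rna"] = histology_correlation(cpm_expr, ann)
        # proteins: relative (linear) intensities carry the fibrosis signal
        for key, raw in [
            ("liver_protein", study.liver_protein),
            ("plasma_protein", study.plasma_protein),
        ]:
            kept = de[key]["feature_id"]
            sub = raw.with_values(raw.values.loc[kept])
            corr[key] = histology_correlation(sub, ann)
            _write(corr[key], out / f"histocorr_{key}.tsv")
        _write(corr["liver_rna"], out / "histocorr_liver_rna.tsv")
        manifest["stages"]["correlate"] = {
            k: int(len(v)) for k, v in corr.items()
        }

        # --- rank ------------------------------------------------------------
        current = "rank"
        logger.info("stage rank")
        subs = assemble_subscores(de, corr, prior, study.id_map)
        dims = dimension_scores(subs)
        settings = load_weight_settings(cfg.weights_path)
        default = next(s for s in settings if s.name == "default")
        ranking = total_score_and_rank(dims, default)
        full = subs.join(ranking, how="right")
        _write(full.reset_index(), out / "ranking_default.tsv")
        sens = sensitivity_analysis(dims, settings)
        _write(sens["scores"].reset_index(), out / "sensitivity_scores.tsv")
        _write(
            sens["ranks"].assign(best_rank=sens["best_rank"]).reset_index(),
            out / "sensitivity_ranks.tsv",
        )
        top_default = list(ranking.index[: cfg.top_k])
        planted = set(
            study.truth.loc[study.truth["class"] == "secreted_biomarker", "feature_id"]
        )
        recovery = (
            len(planted & set(top_default)) / len(planted) if planted else float("nan")
        )
        manifest["stages"]["rank"] = {
            "n_candidates": int(len(subs)),
            "settings": [s.name for s in settings],
            "top_k": cfg.top_k,
            "planted_markers": int(len(planted)),
            "planted_in_top_k": int(len(planted & set(top_default))),
            "recovery_fraction": recovery,
        }

        # --- evaluate --------------------------------------------------------
        current = "evaluate"
        logger.info("stage evaluate")
        k = min(3, len(lw_samples) - 1, rna_lw.values.shape[0])
        pcas = {
            "liver_rna": pca_scores(rna_lw, k),
            "liver_protein": pca_scores(liver_prot, k),
        }
        top10 = top_default[: min(10, len(top_default))]
        reg_rows = []
        for marker in top10:
            if marker not in plasma_prot.features:
                continue
            vec = plasma_prot.values.loc[marker]
            for kind, pca in pcas.items():
                res = marker_pc_regression(vec, pca, components=k)
                res.insert(0, "marker", marker)
                res.insert(1, "matrix", kind)
                reg_rows.append(res)
        reg = pd.concat(reg_rows, ignore_index=True) if reg_rows else pd.DataFrame()
        _write(reg, out / "marker_pc_regression.tsv")
        manifest["stages"]["evaluate"] = {
            "components": k,
            "markers": top10,
            "variance_explained_rna": [float(v) for v in pcas["liver_rna"]["variance_explained"]],
        }
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
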
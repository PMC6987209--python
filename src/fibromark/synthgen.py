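"""Seeded synthetic multi-omics study generator.

Emulates a two-arm dietary NASH rodent study (control vs diseased, eight
animals per arm) profiled by liver RNA-Seq over several weeks and by liver
and plasma proteomics at the final week, with:

* a latent disease severity per animal that increases with time on the
  diseased diet and drives an ordinal liver fibrosis score (0-4),
* negative-binomial RNA counts whose log-means move linearly with severity
  for non-null genes,
* log-normal protein intensities coupled to the RNA effects with a
  configurable correlation, including a small anti-regulated class whose
  protein effect sign opposes the RNA effect,
* plasma intensities coupled (attenuated) to liver protein only for planted
  secreted biomarkers,
* left-censored (intensity-dependent) missingness and per-run batch offsets
  in the protein matrices.

Every feature's class and true effect are recorded in a truth table so each
downstream stage can be recovery-tested. The same (design, effects, seed)
always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix, SampleAnnotation

FEATURE_CLASSES = ("null", "liver_de_only", "secreted_biomarker", "antiregulated")


@dataclass
class StudyDesign:
    """Animal-study layout: arms, cohort size, time points, proteomics runs."""

    groups: tuple[str, str] = ("CSAA", "CDAA")  # (control, diseased)
    animals_per_group: int = 8
    weeks: tuple[int, ...] = (4, 8, 12)
    batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_group < 3:
            raise ValueError("animals_per_group must be >= 3")
        if len(self.groups) != 2:
            raise ValueError("need exactly one control and one diseased group")
        if self.batches < 1:
            raise ValueError("batches must be >= 1")
        if not self.weeks:
            raise ValueError("at least one week required")

    @property
    def control(self) -> str:
        return self.groups[0]

    @property
    def diseased(self) -> str:
        return self.groups[1]


@dataclass
class EffectConfig:
    """Effect structure and noise levels of the generated study.

    Defaults encode the study conditions the pipeline is tested under:
    strong liver regulation (about a third of genes differential at
    |log2FC| ~ 2), a ~1.5% anti-regulated class, 1% planted secreted
    biomarkers, RNA-protein effect coupling 0.75, and a low left-censored
    missing rate in the protein matrices.
    """

    n_features_rna: int = 2000
    n_features_liver_protein: int = 1500
    n_features_plasma: int = 400
    fraction_de: float = 0.35
    fraction_secreted_biomarker: float = 0.01
    fraction_antiregulated: float = 0.015
    effect_size_log2: float = 2.0
    rna_protein_coupling: float = 0.75
    plasma_attenuation: float = 0.7
    protein_noise_sd: float = 0.3
    rna_dispersion: float = 0.1
    rna_base_log2_mean: float = 6.0
    rna_base_log2_sd: float = 1.5
    protein_base_log2_mean: float = 20.0
    protein_base_log2_sd: float = 2.0
    batch_effect_sd: float = 0.3
    missing_rate: float = 0.02
    censoring_steepness: float = 1.5
    severity_noise_sd: float = 0.1
    fibrosis_noise_sd: float = 0.5
    fibrosis_max: int = 4
    ortholog_fraction: float = 0.9
    secreted_background_fraction: float = 0.1

    def __post_init__(self) -> None:
        frac = (
            self.fraction_de
            + self.fraction_secreted_biomarker
            + self.fraction_antiregulated
        )
        if not 0 <= frac <= 1:
            raise ValueError("feature-class fractions must sum to <= 1")
        for name in ("fraction_de", "fraction_secreted_biomarker", "fraction_antiregulated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.rna_protein_coupling <= 1:
            raise ValueError("rna_protein_coupling must be in [0, 1]")
        if not 0 <= self.plasma_attenuation <= 1:
            raise ValueError("plasma_attenuation must be in [0, 1]")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_features_rna", "n_features_liver_protein", "n_features_plasma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_features_liver_protein > self.n_features_rna:
            raise ValueError("liver protein features cannot exceed gene universe")
        if self.n_features_plasma > self.n_features_liver_protein:
            raise ValueError("plasma features cannot exceed liver protein features")


@dataclass
class SyntheticStudy:
    """A complete generated study: three matrices, annotation, maps, truth."""

    liver_rna: OmicsMatrix
    liver_protein: OmicsMatrix
    plasma_protein: OmicsMatrix
    annotation: SampleAnnotation
    id_map: pd.DataFrame
    truth: pd.DataFrame
    design: StudyDesign
    effects: EffectConfig

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write all tables as TSV; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, m in [
            ("liver_rna", self.liver_rna),
            ("liver_protein", self.liver_protein),
            ("plasma_protein", self.plasma_protein),
        ]:
            p = outdir / f"{name}.tsv"
            m.to_tsv(p)
            paths[name] = str(p)
        p = outdir / "annotation.tsv"
        self.annotation.to_tsv(p)
        paths["annotation"] = str(p)
        for name, df in [("id_map", self.id_map), ("truth", self.truth)]:
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = str(p)
        return paths


def fibrosis_from_severity(
    severity: np.ndarray,
    noise_sd: float,
    seed: int,
    slope: float = 1.0,
    intercept: float = 0.0,
    max_score: int = 4,
) -> np.ndarray:
    """Map latent severity to an ordinal histology fibrosis score.

    Affine map of severity plus Gaussian noise, rounded and clipped to
    [0, max_score]. With zero noise and the identity affine map, integer
    severities pass through unchanged.
    """
    severity = np.asarray(severity, dtype=float)
    if not np.all(np.isfinite(severity)):
        raise ValueError("severity must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    raw = slope * severity + intercept + rng.normal(0.0, noise_sd, size=severity.shape)
    return np.clip(np.rint(raw), 0, max_score).astype(int)


def _assign_classes(n: int, effects: EffectConfig, rng: np.random.Generator) -> np.ndarray:
    """Partition the gene universe into truth classes (exact counts)."""
    n_bio = int(round(effects.fraction_secreted_biomarker * n))
    n_anti = int(round(effects.fraction_antiregulated * n))
    n_de = int(round(effects.fraction_de * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_bio]] = "secreted_biomarker"
    classes[order[n_bio : n_bio + n_anti]] = "antiregulated"
    classes[order[n_bio + n_anti : n_bio + n_anti + n_de]] = "liver_de_only"
    return classes


def _severity(
    design: StudyDesign, weeks: np.ndarray, groups: np.ndarray, rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    """Latent severity: ~0 for controls, ramps to 1 with week for diseased."""
    sev = np.zeros(len(weeks), dtype=float)
    diseased = groups == design.diseased
    max_week = max(design.weeks)
    sev[diseased] = weeks[diseased] / max_week
    sev += rng.normal(0.0, noise_sd, size=len(weeks))
    return np.clip(sev, 0.0, None)


def _left_censor(
    values: np.ndarray, rate: float, steepness: float, rng: np.random.Generator
) -> np.ndarray:
    """Set entries missing with logistic probability decreasing in intensity.

    The logistic midpoint is solved by bisection so the expected overall
    missing fraction equals ``rate``.
    """
    if rate <= 0:
        return values
    flat = values.ravel()
    lo, hi = flat.min() - 10.0, flat.max() + 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(steepness * (flat - mid)))
        if p.mean() > rate:
            hi = mid
        else:
            lo = mid
    x0 = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(steepness * (values - x0)))
    out = values.copy()
    out[rng.random(values.shape) < p] = np.nan
    return out


def generate_study(design: StudyDesign, effects: EffectConfig) -> SyntheticStudy:
    """Generate a complete synthetic multi-omics study with ground truth.

    RNA covers all weeks; the protein matrices cover the final week only
    (the week at which proteomics is profiled). The returned truth table
    records each gene's class, its true RNA and liver-protein log2 effects
    (per unit severity), and the sign of its fibrosis correlation.
    """
    rng = np.random.default_rng(design.seed)
    n = effects.n_features_rna
    genes = np.array([f"GENE{i:05d}" for i in range(n)])

    classes = _assign_classes(n, effects, rng)
    is_null = classes == "null"
    is_bio = classes == "secreted_biomarker"
    is_anti = classes == "antiregulated"

    # True RNA effects (log2 per unit severity). Planted biomarkers get
    # positive sign (positive fibrosis correlation); other non-null genes
    # are up or down at random. Magnitudes vary around effect_size_log2.
    beta = np.zeros(n)
    nonnull = ~is_null
    mag = effects.effect_size_log2 * rng.uniform(0.5, 1.5, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    sign[is_bio] = 1.0
    beta[nonnull] = (mag * sign)[nonnull]

    # Protein effects: coupled to RNA effects at the configured correlation.
    # Orthogonal noise is confined to non-null genes (nulls stay null in
    # every matrix). Within the non-null set the noise is residualized
    # against the RNA effect vector and rescaled so the realized sample
    # correlation over all features equals the coupling parameter exactly
    # (when the anti-regulated class is empty), not merely in expectation.
    c = effects.rna_protein_coupling
    eps = np.zeros(n)
    if beta.std() > 0 and nonnull.sum() >= 3 and c < 1.0:
        raw_eps = rng.normal(0.0, 1.0, size=int(nonnull.sum()))
        b_nn = beta[nonnull]
        design_mat = np.column_stack([np.ones_like(b_nn), b_nn])
        coef, *_ = np.linalg.lstsq(design_mat, raw_eps, rcond=None)
        resid = raw_eps - design_mat @ coef  # sum resid = 0, resid . beta = 0
        e_full = np.zeros(n)
        e_full[nonnull] = resid
        scale = np.sqrt(1.0 - c * c) * beta.std() / e_full.std()
        eps = scale * e_full
    coupled = beta.copy()
    coupled[is_anti] = -coupled[is_anti]
    beta_prot = c * coupled + eps
    # Keep anti-regulated genes genuinely anti-regulated at the protein
    # level: their protein effect must oppose the RNA sign.
    flip = is_anti & (np.sign(beta_prot) == np.sign(beta)) & (beta != 0)
    beta_prot[flip] = -beta_prot[flip]

    # --- samples -------------------------------------------------------------
    rows = []
    for group in design.groups:
        for week in design.weeks:
            for a in range(1, design.animals_per_group + 1):
                rows.append((f"{group}_w{week:02d}_a{a:02d}", group, week, a))
    samp = pd.DataFrame(rows, columns=["sample_id", "group", "week", "animal"])
    samp = samp.set_index("sample_id")
    severity = _severity(
        design,
        samp["week"].to_numpy(float),
        samp["group"].to_numpy(),
        rng,
        effects.severity_noise_sd,
    )
    fib_seed = int(rng.integers(0, 2**31 - 1))
    samp["fibrosis_score"] = fibrosis_from_severity(
        severity,
        effects.fibrosis_noise_sd,
        fib_seed,
        slope=float(effects.fibrosis_max),
        max_score=effects.fibrosis_max,
    )
    # Proteomics batches: final-week animals split round-robin within each
    # group so runs stay balanced across arms; other samples inherit batch 1.
    last_week = max(design.weeks)
    samp["batch"] = 1
    lw = samp["week"] == last_week
    samp.loc[lw, "batch"] = (samp.loc[lw, "animal"] - 1) % design.batches + 1
    annotation = SampleAnnotation(
        samp[["group", "week", "batch", "fibrosis_score"]].copy()
    )

    # --- liver RNA: negative binomial counts ---------------------------------
    base_rna = rng.normal(effects.rna_base_log2_mean, effects.rna_base_log2_sd, size=n)
    log2_mu = base_rna[:, None] + beta[:, None] * severity[None, :]
    mu = np.power(2.0, log2_mu)
    disp = effects.rna_dispersion
    if disp > 0:
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)
    liver_rna = OmicsMatrix(
        pd.DataFrame(counts, index=genes, columns=samp.index),
        scale="counts",
        kind="liver_rna",
    )

    # --- liver protein: log-normal intensities at the final week --------------
    prot_samples = samp.index[lw]
    sev_lw = severity[lw.to_numpy()]
    batch_lw = samp.loc[lw, "batch"].to_numpy()
    # Liver protein panel: all biomarker and anti-regulated genes, then the
    # highest-expressed remainder (abundance-driven detectability).
    must = np.where(is_bio | is_anti)[0]
    by_abundance = np.argsort(-base_rna)
    rest = by_abundance[~np.isin(by_abundance, must)]
    lp_idx = np.sort(
        np.concatenate([must, rest[: effects.n_features_liver_protein - len(must)]])
    )
    base_lp = rng.normal(
        effects.protein_base_log2_mean, effects.protein_base_log2_sd, size=len(lp_idx)
    )
    lp_log2 = (
        base_lp[:, None]
        + beta_prot[lp_idx][:, None] * sev_lw[None, :]
        + rng.normal(0.0, effects.protein_noise_sd, size=(len(lp_idx), len(prot_samples)))
    )
    batch_offsets = rng.normal(
        0.0, effects.batch_effect_sd, size=(len(lp_idx), design.batches)
    )
    lp_log2 += batch_offsets[:, batch_lw - 1]
    lp_log2 = _left_censor(lp_log2, effects.missing_rate, effects.censoring_steepness, rng)
    liver_protein = OmicsMatrix(
        pd.DataFrame(np.power(2.0, lp_log2), index=genes[lp_idx], columns=prot_samples),
        scale="linear",
        kind="liver_protein",
    )

    # --- plasma protein --------------------------------------------------------
    bio_in_lp = np.where(is_bio[lp_idx])[0]
    other_lp = np.setdiff1d(np.arange(len(lp_idx)), bio_in_lp)
    n_other = effects.n_features_plasma - len(bio_in_lp)
    pick = rng.choice(other_lp, size=n_other, replace=False)
    pp_pos = np.sort(np.concatenate([bio_in_lp, pick]))  # positions within lp_idx
    pp_idx = lp_idx[pp_pos]
    base_pp = rng.normal(
        effects.protein_base_log2_mean - 2.0, effects.protein_base_log2_sd, size=len(pp_idx)
    )
    beta_plasma = np.zeros(len(pp_idx))
    bio_mask_pp = is_bio[pp_idx]
    beta_plasma[bio_mask_pp] = effects.plasma_attenuation * beta_prot[pp_idx][bio_mask_pp]
    pp_log2 = (
        base_pp[:, None]
        + beta_plasma[:, None] * sev_lw[None, :]
        + rng.normal(0.0, effects.protein_noise_sd, size=(len(pp_idx), len(prot_samples)))
    )
    pp_batch_offsets = rng.normal(
        0.0, effects.batch_effect_sd, size=(len(pp_idx), design.batches)
    )
    pp_log2 += pp_batch_offsets[:, batch_lw - 1]
    pp_log2 = _left_censor(pp_log2, effects.missing_rate, effects.censoring_steepness, rng)
    plasma_protein = OmicsMatrix(
        pd.DataFrame(np.power(2.0, pp_log2), index=genes[pp_idx], columns=prot_samples),
        scale="linear",
        kind="plasma_protein",
    )

    # --- id map and truth ------------------------------------------------------
    has_ortholog = rng.random(n) < effects.ortholog_fraction
    has_ortholog[is_bio] = True  # planted biomarkers are mappable by definition
    secreted = rng.random(n) < effects.secreted_background_fraction
    secreted[is_bio] = True
    id_map = pd.DataFrame(
        {
            "rat_protein_id": [f"RPROT{i:05d}" for i in range(n)],
            "rat_gene_id": genes,
            "human_gene_id": [
                f"HGENE{i:05d}" if has_ortholog[i] else "" for i in range(n)
            ],
            "human_protein_id": [
                f"HPROT{i:05d}" if has_ortholog[i] else "" for i in range(n)
            ],
            "secreted": secreted.astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "feature_id": genes,
            "class": classes,
            "true_effect_log2": beta,
            "true_protein_effect_log2": beta_prot,
            "fibrosis_corr_sign": np.sign(beta).astype(int),
        }
    )

    return SyntheticStudy(
        liver_rna=liver_rna,
        liver_protein=liver_protein,
        plasma_protein=plasma_protein,
        annotation=annotation,
        id_map=id_map,
        truth=truth,
        design=design,
        effects=effects,
    )


def generate_prior_evidence(
    features: list[str] | np.ndarray,
    truth: pd.DataFrame,
    seed: int,
    evidence_fraction: float = 0.8,
) -> pd.DataFrame:
    """Generate a prior-evidence table (disease-association score,
    publication counts, expected counts, patent and database flags).

    A fraction ``evidence_fraction`` of true secreted biomarkers receives
    elevated evidence (higher association score, more publications, likely
    flags); all other genes draw from background distributions independent
    of their truth class. With ``evidence_fraction=0`` the table is fully
    decoupled from the data, so prior-knowledge-only and data-driven
    rankings can disagree.
    """
    features = np.asarray(features)
    if len(features) == 0:
        raise ValueError("features must be non-empty")
    known = set(truth["feature_id"])
    unknown = [f for f in features if f not in known]
    if unknown:
        raise KeyError(f"unknown feature ids: {unknown[:5]}")
    rng = np.random.default_rng(seed)
    cls = truth.set_index("feature_id").loc[features, "class"].to_numpy()
    elevated = (cls == "secreted_biomarker") & (rng.random(len(features)) < evidence_fraction)

    assoc = rng.beta(1.2, 6.0, size=len(features))
    assoc[elevated] = rng.beta(5.0, 2.0, size=int(elevated.sum()))
    # Long-tailed publication counts (mostly 0, occasional heavy hitters).
    pubs = rng.negative_binomial(0.4, 0.08, size=len(features)).astype(float)
    pubs[elevated] += rng.poisson(30.0, size=int(elevated.sum()))
    expected = np.exp(rng.normal(0.5, 0.75, size=len(features)))
    patent = (rng.random(len(features)) < 0.03).astype(int)
    database = (rng.random(len(features)) < 0.05).astype(int)
    patent[elevated] = (rng.random(int(elevated.sum())) < 0.6).astype(int)
    database[elevated] = (rng.random(int(elevated.sum())) < 0.6).astype(int)

    return pd.DataFrame(
        {
            "gene_id": features,
            "fibrosis_association": assoc,
            "publication_count": pubs,
            "expected_count": expected,
            "patent_flag": patent,
            "database_flag": database,
        }
    )
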
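"""Differential statistics on the diseased-vs-control contrast.

Pooled-variance Student t per protein, BH adjustment, SAM-style permutation
FDR, and regulation calls at padj < 0.01 with |log2FC| >= 1. The dge_score
(-log10 padj x |log2FC|) is the subscore the ranking consumes.
"""

from fibromark import (
    EffectConfig, StudyDesign, call_regulated, dge_score, differential_stats,
    generate_study, permutation_fdr, prep_protein_matrix,
)

study = generate_study(StudyDesign(seed=3), EffectConfig(
    n_features_rna=800, n_features_liver_protein=600, n_features_plasma=150))
m = prep_protein_matrix(study.liver_protein, study.annotation, seed=5)

contrast = ("CSAA", "CDAA")
de = differential_stats(m, study.annotation, contrast)
q = permutation_fdr(m, study.annotation, contrast, n_perm=1000, seed=11)
de = de.merge(q[["feature_id", "q"]], on="feature_id")
de["call"] = call_regulated(de)
de["dge_score"] = dge_score(de["padj"].clip(lower=1e-300), de["log2fc"])

print(de["call"].value_counts().to_string())
print("\nproteins at permutation FDR q < 0.01:", (de["q"] < 0.01).sum())
top = de.nlargest(5, "dge_score")[["feature_id", "log2fc", "padj", "q", "dge_score"]]
print("\ntop 5 by dge_score (large = strong, significant regulation):")
print(top.to_string(index=False))
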
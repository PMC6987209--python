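"""Sensitivity of the ranking to the dimension weights.

Scores every candidate under six weight settings and reports each
candidate's best rank. With evidence decoupled from the data
(evidence_fraction = 0), the prior-knowledge-only ranking promotes
different candidates than the data-driven settings — the reason purely
literature-based shortlists can mislead.
"""

from fibromark.benchmarks import prior_vs_data_divergence
from fibromark.ranker import load_weight_settings

print("packaged weight settings (plasma/liver/prior/secreted):")
for s in load_weight_settings():
    print(f"  {s.name:24s} {s.plasma:.1f}/{s.liver:.1f}/{s.prior:.1f}/{s.secreted:.1f}")

res = prior_vs_data_divergence(n_seeds=3, top_k=10, seed=101)
print("\nwith prior evidence decoupled from the data:")
print(f"  top-10 overlap, prior-knowledge vs default ranking: "
      f"{res['mean_prior_overlap']:.1f} of 10")
print(f"  mean top-10 overlap among data-driven rankings:     "
      f"{res['mean_data_overlap']:.1f} of 10")
print("a large gap means the data, not the literature, drives the shortlist")
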
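"""Run the interaction-prediction pipeline and its feature ablation.

Generates a modest synthetic dataset whose positive pairs all join proteins
of the same network community, then cross-validates the Random Forest twice:
once on network (DeepWalk) features and once on sequence (auto-covariance)
features.  Only the network carries planted signal here, so the first run
should score well above chance and the second should sit at it — the
ablation with a known answer.  The full-scale combined-feature run is what
`scripts/acceptance.py` reproduces.
"""

from multippi import RFConfig, SynthConfig, WalkConfig, generate
from multippi.pipeline import run_pipeline

config = SynthConfig(n_proteins=120, n_mirna=40, n_lncrna=40, n_drug=40,
                     n_disease=40, n_positive_pairs=500, seed=21)
bundle = generate(config)
print(f"fixture: {config.n_proteins} proteins, "
      f"{config.n_positive_pairs} planted positive pairs, "
      f"{config.n_blocks} network communities")

for mode in ("network_only", "sequence_only"):
    result = run_pipeline(bundle, mode=mode, walk_config=WalkConfig(seed=21),
                          rf=RFConfig(seed=21), seed=21)
    m, s = result.cv.mean, result.cv.sd
    print(f"{mode:>14} ({result.n_features:3d} features/pair): "
          f"auc={m['auc']:.3f}+/-{s['auc']:.3f}  "
          f"acc={m['acc']:.3f}+/-{s['acc']:.3f}  "
          f"aupr={m['aupr']:.3f}+/-{s['aupr']:.3f}")

print("\nPositives were planted through community co-membership, which the")
print("network embedding recovers; the sequences carry no signal in this")
print("fixture, so sequence-only cross-validation stays at chance.")
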
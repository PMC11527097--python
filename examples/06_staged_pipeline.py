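"""Run the full staged pipeline: route each sample through as few omics
modalities as its prediction uncertainty allows.

Stage 1 classifies from the first modality alone; samples whose ensemble
uncertainty exceeds t1 escalate to the bi-view model, and those still above
t2 get the tri-view model.  (t1, t2) are chosen by exhaustive grid search on
a validation subset of the training samples.
"""

import sguq

matrices, labels, _ = sguq.make_routing_fixture(0, n_samples=150, n_features=40)
split = sguq.make_stratified_split(labels, test_fraction=0.3, seed=0)

config = sguq.PipelineConfig(
    K=2.0,
    gcn=sguq.GCNConfig(hidden_units=(32, 32, 16), mlp_hidden=16,
                       pretrain_epochs=200, train_epochs=200),
    fusion_epochs=200,
    T=5,
    base_seed=0,
    stage_order=[["mRNA"], ["mRNA", "meth"], ["mRNA", "meth", "miRNA"]],
)
result = sguq.run_staged_pipeline(matrices, labels, split, config)

print("stage order:", " -> ".join("+".join(s) for s in result.stage_order))
print(f"selected thresholds: t1={result.thresholds[0]:.4f}  "
      f"t2={result.thresholds[1]:.4f}")
f1, f2, f3 = result.test_fractions
print(f"test samples finalized at stage 1/2/3: {f1:.2%} / {f2:.2%} / {f3:.2%}")
m = result.test_metrics
print(f"staged test ACC={m.acc:.4f}  F1={m.f1:.4f}  AUC={m.auc:.4f}")
print(result.predictions.head().to_string(index=False))
# Most samples are finalized with a single modality; only the uncertain
# minority pays for additional omics measurements.
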
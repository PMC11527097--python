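# sguq — staged multi-omics classification with uncertainty quantification

Collecting every omics layer (transcriptome, methylome, miRNA, ...) for every
patient is expensive, and for many patients it is unnecessary: a single cheap
assay already supports a confident diagnosis.  `sguq` implements a staged
classifier for binary case/control prediction from multi-omics data that
starts from one modality and escalates a sample to additional modalities
*only when its prediction is uncertain*.

The method combines four pieces:

1. **Patient-similarity GCNs.** For each omics matrix `X⁽ᵏ⁾ ∈ ℝ^{n×d_k}` a
   sample-similarity graph is built from cosine similarity
   `s(x_i, x_j) = x_i·x_j / (‖x_i‖‖x_j‖)`, keeping edges with `s ≥ ε` where
   `ε` is derived from `K`, the target average number of connections per node
   (self-connection included).  A graph convolutional network propagates
   features through the symmetrically normalized adjacency,
   `H⁽ˡ⁺¹⁾ = σ(Ã H⁽ˡ⁾ W⁽ˡ⁾)` with `Ã = D^{-1/2}(A + I)D^{-1/2}`, and a
   two-layer perceptron head emits per-class probabilities.  With `K = 1` the
   graph holds self-connections only and the model degenerates to a plain
   fully connected network.
2. **Label-space fusion (VCDN).** For two or three views, the outer product
   of the per-view class distributions forms a cross-omics tensor
   `C_i = ŷ⁽¹⁾ ⊗ ŷ⁽²⁾ (⊗ ŷ⁽³⁾)`; a small fully connected network on the
   flattened tensor learns cross-view label correlations.  Training
   alternates view-classifier steps (fusion frozen) with fusion steps (views
   frozen) after per-view pretraining.
3. **T-trial ensemble uncertainty.** Each stage model is retrained `T` times
   under different seeds; per sample, the mean case probability `p̄_i` is the
   prediction, the sample standard deviation `σ_i` (denominator `T−1`) is the
   uncertainty, and the label is a majority vote across trials.
4. **Staged routing.** A sample is finalized at stage 1 if `σ₁ ≤ t1`, at
   stage 2 if `σ₂ ≤ t2`, else at stage 3.  The thresholds `(t1, t2)` are
   selected by exhaustive grid search (100 evenly spaced values spanning each
   stage's observed uncertainty range) maximizing routed accuracy on a
   held-out validation subset.

## Worked example

`examples/06_staged_pipeline.py` generates a 150-sample tri-omics dataset in
which 30% of samples carry a tenfold-attenuated first-view signal, then runs
the full staged pipeline:

```
stage order: mRNA -> mRNA+meth -> mRNA+meth+miRNA
selected thresholds: t1=0.0691  t2=0.1120
test samples finalized at stage 1/2/3: 73.33% / 26.67% / 0.00%
staged test ACC=0.9556  F1=0.9524  AUC=0.9960
sample_id  stage   p_mean    sigma  label
    S0005      2 0.900311 0.015989      1
    S0009      1 0.998955 0.000684      1
```

Reading: about three quarters of the test samples are confidently resolved
from the first modality alone (their ensemble spread `sigma` is below `t1`);
the uncertain quarter — dominated by the planted hard sub-population — is
escalated to the bi-view model, and the staged accuracy matches what the
full tri-view model would deliver while measuring far fewer modalities.
The other scripts in `examples/` walk through each capability separately
(generator, similarity graph, single-view GCN, fusion, ensembles).

A thin CLI wraps the same pipeline:

```bash
sguq simulate --seed 0 --out data/
sguq run --config config.yaml --data data/ --out predictions.csv
sguq evaluate --predictions predictions.csv --labels data/labels.csv
```

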
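# encanet

Attention-based blood-cell detection for microscopy smears, with exact
model-complexity audits and a synthetic data generator.

Automated counting of platelets, red and white blood cells in smear images
is a routine but labor-intensive step in hematological diagnosis. `encanet`
implements a lightweight single-level detector for this task: an
EfficientNet feature extractor, a fixed 512-channel projection, a pluggable
**attention encoder**, and a dual-head depthwise-separable decoder (K=3
classes, A=5 anchors per 13×13 grid cell at 416×416 input).

The scientific core is the encoder. Where the base detector family spends
3.48 M parameters on a dilated residual encoder, this design replaces it
with a channel-attention gate costing at most 0.04 M. Given per-channel
spatial mean `z_c` and max `m_c`, the **enhanced channel attention module
(ECAM)** computes

    z′_c = σ(m_c) · z_c            (max-gated descriptor)
    P    = σ(W₂ δ(W₁ z′ + b₁) + b₂)  (bottleneck MLP, reduction r)

so the max-pool branch informs the gate through a single sigmoid instead of
a second MLP evaluation (CAM's `σ(MLP(z) + MLP(m))`). **ECBAM** follows
ECAM with CBAM's spatial attention `σ(f^{k×k}([mean_c; max_c]))`. SE, ECA,
CAM, SAM and CBAM baselines are included, all as pure, oracle-checkable
operators that also run inside the trainable network.

The network layer itself (convolutions, batch norm, autograd, SGD) is
implemented on numpy with numba-compiled inner loops, so everything runs
and trains on a plain CPU with no deep-learning framework.

## Worked example: auditing model complexity

The paper-facing capability that reproduces exactly at desk scale is the
parameter audit. `examples/audit_model_complexity.py` builds every variant
and counts trainable arrays:

```
configuration                          params  millions
b0 baseline (no encoder)            6,461,604      6.46
b1 baseline (no encoder)            8,967,240      8.97
b2 baseline (no encoder)           10,220,586     10.22
b3 baseline (no encoder)           13,281,360     13.28
b0 + sam                            6,461,703      6.46
b0 + eca                            6,461,609      6.46
b0 + se                             6,494,916      6.49
b0 + cam                            6,494,916      6.49
b0 + ecam                           6,494,916      6.49
b0 + cbam                           6,495,015       6.5
b0 + ecbam                          6,495,015       6.5
b0 + dilated                        9,945,764      9.95
```

Reading: swapping the 3.48 M dilated encoder for ECBAM saves 3.45 M
parameters net; ECAM itself adds 33,312 parameters (the bottleneck MLP at
C=512, r=16) and the spatial stage 99 more — the 6.46 → 6.5 M step printed
in the complexity tables.

Other examples: `attention_gates.py` (the ECAM math on a toy feature map),
`synthetic_dataset.py` (COCO-annotated synthetic smears and the 7:2:1
split), `train_and_evaluate.py` (a short end-to-end training run with COCO
metrics), `visualize_attention.py` (channel-mean heatmaps before/after the
encoder).

A thin CLI wraps the same API:

```bash
encanet generate --n 20 --seed 0 --out smears/
encanet audit --backbone b0 --encoder ecbam
encanet train --data smears/annotations.json --encoder ecbam --seed 0
encanet visualize --image smears/scene_000000.png --tap after_encoder
```

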
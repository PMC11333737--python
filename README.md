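# hrea — home rehabilitation exercise assessment from wearable IMU sensors

Stroke survivors do most of their rehabilitation exercises at home, where no
therapist can grade the quality of each movement. `hrea` implements an
automatic assessment pipeline for that setting: two 9-axis inertial sensors
(forearm **#S1**, upper arm **#S2**, 30 Hz) record an upper-limb exercise
drawn from the Fugl-Meyer Assessment (FMA), and the system returns the
clinical item score — 0 (movement cannot be performed), 1 (performed partly)
or 2 (performed normally).

The pipeline has three stages:

1. **Attitude estimation.** A linear Kalman filter tracks the state
   x = [φ, θ, ψ, φ̇, θ̇, ψ̇]ᵀ (roll/pitch/yaw and their rates) per sensor.
   Raw 9-axis readings are reduced to a 6-dim pseudo-measurement — roll/pitch
   from the accelerometer gravity direction, yaw from the tilt-compensated
   magnetometer heading, rates from the gyroscope — so the observation model
   is exactly linear (H = I) and the classic recursion
   x̂ₖ = F x̂ₖ₋₁, P = F P Fᵀ + Q, K = P Hᵀ(H P Hᵀ + R)⁻¹ applies unchanged.
2. **Per-channel scoring.** Each sensor's attitude trace is min-max
   normalized with fixed bounds (±180° → (−1, 1)), resampled to 128 samples,
   and scored by a lightweight 1D-CNN:
   `[Conv1D(k=10) → ReLU → Dropout(0.5) → MaxPool(2)] × 2 → Flatten →
   Dense(6) → softmax`, trained with categorical cross-entropy
   `L = −Σᵢ yᵢ log ŷᵢ`. The six-class head (scores 0–2 plus three reserved
   classes) is shape-compatible with a model pretrained on the six-activity
   UCI-HAR benchmark, so convolution blocks transfer.
3. **Decision fusion (MCDF).** The two channels' posteriors p(ĉᵢ|xⱼ) are
   combined by one of four rules — **max** (largest single posterior),
   **sum** (largest posterior sum), **D-S** (Dempster–Shafer: normalized
   posterior product, c = argmaxᵢ (1/K) p(ĉᵢ|x₁)p(ĉᵢ|x₂) with
   K = 1 − Σᵢ p(ĉᵢ|x₁)p(ĉᵢ|x₂)) or **Naive Bayes**
   (c = argmaxᵢ p(ĉᵢ) ∏ⱼ p(ĉᵢ|xⱼ)). A feature-fusion comparator (**MCFF**)
   that concatenates the two channels' convolutional features before a shared
   head is included for comparison, as is a synthetic scored-action generator
   so the whole pipeline runs and is tested fully offline.

The neural layers (1D convolution, pooling, dropout, dense, Adam) are
implemented in NumPy with explicit backpropagation — the windows are tiny
(128×3), so training two channel models takes seconds on one CPU and every
run is bit-reproducible from its seed.

## Worked example

```python
import numpy as np
from hrea import (BackboneConfig, build_backbone, train_backbone,
                  generate_dataset, split_dataset, make_window,
                  estimate_priors, mcdf_predict, evaluate_model,
                  predict_proba)

recs = generate_dataset(10, seed=42)                  # 150 scored recordings
labels = [r.score_label for r in recs]
train, val, test = split_dataset(recs, labels, (0.6, 0.2, 0.2), seed=1)

models = {}
for ch, seed in (("S1", 11), ("S2", 12)):
    model = build_backbone(BackboneConfig(seed=seed))  # lr 1e-3, 120 epochs
    model, _ = train_backbone(model,
                              [make_window(r, ch) for r in train],
                              [make_window(r, ch) for r in val])
    models[ch] = model

priors = estimate_priors([r.score_label for r in train])
report = evaluate_model(
    lambda r: mcdf_predict(r, models["S1"], models["S2"], "nb",
                           priors).predicted_class,
    test, [r.score_label for r in test])
print(report.table())
```

Output (per-class then weighted precision/recall/F1 in percent over the 30
held-out recordings; classes 3–5 are the reserved empty labels and carry zero
support):

```
   class    P (%)    R (%)   F1 (%)      N
       0   100.00   100.00   100.00     10
       1    83.33   100.00    90.91     10
       2   100.00    80.00    88.89     10
       3     0.00     0.00     0.00      0
       4     0.00     0.00     0.00      0
       5     0.00     0.00     0.00      0
weighted    94.44    93.33    93.27     30
```

Score 0 movements (tiny amplitude, tremor) are perfectly separated; the
occasional confusion is between partial (1) and normal (2) movements, and
fusing the two sensors lifts the weighted F1 above either single channel
(here S1 alone reaches 87.0 %, S2 alone 90.0 %).

The same pipeline is available from the shell:

```bash
hrea simulate   --config run.yaml --out data/
hrea train-mcdf --config run.yaml --out models/
hrea evaluate   --config run.yaml --models models/
hrea assess     --config run.yaml --models models/ --recording data/rec_0007.csv
```

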
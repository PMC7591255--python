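# v1contrast

Contrast and direction tuning analysis of VIP, SST and pyramidal neuron
populations in mouse primary visual cortex, with a four-population
stabilized supralinear network (SSN) model of the underlying circuit.

VIP interneurons disinhibit pyramidal cells by suppressing SST
interneurons.  This package implements, end to end on synthetic data, the
computational toolkit for studying how that VIP–SST motif shapes contrast
coding in V1:

* **Trial statistics for calcium-event responses** to drifting gratings
  (8 directions × 6 contrasts, 5–80%, interleaved blanks): a bootstrapped
  χ² responsiveness test, blank-subtracted condition significance and
  suppressed-by-contrast classification, selectivity metrics
  (gOSI = |Σ R e^{i2θ}|/Σ R, DSI = (R_pref − R_null)/(R_pref + R_null),
  cCoM = exp(Σ R ln c / Σ R)), population direction-bias vector sums with
  uniform-null confidence radii, and locomotion-conditioned tuning
  surfaces (running ⇔ speed ≥ 1 cm/s).
* **Contrast-response model selection**: rising / falling / band-pass
  sigmoids (slope fixed at 10) compared by AIC = 2k − 2 ln L with either a
  trial-shuffle likelihood or a closed-form normal likelihood.
* **A 126-term L1-regularized exponential-link GLM** of trial-wise
  population responses (blank, run, direction, contrast and all their
  interactions; R̂ = e^{w·a + k}), fit by IRLS with proximal
  soft-thresholding and leave-one-session-out cross-validation of λ.
* **The SSN ring model**: 184 pyramidal + 40 PV + 15 SST + 15 VIP rate
  units with rectified-quadratic transfer r_ss(I) = k I², wrapped-Gaussian
  connectivity on a 180° ring, VIP→SST as VIP's only output.  Steady
  states, current decomposition, gain analysis (intact vs VIP→SST-ablated),
  analytic E-E linear stability J(x, n) = g W Ĝ(n) with the ISN criterion
  J00 − 1 > 0, and parameter sweeps (VIP→SST strength; PV fraction of
  inhibition).
* **A synthetic-data generator** that emulates the experimental design
  with known per-neuron ground truth (contrast class, preferred direction,
  locomotion gain, zero-inflated gamma trial noise), so every estimator is
  validated by recovery.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
import numpy as np
from v1contrast import synth, tuning, crf, ssn

# 30 VIP-like neurons, 15 repeats x 48 grating conditions + 30 blanks
stim, truth, responses = synth.generate_dataset("vip", 30, n_reps=15, seed=1)

chi2, p = tuning.chisq_responsiveness(responses[0], stim, n_shuffles=2000, seed=0)
print(f"cell 0: chi2 = {chi2:.2f}, p = {p:.4g}")

metrics = tuning.compute_cell_metrics(responses[:5], stim, seed=0)
print(metrics[["p_value", "preferred_direction", "gOSI", "DSI", "cCoM"]].round(3))

# circuit: stability regime along the drive axis
net = ssn.SSNetwork()
print(ssn.stability_curve(net, [0, 20, 60]).to_string(index=False))
```

Output:

```
cell 0: chi2 = 22.47, p = 0.0004998
   p_value  preferred_direction   gOSI    DSI   cCoM
0      0.0                  0.0  0.399  0.979  0.113
1      0.0                  0.0  0.529  0.995  0.100
2      0.0                315.0  0.216  0.939  0.105
3      0.0                 45.0  0.251  0.923  0.111
4      0.0                  0.0  0.402  0.996  0.111
 strength  ee_stability  regime    e_rate
      0.0     -0.904673 non_isn  0.157763
     20.0      0.674735     isn 15.195391
     60.0      2.311260     isn 44.206698
```

Cell 0 is strongly responsive (p < 0.01), prefers front-to-back motion
(0°) at low contrast (cCoM ≈ 0.1, i.e. ~10% contrast) and is highly
direction selective — the VIP phenotype the generator planted.  The
circuit sits in the non-inhibitory-stabilized regime at rest
(EE stability −0.90) and crosses into the ISN regime as drive grows.

A command-line interface wraps the same stages:

```bash
v1contrast simulate-data --seed 1 --out outputs
v1contrast tuning --out outputs
v1contrast ssn-stability --out outputs
```

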
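# Methods

This note documents the models, statistics and numerical choices behind
`v1contrast`, and what the synthetic-data studies can and cannot show.

## Experimental design being emulated

All statistics operate on trial tables from a drifting-grating protocol:
8 directions (45° steps, 0° = horizontal front-to-back motion) × 6
contrasts (5, 10, 20, 40, 60, 80%), each condition repeated 15–24 times,
plus 30 randomly interleaved blank (mean-luminance) trials per session.
The response of a neuron on a trial is the mean calcium-event magnitude
per second (arbitrary units, ≥ 0), and each trial carries the animal's
mean running speed; trials with speed ≥ 1 cm/s count as running.

## Synthetic data generator (`synth`)

Per-neuron ground truth is a multiplicative mean model

    mu(trial) = baseline · run_gain^run · D(direction) · C(contrast),

with `D` a von-Mises kernel on 360° (peak 1 at the preferred direction,
concentration κ per neuron) and `C` a sigmoidal contrast kernel expressed
relative to the blank baseline (`C ≡ 1` for blanks).  `C` uses the same
three families the fitting stage assumes — rising, falling, and
rising×falling product, slope fixed at 10 with contrast as a fraction — so
that class recovery is well-posed.  "Suppressed" neurons use a falling
kernel whose floor is below 1, putting their high-contrast mean below the
blank baseline by construction.

Trial noise is zero-inflated gamma: with probability `zero_prob` (default
0.15) the trial is eventless, otherwise gamma with shape 2 and scale chosen
so the overall expectation equals `mu` exactly.  The defaults give a
coefficient of variation ≈ 0.87, which we consider realistic for sparse
event-magnitude data; the trial-level statistics only assume nonnegative,
overdispersed, non-normal responses, and the family is configurable.  The
noise model is a stand-in: real event magnitudes have temporal structure,
neuron-to-neuron correlations, and slow state drifts that the generator
does not emulate, so passing recovery tests demonstrates estimator
correctness under the assumed trial-exchangeable model, not robustness to
those real-data features.

Population presets encode the class phenomenology used throughout:
`vip` (95% low-pass / 5% suppressed, preferred directions von-Mises
concentrated at 0°, high baseline, run gain 1.5–2.5), `sst` (all
high-pass, weak direction selectivity, tiled preferences), `cux2`
(low/high-pass mixture with tiled, selective preferences), and `flat`
(exchangeable null cells with run gain 1, used for calibration).

## Responsiveness test (`tuning.chisq_responsiveness`)

The statistic is `chi2 = Σ_i (E − O_i)² / E` over the 49 conditions
(48 gratings + blank), where `O_i` is the condition's mean response and `E`
the grand per-presentation mean.  The null distribution resamples the
cell's responses across all presentations *with replacement* (a bootstrap,
as described by the source procedure; a permutation variant is available)
and the p-value uses +1 smoothing: `p = (1 + #{null ≥ obs}) / (1 + n)`.
Default 200 000 resamples; the calibration studies use 2 000, which already
gives a type-I error indistinguishable from the nominal 1% on 2 000 null
cells.  An all-zero cell has `E = 0`; the statistic is defined as 0 with
p = 1.

## Condition significance and suppression-by-contrast

For each condition the blank-subtracted mean `R̄ = O_i − R_blank` is ranked
within a bootstrap null built from `n_boot` draws of (mean of m_i
resampled responses − mean of m_blank resampled responses); ties use
midranks so a constant cell sits at percentile 0.5.  Because the null
depends only on the sample sizes, one null per distinct `m` is shared
across conditions.

Two published definitions of "suppressed by contrast" coexist and both are
implemented, neither privileged: (a) *peak_direction* — the percentile of
the 80%-contrast condition at the cell's peak direction is < 0.05; (b)
*all_directions* — the percentile of the pooled all-direction 80%-contrast
response is below a family-wise corrected threshold.  The family is the six
contrasts; Bonferroni is the default correction (Šidák available) since no
procedure is named in the source.

## Selectivity metrics

* gOSI: `|Σ R(θ) e^{i2θ}| / Σ R(θ)` — angles doubled by default, the
  standard global orientation selectivity index.  The printed formula
  without doubling conflicts with "orientation" selectivity (it scores
  opposite directions as different orientations); it is available via
  `convention="literal"`.
* DSI: `(R_pref − R_null) / (R_pref + R_null)`, null = direction opposite
  the peak.
* cCoM: `exp(Σ R_c ln c / Σ R_c)`, the log-scaled center of mass of the
  contrast response function, in [0.05, 0.8] for nonzero responses.
* Preferred direction/contrast: argmax of condition means, ties broken
  toward the lowest index (deterministic).
* Population bias: `r_bias` is the normalized resultant of preferred
  directions, `θ_bias` its two-argument arctangent.  The null confidence
  radius is the corrected (1 − α) quantile of `r_bias` for uniform draws
  from the eight stimulus directions; the correction for testing at six
  contrasts is Šidák by default.

All-zero inputs return NaN markers rather than raising.

## Locomotion conditioning

A (cell, condition) enters run/stationary averages only with ≥ 4 running
and ≥ 4 stationary presentations; an experiment enters population
summaries only with ≥ 3 responsive neurons.  Population surfaces are
blank-subtracted within state before averaging across cells (mean ± SEM).

## Contrast-response model selection (`crf`)

Trial responses at the preferred direction are fit by bounded least
squares (multi-start over a half-point grid; the band-pass product starts
from all ordered c50 pairs) to the three sigmoid families (3 free
parameters for single sigmoids, 4 for the product; slope fixed at 10), and
compared by `AIC = 2k − 2 ln L`.

Two likelihoods are provided.  The default follows the source procedure:
shuffle responses across trials 1 000 times and take the likelihood as the
fraction of shuffles whose SS against the model predictions exceeds the
observed SS, smoothed as `(count + 1)/(n + 1)`.  This bootstrap likelihood
has a structural property worth stating plainly: the shuffle SS always
contains the *full* tuning variance, so any model that fits at least as
well as a constant gets likelihood ≈ 1, the log-likelihoods of competing
decent fits collapse toward 0, and AIC reduces to the parameter penalty —
the 4-parameter band-pass model can then never be selected.  (This is
consistent with band-pass classifications being vanishingly rare in
practice.)  The closed-form normal likelihood
`ln L = −SS / (2σ_R²)` (σ_R² the variance of all the cell's responses) is
therefore used for the class-recovery studies; a dedicated test documents
the saturation.

Ties in AIC break toward fewer parameters, then toward the rising model.

## Population GLM (`glm`)

126 binary predictors in a fixed, documented order — blank, run, 8
directions, 6 contrasts, run×direction (8), run×contrast (6),
direction×contrast (48, direction-major), run×direction×contrast (48) —
plus an unpenalized constant.  The predicted trial response is
`exp(w·a + k)` and the default objective is the printed one,
`SSE + λ Σ|w|`; a Poisson-deviance objective is available behind a flag.

The solver is IRLS: each outer iteration builds the Gauss-Newton weighted
least-squares model of the data term, solves it with FISTA (an accelerated
proximal-gradient method whose proximal operator is the soft threshold;
the constant rides along unpenalized), and applies a step-halving line
search on the true objective, so the objective is non-increasing.
Convergence: max weight change < 1e-8, ≤ 500 outer iterations.  Because
only 98 distinct covariate patterns exist (2 blank×run + 96 grating
patterns), trials are pooled by pattern before solving — exact for both
objectives — which makes the solve cost independent of trial count.

That same count (98 patterns < 127 parameters) means individual weights
are *not identifiable* at λ = 0: any fit can only be assessed through its
predictions, its support and its signs.  Recovery studies therefore plant
sparse weight vectors and score sign agreement at the cross-validated λ
(leave-one-session-out; 16 log-spaced penalties from λ_max down; ties
toward the sparser penalty).

## SSN ring model (`ssn`)

Four populations on a ring spanning 180° of direction preference: 184
excitatory units (180 tiling the ring at 1° spacing plus 4 extra at 0°,
the measured front-to-back over-representation), 40 PV, 15 SST and 15 VIP
units, all interneurons at 0°.  Units are rate models with the rectified
quadratic transfer `r_ss(I) = k I²` for `I > 0` (k = 0.04), time constants
20 ms (10 ms for PV), spontaneous inputs 2 (10 for VIP), Euler integration
at Δt = 0.1 ms.

Connectivity follows the canonical superficial-V1 motif:
E→{E, PV, SST, VIP}, PV→{E, PV}, SST→{E, PV, VIP}, VIP→{SST} (VIP's only
output).  Each projection's strength falls off as a wrapped Gaussian of
preferred-direction difference — σ = 30° for E→E and E→VIP, σ = 100° for
everything else — normalized per postsynaptic cell so that the summed
weight equals the population-level coupling constant.  That normalization
makes the couplings independent of unit counts (pools of identical
interneurons collapse exactly), and gives the Fourier-domain stability
matrix the clean form `J(x, n) = g(x) · W · Ĝ(n)` with
`Ĝ(n) = exp(−2 (nπσ/L)²)` the normalized wrapped-Gaussian transform
(validated against a brute-force ring sum).

External drive (a monotone stand-in for contrast, arbitrary units 0–100)
reaches E units through a 30° kernel centered on the stimulus direction
(with a +5% multiplicative bias toward 0° units, representing the
direction bias of feed-forward input), and PV units untuned at 0.4× the
drive strength; SST and VIP receive none.  Stimulus directions from the
360° experiment map onto the ring modulo 180°.

### Calibration

Absolute coupling strengths are not anatomically constrained; the shipped
defaults are a documented calibration found by grid search plus 1-D
refinement (all values exposed in `Couplings`):

| projection | value | | projection | value |
|---|---|---|---|---|
| E→E | 0.6 | | PV→E | −0.7 |
| E→PV | 0.65 | | PV→PV | −0.8 |
| E→SST | 0.8 | | SST→E | −0.7 |
| E→VIP | 0.293 | | SST→PV | −0.2 |
| VIP→SST | −0.6 | | SST→VIP | −0.6 |

The PV share of inhibition onto E is 0.5.  The load-bearing structural
choice is that the PV loop alone is asymptotically insufficient
(`W_{E→PV}·|W_{PV→E}| = 0.455 < W_{E→E}·|W_{PV→PV}| = 0.48`): at strong
drive the network *needs* SST recruitment, so silencing SST through an
over-strong VIP→SST coupling destabilizes it.  With these defaults the
measured critical magnitude is |W_VIP→SST| ≈ 0.607 and the default −0.6
operates at ≈ 0.99 of critical — a deliberately near-critical regime, which
is why a few drive strengths near the disinhibition transition converge
slowly (weakly damped oscillatory mode; default `t_max` is 6 000 ms of
simulated time, tolerance 1e-6 on `max|r_ss − r|`, divergence ceiling 1e6).

### Stability analysis

`EE_stability = J00 − 1` with `J00 = g_E(0°) · W_{E→E} · Ĝ_{EE}(n)` and
`g = 2k·max(I, 0)` the gain at the steady state; `n = 0` (spatially
homogeneous perturbation) by default.  `EE_stability > 0` with a stable
full network marks the inhibitory-stabilized (ISN) regime; a non-settling
or diverging simulation is classified unstable.  For a spatially
homogeneous steady state this analysis is exact (the E-E Jacobian block is
row-stochastic times `g·W_EE`, so `J00` is its Perron eigenvalue), and the
oracle test compares its sign against the numerically differentiated
Jacobian's leading eigenvalue under uniform drive.  At tuned steady states
the gain profile is inhomogeneous and `J00(x=0°)` is a local summary
evaluated at the stimulus center, as in the source analysis.

### Gain and sweeps

Pyramidal "gain" is the centered finite difference of the 0°-unit rate
against drive strength (default grid spacing 1 a.u.; the validation suite
uses 2 a.u. to keep runtimes modest, stated per study).  Δgain compares
the intact network with an otherwise-identical network whose VIP→SST
coupling is zeroed.  Parameter sweeps treat instability as data; the
critical VIP→SST magnitude is found by bisection on "every strength on
the grid reaches a steady state".

With the shipped calibration the suite reproduces, qualitatively: VIP most
active at weak drive and suppressed below its spontaneous rate at strong
drive; a single non-ISN→ISN transition with increasing drive; a VIP→SST
gain enhancement confined to weak drive (peaking below the SST activity
peak); above-critical runaway with silenced SST; and PV-fraction
robustness over 0.2–0.8 with instability appearing from 0.9 (compare the
reported bifurcation near 0.8 and instability above 0.95).  No
quantitative match of published axis values is claimed, since the absolute
weights are unpublished.

## Problem sizes in the shipped studies

Calibration of the responsiveness test uses 2 000 null cells × 750 trials
× 2 000 resamples; class recovery uses 100 cells per class at 15 repeats
with gamma shape 16 (CV 0.25, "high SNR") and no zero inflation; GLM
recovery plants 12 signed weights among the 30 main-effect/two-way terms
over 3 sessions with variance-proportional-to-mean noise; the stability
oracle runs 10 drive strengths on a 60-unit homogeneous ring; the circuit
suite runs the full 254-unit network over drive 0–100.

## Known limitations

* The generator's trial exchangeability makes bootstrap and permutation
  nulls nearly equivalent; real data with slow drifts would separate them.
* The shuffle-based model-comparison likelihood cannot select the
  band-pass model (see above); this is a property of the procedure, not of
  the implementation.
* GLM weights are reported per term but are identifiable only up to the
  null space of the 98-pattern design; interpretation should rest on
  predictions, supports and signs.
* The SSN operates at 0.99 of the critical VIP→SST coupling by design;
  conclusions are robust to the ring discretization only if couplings are
  re-measured against the critical point at that discretization (the
  60-unit test ring uses a slightly backed-off coupling for this reason).
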
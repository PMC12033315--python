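# stimnet

Desk-scale analysis chain linking the intensity of subthalamic deep brain
stimulation (STN-DBS) in Parkinson's disease to (a) spiral-drawing
kinematics, (b) source-level oscillatory band power, (c) directed
subthalamo-cortical effective connectivity, and (d) prediction of kinematic
improvement from spectral-power slopes. A synthetic-data generator with
known ground truth stands in for patient recordings, so every stage of the
chain is testable end to end.

Who it is for: researchers working on closed-loop / adaptive DBS who need a
reusable, verifiable implementation of this analysis chain, and anyone who
wants a ground-truthed testbed for directed-connectivity estimation.

## What it computes

**Kinematics.** Spirals are Archimedean, r = b·θ/2π. For each drawn spiral
the tangential velocity is v_t = r·dθ/dt (instantaneous radius times the
rate of unwrapped angular displacement, center = first pen sample). Per
condition the package reports the mean and peak of v_t and its sample
entropy, SampEn(m=2, r = 0.2·SD) = −ln(A/B) with Chebyshev template
matching, and the ordinary-least-squares slope of each parameter across
stimulation levels 0–3.

**Sources.** Sensor recordings are re-referenced to the common average,
band-passed with a fourth-order Butterworth (0.5/300 Hz, applied zero
phase), notched at 50/100/150 Hz, and projected to region-of-interest
source series with an LCMV beamformer: w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹ for lead
column l and (optionally diagonally loaded) sensor covariance C — unit gain
on the target source, minimum output variance otherwise.

**Spectra.** Welch densities (1-s Hamming windows, 50% overlap) integrated
over four bands: low beta 13–20, high beta 21–30, low gamma 31–60, high
gamma 61–100 Hz.

**Connectivity.** A joint MVAR model x_t = Σ_r A_r x_{t−r} + e_t is fitted
to the ROI series (least squares; BIC order selection available) and the
generalized partial directed coherence from region j to i is

    |π_ij(f)| = (1/σ_i)|Ā_ij(f)| / sqrt( Σ_k (1/σ_k²)|Ā_kj(f)|² ),
    Ā(f) = I − Σ_r A_r e^(−i2πfr/fs),

with σ_k the innovation standard deviations — a column-normalized directed
outflow ratio (Σ_i |π_ij|² = 1). Band means over ordered ROI pairs form the
effective-connectivity tables.

**Prediction.** Gaussian-kernel support vector regression maps the eight
per-ROI power slopes of one band to the per-subject velocity slope
(C = 3·SD(y), ε = 0.1·SD(y), γ = 1/2d on z-scored features), scored by
repeated 5-fold cross-validation, with exact Shapley attribution by full
2⁸-coalition enumeration.

**Statistics.** Paired t, exact Wilcoxon matched-pairs signed rank,
one-within-factor repeated-measures ANOVA over the four levels
(F = MS_level / MS_subject×level, df = (3, 3(n−1))), and Tukey HSD post hoc
on the level means.

## Worked example

Ground-truth check of the headline connectivity effect: simulate the stock
5-ROI motor network at the lowest and highest stimulation level, fit the
MVAR, and read off band-mean gPDC.

```python
from stimnet import synthetic, connectivity
from stimnet.containers import DEFAULT_BANDS
from stimnet.validation import motor_connectivity_subnetwork

net = motor_connectivity_subnetwork()
for level in (0, 3):
    model = synthetic.build_mvar_from_spec(net, level)
    rec = synthetic.simulate_mvar(model, 10_000, seed=42 + level)
    spec = connectivity.gpdc(connectivity.fit_mvar(rec, order=model.p))
    hb = connectivity.band_mean_gpdc(spec, DEFAULT_BANDS["high_beta"], [("STN", "M1")])
    hg = connectivity.band_mean_gpdc(spec, DEFAULT_BANDS["high_gamma"],
                                     [("SMA", "M1"), ("STN", "M1")])
    print(f"level {level}: high-beta STN->M1 gPDC = {hb['gpdc'][0]:.3f}, "
          f"high-gamma SMA->M1 = {hg['gpdc'][0]:.3f}, "
          f"high-gamma STN->M1 = {hg['gpdc'][1]:.3f}")
```

prints

```
level 0: high-beta STN->M1 gPDC = 0.560, high-gamma SMA->M1 = 0.048, high-gamma STN->M1 = 0.053
level 3: high-beta STN->M1 gPDC = 0.216, high-gamma SMA->M1 = 0.211, high-gamma STN->M1 = 0.029
```

Ramping stimulation weakens the high-beta subthalamo-cortical outflow
(0.560 → 0.216), strengthens the high-gamma premotor→M1 coupling
(0.048 → 0.211), and leaves the high-gamma STN→M1 pair at its estimation
noise floor — the qualitative fingerprint the analysis is built to detect.

A full synthetic-cohort run (spirals → kinematics, EEG → sources → power →
connectivity, features → prediction, group statistics) is one command:

```sh
stimnet run --seed 7 --out results/
```

which writes `spiral_summary.tsv`, `velocity_slopes.tsv`, `band_power.tsv`,
`power_slopes.tsv`, `connectivity.tsv`, `attribution.tsv`,
`prediction.json`, `stats.tsv` and `run_meta.json`, each stamped with the
configuration hash. Individual stages are available as
`stimnet simulate|preprocess|power|connect|kinematics|predict`.

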
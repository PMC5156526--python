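# mitodyn

Quantitative analysis of transcription-factor (TF) dynamics on mitotic
chromosomes from live-cell microscopy: single-particle-tracking (SPT)
kinetics, FRAP recovery, chromosome-enrichment imaging, and a stochastic
model of the formaldehyde-fixation artifact that makes dynamically bound TFs
appear excluded from mitotic chromosomes in fixed-cell images.

The package is aimed at quantitative cell biologists analysing live-cell
SPT/FRAP/imaging experiments on mitotic cells — and at anyone who wants to
explore, in simulation, how chemical fixation can erase the chromosomal
enrichment of a dynamically exchanging protein.

## What it computes

**Residence times (slow tracking).** Long camera exposures blur out freely
diffusing molecules, so detected spots are bound molecules. Observed dwell
times (time until unbinding *or* photobleaching) give a survival curve S(t)
fitted with a two-exponential model

    P(t) = F·exp(−k_ns·t) + (1 − F)·exp(−k_s·t),

fast component = non-specific binding, slow component = specific binding.
Because the empirical slow rate is k_s,emp = k_photobleach + k_off,s, the
bleaching rate — measured from a no-unbinding histone control fitted the same
way — is subtracted, and the specific residence time is τ_s = 1/k_off,s.

**Bound fraction (fast tracking).** Jump lengths r pooled at lags
Δτ = 4.5 … 31.5 ms are fitted with a two-state model of bound
(D_bound) and free (D_free) populations,

    P(r, Δτ) = F·p_Db(r) + Z_corr(Δτ)·(1 − F)·p_Df(r),

where p_D(r) is the 2D Rayleigh jump density with localization-error
broadening (σ ≈ 35 nm) and Z_corr(Δτ) ∈ [0, 1] corrects for free molecules
diffusing out of the ~0.7 µm axial detection slice between frames —
otherwise the bound fraction is overestimated. Z_corr is the absorbing-slab
survival integral (erfc image series) evaluated over an empirically corrected
effective slice thickness Δz_eff = Δz + 0.15716·√D + 0.20811 µm.

**FRAP.** Double normalization (background subtraction, whole-cell division,
pre-bleach mean = 1) followed by the time to reach 90% of the recovered
plateau measured from the bleach floor (t90), no model fit required.

**Chromosome enrichment.** E = log2(mean TF intensity on chromosomes /
mean TF intensity over the whole cell), with the chromosome mask thresholded
from an H2B marker channel; positive E = enrichment, negative E = apparent
exclusion. A time-lapse variant follows the normalized chromosome intensity
through fixative-addition movies and reports its value 60 s after addition.

**Fixation-artifact model.** A particle simulation of TFs exchanging on a
chromosome disc inside a cell disc while an inward-moving crosslinking front
(erfc profile) immobilizes molecules where it finds them. It reproduces the
three signature predictions: the artifact grows with fixative dose; stably
bound factors (low k_off) resist it; spatially uniform instantaneous
fixation (the high-pressure-freezing control) preserves live enrichment
exactly.

Every stage has a synthetic-data generator with the exact statistical
structure the model assumes, so the full pipeline is testable by parameter
recovery without any external data.

## Worked example

Simulate an interphase-like slow-tracking experiment and recover the
residence time:

```
$ mitodyn simulate dwell --preset interphase --n-events 5000 --seed 11 --out dwells.csv
wrote 5000 dwell events to dwells.csv
$ mitodyn fit-residence --dwells dwells.csv --k-photobleach 0.05 --out residence.json
{"F": 0.711, "k_off_emp_ns": 4.32, "k_off_emp_s": 0.1419, "n_events": 5000,
 "convergence": true, "k_photobleach": 0.05, "k_off_s": 0.0919, "tau_s": 10.88}
```

The generator drew dwells from a 70/30 mixture of non-specific
(k_ns = 2 s⁻¹) and specific (k_s = 0.08 s⁻¹) binding, censored by
photobleaching at 0.05 s⁻¹. The fitted empirical slow rate 0.142 s⁻¹ minus
the bleaching rate gives k_off,s = 0.092 s⁻¹, i.e. τ_s ≈ 10.9 s against a
ground truth of 12.5 s (the specific rate is recovered within ~15% at
5000 events; the non-specific rate is only loosely constrained at 0.5 s
frames).

Same idea for the bound fraction:

```
$ mitodyn simulate spt --preset interphase --n-particles 20000 --seed 11 --out fast.csv
wrote 80819 localizations in 7921 trajectories to fast.csv
$ mitodyn fit-jumps --tracks fast.csv --out jumps.json
{"f_bound": 0.331, "d_free": 2.06, "d_bound": 0.0103}
```

The preset simulates a stationary bound fraction of 0.309 with
D_free = 2 µm²/s and D_bound = 0.01 µm²/s through a 0.7 µm detection slice;
the two-state fit with defocus correction recovers all three parameters.

The same stages are available as a library — estimator classes
(`TwoExponentialSurvival`, `TwoStateJumpModel`, `FrapRecovery`) follow
scikit-learn conventions (`fit`, fitted `*_` attributes, `get_params`), and
`simulate_*`/`render_*`/`estimate_*` functions cover generation and imaging.

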
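# h2axdose

Biodosimetry for protracted internal Cs-137 exposures from γ-H2AX
fluorescence kinetics.

After an incident that disperses soluble Cs-137 (a "dirty bomb", reactor
accident or orphaned-source event), incorporated radionuclide irradiates
the whole body continuously while it is excreted, so absorbed dose and dose
rate both change with time. `h2axdose` implements an analysis pipeline for
this setting, developed around a mouse internal-emitter model (four
injected ¹³⁷CsCl activities, 5.74–9.28 MBq, sampled on days 2–14): it
estimates how much activity was incorporated — and hence the committed
whole-body dose — from two inputs a triage lab can obtain: the time since
exposure and the mean γ-H2AX fluorescence of blood mononuclear cells.

## The models

**Biokinetics.** Whole-body retention of caesium is biexponential in
biological half-times,

    R(t) = 0.20·e^(−0.693 t / 0.6) + 0.80·e^(−0.693 t / 7.8)   [t in days],

from which cumulative disintegrations, committed dose D = (D/A)·A and daily
dose rates follow by closed form (the specific effective energy, Gy per
disintegration, is an explicit configuration value).

**γ-H2AX kinetics.** Mean fluorescence F (arbitrary units) after injecting
activity A (MBq), measured t days later, follows

    F(A, t) = b + k·A·t·exp(−α·A + 1 − (1 + r·t)^p),

where b is the unirradiated background, k·A·t the initial dose-rate-driven
rise, e^(−αA) the loss of heavily damaged cells at high activity, and the
stretched exponential (0 < p < 1) the multi-scale decline from excretion,
DNA repair and cell death. The four free parameters are fitted to
group-mean data by weighted Gaussian maximum likelihood (weights 1/SEM²)
with seeded multistart; uncertainty comes from profile likelihood.

**Inversion.** The fitted curve is used as a calibration curve: ≥ 5000
parameter combinations ψᵢ are rejection-sampled from the joint 95%
confidence region, and for each draw the measured (t, F) is inverted for
activity on the falling limb A ≥ 1/α (closed form via the Lambert-W
function). Median/min/max estimates per data point are scored by
Pearson/Spearman correlation against true activities over time windows,
converted to dose with measured per-day coefficients, and assessed as a
low/high-activity classifier by ROC analysis with a DeLong AUC interval.

Because the study's raw fluorescence tables are not machine-readable, the
package ships a seeded synthetic-data generator that reproduces the study
design and the statistical structure the analysis assumes (group-level
Gaussian noise anchored to the measured control SEM of 36 AU, per-animal
retention variability, per-cell mixtures with an apoptotic tail above the
3000 AU editing cutoff).

## Worked example

```python
import h2axdose as hx
from h2axdose.presets import BLOOD_BESTFIT, BLOOD_BACKGROUND_AU

# retention headline: fraction excreted by day 5
print(1 - hx.retention_fraction(hx.RetentionParams(), 5.0))  # 0.486

# forward model at the lowest study activity, day 2
print(hx.predict_fluorescence(BLOOD_BESTFIT, activity=5.74, time=2.0))
# 1312.49 AU, ~306 AU above the 1006 AU control background

# fit a synthetic calibration study and invert it
data = hx.generate_group_means(hx.StudyDesign(), BLOOD_BESTFIT,
                               hx.NoiseConfig(), seed=42)
fit = hx.H2AXKineticsModel(data, BLOOD_BACKGROUND_AU).fit(n_starts=12, seed=0)
print(fit.params.alpha)        # ~0.33 (published calibration: 0.255)

ens = fit.sample_confidence_region(n_min=5000, seed=11)
points = [(m.time, m.mean_fluorescence, m.activity) for m in data]
est = hx.summarize_estimates(ens, points)
print(hx.correlation_report(est)[["time_range", "pearson_r"]])
#   time_range  pearson_r
#     2-3 days      0.823   <- the early triage window reconstructs best;
#     2-5 days      0.674      by day 14 the fluorescence of the four
#     2-7 days      0.751      activity groups overlaps and single-study
#    2-14 days      0.773      correlations become noisy
```

The `h2axdose` CLI exposes the same stages (`simulate`, `dose`, `fit`,
`invert`, `cells`) and an end-to-end `run` driven by a YAML config.

## Layout

| module | contents |
|---|---|
| `h2axdose.biokinetics` | retention curve, disintegrations, dose, dose rate, retention fitting |
| `h2axdose.kinetics` | forward fluorescence model, response peak geometry |
| `h2axdose.model` | `H2AXKineticsModel` / `H2AXKineticsResults`: weighted-ML fit, profile CIs, confidence region |
| `h2axdose.inversion` | ensemble sampling, activity inversion, correlations, dose conversion, ROC |
| `h2axdose.cells` | per-cell filtering (> 3000 AU), damage classes (< 500 / > 3000 AU), group summaries |
| `h2axdose.simulate` | seeded study-design generator (group means, retention curves, per-cell samples) |
| `h2axdose.cli` | command-line interface |

See `docs/methods.md` for model assumptions, parameter defaults, numerical
choices and limitations.
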
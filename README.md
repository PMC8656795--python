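# ssopkit

Widefield tissue oximetry from structured illumination: a Python toolkit
for **spatial frequency domain imaging (SFDI)** and its real-time variant
**single-snapshot imaging of optical properties (SSOP)**.

## The problem

Surgeons assessing tissue perfusion — for example of a gastric conduit
before an esophageal anastomosis — need a quantitative, widefield map of
tissue oxygen saturation (StO₂%), not a subjective color judgment.  SFDI
provides exactly that: sinusoidal light patterns at a low and a high
spatial frequency are projected onto the tissue, and the amplitude of the
backscattered modulation encodes the tissue's absorption μₐ and reduced
scattering μ′ₛ independently.  Two wavelengths straddling the hemoglobin
isosbestic point turn the per-pixel absorption into oxy-/deoxy-hemoglobin
concentrations, hence an StO₂ map.  SSOP trades a small accuracy margin
for speed by extracting both modulation amplitudes from a *single* frame
with Fourier-domain filtering, enabling video-rate imaging in the OR.

`ssopkit` implements the full classical processing chain, plus a
ground-truthed synthetic renderer so every stage can be validated without
instrument data:

1. **Demodulation** — three-phase (`M_AC = (√2/3)·√[(I₁−I₂)²+(I₂−I₃)²+(I₃−I₁)²]`,
   `M_DC = (I₁+I₂+I₃)/3`), or single-snapshot via a raised-cosine band
   split at half the carrier frequency.
2. **Calibration** — `R_d = (M_sample/M_ref)·R_d,model(ref)` against a
   phantom of known properties; cancels illumination nonuniformity.
3. **Inversion** — per-pixel look-up-table mapping `(R_DC, R_AC) → (μₐ, μ′ₛ)`
   built from the diffusion-approximation closed form
   `R_d(f_x) = 3Aa′ / ((μ′_eff/μ_tr + 1)(μ′_eff/μ_tr + 3A))`,
   `μ′_eff = √(3μₐμ_tr + (2πf_x)²)`, refined by Gauss–Newton on the
   bilinear table interpolant.  External (e.g. Monte Carlo) tables can be
   loaded in place of the built-in model.
4. **Chromophores** — Beer–Lambert unmixing
   `μₐ(λ) = ln10·[ε_HbO₂(λ)C_HbO₂ + ε_Hb(λ)C_Hb]` at 665/860 nm,
   `StO₂ = 100·C_HbO₂/(C_HbO₂+C_Hb)`.
5. **ROI analysis** — per-ROI time series, normalization to a reference
   ROI at T0, Pearson StO₂–lactate correlation (Fisher-z CI), and a ROC /
   Youden cut-off with a DeLong CI for two-group discrimination.

## Worked example

```bash
python examples/03_end_to_end_sto2_map.py
```

simulates a four-region perfusion phantom (antrum A, corpus C, fundus F
and a resected ischemic control R, ground truth StO₂ = 70/73/75/30 %)
under shot noise, runs the whole pipeline, and prints:

```
method = three_phase, flagged pixels = 10
 ROI  StO2 est (%)  truth (%)
   A      69.64+-0.05     70.0
   C      72.70+-0.05     73.0
   F      74.68+-0.05     75.0
   R      29.75+-0.09     30.0
```

Each ROI mean lands within a fraction of a percentage point of the
ground truth; the resected region is unambiguously deoxygenated.  The
other examples show the forward model and LUT inversion (`01`), the
SFDI-vs-SSOP comparison (`02`), and the ischemia statistics (`04`),
where the simulated six-subject time course gives

```
Pearson r = -0.9283  (95% CI -0.9496 to -0.8986, p = 1.53e-52, n = 120)
resected vs perfused: AUC = 0.9715, Youden cut-off = 68.56% StO2
```

i.e. capillary lactate rises as StO₂ falls, and an StO₂ threshold close
to 69 % separates ischemic from perfused regions.

A thin CLI mirrors the pipeline stages
(`ssop simulate | demodulate | calibrate | invert | sto2 | roi | run | report`),
e.g. `ssop simulate --out data/ && ssop run --data data/ --out results/`.

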
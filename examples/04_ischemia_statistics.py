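"""Perfusion-study statistics on a simulated ischemia time course.

Six subjects, four ROIs, five timepoints (T0..T60): the resected region
desaturates while local capillary lactate rises.  Computes the pooled
StO2-lactate Pearson correlation and the ROC cut-off separating the
resected from the perfused regions.
"""

from ssopkit import (
    normalize_to_reference,
    pearson_correlation,
    roc_threshold,
    simulate_ischemia_timecourse,
)

df = simulate_ischemia_timecourse(seed=1)
res = pearson_correlation(df["sto2"], df["lactate"])
print(f"Pearson r = {res.r:.4f}  (95% CI {res.ci_low:.4f} to {res.ci_high:.4f}, "
      f"p = {res.p_value:.2e}, n = {res.n})")
print("-> strong negative coupling: the lower the oxygen saturation, the "
      "higher the capillary lactate.\n")

roc = roc_threshold(df.loc[df.roi == "R", "sto2"], df.loc[df.roi != "R", "sto2"])
print(f"resected vs perfused: AUC = {roc.auc:.4f} "
      f"(95% CI {roc.ci_low:.4f}-{roc.ci_high:.4f}), "
      f"Youden cut-off = {roc.threshold:.2f}% StO2")
print("-> an StO2 threshold near the cut-off separates ischemic from "
      "perfused tissue almost perfectly.\n")

norm = normalize_to_reference(df, include_lactate=True)
t0 = norm[(norm.roi == "A") & (norm.timepoint == "T0")]
print(f"after normalization, ROI-A at T0 = {t0['sto2'].iloc[0]:.2f} "
      "(by definition) for every subject")
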
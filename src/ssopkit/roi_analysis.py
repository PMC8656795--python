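"""ROI quantification and perfusion-study statistics.

Time-series tables are tidy pandas DataFrames with one row per
(subject, roi, timepoint): columns ``subject``, ``roi``, ``timepoint``,
``sto2_mean``, ``sto2_sem`` and optionally ``lactate``.  Statistics
follow common perfusion-study practice: per-subject normalization to a
reference ROI at the first timepoint, Pearson correlation between StO2
and lactate with a Fisher-z confidence interval, and a ROC / Youden
cut-off to discriminate two ROI groups (AUC confidence interval by
DeLong's method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "extract_roi_means",
    "normalize_to_reference",
    "pearson_correlation",
    "roc_threshold",
    "PearsonResult",
    "RocResult",
]


def extract_roi_means(
    map_stack,
    roi_masks: dict,
    subject: str = "s1",
    timepoints=None,
) -> pd.DataFrame:
    """Mean and SEM of StO2 over unflagged pixels, per ROI per timepoint.

    Parameters
    ----------
    map_stack : StO2Map, or sequence/dict of StO2Map
        One map per timepoint.  A dict maps timepoint labels to maps;
        sequences are labelled T0, T15, ... by default.
    roi_masks : dict
        ROI name -> boolean mask, all within image bounds.

    A ROI whose mask has no unflagged pixel raises, naming the ROI.
    """
    from .chromophores import StO2Map  # local import to avoid cycle

    if isinstance(map_stack, StO2Map):
        map_stack = [map_stack]
    if isinstance(map_stack, dict):
        items = list(map_stack.items())
    else:
        labels = timepoints or [f"T{15 * i}" for i in range(len(map_stack))]
        items = list(zip(labels, map_stack))

    rows = []
    for label, m in items:
        good = (m.qc == 0) & np.isfinite(m.sto2)
        for name, mask in roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != m.sto2.shape:
                raise ValueError(f"ROI {name!r} mask shape {mask.shape} "
                                 f"does not match map shape {m.sto2.shape}")
            sel = m.sto2[mask & good]
            if sel.size == 0:
                raise ValueError(f"ROI {name!r} has no unflagged pixels at {label}")
            sem = float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else 0.0
            rows.append(
                dict(subject=subject, roi=name, timepoint=label,
                     sto2_mean=float(sel.mean()), sto2_sem=sem, n_pixels=int(sel.size))
            )
    df = pd.DataFrame(rows)
    df["normalized"] = False
    return df


def normalize_to_reference(
    series: pd.DataFrame,
    ref_roi: str = "A",
    ref_time: str = "T0",
    include_lactate: bool = False,
) -> pd.DataFrame:
    """Normalize per subject to the reference ROI at the reference timepoint.

    StO2 mean and SEM (and, when requested, lactate) of every row are
    divided by that subject's ``ref_roi``@``ref_time`` value, so the
    reference row maps to exactly 1.0.  The operation is idempotent and
    invariant to per-subject rescaling of the raw values.
    """
    out = series.copy()
    value_col = "sto2_mean" if "sto2_mean" in out.columns else "sto2"
    for subject, grp in out.groupby("subject"):
        ref = grp[(grp["roi"] == ref_roi) & (grp["timepoint"] == ref_time)]
        if len(ref) == 0:
            raise ValueError(f"subject {subject!r}: no {ref_roi}@{ref_time} reference row")
        ref_val = float(ref[value_col].iloc[0])
        if ref_val <= 0:
            raise ValueError(f"subject {subject!r}: reference value {ref_val} <= 0")
        idx = grp.index
        out.loc[idx, value_col] = grp[value_col] / ref_val
        if "sto2_sem" in out.columns:
            out.loc[idx, "sto2_sem"] = grp["sto2_sem"] / ref_val
        if include_lactate and "lactate" in out.columns:
            ref_lac = float(ref["lactate"].iloc[0])
            if ref_lac <= 0:
                raise ValueError(f"subject {subject!r}: reference lactate {ref_lac} <= 0")
            out.loc[idx, "lactate"] = grp["lactate"] / ref_lac
    out["normalized"] = True
    return out


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def pearson_correlation(x, y, alpha: float = 0.05) -> PearsonResult:
    """Pearson r with two-sided p-value and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    if abs(r) >= 1.0 or n <= 3:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return PearsonResult(r=r, ci_low=float(lo), ci_high=float(hi),
                         p_value=float(res.pvalue), n=n)


@dataclass(frozen=True)
class RocResult:
    threshold: float
    auc: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


def _mann_whitney_auc(neg: np.ndarray, pos: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic with half-weight ties."""
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def _delong_variance(neg: np.ndarray, pos: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC from placement values."""
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    return s10 / len(pos) + s01 / len(neg)


def roc_threshold(values_group1, values_group2, alpha: float = 0.05) -> RocResult:
    """Univariate two-group discrimination: AUC, DeLong CI, Youden cut-off.

    Group 2 is the positive class, so AUC = P(g2 > g1) + 0.5 P(tie);
    fully separated groups give AUC exactly 0 or 1 with a degenerate CI.
    The optimal cut-off maximizes Youden's J = sensitivity + specificity
    - 1 on the measurement scale, ties broken toward the lower threshold.
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two values")
    auc = float(_mann_whitney_auc(g1, g2))
    var = _delong_variance(g1, g2, auc)
    half = float(stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0)))
    lo, hi = max(auc - half, 0.0), min(auc + half, 1.0)

    scores = np.concatenate([g1, g2])
    labels = np.concatenate([np.zeros(g1.size), np.ones(g2.size)])
    if np.ptp(scores) == 0:
        threshold = float(scores[0])  # degenerate: identical groups
    else:
        fpr, tpr, thr = roc_curve(labels, scores)
        j = tpr - fpr
        best = j == j.max()
        threshold = float(thr[best].min())  # ties toward the lower cut-off
    return RocResult(threshold=threshold, auc=auc, ci_low=lo, ci_high=hi,
                     n1=int(g1.size), n2=int(g2.size))
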
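"""ROC analysis of a continuous marker with Youden-index cut-off.

Used to evaluate promoter methylation rate as a tumor/normal
classifier: the full sensitivity/specificity profile over all
thresholds, the trapezoid AUC, and the operating point maximizing the
Youden index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ROCResult:
    thresholds: np.ndarray = field(repr=False)  # ascending, with +-inf sentinels
    sens: np.ndarray = field(repr=False)
    spec: np.ndarray = field(repr=False)
    auc: float = 0.0
    youden_cutoff: float = 0.0
    youden_j: float = 0.0
    sens_at_cutoff: float = 0.0
    spec_at_cutoff: float = 0.0
    positive_high: bool = True


def roc(values, labels, positive_high: bool = True) -> ROCResult:
    """ROC curve of a continuous marker against binary class labels.

    Thresholds are the midpoints between consecutive distinct marker
    values plus -inf/+inf sentinels; a sample is predicted positive iff
    its value >= threshold (or <= threshold when ``positive_high`` is
    False). The AUC is the trapezoid area of the (1 - specificity,
    sensitivity) curve, identical to the tie-aware U-statistic
    U / (n1 * n0) with 0.5 credit per tie.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if v.shape != y.shape:
        raise ValueError("values and labels differ in length")
    if np.any(np.isnan(v)):
        raise ValueError("missing marker values not allowed")
    if len(np.unique(y)) != 2 or not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    x = v if positive_high else -v
    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos = y == 1
    n1, n0 = pos.sum(), (~pos).sum()
    sens = np.array([np.sum(x[pos] >= t) / n1 for t in thresholds])
    spec = np.array([np.sum(x[~pos] < t) / n0 for t in thresholds])
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ascending fpr, sens breaks ties
    auc = float(np.trapezoid(sens[order], fpr[order]))

    if not positive_high:
        # report thresholds on the marker's own scale, kept ascending;
        # a sample is then positive iff value <= threshold
        thresholds = -thresholds[::-1]
        sens, spec = sens[::-1], spec[::-1]
    res = ROCResult(
        thresholds=thresholds,
        sens=sens, spec=spec, auc=auc, positive_high=positive_high,
    )
    cutoff, j, s, sp = youden(res)
    res.youden_cutoff, res.youden_j = cutoff, j
    res.sens_at_cutoff, res.spec_at_cutoff = s, sp
    return res


def youden(r: ROCResult) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties in J are broken toward higher sensitivity, then the lower
    cutoff on the marker's own scale. The reported cutoff is the
    midpoint threshold itself (finite optima only, unless the curve is
    degenerate).
    """
    j = r.sens + r.spec - 1.0
    # marker-scale cutoffs: thresholds were stored on the original scale
    cut = r.thresholds
    best = None
    for i in range(len(j)):
        key = (-j[i], -r.sens[i], cut[i] if np.isfinite(cut[i]) else np.inf)
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    return float(cut[i]), float(j[i]), float(r.sens[i]), float(r.spec[i])


def roc_to_tsv(r: ROCResult, path) -> None:
    pd.DataFrame(
        {"threshold": r.thresholds, "sensitivity": r.sens, "specificity": r.spec}
    ).to_csv(path, sep="\t", index=False)


__all__ = ["ROCResult", "roc", "youden", "roc_to_tsv"]
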
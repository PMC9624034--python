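"""Kaplan-Meier estimation and two-group log-rank testing.

Survival is stratified by dichotomizing a continuous marker (promoter
methylation or expression) at its median: "high" means strictly above
the median. The product-limit estimator uses the convention that a
subject censored at an event time is still at risk at that time; the
log-rank test is the standard 1-df chi-square with hypergeometric
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: int  # 1 death, 0 censored
    marker: float = float("nan")
    group: str | None = None  # "high" / "low" once dichotomized

    def __post_init__(self):
        if not self.time > 0:
            raise ValueError(f"{self.sample_id}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")


@dataclass
class KMCurve:
    times: np.ndarray = field(repr=False)  # distinct event times, ascending
    survival: np.ndarray = field(repr=False)  # S(t) just after each event time
    at_risk: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)

    def at(self, t: float) -> float:
        """S(t): survival probability at time t."""
        s = 1.0
        for tk, sk in zip(self.times, self.survival):
            if tk <= t:
                s = sk
            else:
                break
        return s


def dichotomize(
    records: list[SurvivalRecord], rule: str = "median", quantile: float = 0.5
) -> list[SurvivalRecord]:
    """Assign high/low groups by a marker quantile split (default median).

    "high" means marker strictly greater than the split value (a marker
    equal to the median goes to "low"); the median uses the
    average-of-middle-two convention. All-equal markers are an error.
    """
    if rule != "median" and not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    markers = np.array([r.marker for r in records], dtype=float)
    if len(np.unique(markers)) < 2:
        raise ValueError("all marker values equal; cannot dichotomize")
    q = 0.5 if rule == "median" else quantile
    split = float(np.quantile(markers, q))
    out = [replace(r, group="high" if r.marker > split else "low") for r in records]
    n_high = sum(r.group == "high" for r in out)
    logger.info("dichotomize: split at %.6g -> %d high, %d low", split, n_high,
                len(out) - n_high)
    return out


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate S(t) = prod (1 - d_k / n_k).

    n_k counts subjects with observation time >= t_k, so a subject
    censored exactly at an event time is at risk there. With no events
    the curve is the constant 1.
    """
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    etimes = np.unique(times[events == 1])
    surv, n_at_risk, d_at = [], [], []
    s = 1.0
    for t in etimes:
        n_k = int(np.sum(times >= t))
        d_k = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_k / n_k
        surv.append(s)
        n_at_risk.append(n_k)
        d_at.append(d_k)
    return KMCurve(etimes, np.array(surv), np.array(n_at_risk), np.array(d_at))


def logrank(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test over the high/low groups.

    Sums observed-minus-expected deaths of the first group over all
    distinct event times with the hypergeometric variance; the
    statistic is chi-square with 1 df.
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    in_g1 = np.array([r.group == groups[0] for r in records])
    if events.sum() == 0:
        raise ValueError("no events observed")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def read_clinical_tsv(path) -> list[SurvivalRecord]:
    """Read a clinical table TSV: sample, time, event [, marker]."""
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(
            str(r.sample), float(r.time), int(r.event),
            float(getattr(r, "marker", float("nan"))),
        )
        for r in df.itertuples(index=False)
    ]


def km_to_tsv(curve: KMCurve, path) -> None:
    pd.DataFrame(
        {"time": curve.times, "survival": curve.survival,
         "at_risk": curve.at_risk, "events": curve.events}
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "dichotomize",
    "km_curve",
    "logrank",
    "read_clinical_tsv",
    "km_to_tsv",
]
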
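"""Differential methylation: per-probe delta-beta screening and
bump-hunting DMR detection with label-permutation significance.

Per-probe calls use the mean beta difference (tumor minus normal) with
a two-sided Mann-Whitney test and BH FDR. Region calls follow a
bumphunter-style scheme: probes are clustered by genomic gap, candidate
regions are maximal runs of consecutive probes whose |delta-beta|
exceeds a cutoff with a common sign, and empirical p-values come from
permuting the sample group labels and recording the maximum candidate
area per permutation (area = sum of |delta-beta| over member probes).
No loess smoothing is applied; the statistic is the raw delta-beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, mann_whitney
from .annotation import ProbeRecord

logger = logging.getLogger(__name__)


@dataclass
class BetaMatrix:
    """Methylation beta values in [0, 1], probes x samples; NaN = missing."""

    probes: list[str]
    samples: list[str]
    beta: np.ndarray = field(repr=False)
    group: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.beta.shape != (len(self.probes), len(self.samples)):
            raise ValueError("beta shape does not match probe/sample lists")
        finite = self.beta[~np.isnan(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values outside [0, 1]")
        for g in ("tumor", "normal"):
            if not np.any(self.group == g):
                raise ValueError(f"group {g!r} is empty")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.group == "tumor"

    @classmethod
    def read_tsv(cls, beta_path, sheet_path):
        df = pd.read_csv(beta_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str).set_index("sample")
        return cls(
            probes=list(df.index.astype(str)),
            samples=list(df.columns.astype(str)),
            beta=df.to_numpy(),
            group=sheet["group"].reindex(df.columns).to_numpy(),
        )

    def to_tsv(self, beta_path, sheet_path) -> None:
        pd.DataFrame(self.beta, index=self.probes, columns=self.samples).to_csv(
            beta_path, sep="\t", index_label="probe_id"
        )
        pd.DataFrame({"sample": self.samples, "group": self.group}).to_csv(
            sheet_path, sep="\t", index=False
        )


@dataclass(frozen=True)
class DMResult:
    probe_id: str
    delta_beta: float  # mean tumor beta - mean normal beta
    p: float
    fdr: float
    direction: str  # "hyper", "hypo" or "ns"


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region of >= 2 same-sign probes."""

    chrom: str
    start: int  # 0-based half-open over member probe positions
    end: int
    probe_ids: tuple[str, ...]
    n_probes: int
    mean_delta_beta: float
    area: float  # sum of |delta-beta| over member probes
    p_empirical: float


def _delta_beta(beta: np.ndarray, tmask: np.ndarray) -> np.ndarray:
    """Row-wise mean(tumor) - mean(normal) over non-missing entries."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(beta[:, tmask], axis=1) - np.nanmean(beta[:, ~tmask], axis=1)


def probe_dm(b: BetaMatrix, alpha: float = 0.05) -> list[DMResult]:
    """Per-probe differential methylation with BH FDR.

    Probes with fewer than 2 non-missing values in either group are
    skipped (counted in a log message). Direction is "hyper" iff
    fdr < alpha and delta_beta > 0, "hypo" iff fdr < alpha and
    delta_beta < 0.
    """
    tmask = b.tumor_mask
    ok_rows, dbs, ps = [], [], []
    n_skipped = 0
    for i, probe in enumerate(b.probes):
        t = b.beta[i, tmask]
        n = b.beta[i, ~tmask]
        t, n = t[~np.isnan(t)], n[~np.isnan(n)]
        if len(t) < 2 or len(n) < 2:
            n_skipped += 1
            continue
        ok_rows.append(i)
        dbs.append(t.mean() - n.mean())
        _, p = mann_whitney(t, n)
        ps.append(p)
    if n_skipped:
        logger.warning("probe_dm: skipped %d probes with < 2 values in a group", n_skipped)
    fdr = bh_adjust(ps)
    out = []
    for k, i in enumerate(ok_rows):
        db = dbs[k]
        if fdr[k] < alpha and db > 0:
            direction = "hyper"
        elif fdr[k] < alpha and db < 0:
            direction = "hypo"
        else:
            direction = "ns"
        out.append(DMResult(b.probes[i], float(db), float(ps[k]), float(fdr[k]), direction))
    return out


def _candidate_regions(
    delta: np.ndarray, cluster_ids: np.ndarray, cutoff: float, min_probes: int
) -> list[np.ndarray]:
    """Maximal runs of consecutive probes with |d| >= cutoff, same sign.

    ``delta`` must be ordered by (chrom, pos); ``cluster_ids`` label
    max-gap clusters in the same order. Returns index arrays.
    """
    sign = np.where(delta >= cutoff, 1, np.where(delta <= -cutoff, -1, 0))
    regions = []
    start = None
    for i in range(len(delta)):
        if start is not None:
            same_run = (
                sign[i] == sign[start]
                and sign[i] != 0
                and cluster_ids[i] == cluster_ids[start]
            )
            if not same_run:
                if i - start >= min_probes:
                    regions.append(np.arange(start, i))
                start = None
        if start is None and sign[i] != 0:
            start = i
    if start is not None and len(delta) - start >= min_probes:
        regions.append(np.arange(start, len(delta)))
    return regions


def find_dmrs(
    b: BetaMatrix,
    probes: list[ProbeRecord],
    cutoff: float = 0.2,
    min_probes: int = 2,
    resamples: int = 100,
    max_gap: int = 500,
    seed: int = 0,
) -> list[DMR]:
    """Bump-hunting DMR detection with permutation p-values.

    Probes are ordered per chromosome and clustered with inter-probe
    gap <= max_gap; candidates are maximal same-sign runs of probes
    with |delta-beta| >= cutoff and at least ``min_probes`` members.
    The null distribution permutes the sample group labels
    ``resamples`` times and records the maximum candidate area per
    permutation; p_empirical = (1 + #{null max >= area}) / (resamples + 1).
    Missing betas are imputed as the observed group mean for the
    permutation rounds only. Output is sorted by (p, -area).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    coord = {p.probe_id: (p.chrom, p.pos) for p in probes}
    keep = [i for i, pid in enumerate(b.probes) if pid in coord]
    if not keep:
        return []
    order = sorted(keep, key=lambda i: coord[b.probes[i]])
    ids = [b.probes[i] for i in order]
    chroms = np.array([coord[pid][0] for pid in ids], dtype=object)
    pos = np.array([coord[pid][1] for pid in ids])
    beta = b.beta[order]
    tmask = b.tumor_mask

    new_cluster = np.ones(len(ids), dtype=bool)
    if len(ids) > 1:
        same = (chroms[1:] == chroms[:-1]) & (pos[1:] - pos[:-1] <= max_gap)
        new_cluster[1:] = ~same
    cluster_ids = np.cumsum(new_cluster)

    delta_obs = _delta_beta(beta, tmask)
    delta_obs = np.where(np.isnan(delta_obs), 0.0, delta_obs)
    regions = _candidate_regions(delta_obs, cluster_ids, cutoff, min_probes)
    if not regions:
        return []

    # group-mean imputation keeps the permutation null exchangeable
    imputed = beta.copy()
    for mask in (tmask, ~tmask):
        sub = imputed[:, mask]
        row_mean = np.nanmean(np.where(np.isnan(sub), np.nan, sub), axis=1)
        row_mean = np.where(np.isnan(row_mean), 0.5, row_mean)
        idx = np.where(np.isnan(sub))
        sub[idx] = row_mean[idx[0]]
        imputed[:, mask] = sub

    rng = np.random.default_rng(seed)
    n_tumor = int(tmask.sum())
    null_max = np.empty(resamples)
    for r in range(resamples):
        perm = rng.permutation(len(b.samples))
        pmask = np.zeros(len(b.samples), dtype=bool)
        pmask[perm[:n_tumor]] = True
        d = _delta_beta(imputed, pmask)
        cand = _candidate_regions(d, cluster_ids, cutoff, min_probes)
        null_max[r] = max((float(np.abs(d[idx]).sum()) for idx in cand), default=0.0)

    out = []
    for idx in regions:
        area = float(np.abs(delta_obs[idx]).sum())
        p_emp = (1.0 + float(np.sum(null_max >= area))) / (resamples + 1.0)
        out.append(
            DMR(
                chrom=str(chroms[idx[0]]),
                start=int(pos[idx].min()),
                end=int(pos[idx].max()) + 1,
                probe_ids=tuple(ids[i] for i in idx),
                n_probes=len(idx),
                mean_delta_beta=float(delta_obs[idx].mean()),
                area=area,
                p_empirical=p_emp,
            )
        )
    out.sort(key=lambda d: (d.p_empirical, -d.area))
    return out


def dm_results_to_tsv(results: list[DMResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)


def read_dm_table(path) -> list[DMResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        DMResult(str(r.probe_id), float(r.delta_beta), float(r.p), float(r.fdr),
                 str(r.direction))
        for r in df.itertuples(index=False)
    ]


def dmrs_to_tsv(dmrs: list[DMR], path) -> None:
    rows = [
        {
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "n_probes": d.n_probes, "mean_delta_beta": d.mean_delta_beta,
            "area": d.area, "p_empirical": d.p_empirical,
            "probe_ids": ",".join(d.probe_ids),
        }
        for d in dmrs
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_probes", "mean_delta_beta",
                 "area", "p_empirical", "probe_ids"],
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "BetaMatrix",
    "DMResult",
    "DMR",
    "probe_dm",
    "find_dmrs",
    "dm_results_to_tsv",
    "read_dm_table",
    "dmrs_to_tsv",
]
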
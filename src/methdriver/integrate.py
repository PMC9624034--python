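"""Integration of differential methylation and expression screens.

A methylation-driven lncRNA call requires (i) a CpG probe that is
differentially methylated, (ii) a lncRNA that is differentially
expressed, and (iii) the probe lying in that lncRNA's promoter window.
Pairs can optionally be restricted to the concordant configurations
(promoter hypermethylation with downregulation, or hypomethylation with
upregulation) and annotated with the Spearman correlation between
promoter methylation and expression across samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult
from .diffmeth import DMResult

logger = logging.getLogger(__name__)

# largest n for which the Spearman p-value is computed by exhaustive
# permutation of one vector (n! pairings); above this the t-approximation
EXACT_SPEARMAN_N = 8


@dataclass
class MethDrivenPair:
    """A (CpG probe, lncRNA) pair surviving both differential screens."""

    probe_id: str
    gene_id: str
    delta_beta: float
    log2fc: float
    meth_direction: str  # "hyper" or "hypo"
    expr_direction: str  # "up" or "down"
    rho: float = math.nan
    rho_p: float = math.nan

    @property
    def concordant(self) -> bool:
        return (self.meth_direction, self.expr_direction) in (
            ("hyper", "down"),
            ("hypo", "up"),
        )


def call_pairs(
    dm: list[DMResult],
    de: list[DEResult],
    join: list[tuple[str, str]],
    require_concordance: bool = False,
) -> list[MethDrivenPair]:
    """Emit every promoter (probe, gene) pair significant in both screens.

    A pair is emitted iff the probe's direction is hyper/hypo in the
    methylation screen AND the gene's direction is up/down in the
    expression screen AND (probe, gene) is in the promoter join. With
    ``require_concordance`` only hyper+down and hypo+up survive.
    Output is sorted by (gene_id, probe_id).
    """
    dm_sig = {r.probe_id: r for r in dm if r.direction in ("hyper", "hypo")}
    de_sig = {r.gene_id: r for r in de if r.direction in ("up", "down")}
    n_unknown = sum(
        1 for p, g in join
        if p not in {r.probe_id for r in dm} or g not in {r.gene_id for r in de}
    )
    if n_unknown:
        logger.info("call_pairs: %d join entries with ids absent from a screen", n_unknown)
    pairs = []
    for probe_id, gene_id in join:
        d = dm_sig.get(probe_id)
        e = de_sig.get(gene_id)
        if d is None or e is None:
            continue
        pair = MethDrivenPair(
            probe_id=probe_id,
            gene_id=gene_id,
            delta_beta=d.delta_beta,
            log2fc=e.log2fc,
            meth_direction=d.direction,
            expr_direction=e.direction,
        )
        if require_concordance and not pair.concordant:
            continue
        pairs.append(pair)
    pairs.sort(key=lambda p: (p.gene_id, p.probe_id))
    return pairs


def spearman_pair(beta_row, expr_row) -> tuple[float, float]:
    """Spearman correlation of promoter methylation against expression.

    Average ranks for ties; the p-value comes from exhaustive
    permutation when n <= 8 and the t-approximation otherwise.
    Incomplete pairs (NaN in either vector) are dropped; fewer than 3
    complete pairs, or a constant vector, gives (nan, nan).
    """
    x = np.asarray(beta_row, dtype=float)
    y = np.asarray(expr_row, dtype=float)
    if x.shape != y.shape:
        raise ValueError("beta and expression vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        logger.info("spearman_pair: only %d complete pairs, need >= 3", n)
        return math.nan, math.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("spearman_pair: zero-variance vector, rho undefined")
        return math.nan, math.nan
    if n <= EXACT_SPEARMAN_N:
        def _rho(a):
            return stats.spearmanr(a, y).statistic

        res = stats.permutation_test(
            (x,), _rho, permutation_type="pairings",
            n_resamples=np.inf, alternative="two-sided",
        )
        return float(res.statistic), float(res.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def annotate_correlation(
    pairs: list[MethDrivenPair],
    beta: "pd.DataFrame | np.ndarray",
    expr: "pd.DataFrame | np.ndarray",
) -> list[MethDrivenPair]:
    """Fill rho / rho_p on each pair from probe beta and gene expression.

    ``beta`` is indexed by probe_id and ``expr`` by gene_id, with the
    same sample columns in the same order.
    """
    beta = pd.DataFrame(beta)
    expr = pd.DataFrame(expr)
    for pair in pairs:
        if pair.probe_id in beta.index and pair.gene_id in expr.index:
            rho, p = spearman_pair(
                beta.loc[pair.probe_id].to_numpy(),
                expr.loc[pair.gene_id].to_numpy(),
            )
            pair.rho, pair.rho_p = rho, p
    return pairs


def rank_pairs(
    pairs: list[MethDrivenPair], top_k: int
) -> tuple[list[MethDrivenPair], list[MethDrivenPair]]:
    """Top-k hyper- and hypomethylated genes by promoter |delta-beta|.

    Each gene is represented by its max-|delta-beta| probe; within each
    methylation direction genes are ranked by |delta-beta| descending,
    ties broken by gene_id lexicographic order.
    """
    best: dict[str, MethDrivenPair] = {}
    for p in pairs:
        cur = best.get(p.gene_id)
        if cur is None or abs(p.delta_beta) > abs(cur.delta_beta):
            best[p.gene_id] = p
    key = lambda p: (-abs(p.delta_beta), p.gene_id)
    hyper = sorted((p for p in best.values() if p.meth_direction == "hyper"), key=key)
    hypo = sorted((p for p in best.values() if p.meth_direction == "hypo"), key=key)
    return hyper[:top_k], hypo[:top_k]


def pairs_to_tsv(pairs: list[MethDrivenPair], path) -> None:
    rows = [
        {
            "probe_id": p.probe_id, "gene_id": p.gene_id,
            "delta_beta": p.delta_beta, "log2fc": p.log2fc,
            "meth_direction": p.meth_direction, "expr_direction": p.expr_direction,
            "rho": p.rho, "rho_p": p.rho_p, "concordant": p.concordant,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=["probe_id", "gene_id", "delta_beta", "log2fc", "meth_direction",
                 "expr_direction", "rho", "rho_p", "concordant"],
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "MethDrivenPair",
    "call_pairs",
    "spearman_pair",
    "annotate_correlation",
    "rank_pairs",
    "pairs_to_tsv",
]
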
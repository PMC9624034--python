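"""Differential lncRNA expression between tumor and normal samples.

The built-in engine is a per-gene two-sided Mann-Whitney test on
CPM-normalized counts with Benjamini-Hochberg FDR control, matching the
rank-based screen used for small-RNA calls. Externally produced
differential-expression tables (e.g. from edgeR, limma or DESeq2) can
be imported in the same schema, and :func:`consensus` intersects any
mixture of built-in and imported result lists with direction
concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, mann_whitney

logger = logging.getLogger(__name__)

GROUPS = ("tumor", "normal")


@dataclass
class CountMatrix:
    """Raw RNA-seq counts, genes x samples, with tumor/normal labels."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # int, genes x samples
    group: np.ndarray = field(repr=False)  # per-sample, "tumor" or "normal"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.group = np.asarray(self.group, dtype=object)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for g in GROUPS:
            if not np.any(self.group == g):
                raise ValueError(f"group {g!r} is empty")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.group == "tumor"

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group: dict[str, str] | pd.Series):
        group = pd.Series(group)
        return cls(
            genes=list(df.index.astype(str)),
            samples=list(df.columns.astype(str)),
            counts=df.to_numpy(),
            group=group.reindex(df.columns).to_numpy(),
        )

    @classmethod
    def read_tsv(cls, counts_path, sheet_path):
        """Read a genes x samples count TSV plus a (sample, group) sheet."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
        return cls.from_dataframe(df, sheet.set_index("sample")["group"])

    def to_tsv(self, counts_path, sheet_path) -> None:
        pd.DataFrame(self.counts, index=self.genes, columns=self.samples).to_csv(
            counts_path, sep="\t", index_label="gene_id"
        )
        pd.DataFrame({"sample": self.samples, "group": self.group}).to_csv(
            sheet_path, sep="\t", index=False
        )


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float  # tumor vs normal, log2 ratio of mean CPM
    p: float
    fdr: float
    direction: str  # "up", "down" or "ns"


def cpm_normalize(m: CountMatrix, pseudocount: float = 0.5) -> np.ndarray:
    """Counts-per-million with a pseudocount added to every cell.

    value[g, s] = (counts[g, s] + pc) / (library_size[s] + 2 * pc * n_genes) * 1e6

    Strictly positive for pc > 0; scale-invariant per sample at pc = 0.
    """
    counts = m.counts.astype(float)
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"zero-total sample(s): {[m.samples[i] for i in zero]}")
    denom = lib + 2.0 * pseudocount * len(m.genes)
    return (counts + pseudocount) / denom * 1e6


def _direction(log2fc: float, fdr: float, alpha: float, fc_min: float) -> str:
    if fdr < alpha and log2fc >= np.log2(fc_min):
        return "up"
    if fdr < alpha and log2fc <= -np.log2(fc_min):
        return "down"
    return "ns"


def rank_test_de(
    m: CountMatrix,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = 0.5,
) -> list[DEResult]:
    """Per-gene Mann-Whitney differential expression on CPM values.

    log2 fold change is the log2 ratio of group mean CPMs (tumor over
    normal); p-values are BH-adjusted across all genes. All-constant
    genes get p = 1, log2fc = 0, direction "ns".
    """
    for g in GROUPS:
        if np.sum(m.group == g) < 2:
            raise ValueError(f"need >= 2 samples in group {g!r}")
    cpm = cpm_normalize(m, pseudocount)
    tmask = m.tumor_mask
    pvals = np.empty(len(m.genes))
    l2fc = np.empty(len(m.genes))
    for i in range(len(m.genes)):
        row = cpm[i]
        t, n = row[tmask], row[~tmask]
        if np.all(row == row[0]):
            pvals[i], l2fc[i] = 1.0, 0.0
            continue
        _, pvals[i] = mann_whitney(t, n)
        l2fc[i] = np.log2(t.mean() / n.mean())
    fdr = bh_adjust(pvals)
    return [
        DEResult(g, float(l2fc[i]), float(pvals[i]), float(fdr[i]),
                 _direction(l2fc[i], fdr[i], alpha, fc_min))
        for i, g in enumerate(m.genes)
    ]


def consensus(
    results: list[list[DEResult]], alpha: float = 0.05, fc_min: float = 2.0,
    require_concordance: bool = True,
) -> list[tuple[str, str]]:
    """Genes significant in every method, with agreeing direction.

    A gene is retained iff in EVERY result list it has fdr < alpha and
    |log2fc| >= log2(fc_min); with ``require_concordance`` the sign of
    log2fc must also agree across methods (conflicts are dropped, not
    errors). Returns sorted (gene_id, direction) tuples.
    """
    if not results:
        return []
    universe = {r.gene_id for r in results[0]}
    for rl in results[1:]:
        if {r.gene_id for r in rl} != universe:
            raise ValueError("methods do not cover the same gene universe")
    kept: dict[str, str] | None = None
    thr = np.log2(fc_min)
    for rl in results:
        sig = {
            r.gene_id: ("up" if r.log2fc > 0 else "down")
            for r in rl
            if r.fdr < alpha and abs(r.log2fc) >= thr
        }
        if kept is None:
            kept = sig
        else:
            common = kept.keys() & sig.keys()
            if require_concordance:
                common = {g for g in common if kept[g] == sig[g]}
            kept = {g: kept[g] for g in common}
    n_in = len({r.gene_id for rl in results for r in rl})
    logger.info("consensus retained %d of %d genes", len(kept), n_in)
    return sorted(kept.items())


def results_to_tsv(results: list[DEResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)


def read_de_table(path, alpha: float = 0.05, fc_min: float = 2.0) -> list[DEResult]:
    """Import an external DE table (gene_id, log2fc, p, fdr [, direction]).

    Direction is recomputed from the stated thresholds so imported and
    built-in tables behave identically in :func:`consensus`.
    """
    df = pd.read_csv(path, sep="\t")
    return [
        DEResult(
            str(r.gene_id), float(r.log2fc), float(r.p), float(r.fdr),
            _direction(float(r.log2fc), float(r.fdr), alpha, fc_min),
        )
        for r in df.itertuples(index=False)
    ]


__all__ = [
    "CountMatrix",
    "DEResult",
    "cpm_normalize",
    "rank_test_de",
    "consensus",
    "results_to_tsv",
    "read_de_table",
]
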
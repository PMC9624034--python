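"""End-to-end orchestration of the screen and the validation arm.

The screen runs annotation -> differential expression -> differential
methylation -> DMR detection -> integration from file-based inputs,
persisting every intermediate as TSV and writing a machine-readable
run manifest (config hash, seed, input checksums, per-stage record
counts). The validation arm runs BSP clone calling, the group
comparison, ROC/Youden cut-off selection and the Kaplan-Meier /
log-rank split. All thresholds default to the screen's canonical
values: alpha 0.05, fold change 2, DMR cutoff 0.2 with 100 resamples
and at least 2 probes, promoter window -2500/+1000.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, biomarker, bsp, diffexpr, diffmeth, integrate
from . import simulate as sim
from . import survival as surv

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Single source of analysis thresholds, defaulting to the
    screen's published operating point."""

    alpha: float = 0.05
    fc_min: float = 2.0
    dmr_cutoff: float = 0.2
    dmr_min_probes: int = 2
    dmr_resamples: int = 100
    dmr_max_gap: int = 500
    upstream: int = 2500
    downstream: int = 1000
    require_concordance: bool = False
    biotypes: tuple[str, ...] = ("lincRNA", "antisense")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["biotypes"] = list(d["biotypes"])
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: ScreenConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_screen(
    manifest_path,
    gtf_path,
    beta_path,
    counts_path,
    sheet_path,
    outdir,
    cfg: ScreenConfig | None = None,
) -> dict:
    """Run the full methylation-driven lncRNA screen from files.

    Returns the run manifest dict (also written to manifest.json).
    """
    cfg = cfg or ScreenConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "manifest": str(manifest_path), "gtf": str(gtf_path),
        "beta": str(beta_path), "counts": str(counts_path), "sheet": str(sheet_path),
    }
    stage_counts: dict[str, int] = {}
    t0 = time.time()

    probes = annotation.read_manifest(manifest_path)
    transcripts = annotation.read_gtf_lnc(gtf_path, set(cfg.biotypes))
    windows = annotation.promoter_windows(transcripts, cfg.upstream, cfg.downstream)
    join = annotation.join_probes_to_promoters(probes, windows)
    annotation.windows_to_bed(windows, outdir / "promoters.bed")
    annotation.pairs_to_tsv(join, outdir / "join.tsv")
    stage_counts.update(
        probes=len(probes), transcripts=len(transcripts), join_pairs=len(join)
    )
    logger.info("annotation: %d probes, %d windows, %d join pairs [%.1fs]",
                len(probes), len(windows), len(join), time.time() - t0)

    counts = diffexpr.CountMatrix.read_tsv(counts_path, sheet_path)
    de = diffexpr.rank_test_de(counts, cfg.alpha, cfg.fc_min)
    diffexpr.results_to_tsv(de, outdir / "de.tsv")
    stage_counts["de_genes"] = sum(r.direction != "ns" for r in de)

    beta = diffmeth.BetaMatrix.read_tsv(beta_path, sheet_path)
    dm = diffmeth.probe_dm(beta, cfg.alpha)
    diffmeth.dm_results_to_tsv(dm, outdir / "dm.tsv")
    stage_counts["probes_tested"] = len(dm)
    stage_counts["dm_probes"] = sum(r.direction != "ns" for r in dm)

    dmrs = diffmeth.find_dmrs(
        beta, probes, cfg.dmr_cutoff, cfg.dmr_min_probes,
        cfg.dmr_resamples, cfg.dmr_max_gap, cfg.seed,
    )
    diffmeth.dmrs_to_tsv(dmrs, outdir / "dmrs.tsv")
    stage_counts["dmrs"] = len(dmrs)

    pairs = integrate.call_pairs(dm, de, join, cfg.require_concordance)
    beta_df = pd.DataFrame(beta.beta, index=beta.probes, columns=beta.samples)
    cpm_df = pd.DataFrame(
        diffexpr.cpm_normalize(counts), index=counts.genes, columns=counts.samples
    )
    integrate.annotate_correlation(pairs, beta_df, cpm_df)
    integrate.pairs_to_tsv(pairs, outdir / "pairs.tsv")
    stage_counts["pairs"] = len(pairs)
    if not pairs:
        logger.warning("screen produced an empty pair table")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {k: _sha256(v) for k, v in inputs.items()},
        "counts": stage_counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("screen finished in %.1fs: %s", time.time() - t0, stage_counts)
    return manifest


def run_validation(
    ref_path,
    clones_dir,
    sheet_path,
    outdir,
    clinical_path=None,
    cfg: ScreenConfig | None = None,
    min_clones: int = 10,
    paired: bool = True,
) -> dict:
    """Run the validation arm: BSP -> group test -> ROC -> survival.

    The per-sample BSP methylation rate is the marker for both the ROC
    analysis (tumor = positive) and, joined to the clinical table when
    one is supplied, the Kaplan-Meier median split. Without a clinical
    table the survival stage is skipped with a log message.
    """
    cfg = cfg or ScreenConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_seqs = annotation.read_fasta(ref_path)
    name, seq = next(iter(ref_seqs.items()))
    amplicon = bsp.Amplicon.from_seq(name, seq)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)

    summaries = []
    clone_rows = []
    for row in sheet.itertuples(index=False):
        fasta = Path(clones_dir) / f"{row.sample}.fa"
        clones = annotation.read_fasta(fasta)
        calls = [
            bsp.call_clone(amplicon, cseq, clone_id=cid)
            for cid, cseq in clones.items()
        ]
        for c in calls:
            clone_rows.append(
                {"sample": row.sample, "clone_id": c.clone_id,
                 "conversion_rate": c.conversion_rate, "passed_qc": c.passed_qc,
                 "calls": "".join(
                     {"methylated": "1", "unmethylated": "0", "ambiguous": "?"}[x]
                     for x in c.calls
                 )}
            )
        summaries.append(
            bsp.sample_summary(calls, row.sample, row.group, min_clones=min_clones)
        )
    pd.DataFrame(clone_rows).to_csv(outdir / "bsp_clones.tsv", sep="\t", index=False)
    summary_df = pd.DataFrame(
        [{"sample": s.sample_id, "group": s.group, "n_clones": s.n_clones,
          "rate": s.rate} for s in summaries]
    )
    summary_df.to_csv(outdir / "bsp_summary.tsv", sep="\t", index=False)

    stat, group_p = bsp.compare_groups(summaries, paired=paired)
    rates = np.array([s.rate for s in summaries])
    labels = np.array([1 if s.group == "tumor" else 0 for s in summaries])
    roc_res = biomarker.roc(rates, labels, positive_high=True)
    biomarker.roc_to_tsv(roc_res, outdir / "roc.tsv")

    report = {
        "n_samples": len(summaries),
        "mean_rate_tumor": float(rates[labels == 1].mean()),
        "mean_rate_normal": float(rates[labels == 0].mean()),
        "group_test_statistic": float(stat),
        "group_test_p": float(group_p),
        "paired": paired,
        "auc": roc_res.auc,
        "youden_cutoff": roc_res.youden_cutoff,
        "youden_j": roc_res.youden_j,
        "sens_at_cutoff": roc_res.sens_at_cutoff,
        "spec_at_cutoff": roc_res.spec_at_cutoff,
    }

    if clinical_path is not None and Path(clinical_path).exists():
        clinical = surv.read_clinical_tsv(clinical_path)
        rate_by_sample = {s.sample_id: s.rate for s in summaries}
        recs = [
            dataclasses.replace(r, marker=rate_by_sample.get(r.sample_id, r.marker))
            for r in clinical
            if not np.isnan(rate_by_sample.get(r.sample_id, r.marker))
        ]
        recs = surv.dichotomize(recs)
        for grp in ("high", "low"):
            curve = surv.km_curve([r for r in recs if r.group == grp])
            surv.km_to_tsv(curve, outdir / f"km_{grp}.tsv")
        chi2, p = surv.logrank(recs)
        report["logrank_chi2"] = float(chi2)
        report["logrank_p"] = float(p)
        report["n_high"] = sum(r.group == "high" for r in recs)
        report["n_low"] = sum(r.group == "low" for r in recs)
    else:
        logger.info("no clinical table: survival stage skipped")
        report["survival"] = "skipped (no clinical table)"

    with open(outdir / "validation.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_demo(outdir, seed: int = 0, sim_cfg: sim.SimConfig | None = None,
             cfg: ScreenConfig | None = None) -> dict:
    """Simulate a full synthetic cohort, then run both pipeline arms.

    Returns {"truth": ..., "screen": manifest, "validation": report,
    "recovery": fraction of planted driver genes present in the pair
    table}.
    """
    outdir = Path(outdir)
    sim_cfg = sim_cfg or sim.SimConfig(seed=seed)
    cfg = cfg or ScreenConfig(seed=seed)
    fixdir = outdir / "fixtures"
    truth = sim.simulate_all(sim_cfg, fixdir)
    screen_manifest = run_screen(
        fixdir / "manifest.tsv", fixdir / "lnc.gtf", fixdir / "beta.tsv",
        fixdir / "counts.tsv", fixdir / "samples.tsv", outdir / "screen", cfg,
    )
    validation = run_validation(
        fixdir / "bsp_ref.fa", fixdir / "bsp_clones", fixdir / "bsp_sheet.tsv",
        outdir / "validation", clinical_path=fixdir / "clinical.tsv", cfg=cfg,
    )
    pairs = pd.read_csv(outdir / "screen" / "pairs.tsv", sep="\t")
    recovered_genes = set(pairs["gene_id"].astype(str)) if len(pairs) else set()
    drivers = set(truth.driver_genes)
    recovery = len(recovered_genes & drivers) / len(drivers) if drivers else float("nan")
    false_pairs = int(
        sum(1 for g in pairs["gene_id"].astype(str) if g not in drivers)
    ) if len(pairs) else 0
    summary = {
        "screen": screen_manifest,
        "validation": validation,
        "n_driver_genes": len(drivers),
        "driver_recovery": recovery,
        "false_pair_rows": false_pairs,
    }
    with open(outdir / "demo_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


__all__ = ["ScreenConfig", "run_screen", "run_validation", "run_demo"]
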
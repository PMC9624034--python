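"""Synthetic fixtures with planted ground truth for the whole screen.

Every generator emulates the statistical structure the analysis
assumes: beta-distributed array methylation with planted promoter
hyper/hypomethylation, negative-binomial RNA-seq counts with planted
fold changes anticorrelated with promoter methylation, bisulfite clone
sequences with per-CpG methylation probabilities and imperfect
conversion, and exponential survival times with group-dependent
hazards. Each generator draws from its own pseudo-random stream
derived from the master seed by a fixed offset, so a partial rerun of
one generator reproduces its output exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    ProbeRecord,
    TranscriptRecord,
    promoter_windows,
    write_fasta,
)
from .bsp import Amplicon
from .diffexpr import CountMatrix
from .diffmeth import BetaMatrix
from .survival import SurvivalRecord

# fixed per-generator stream offsets
_STREAM = {"annotation": 11, "methylation": 23, "counts": 37, "bsp": 53, "survival": 71}


def _rng(cfg: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[stream]])


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Effect-size defaults echo the regimes the screen is designed for:
    planted promoter delta-beta of 0.5, two-fold expression changes,
    clone methylation probabilities of 0.361 (tumor) vs 0.055 (normal),
    and a three-fold hazard ratio for the high-methylation group.
    """

    seed: int = 0
    n_tumor: int = 20
    n_normal: int = 20
    n_genes: int = 120
    n_probes: int = 800
    frac_driver: float = 0.1
    frac_hyper: float = 0.7  # of drivers; the rest are hypomethylated
    delta_beta_planted: float = 0.5
    log2fc_planted: float = 2.0
    nb_dispersion: float = 0.2
    beta_shape_null: tuple[float, float] = (2.0, 2.0)
    missing_rate: float = 0.0
    probes_per_driver: int = 5
    driver_probe_spacing: int = 80  # bp between planted promoter probes
    frac_probes_in_promoters: float = 0.3
    linkage: bool = True  # scale driver expression by promoter methylation
    baseline_log_mean: float = 5.3  # log count scale, ~200 counts
    hazard_ratio: float = 3.0
    baseline_hazard: float = float(np.log(2) / 60.0)  # median 60 months
    censor_rate: float = 0.3
    n_bsp_pairs: int = 18
    clones_per_sample: int = 10
    clone_meth_p_tumor: float = 0.361
    clone_meth_p_normal: float = 0.055
    conversion_eff: float = 0.99
    amplicon_len: int = 360
    amplicon_n_cpg: int = 20

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_shape_null"] = list(d["beta_shape_null"])
        return d


@dataclass
class TruthTable:
    """Planted truth consistent with the emitted matrices."""

    driver_genes: dict[str, dict] = field(default_factory=dict)
    # gene_id -> {"direction": hyper/hypo, "delta_beta": ..., "log2fc": ...,
    #             "probe_ids": [...]}
    join: list[tuple[str, str]] = field(default_factory=list)
    dmr_spans: list[dict] = field(default_factory=list)
    sample_groups: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "driver_genes": self.driver_genes,
                    "join": [list(p) for p in self.join],
                    "dmr_spans": self.dmr_spans,
                    "sample_groups": self.sample_groups,
                },
                fh, indent=1, sort_keys=True,
            )


@dataclass
class AnnotationFixture:
    probes: list[ProbeRecord]
    transcripts: list[TranscriptRecord]
    genome: dict[str, str]
    truth: TruthTable


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _island_seq(rng: np.random.Generator, n: int) -> str:
    """High-GC sequence with frequent CpG dinucleotides."""
    out = []
    while len(out) < n:
        if rng.random() < 0.25:
            out.extend("CG")
        else:
            out.append(rng.choice(list("ACGT"), p=[0.18, 0.33, 0.33, 0.16]))
    return "".join(out[:n])


def gen_annotation(cfg: SimConfig) -> AnnotationFixture:
    """Toy genome, lncRNA GTF and probe manifest with a known join.

    Genes alternate between two chromosomes and strands; driver genes
    carry a clustered block of promoter probes (the planted DMR span)
    and a CpG-island-like promoter sequence. The ground-truth join is
    an exhaustive containment scan of every probe against every
    promoter window.
    """
    rng = _rng(cfg, "annotation")
    spacing, tx_len, margin = 8000, 1500, 20000
    chroms = ["chr1", "chr2"]
    transcripts = []
    for i in range(cfg.n_genes):
        chrom = chroms[i % 2]
        slot = i // 2
        start = margin + slot * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"LNC{i:04d}"
        transcripts.append(
            TranscriptRecord(
                gene_id=gid, transcript_id=f"{gid}.T1", gene_name=gid,
                gene_type="lincRNA" if i % 3 else "antisense",
                chrom=chrom, start=start, end=start + tx_len, strand=strand,
            )
        )
    windows = promoter_windows(transcripts)
    win_by_gene = {w.gene_id: w for w in windows}

    n_driver = max(1, round(cfg.frac_driver * cfg.n_genes))
    driver_idx = sorted(rng.choice(cfg.n_genes, size=n_driver, replace=False))
    n_hyper = max(1, round(cfg.frac_hyper * n_driver)) if n_driver > 1 else 1

    truth = TruthTable()
    probes: list[ProbeRecord] = []
    pid = 0
    for k, gi in enumerate(driver_idx):
        t = transcripts[gi]
        w = win_by_gene[t.gene_id]
        direction = "hyper" if k < n_hyper else "hypo"
        # planted probe block just upstream of the TSS, inside the window
        first = w.tss - cfg.driver_probe_spacing * cfg.probes_per_driver
        first = max(first, w.start)
        ids = []
        for j in range(cfg.probes_per_driver):
            pos = first + j * cfg.driver_probe_spacing
            probes.append(ProbeRecord(f"cg{pid:06d}", w.chrom, pos, "+"))
            ids.append(f"cg{pid:06d}")
            pid += 1
        db = cfg.delta_beta_planted if direction == "hyper" else -cfg.delta_beta_planted
        fc = -cfg.log2fc_planted if direction == "hyper" else cfg.log2fc_planted
        truth.driver_genes[t.gene_id] = {
            "direction": direction, "delta_beta": db, "log2fc": fc, "probe_ids": ids,
        }
        truth.dmr_spans.append(
            {"chrom": w.chrom, "start": first,
             "end": first + (cfg.probes_per_driver - 1) * cfg.driver_probe_spacing + 1,
             "probe_ids": ids, "gene_id": t.gene_id, "direction": direction}
        )

    # remaining probes: some in non-driver promoters, rest intergenic,
    # all kept out of driver promoter windows so planted runs stay intact
    driver_windows = [win_by_gene[transcripts[gi].gene_id] for gi in driver_idx]
    non_driver_windows = [
        w for w in windows if w.gene_id not in truth.driver_genes
    ]
    n_rest = cfg.n_probes - len(probes)
    n_promoter_rest = max(0, round(cfg.frac_probes_in_promoters * cfg.n_probes)
                          - len(probes))
    chrom_len = {c: max(t.end for t in transcripts if t.chrom == c) + 5000
                 for c in chroms}
    used = {(p.chrom, p.pos) for p in probes}

    def _in_driver_window(chrom: str, pos: int) -> bool:
        return any(w.chrom == chrom and w.start <= pos < w.end for w in driver_windows)

    placed = 0
    while placed < n_rest:
        if placed < n_promoter_rest and non_driver_windows:
            w = non_driver_windows[rng.integers(len(non_driver_windows))]
            pos = int(rng.integers(w.start, w.end))
            chrom = w.chrom
        else:
            chrom = chroms[int(rng.integers(2))]
            pos = int(rng.integers(0, chrom_len[chrom]))
        if (chrom, pos) in used or _in_driver_window(chrom, pos):
            continue
        probes.append(ProbeRecord(f"cg{pid:06d}", chrom, pos, "+"))
        used.add((chrom, pos))
        pid += 1
        placed += 1

    # exhaustive containment scan defines the ground-truth join
    truth.join = sorted(
        {
            (p.probe_id, w.gene_id)
            for p in probes
            for w in windows
            if p.chrom == w.chrom and w.start <= p.pos < w.end
        },
        key=lambda pg: (pg[1], pg[0]),
    )

    genome = {c: list(_random_seq(rng, chrom_len[c])) for c in chroms}
    for gi in driver_idx:
        w = win_by_gene[transcripts[gi].gene_id]
        a = max(w.tss - 400, 0)
        island = _island_seq(rng, 600)
        genome[w.chrom][a : a + 600] = island[: len(genome[w.chrom]) - a]
    genome = {c: "".join(s) for c, s in genome.items()}
    return AnnotationFixture(probes, transcripts, genome, truth)


def _sample_names(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    samples = [f"T{i + 1:02d}" for i in range(cfg.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(cfg.n_normal)
    ]
    group = np.array(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal, dtype=object)
    return samples, group


def gen_methylation(cfg: SimConfig, ann: AnnotationFixture) -> BetaMatrix:
    """Beta matrix with planted driver-promoter methylation shifts.

    Null probes draw iid Beta(a, b) in both groups; planted
    hypermethylated probes draw the normal group from a low-centred
    Beta and shift the tumor draws by +delta_beta (clipped to [0, 1]),
    mirrored for hypomethylated drivers.
    """
    rng = _rng(cfg, "methylation")
    samples, group = _sample_names(cfg)
    ann.truth.sample_groups = dict(zip(samples, group))
    a, b = cfg.beta_shape_null
    n = len(samples)
    beta = rng.beta(a, b, size=(len(ann.probes), n))
    probe_ix = {p.probe_id: i for i, p in enumerate(ann.probes)}
    tmask = group == "tumor"
    for info in ann.truth.driver_genes.values():
        lo, hi = (1.5, 8.5) if info["direction"] == "hyper" else (8.5, 1.5)
        shift = info["delta_beta"]
        for pid in info["probe_ids"]:
            i = probe_ix[pid]
            base = rng.beta(lo, hi, size=n)
            base[tmask] = np.clip(base[tmask] + shift, 0.0, 1.0)
            beta[i] = base
    if cfg.missing_rate > 0:
        mask = rng.random(beta.shape) < cfg.missing_rate
        beta[mask] = np.nan
    return BetaMatrix([p.probe_id for p in ann.probes], samples, beta, group)


def gen_counts(cfg: SimConfig, ann: AnnotationFixture,
               beta: BetaMatrix | None = None) -> CountMatrix:
    """Negative-binomial counts with planted driver fold changes.

    In linkage mode (the default, requires ``beta``) a driver gene's
    mean is scaled by 2^(-k * promoter beta) with k chosen so the
    tumor/normal fold change equals the planted log2fc; this couples
    expression to the actual methylation draws and induces a negative
    methylation-expression correlation. Otherwise a plain group
    multiplier is applied. Dispersion below 1e-8 falls back to Poisson.
    """
    rng = _rng(cfg, "counts")
    samples, group = _sample_names(cfg)
    genes = [t.gene_id for t in ann.transcripts]
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, 1.0, size=len(genes)))
    mu = np.tile(baseline[:, None], (1, len(samples)))
    tmask = group == "tumor"
    gene_ix = {g: i for i, g in enumerate(genes)}
    use_linkage = cfg.linkage and beta is not None and cfg.delta_beta_planted != 0
    if use_linkage:
        probe_ix = {p: i for i, p in enumerate(beta.probes)}
        k = cfg.log2fc_planted / cfg.delta_beta_planted
    for gid, info in ann.truth.driver_genes.items():
        gi = gene_ix[gid]
        if use_linkage:
            rows = [probe_ix[p] for p in info["probe_ids"] if p in probe_ix]
            mean_beta = np.nanmean(beta.beta[rows], axis=0)
            center = float(np.nanmean(mean_beta[~tmask]))
            mu[gi] = baseline[gi] * 2.0 ** (-k * (mean_beta - center))
        else:
            mu[gi, tmask] = baseline[gi] * 2.0 ** info["log2fc"]
    if cfg.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    return CountMatrix(genes, samples, counts.astype(np.int64), group)


@dataclass
class BSPFixture:
    amplicon: Amplicon
    clones: dict[str, list[str]]  # sample -> clone sequences
    sheet: pd.DataFrame  # sample, group, pair


def gen_bsp(cfg: SimConfig) -> BSPFixture:
    """Reference amplicon plus per-sample bisulfite clone sequences.

    Each CpG of each clone is methylated with the group's probability;
    unmethylated CpG cytosines and all non-CpG cytosines convert C->T
    with probability ``conversion_eff`` (failures stay C, mimicking
    incomplete conversion). Tumor/normal pairs share a pair index.
    """
    rng = _rng(cfg, "bsp")
    # backbone without accidental CpGs, then plant evenly spaced CpGs
    seq = list(_random_seq(rng, cfg.amplicon_len, gc=0.45))
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    gap = cfg.amplicon_len // (cfg.amplicon_n_cpg + 1)
    for j in range(cfg.amplicon_n_cpg):
        i = gap * (j + 1)
        seq[i], seq[i + 1] = "C", "G"
        if i + 2 < len(seq) and seq[i + 2] == "G" and seq[i + 1] == "C":
            seq[i + 2] = "A"
    # remove CpGs accidentally created at plant boundaries
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in {
            gap * (j + 1) for j in range(cfg.amplicon_n_cpg)
        }:
            seq[i] = "A"
    ref = Amplicon.from_seq("amplicon", "".join(seq))

    clones: dict[str, list[str]] = {}
    rows = []
    for pair in range(cfg.n_bsp_pairs):
        for group, meth_p in (
            ("tumor", cfg.clone_meth_p_tumor),
            ("normal", cfg.clone_meth_p_normal),
        ):
            sample = f"B{'T' if group == 'tumor' else 'N'}{pair + 1:02d}"
            rows.append({"sample": sample, "group": group, "pair": pair + 1})
            clones[sample] = [
                _make_clone(rng, ref, meth_p, cfg.conversion_eff)
                for _ in range(cfg.clones_per_sample)
            ]
    return BSPFixture(ref, clones, pd.DataFrame(rows))


def _make_clone(rng, ref: Amplicon, meth_p: float, conversion_eff: float) -> str:
    seq = list(ref.seq)
    cpg = set(ref.cpg_positions)
    for i, base in enumerate(ref.seq):
        if base != "C":
            continue
        if i in cpg:
            if rng.random() < meth_p:
                continue  # methylated: protected from conversion
        if rng.random() < conversion_eff:
            seq[i] = "T"
    return "".join(seq)


def gen_survival(cfg: SimConfig, groups: dict[str, str],
                 markers: dict[str, float] | None = None) -> list[SurvivalRecord]:
    """Exponential survival times with a hazard ratio for the high group.

    ``groups`` maps sample -> "high"/"low". With probability
    ``censor_rate`` a subject is censored at a uniform fraction of its
    event time; otherwise the event is observed.
    """
    if cfg.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = _rng(cfg, "survival")
    records = []
    for sample, grp in groups.items():
        h = cfg.baseline_hazard * (cfg.hazard_ratio if grp == "high" else 1.0)
        t = float(rng.exponential(1.0 / h))
        if rng.random() < cfg.censor_rate:
            t, event = t * float(rng.uniform(0.05, 1.0)), 0
        else:
            event = 1
        marker = markers.get(sample, float("nan")) if markers else float("nan")
        records.append(SurvivalRecord(sample, max(t, 1e-6), event, marker, grp))
    return records


def simulate_all(cfg: SimConfig, outdir) -> TruthTable:
    """Emit every fixture file plus the truth table into ``outdir``.

    Files: manifest.tsv, lnc.gtf, genome.fa, beta.tsv, counts.tsv,
    samples.tsv, bsp_ref.fa, bsp_clones/<sample>.fa, bsp_sheet.tsv,
    clinical.tsv, truth.json, config.json. Byte-identical for the same
    config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = gen_annotation(cfg)
    beta = gen_methylation(cfg, ann)
    counts = gen_counts(cfg, ann, beta)
    bsp_fix = gen_bsp(cfg)

    pd.DataFrame(
        [{"probe_id": p.probe_id, "chrom": p.chrom, "pos": p.pos, "strand": p.strand}
         for p in ann.probes]
    ).to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    with open(outdir / "lnc.gtf", "w") as fh:
        for t in ann.transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}"; gene_type "{t.gene_type}";'
            )
            fh.write(
                f"{t.chrom}\tsim\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
    write_fasta(ann.genome, outdir / "genome.fa")

    beta.to_tsv(outdir / "beta.tsv", outdir / "samples.tsv")
    counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")

    write_fasta({bsp_fix.amplicon.name: bsp_fix.amplicon.seq}, outdir / "bsp_ref.fa")
    clone_dir = outdir / "bsp_clones"
    clone_dir.mkdir(exist_ok=True)
    for sample, seqs in bsp_fix.clones.items():
        write_fasta(
            {f"{sample}_clone{i + 1:02d}": s for i, s in enumerate(seqs)},
            clone_dir / f"{sample}.fa",
        )
    bsp_fix.sheet.to_csv(outdir / "bsp_sheet.tsv", sep="\t", index=False)

    # clinical arm: high methylation burden (tumor BSP samples with
    # high clone methylation) against low; marker = true clone meth p
    groups = {}
    markers = {}
    for row in bsp_fix.sheet.itertuples(index=False):
        groups[row.sample] = "high" if row.group == "tumor" else "low"
        markers[row.sample] = (
            cfg.clone_meth_p_tumor if row.group == "tumor" else cfg.clone_meth_p_normal
        )
    clinical = gen_survival(cfg, groups, markers)
    pd.DataFrame(
        [{"sample": r.sample_id, "time": r.time, "event": r.event, "marker": r.marker}
         for r in clinical]
    ).to_csv(outdir / "clinical.tsv", sep="\t", index=False)

    ann.truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
    return ann.truth


__all__ = [
    "SimConfig",
    "TruthTable",
    "AnnotationFixture",
    "BSPFixture",
    "gen_annotation",
    "gen_methylation",
    "gen_counts",
    "gen_bsp",
    "gen_survival",
    "simulate_all",
]
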
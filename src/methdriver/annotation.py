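"""Probe-to-promoter annotation for 450K methylation arrays.

Parses a 4-column probe manifest (an hm450-style extract) and a
GENCODE-dialect GTF of lncRNA transcripts, builds strand-aware promoter
windows around each transcription start site, joins CpG probes to the
promoters that contain them, and predicts CpG islands in promoter
sequence with the Gardiner-Garden criteria.

All internal coordinates are 0-based half-open. GTF input is read as
1-based inclusive and converted on ingest; the manifest is declared
0-based (set ``one_based=True`` in :func:`read_manifest` for 1-based
manifests).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_UPSTREAM = 2500
DEFAULT_DOWNSTREAM = 1000


@dataclass(frozen=True)
class ProbeRecord:
    """A CpG probe anchored at the 0-based coordinate of the CpG's C."""

    probe_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"probe {self.probe_id}: negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"probe {self.probe_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    gene_id: str
    transcript_id: str
    gene_name: str
    gene_type: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter span containing the TSS, clipped at 0."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self):
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"window for {self.gene_id} does not contain its TSS")


@dataclass(frozen=True)
class CpGIsland:
    """A Gardiner-Garden CpG island relative to the query sequence."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float


class ManifestFormatError(ValueError):
    pass


def read_manifest(path, one_based: bool = False) -> list[ProbeRecord]:
    """Read a probe manifest TSV with columns probe_id, chrom, pos, strand.

    Positions are taken as 0-based unless ``one_based`` is set, in which
    case 1 is subtracted on ingest. Duplicate probe_ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["probe_id", "chrom", "pos", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest {path} lacks columns: {missing}")
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise ManifestFormatError(
                f"manifest {path} row {i + 2}: non-integer pos {row.pos!r}"
            ) from None
        if row.probe_id in seen:
            raise ManifestFormatError(f"duplicate probe_id {row.probe_id!r} in {path}")
        seen.add(row.probe_id)
        records.append(
            ProbeRecord(row.probe_id, row.chrom, pos - (1 if one_based else 0), row.strand)
        )
    return records


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().rstrip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        parts = field.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed GTF attribute field {field!r}")
        key, value = parts
        out[key] = value.strip().strip('"')
    return out


def read_gtf_lnc(path, biotypes: set[str]) -> list[TranscriptRecord]:
    """Read transcript records of the given gene biotypes from a GTF.

    Coordinates are converted from GTF 1-based inclusive to 0-based
    half-open. Gzip-transparent.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line[:80]!r}")
            if fields[2] != "transcript":
                continue
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand {strand!r} in GTF {path}")
            attrs = _parse_gtf_attributes(fields[8])
            if attrs.get("gene_type") not in biotypes:
                continue
            records.append(
                TranscriptRecord(
                    gene_id=attrs["gene_id"],
                    transcript_id=attrs["transcript_id"],
                    gene_name=attrs.get("gene_name", attrs["gene_id"]),
                    gene_type=attrs["gene_type"],
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=strand,
                )
            )
    return records


def promoter_windows(
    transcripts: list[TranscriptRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[PromoterWindow]:
    """One promoter window per transcript, strand-aware, clipped at 0.

    The window covers strand-relative offsets [-upstream, +downstream)
    around the TSS. On the plus strand the TSS is the transcript start;
    on the minus strand it is the last transcribed base (end - 1), and
    the genomic window is [tss - downstream + 1, tss + upstream + 1).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    windows = []
    for t in transcripts:
        if t.strand == "+":
            tss = t.start
            start, end = tss - upstream, tss + downstream
        else:
            tss = t.end - 1
            start, end = tss - downstream + 1, tss + upstream + 1
        start = max(start, 0)
        # keep the TSS inside even under extreme clipping
        end = max(end, tss + 1)
        windows.append(PromoterWindow(t.gene_id, t.chrom, start, end, t.strand, tss))
    return windows


def join_probes_to_promoters(
    probes: list[ProbeRecord], windows: list[PromoterWindow]
) -> list[tuple[str, str]]:
    """All (probe_id, gene_id) pairs where the probe lies in the window.

    Containment is half-open (start <= pos < end) on the shared
    chromosome; probe strand is ignored (a CpG is strand-symmetric).
    Pairs are deduplicated and sorted by (gene_id, probe_id).
    """
    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    pairs = set()
    for chrom, plist in by_chrom.items():
        positions = np.array([p.pos for p in plist])
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        ids = [plist[i].probe_id for i in order]
        for w in windows:
            if w.chrom != chrom:
                continue
            lo = np.searchsorted(positions, w.start, side="left")
            hi = np.searchsorted(positions, w.end, side="left")
            for i in range(lo, hi):
                pairs.add((ids[i], w.gene_id))
    return sorted(pairs, key=lambda pg: (pg[1], pg[0]))


def find_cpg_islands(
    seq: str, min_len: int = 200, min_gc: float = 0.5, min_oe: float = 0.6
) -> list[CpGIsland]:
    """Predict CpG islands by the Gardiner-Garden criteria.

    A 200-bp window (step 1) passes if GC fraction >= min_gc and the
    observed/expected CpG ratio (#CG x L) / (#C x #G) >= min_oe.
    Overlapping or adjacent passing windows are merged into maximal
    islands, and each merged island is re-validated against all three
    thresholds. N bases count toward window length but not toward the
    base or dinucleotide counts.
    """
    seq = seq.upper()
    L = len(seq)
    win = 200
    if L < min_len or L < win:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    if L >= 2:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    def _stats(a: int, b: int) -> tuple[float, float]:
        n = b - a
        c = cum_c[b] - cum_c[a]
        g = cum_g[b] - cum_g[a]
        # dinucleotides fully inside [a, b)
        cg = cum_cg[b - 1] - cum_cg[a]
        gc_frac = (c + g) / n
        oe = (cg * n) / (c * g) if c > 0 and g > 0 else 0.0
        return gc_frac, oe

    starts = np.arange(0, L - win + 1)
    c_w = cum_c[starts + win] - cum_c[starts]
    g_w = cum_g[starts + win] - cum_g[starts]
    cg_w = cum_cg[starts + win - 1] - cum_cg[starts]
    gc_ok = (c_w + g_w) / win >= min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_w = np.where((c_w > 0) & (g_w > 0), cg_w * win / (c_w * g_w), 0.0)
    passing = starts[gc_ok & (oe_w >= min_oe)]
    if passing.size == 0:
        return []

    # merge runs of passing windows whose spans overlap or touch
    islands = []
    run_start = passing[0]
    prev = passing[0]
    for s in passing[1:]:
        if s <= prev + win:  # window spans [s, s+win) and [prev, prev+win) touch
            prev = s
        else:
            islands.append((run_start, prev + win))
            run_start = prev = s
    islands.append((run_start, prev + win))

    out = []
    for a, b in islands:
        gc_frac, oe = _stats(a, b)
        if b - a >= min_len and gc_frac >= min_gc and oe >= min_oe:
            out.append(CpGIsland(int(a), int(b), float(gc_frac), float(oe)))
    return out


def windows_to_bed(windows: list[PromoterWindow], path) -> None:
    """Write promoter windows as BED6 (name = gene_id, score = TSS)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t{w.tss}\t{w.strand}\n")


def read_windows_bed(path) -> list[PromoterWindow]:
    """Read promoter windows from BED6 written by :func:`windows_to_bed`.

    The score column carries the TSS, making the round trip lossless.
    """
    windows = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, gene_id, score, strand = line.rstrip("\n").split("\t")
            windows.append(
                PromoterWindow(gene_id, chrom, int(start), int(end), strand, int(score))
            )
    return windows


def pairs_to_tsv(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["probe_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(r) for r in df[["probe_id", "gene_id"]].itertuples(index=False)]


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA reader returning name -> sequence."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


__all__ = [
    "ProbeRecord",
    "TranscriptRecord",
    "PromoterWindow",
    "CpGIsland",
    "ManifestFormatError",
    "read_manifest",
    "read_gtf_lnc",
    "promoter_windows",
    "join_probes_to_promoters",
    "find_cpg_islands",
    "windows_to_bed",
    "read_windows_bed",
    "pairs_to_tsv",
    "read_pairs_tsv",
    "read_fasta",
    "write_fasta",
]
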
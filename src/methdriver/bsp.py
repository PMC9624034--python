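"""Clone-level bisulfite-sequencing-PCR (BSP) methylation analysis.

Sanger-sequenced clones of a bisulfite-converted amplicon are compared
with the untreated reference: at each CpG cytosine, a retained C means
the site was methylated (protected from conversion) and a T means
unmethylated; any other base is ambiguous. The fraction of non-CpG
reference cytosines read as T is the bisulfite conversion rate, used
as per-clone QC. Only the top strand (C-to-T conversion) is modelled.

Clones with indels are pre-aligned to the reference with a global
Needleman-Wunsch alignment that scores match +1, mismatch -1, gap -2
and treats reference C vs clone T (and reference G vs clone A) as
matches so that conversion never penalizes the alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._stats import mann_whitney, wilcoxon_paired

METHYLATED, UNMETHYLATED, AMBIGUOUS = "methylated", "unmethylated", "ambiguous"
DEFAULT_CONVERSION_QC = 0.95


@dataclass(frozen=True)
class Amplicon:
    """Reference BSP amplicon with the 0-based index of each CpG's C."""

    name: str
    seq: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self):
        for i in self.cpg_positions:
            if not (self.seq[i] == "C" and i + 1 < len(self.seq) and self.seq[i + 1] == "G"):
                raise ValueError(f"position {i} of {self.name} is not the C of a CpG")

    @classmethod
    def from_seq(cls, name: str, seq: str) -> "Amplicon":
        seq = seq.upper()
        cpgs = tuple(i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        return cls(name, seq, cpgs)

    @property
    def non_cpg_c_positions(self) -> tuple[int, ...]:
        cpg = set(self.cpg_positions)
        return tuple(i for i, b in enumerate(self.seq) if b == "C" and i not in cpg)


@dataclass(frozen=True)
class CloneCall:
    clone_id: str
    calls: tuple[str, ...]  # per CpG site: methylated / unmethylated / ambiguous
    conversion_rate: float
    passed_qc: bool


@dataclass
class SampleMethylation:
    sample_id: str
    group: str
    n_clones: int  # passing clones
    rate: float  # methylated / (methylated + unmethylated), ambiguous excluded
    per_site_rates: np.ndarray = field(repr=False)


def _bisulfite_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN-"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = 1.0 if a == b else -1.0
    # bisulfite top strand: reference C read as T (and G as A on the
    # complementary readout) is not a mismatch
    mat["C", "T"] = 1.0
    mat["G", "A"] = 1.0
    for b in alphabet:
        mat["N", b] = mat[b, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _bisulfite_aligner()


def align_clone(ref_seq: str, clone_seq: str) -> str:
    """Project a clone onto reference coordinates by global alignment.

    Returns a string of len(ref_seq): the clone base aligned to each
    reference position, '-' where the clone has a deletion. Clone
    insertions relative to the reference are dropped.
    """
    aln = _ALIGNER.align(ref_seq.upper(), clone_seq.upper())[0]
    out = ["-"] * len(ref_seq)
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            out[t0 + k] = aln.query[q0 + k]
    return "".join(out)


def call_clone(
    ref: Amplicon,
    clone_seq: str,
    clone_id: str = "clone",
    qc_threshold: float = DEFAULT_CONVERSION_QC,
    align: bool = True,
) -> CloneCall:
    """Call per-CpG methylation of one clone against the reference.

    At each CpG cytosine: C -> methylated, T -> unmethylated, anything
    else (including a deletion) -> ambiguous. The conversion rate is
    the fraction of non-CpG reference cytosines read as T; a clone
    passes QC when it is at least ``qc_threshold``.
    """
    clone_seq = clone_seq.upper()
    if len(clone_seq) != len(ref.seq):
        if not align:
            raise ValueError(
                f"clone {clone_id}: length {len(clone_seq)} != reference "
                f"{len(ref.seq)} and alignment disabled"
            )
        clone_seq = align_clone(ref.seq, clone_seq)
    calls = []
    for i in ref.cpg_positions:
        base = clone_seq[i]
        if base == "C":
            calls.append(METHYLATED)
        elif base == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)
    non_cpg = ref.non_cpg_c_positions
    if non_cpg:
        converted = sum(1 for i in non_cpg if clone_seq[i] == "T")
        conversion = converted / len(non_cpg)
    else:
        conversion = 1.0  # no informative sites: cannot fail conversion QC
    return CloneCall(clone_id, tuple(calls), conversion, conversion >= qc_threshold)


def sample_summary(
    calls: list[CloneCall],
    sample_id: str = "sample",
    group: str = "tumor",
    min_clones: int = 10,
) -> SampleMethylation:
    """Per-sample methylation rate over QC-passing clones.

    Ambiguous calls are excluded from both numerator and denominator,
    overall and per site. Fewer passing clones than ``min_clones``
    warns; zero passing clones is an error.
    """
    passing = [c for c in calls if c.passed_qc]
    if not passing:
        raise ValueError(f"sample {sample_id}: no clones passed conversion QC")
    if len(passing) < min_clones:
        warnings.warn(
            f"sample {sample_id}: only {len(passing)} passing clones "
            f"(protocol expects {min_clones})",
            stacklevel=2,
        )
    mat = np.array([c.calls for c in passing], dtype=object)
    meth = mat == METHYLATED
    unmeth = mat == UNMETHYLATED
    total = meth.sum() + unmeth.sum()
    if total == 0:
        raise ValueError(f"sample {sample_id}: all calls ambiguous")
    with np.errstate(invalid="ignore", divide="ignore"):
        site_denom = meth.sum(axis=0) + unmeth.sum(axis=0)
        per_site = np.where(site_denom > 0, meth.sum(axis=0) / np.maximum(site_denom, 1),
                            np.nan)
    return SampleMethylation(
        sample_id=sample_id,
        group=group,
        n_clones=len(passing),
        rate=float(meth.sum() / total),
        per_site_rates=per_site.astype(float),
    )


def compare_groups(
    samples: list[SampleMethylation], paired: bool = False
) -> tuple[float, float]:
    """Two-sided test of tumor vs normal per-sample methylation rates.

    Mann-Whitney for independent groups; Wilcoxon signed-rank when
    ``paired`` (samples must then be in matching order within groups).
    """
    tumor = [s.rate for s in samples if s.group == "tumor"]
    normal = [s.rate for s in samples if s.group == "normal"]
    if not tumor or not normal:
        raise ValueError("both groups must be present")
    if paired:
        if len(tumor) != len(normal):
            raise ValueError("paired comparison needs equal group sizes")
        return wilcoxon_paired(tumor, normal)
    return mann_whitney(tumor, normal)


def lollipop_matrix(calls: list[CloneCall]) -> pd.DataFrame:
    """QUMA-style clones x CpG-sites matrix: 1 methylated, 0 not, ? ambiguous."""
    passing = [c for c in calls if c.passed_qc]
    code = {METHYLATED: "1", UNMETHYLATED: "0", AMBIGUOUS: "?"}
    data = [[code[x] for x in c.calls] for c in passing]
    return pd.DataFrame(
        data,
        index=[c.clone_id for c in passing],
        columns=[f"CpG_{i + 1}" for i in range(len(passing[0].calls))] if passing else [],
    )


__all__ = [
    "Amplicon",
    "CloneCall",
    "SampleMethylation",
    "align_clone",
    "call_clone",
    "sample_summary",
    "compare_groups",
    "lollipop_matrix",
    "METHYLATED",
    "UNMETHYLATED",
    "AMBIGUOUS",
]
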
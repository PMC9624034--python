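# methdriver

A tested, reusable pipeline for screening **DNA-methylation-driven
lncRNAs** in tumor/normal cohorts, with the downstream validation
toolkit used to establish a promoter-methylation biomarker:
bisulfite-sequencing-PCR (BSP) clone analysis, ROC cut-off selection
and Kaplan–Meier survival stratification. The motivating application
is colorectal cancer profiled on the Illumina 450K array plus RNA-seq,
but nothing in the package is tissue-specific.

## What it computes

**The screen.** CpG probes from a 450K-style manifest are joined to
lncRNA promoter windows — the strand-aware span from −2500 to +1000 bp
around each transcription start site — built from a GENCODE-style GTF.
Per probe, differential methylation is the mean beta-value difference
Δβ = β̄(tumor) − β̄(normal) with a two-sided Mann–Whitney test;
per gene, differential expression is a rank test on CPM-normalized
counts with log2 fold change from group mean CPMs; both screens use
Benjamini–Hochberg FDR. A *methylation-driven* lncRNA pair is a
(probe, gene) pair with the probe in the gene's promoter and both
screens significant (FDR < 0.05, |FC| ≥ 2), optionally restricted to
the concordant hyper+down / hypo+up configurations and annotated with
the Spearman correlation ρ between promoter methylation and
expression. Differentially methylated regions (DMRs) are called
bumphunter-style: maximal runs of ≥ 2 neighbouring probes with
|Δβ| ≥ 0.2 and a common sign, with empirical p-values from 100
group-label permutations of the maximum region area Σ|Δβ|.

**The validation arm.** BSP clones are compared with the reference
amplicon QUMA-style (CpG C retained → methylated, C→T → unmethylated),
QC'd on the bisulfite conversion rate of non-CpG cytosines (≥ 0.95),
and summarized into per-sample methylation rates. The rate is then
evaluated as a classifier via the ROC curve, with the operating point
chosen by maximizing the Youden index J = sensitivity + specificity − 1,
and as a prognostic marker via a median split with Kaplan–Meier
curves and the two-group log-rank test. Gardiner–Garden CpG-island
prediction (≥ 200 bp, GC ≥ 0.5, observed/expected CpG ≥ 0.6) is
included for amplicon design checks.

**Synthetic cohorts.** `methdriver.simulate` generates every input
with planted truth — beta-distributed methylation with planted
promoter shifts, negative-binomial counts whose driver-gene means are
coupled to the drawn promoter methylation (inducing negative ρ),
bisulfite clones with per-CpG methylation probabilities and imperfect
conversion, and exponential survival times with a group hazard ratio —
so the whole pipeline is testable end to end without any downloads.

## Worked example

```bash
methdriver pipeline demo --seed 1 -o demo_out
```

simulates the default cohort (20 tumor vs 20 normal arrays, 120
lncRNAs, 800 probes, 12 planted driver genes; 18 BSP tumor/normal
pairs with clone methylation probabilities 0.361 vs 0.055) and runs
both arms. It prints, among other fields:

```
"driver_recovery": 1.0,
"screen_counts": {"de_genes": 12, "dm_probes": 61, "dmrs": 12,
                  "join_pairs": 470, "pairs": 60, ...},
"validation": {"auc": 0.97, "group_test_p": 0.0002,
               "logrank_p": 1.2e-05, ...}
```

meaning: all 12 planted methylation-driven genes were recovered in the
pair table (60 probe–gene pairs from 470 promoter join candidates; 61
significant probes of whom 60 are planted), the 12 planted promoter
blocks were each called as a DMR, the BSP methylation rate separates
tumors from normals (AUC near 1 at these effect sizes, signed-rank
p ≈ 2·10⁻⁴), and the high-methylation group has significantly worse
survival. Exact numbers vary slightly with the seed.

Every stage is also exposed separately (`methdriver annotate ...`,
`de ...`, `dm ...`, `integrate ...`, `bsp call`, `roc`,
`survival km`, `simulate`) over file-based TSV/GTF/FASTA interfaces,
and the same functionality is importable from the library modules.

## Layout

| module | contents |
| --- | --- |
| `methdriver.annotation` | manifest/GTF parsing, promoter windows, probe join, CpG islands |
| `methdriver.diffexpr` | CPM, rank-test DE, multi-method consensus |
| `methdriver.diffmeth` | per-probe Δβ screen, bump-hunting DMRs |
| `methdriver.integrate` | methylation-driven pair calling, Spearman ρ, rankings |
| `methdriver.bsp` | clone calling, conversion QC, sample summaries, group tests |
| `methdriver.biomarker` | ROC, AUC, Youden cut-off |
| `methdriver.survival` | median split, Kaplan–Meier, log-rank |
| `methdriver.simulate` | synthetic cohorts with planted truth |
| `methdriver.pipeline` | orchestration, run manifests; `methdriver.cli` wraps it |

See `docs/methods.md` for the statistical conventions, simulation
model and known limitations.
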
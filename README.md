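# igrep

Analysis pipeline for peripheral B-cell receptor heavy-chain (VH) repertoires,
built around UMI-tagged amplicon sequencing of sorted B-cell subsets (naive N,
double-negative DN, memory M, plasmablasts P) at two timepoints (baseline BL
and six-month follow-up FUP6), with an optional serum-proteomics arm that
matches identified Ig peptides back onto the subject's own VH transcriptome.

The package is aimed at immunologists and bioinformaticians who want the full
chain — raw UMI reads to comparative repertoire statistics — as small,
testable, deterministic components, plus a synthetic repertoire generator so
every stage can be validated end to end without access to patient data.

## What it computes

**UMI consensus.** Reads are filtered at mean Phred ≥ 20, grouped by the exact
(subset index tag, UMI) pair, and collapsed by Phred-weighted majority vote.
A consensus is valid only with ≥ 5 reads per UMI and a mean within-group
mismatch rate ≤ 0.1. Identical consensus sequences under different UMIs merge
into one unique sequence with a copy number (`duplicate_count`).

**Annotation.** Germline V/J segments are assigned by best ungapped identity
against a packaged toy germline set (families IGHV1–IGHV5); the junction —
CDR3 plus its conserved Cys/Trp-or-Phe anchor residues — is cut out between
the projected anchor codons. SHM frequency is the mismatch fraction over the
germline-alignable V region 5′ of the junction.

**Clones.** Productive sequences are partitioned by (same V gene, same J gene,
same junction length) and clustered by single linkage on the length-normalized
junction Hamming distance,

d(a, b) = (1/L) Σᵢ 1[aᵢ ≠ bᵢ],   clone edge ⇔ d ≤ 0.1.

**Diversity.** Clone abundances pᵢ give Hill numbers

ᵠD = (Σᵢ pᵢᵠ)^(1/(1−q)),  with ⁰D = richness and ¹D = exp(−Σᵢ pᵢ ln pᵢ),

estimated on a fixed-depth bootstrap: 126 unique sequences drawn with
replacement, 200 repetitions, samples admitted only with ≥ 100 unique
sequences. The same bootstrap drives the BL↔FUP6 clonal overlap
(|shared clones| / |union of clones| per repetition, Jaccard by default),
computed on clones clustered jointly across both timepoints.

**Proteome matching.** Translated BL + FUP6 VH sequences form one
patient-specific protein database; in-silico tryptic peptides and observed
peptide lists (DDA FDR ≤ 0.1, DIA FDR ≤ 0.01) are exact-substring mapped, and
a VH protein counts as serum-detected when uniquely mapping peptides cover
≥ 30 % of its CDR3 span.

**Group statistics.** Paired Wilcoxon signed-rank (exact for small samples),
Mann–Whitney U, Kruskal–Wallis with Dunn's Bonferroni post hoc, and
Benjamini–Hochberg adjustment, driven by a declarative comparison plan.

## Worked example

```python
from igrep import default_config, PipelineConfig
from igrep.pipeline import run_pipeline

res = run_pipeline(default_config(seed=1), PipelineConfig(seed=1))

m = res["metrics"]
bl = m[(m.timepoint == "BL") & (m.metric.isin(
    ["diversity_q0", "diversity_q1", "pct_clones_gt50", "mean_shm_freq"]))]
print(bl.pivot(index="cell_subset", columns="metric", values="value").round(3))
```

prints, for one simulated subject at baseline:

```
metric       diversity_q0  diversity_q1  mean_shm_freq  pct_clones_gt50
cell_subset
DN                 44.320        27.202          0.039            3.356
M                  64.285        42.095          0.058            0.505
N                 102.515        96.060          0.000            0.000
P                  26.190        13.626          0.067            7.595
```

Read this as: naive cells are diverse (bootstrap richness ⁰D ≈ 103 of at most
126) and unmutated; double-negative cells and plasmablasts are clonally
expanded (low ⁰D and ¹D, a visible fraction of clones with > 50 unique
members) and carry SHM near their simulated rates (0.04 / 0.07). The same run
yields per-subset BL↔FUP6 overlaps of 0.02 %–1.2 % (`res["overlap"]`) — the
low clone-retention regime the generator emulates — and a proteome report
(`res["proteome_report"]`) in which 1192 of 4370 database VH proteins are
covered ≥ 30 % on the CDR3 by uniquely mapping peptides.

The same stages are exposed on the command line:

```sh
igrep simulate --seed 1 --out data/
igrep consensus --fastq data/reads_BL.fastq.gz --manifest data/manifest_BL.tsv --out unique.tsv
igrep annotate --in unique.tsv --out annotated.tsv
igrep clones --in annotated.tsv --out clones.tsv
igrep stats --in clones.tsv --seed 1 --out metrics.tsv
igrep proteome --bl clones.tsv --peptides data/peptides.tsv --mode DIA --out matches.tsv
igrep run --seed 1 --out results/          # all of the above in one step
```

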